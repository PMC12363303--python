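"""Core in-memory containers shared by the analysis modules.

Axis convention
---------------
Volumes are indexed ``(i, j, k)`` where axes 0 and 1 are the two lateral
(skin-parallel) directions and axis 2 is depth, increasing *into* the
animal: ``k = 0`` is exterior air, large ``k`` is deep tissue.  Voxel
centres sit at ``(index + 0.5) * spacing`` millimetres, so a grid of shape
``(nx, ny, nz)`` with spacing ``(dx, dy, dz)`` spans ``nx*dx`` mm laterally
and ``nz*dz`` mm in depth.  Anisotropic spacing (e.g. thick CT slices along
one axis) is supported everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError


@dataclass
class CTVolume:
    """A 3-D CT-like scalar volume with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Intensities on a Hounsfield-unit-like scale (air ~ -1000, soft
        tissue ~ 0-100, iodinated contrast >> 1000).
    spacing : (float, float, float)
        Voxel edge lengths in mm along each array axis; all positive.
    origin : (float, float, float)
        Physical offset of the grid corner, mm.
    acquisition_time_s : float or None
        Scan time relative to injection start, seconds.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    acquisition_time_s: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("CTVolume requires a non-empty 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class BlebMask:
    """Boolean segmentation mask congruent with its source volume."""

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class BlebMorphometry:
    """Ellipsoid-approximation morphometry of one segmented bleb.

    ``a >= b >= c`` are the semi-axes in mm (half the axis-aligned extents
    of the mask), ``surface_area_mm2`` the ellipsoid-formula surface area,
    and ``volume_ml`` the voxel-counting volume of the mask.
    """

    a_mm: float
    b_mm: float
    c_mm: float
    surface_area_mm2: float
    volume_ml: float
    time_s: float | None = None


@dataclass
class SkinSurface:
    """Skin surface as a depth map over the two lateral axes.

    ``depth_mm[i, j]`` is the depth (mm from the exterior face, along axis
    2) of the first tissue voxel in lateral column ``(i, j)``; NaN where a
    column contains no tissue.  Distension raises the skin, i.e. *reduces*
    the depth, so protrusion height = pre depth - post depth.
    """

    depth_mm: np.ndarray
    lateral_spacing: tuple[float, float]
    depth_spacing: float

    def __post_init__(self):
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        if self.depth_mm.ndim != 2:
            raise ValueError("depth map must be 2-D")


@dataclass
class DistensionMeasurement:
    """Half-ellipsoid model of the skin region raised above its pre-injection
    surface: lateral semi-axes ``a, b``, peak height ``c`` (all mm) and the
    half-ellipsoid volume (2/3)pi*a*b*c in mL."""

    a_mm: float
    b_mm: float
    c_mm: float
    volume_ml: float
    time_s: float | None = None


@dataclass
class PressureTrace:
    """Uniformly sampled subcutaneous pressure recording.

    ``time_s`` must be strictly increasing and uniform to within 1% of the
    nominal sample period; pressures are kPa.  Optional markers record when
    the pump started and stopped.
    """

    time_s: np.ndarray
    pressure_kpa: np.ndarray
    rate_hz: float
    t_start_s: float | None = None
    t_cess_s: float | None = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.pressure_kpa = np.asarray(self.pressure_kpa, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.pressure_kpa.shape:
            raise ValueError("time and pressure must be 1-D arrays of equal length")
        if self.time_s.size >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise ValueError(f"time not strictly increasing at sample {row}")
            nominal = 1.0 / self.rate_hz
            if np.any(np.abs(dt - nominal) > 0.01 * nominal):
                row = int(np.argmax(np.abs(dt - nominal) > 0.01 * nominal)) + 1
                raise ValueError(
                    f"sampling not uniform at {self.rate_hz} Hz near sample {row}")

    @property
    def n_samples(self) -> int:
        return self.time_s.size


@dataclass
class InjectionProtocol:
    """Pump programme for one injection: total volume (mL), constant flow
    rate (mL/min), and whether hyaluronidase (HLN) was co-formulated."""

    volume_ml: float
    flow_rate_ml_min: float
    hln: bool = False
    hln_conc_u_ml: float | None = None

    def __post_init__(self):
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be positive")
        if self.flow_rate_ml_min <= 0:
            raise ValueError("flow_rate_ml_min must be positive")

    @property
    def duration_s(self) -> float:
        """Infusion duration implied by volume / flow rate, in seconds."""
        return self.volume_ml / self.flow_rate_ml_min * 60.0


@dataclass
class DecayFit:
    """Result of the post-injection double-exponential pressure-decay fit.

    Model: ``P(tau) = baseline + A1*exp(-k1*tau) + A2*exp(-k2*tau)`` with
    ``tau`` measured from the detected peak.  Components are ordered so
    ``k1 >= k2``.  ``keff`` is the amplitude-weighted mean rate constant
    ``(A1*k1 + A2*k2) / (A1 + A2)``.
    """

    A1_kpa: float
    A2_kpa: float
    k1_per_s: float
    k2_per_s: float
    keff_per_s: float
    baseline_kpa: float
    rss_kpa2: float
    converged: bool
    t_peak_s: float | None = None
    n_samples: int | None = None

    def __post_init__(self):
        if self.k1_per_s < self.k2_per_s:
            raise ValueError("components must be ordered k1 >= k2")

    @property
    def identifiable(self) -> bool:
        """False when both amplitudes vanished (flat trace: no decay to fit).

        Amplitudes below 1e-9 kPa (a micro-pascal) are numerically zero.
        """
        return (self.A1_kpa + self.A2_kpa) > 1e-9


def require(condition: bool, message: str, exc=AnalysisError):
    if not condition:
        raise exc(message)
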