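"""Ground-truth-labelled synthetic CT phantoms and simulated pressure traces.

The study design this package targets — timed CT of a contrast-loaded
subcutaneous injection bleb plus an inline pressure recording — left no
public data, so every downstream stage is exercised against phantoms built
here.  The anatomy is reduced to flat slabs stacked along the depth axis
(exterior air, a skin layer, a subcutaneous layer, deep tissue), with

* an ellipsoidal high-contrast bleb rasterized into the subcutaneous layer
  (the injectate, an iodinated-contrast surrogate at very high HU), and
* a half-ellipsoidal skin bulge: the skin surface height field is raised by
  the cap's profile, so post-injection tissue exists above the original
  surface exactly where the ground truth says.

Bleb axes can grow over the scan schedule via a saturating-growth model
with a hyaluronidase (HLN) factor that amplifies lateral spread and
flattens the cap, mirroring the enzyme's effect on dispersion.  Pressure
traces ramp up during the infusion, peak at pump cessation and then decay
as a two-component exponential — the same generative form the analysis
fits.

All randomness is driven by explicit integer seeds; identical spec + seed
gives bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import GeometryError
from .types import CTVolume, InjectionProtocol, PressureTrace

AIR_HU = -1000.0


@dataclass
class PhantomSpec:
    """Everything needed to rasterize one pre/post phantom pair.

    Lengths are mm, intensities HU.  ``bleb_center`` is in physical
    coordinates (axis order matching the grid; axis 2 = depth).  The skin
    surface sits at depth ``skin_depth_mm``; above it is air, below it a
    ``skin_thickness_mm`` skin slab, then subcutaneous tissue at
    ``background_hu`` down to ``subcut_thickness_mm``, then a deep slab.
    """

    grid_shape: tuple[int, int, int] = (72, 64, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_hu: float = 50.0
    skin_hu: float = 300.0
    contrast_hu: float = 3000.0
    bleb_center: tuple[float, float, float] = (36.0, 32.0, 20.0)
    bleb_axes: tuple[float, float, float] = (16.0, 12.0, 5.6)
    cap_axes: tuple[float, float, float] = (12.0, 10.0, 3.5)
    noise_sd: float = 0.0
    seed: int = 0
    skin_depth_mm: float = 8.0
    skin_thickness_mm: float = 2.0
    subcut_thickness_mm: float = 25.0
    deep_hu: float = 80.0

    def __post_init__(self):
        if any(a <= 0 for a in self.bleb_axes):
            raise ValueError("bleb semi-axes must all be positive")
        if any(a < 0 for a in self.cap_axes):
            raise ValueError("cap semi-axes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.contrast_hu <= self.background_hu + 5 * self.noise_sd:
            raise ValueError(
                "bleb not separable: contrast_hu must exceed background_hu "
                "+ 5*noise_sd")
        _check_containment(self)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.spacing))


@dataclass
class DispersionModel:
    """Saturating growth of the bleb semi-axes over the scan schedule.

    Axis ``i`` at time ``t`` is ``initial + gain_i * amp_i * (1 - exp(-t/tau))``
    where ``gain_i`` is ``hln_factor`` for the two lateral axes and 1 for
    depth.  ``hln_factor >= 1`` models hyaluronidase-enhanced lateral
    dispersion; the skin cap's height is divided by the same factor
    (enhanced spread flattens the bulge).  Growth is monotone, so the
    rasterized bleb volume is non-decreasing along the schedule.
    """

    initial_axes: tuple[float, float, float]
    growth_mm: tuple[float, float, float] = (3.0, 3.0, 0.5)
    tau_s: float = 120.0
    hln_factor: float = 1.0

    def __post_init__(self):
        if self.hln_factor < 1.0:
            raise ValueError("hln_factor must be >= 1 (use 1.0 for no HLN)")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if any(g < 0 for g in self.growth_mm):
            raise ValueError("growth amplitudes must be non-negative")

    def axes_at(self, t_s: float) -> tuple[float, float, float]:
        g = 1.0 - np.exp(-t_s / self.tau_s)
        da, db, dc = self.growth_mm
        a0, b0, c0 = self.initial_axes
        return (a0 + self.hln_factor * da * g,
                b0 + self.hln_factor * db * g,
                c0 + dc * g)

    def cap_axes_for(self, spec: PhantomSpec) -> tuple[float, float, float]:
        a, b, c = spec.cap_axes
        return (a, b, c / self.hln_factor)


@dataclass
class PressureSimSpec:
    """Generative model for one simulated pressure recording.

    During the infusion the pressure rises from ``baseline_kpa`` to
    ``baseline + A1 + A2`` at pump cessation — linearly by default
    (constant-flow pump), or with first-order kinetics (``rise_model =
    'first_order'``, time constant ``rise_tau_s``) to mimic the slower
    early rise of an inline sensor.  After cessation it decays as
    ``baseline + A1*exp(-k1*t') + A2*exp(-k2*t')`` with ``t'`` measured
    from cessation, plus i.i.d. Gaussian noise.
    """

    protocol: InjectionProtocol
    baseline_kpa: float = 0.0
    A1_kpa: float = 10.0
    A2_kpa: float = 5.0
    k1_per_s: float = 0.5
    k2_per_s: float = 0.05
    noise_sd: float = 0.0
    rate_hz: float = 10.0
    duration_s: float = 180.0
    t_start_s: float = 0.0
    rise_model: str = "linear"
    rise_tau_s: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not (self.k1_per_s >= self.k2_per_s > 0):
            raise ValueError("rate constants must satisfy k1 >= k2 > 0")
        if self.A1_kpa < 0 or self.A2_kpa < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.rise_model not in ("linear", "first_order"):
            raise ValueError("rise_model must be 'linear' or 'first_order'")
        if self.duration_s <= self.t_start_s + self.protocol.duration_s + 120.0:
            raise ValueError(
                "duration_s must exceed the infusion end by more than the "
                "120 s decay-analysis window")


@dataclass
class PhantomTruth:
    """Ground truth attached to one rasterized phantom."""

    bleb_center_mm: tuple[float, float, float]
    bleb_axes_mm: tuple[float, float, float]
    cap_axes_mm: tuple[float, float, float]
    skin_depth_mm: float
    bleb_mask: np.ndarray
    bleb_voxel_volume_ml: float
    bleb_analytic_volume_ml: float
    cap_analytic_volume_ml: float

    def to_json_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "bleb_mask"}
        d["bleb_voxel_count"] = int(self.bleb_mask.sum())
        return d


def _check_containment(spec: PhantomSpec):
    """Reject blebs or caps that would be clipped by the grid."""
    ext = [n * s for n, s in zip(spec.grid_shape, spec.spacing)]
    c, ax = spec.bleb_center, spec.bleb_axes
    for i in range(3):
        if c[i] - ax[i] < 0 or c[i] + ax[i] > ext[i]:
            raise GeometryError(
                f"bleb extends outside grid along axis {i}: centre {c[i]} mm, "
                f"semi-axis {ax[i]} mm, extent {ext[i]} mm")
    if c[2] - ax[2] < spec.skin_depth_mm:
        raise GeometryError("bleb reaches above the skin surface")
    ca, cb, cc = spec.cap_axes
    if cc > 0:
        if cc > spec.skin_depth_mm:
            raise GeometryError(
                f"cap height {cc} mm exceeds air gap above skin "
                f"({spec.skin_depth_mm} mm)")
        for i, semi in enumerate((ca, cb)):
            if c[i] - semi < 0 or c[i] + semi > ext[i]:
                raise GeometryError(f"cap extends outside grid along axis {i}")


def _voxel_centers(spec: PhantomSpec):
    return [
        (np.arange(n) + 0.5) * s
        for n, s in zip(spec.grid_shape, spec.spacing)
    ]


def _rasterize_bleb(spec: PhantomSpec,
                    axes: tuple[float, float, float]) -> np.ndarray:
    x, y, z = _voxel_centers(spec)
    cx, cy, cz = spec.bleb_center
    a, b, c = axes
    u = ((x - cx) / a) ** 2
    v = ((y - cy) / b) ** 2
    w = ((z - cz) / c) ** 2
    return (u[:, None, None] + v[None, :, None] + w[None, None, :]) <= 1.0


def _base_anatomy(spec: PhantomSpec) -> np.ndarray:
    """Noiseless layered-slab pre-injection volume."""
    _, _, z = _voxel_centers(spec)
    col = np.full(spec.grid_shape[2], AIR_HU)
    skin = (z >= spec.skin_depth_mm) & (
        z < spec.skin_depth_mm + spec.skin_thickness_mm)
    subq_top = spec.skin_depth_mm + spec.skin_thickness_mm
    subq = (z >= subq_top) & (z < subq_top + spec.subcut_thickness_mm)
    deep = z >= subq_top + spec.subcut_thickness_mm
    col[skin] = spec.skin_hu
    col[subq] = spec.background_hu
    col[deep] = spec.deep_hu
    return np.broadcast_to(
        col, spec.grid_shape).copy()


def _apply_cap(values: np.ndarray, spec: PhantomSpec,
               cap_axes: tuple[float, float, float]):
    """Raise the skin surface in-place by the cap's half-ellipsoid profile."""
    ca, cb, cc = cap_axes
    if cc <= 0 or ca <= 0 or cb <= 0:
        return
    x, y, z = _voxel_centers(spec)
    cx, cy, _ = spec.bleb_center
    r2 = (((x - cx) / ca) ** 2)[:, None] + (((y - cy) / cb) ** 2)[None, :]
    lift = np.zeros_like(r2)
    inside = r2 < 1.0
    lift[inside] = cc * np.sqrt(1.0 - r2[inside])
    # Voxels whose centre lies between the lifted and the original surface
    # become skin tissue: the bulge is a vertical shift of the surface.
    new_surface = spec.skin_depth_mm - lift
    raised = (z[None, None, :] >= new_surface[:, :, None]) & \
             (z[None, None, :] < spec.skin_depth_mm)
    values[raised] = spec.skin_hu


def _ellipsoid_volume_mm3(axes) -> float:
    a, b, c = axes
    return 4.0 / 3.0 * np.pi * a * b * c


def _build_truth(spec: PhantomSpec, axes, cap_axes,
                 bleb_mask: np.ndarray) -> PhantomTruth:
    vox = float(np.prod(spec.spacing))
    ca, cb, cc = cap_axes
    return PhantomTruth(
        bleb_center_mm=tuple(spec.bleb_center),
        bleb_axes_mm=tuple(axes),
        cap_axes_mm=tuple(cap_axes),
        skin_depth_mm=spec.skin_depth_mm,
        bleb_mask=bleb_mask,
        bleb_voxel_volume_ml=bleb_mask.sum() * vox / 1000.0,
        bleb_analytic_volume_ml=_ellipsoid_volume_mm3(axes) / 1000.0,
        cap_analytic_volume_ml=2.0 / 3.0 * np.pi * ca * cb * cc / 1000.0,
    )


def _noise(spec: PhantomSpec, stream: int) -> np.ndarray | float:
    """Seeded Gaussian HU noise; stream 0 is the pre scan, stream i>=1 the
    i-th post scan, so pair and series generation agree sample for sample."""
    if spec.noise_sd == 0:
        return 0.0
    rng = np.random.default_rng([spec.seed, stream])
    return rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)


def _make_post(spec: PhantomSpec, axes, cap_axes, stream: int,
               pre_clean: np.ndarray, time_s: float | None):
    bleb = _rasterize_bleb(spec, axes)
    post = pre_clean.copy()
    post[bleb] = spec.contrast_hu
    _apply_cap(post, spec, cap_axes)
    vol = CTVolume(post + _noise(spec, stream), spec.spacing,
                   acquisition_time_s=time_s)
    return vol, _build_truth(spec, axes, cap_axes, bleb)


def generate_phantom_pair(spec: PhantomSpec):
    """Rasterize one pre/post scan pair.

    Returns ``(pre, post, truth)``: the pre-injection layered volume, the
    post-injection volume (bleb filled with contrast, skin raised by the
    cap), and the :class:`PhantomTruth` record.  Gaussian noise of
    ``spec.noise_sd`` HU is added independently to both scans from
    ``spec.seed``.
    """
    pre_clean = _base_anatomy(spec)
    pre = CTVolume(pre_clean + _noise(spec, 0), spec.spacing,
                   acquisition_time_s=None)
    post, truth = _make_post(spec, spec.bleb_axes, spec.cap_axes, 1,
                             pre_clean, None)
    return pre, post, truth


def generate_phantom_series(spec: PhantomSpec, model: DispersionModel,
                            times_s):
    """Rasterize a timed post-injection series with growing bleb axes.

    Returns ``(pre, frames)`` where ``frames`` is a list of
    ``(time_s, CTVolume, PhantomTruth)``, one per scheduled scan time.  Bleb
    axes follow ``model.axes_at(t)``; the cap is held at the HLN-adjusted
    spec value.  Times must be non-negative and strictly increasing; growth
    pushing the bleb outside the grid is rejected up front.
    """
    times_s = list(times_s)
    if not times_s:
        raise ValueError("times_s must be non-empty")
    if times_s[0] < 0 or any(b <= a for a, b in zip(times_s, times_s[1:])):
        raise ValueError("times_s must be non-negative and strictly increasing")
    cap = model.cap_axes_for(spec)
    for t in times_s:  # containment at every scheduled time, incl. the last
        _check_containment(
            _spec_with(spec, bleb_axes=model.axes_at(t), cap_axes=cap))
    pre_clean = _base_anatomy(spec)
    pre = CTVolume(pre_clean + _noise(spec, 0), spec.spacing)
    frames = []
    for i, t in enumerate(times_s):
        vol, truth = _make_post(spec, model.axes_at(t), cap, i + 1,
                                pre_clean, t)
        frames.append((t, vol, truth))
    return pre, frames


def _spec_with(spec: PhantomSpec, **overrides) -> PhantomSpec:
    d = asdict(spec)
    d.update(overrides)
    return PhantomSpec(**d)


def generate_pressure_trace(spec: PressureSimSpec) -> PressureTrace:
    """Simulate one subcutaneous pressure recording.

    The noiseless trace is continuous at cessation by construction: the
    rise model reaches ``baseline + A1 + A2`` exactly at the cessation
    time, where the double-exponential decay starts at the same value.
    """
    proto = spec.protocol
    t_cess = spec.t_start_s + proto.duration_s
    n = int(round(spec.duration_s * spec.rate_hz))
    t = np.arange(n) / spec.rate_hz
    peak = spec.A1_kpa + spec.A2_kpa
    p = np.full(n, spec.baseline_kpa)

    rising = (t >= spec.t_start_s) & (t <= t_cess)
    tr = t[rising] - spec.t_start_s
    dur = proto.duration_s
    if spec.rise_model == "linear":
        p[rising] += peak * tr / dur
    else:
        norm = 1.0 - np.exp(-dur / spec.rise_tau_s)
        p[rising] += peak * (1.0 - np.exp(-tr / spec.rise_tau_s)) / norm

    decaying = t > t_cess
    tau = t[decaying] - t_cess
    p[decaying] += (spec.A1_kpa * np.exp(-spec.k1_per_s * tau)
                    + spec.A2_kpa * np.exp(-spec.k2_per_s * tau))

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        p = p + rng.normal(0.0, spec.noise_sd, size=n)

    return PressureTrace(t, p, spec.rate_hz,
                         t_start_s=spec.t_start_s, t_cess_s=t_cess)


def save_phantom(out_dir, pre: CTVolume, frames_or_post, spec: PhantomSpec,
                 truths=None):
    """Write a phantom pair or series as NIfTI volumes + JSON truth/spec.

    ``frames_or_post`` is either a single post :class:`CTVolume` (with
    ``truths`` a single :class:`PhantomTruth`) or a list of
    ``(time, volume, truth)`` frames from :func:`generate_phantom_series`.
    """
    from . import io as bio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bio.save_volume(pre, out / "pre.nii.gz")
    records = []
    if isinstance(frames_or_post, CTVolume):
        frames = [(0.0, frames_or_post, truths)]
    else:
        frames = frames_or_post
    for i, (t, vol, truth) in enumerate(frames):
        name = f"post_{i:02d}_t{int(round(t)):04d}s"
        bio.save_volume(vol, out / f"{name}.nii.gz")
        rec = truth.to_json_dict()
        rec["time_s"] = t
        rec["file"] = f"{name}.nii.gz"
        records.append(rec)
    meta = {"spec": asdict(spec), "frames": records}
    (out / "truth.json").write_text(json.dumps(meta, indent=2))
    return out
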