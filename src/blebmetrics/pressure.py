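"""Subcutaneous pressure-trace analysis.

A constant-flow pump drives pressure up during the infusion; once flow
stops the pressure relaxes as fluid redistributes through the
subcutaneous matrix.  The analysis pipeline is:

1. ``cessation_time`` — the pump stop time follows from the protocol:
   ``t_start + volume / flow_rate`` (e.g. 4.5 mL at 10 mL/min -> 27 s).
2. ``max_pressure`` — peak pressure within a symmetric closed window
   (default +/- 2 s) around cessation.
3. ``fit_decay`` — nonlinear least squares of a two-component exponential
   ``P(tau) = baseline + A1 exp(-k1 tau) + A2 exp(-k2 tau)`` over the two
   minutes after the peak, with non-negative amplitudes and positive rate
   constants; a fast component (tissue/line elasticity) and a slow one
   (fluid redistribution).
4. ``effective_decay_constant`` — the single-number summary
   ``keff = (A1 k1 + A2 k2) / (A1 + A2)``, the amplitude-weighted mean
   rate, which always lies between k1 and k2.

Initialisation uses curve peeling (log-linear fit of the tail for the slow
component, of the early residual for the fast one) with a handful of
seeded, jittered restarts, the standard reproducible strategy for
multi-exponential fitting.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import AnalysisError, FitError, TraceFormatError
from .types import DecayFit, InjectionProtocol, PressureTrace
from .units import pressure_to_kpa


def cessation_time(protocol: InjectionProtocol, t_start_s: float = 0.0) -> float:
    """Pump stop time implied by the protocol: start + volume/rate."""
    return t_start_s + protocol.duration_s


def max_pressure(trace: PressureTrace, t_cess_s: float,
                 window_s: float = 2.0) -> tuple[float, float]:
    """Peak pressure (kPa) and its time within ``[t_cess - w, t_cess + w]``.

    The window is closed on both sides; ties are broken by the earliest
    sample.  A window extending beyond the recording is an error.
    """
    lo, hi = t_cess_s - window_s, t_cess_s + window_s
    if lo < trace.time_s[0] - 1e-9 or hi > trace.time_s[-1] + 1e-9:
        raise AnalysisError(
            f"peak-search window [{lo:g}, {hi:g}] s extends beyond the "
            f"recording [{trace.time_s[0]:g}, {trace.time_s[-1]:g}] s")
    sel = (trace.time_s >= lo - 1e-9) & (trace.time_s <= hi + 1e-9)
    idx = np.flatnonzero(sel)
    best = idx[np.argmax(trace.pressure_kpa[idx])]  # argmax -> earliest tie
    return float(trace.pressure_kpa[best]), float(trace.time_s[best])


def _decay_model(params, tau):
    a1, k1, a2, k2, base = params
    return base + a1 * np.exp(-k1 * tau) + a2 * np.exp(-k2 * tau)


def _peel_initial(tau, p):
    """Curve-peeling start values (A1, k1, A2, k2, baseline).

    The baseline is seeded a little *below* the window minimum so the tail
    residual stays strictly positive and log-linear; the slow component is
    peeled from the 50-90% segment of the window (late enough for the fast
    component to have died, early enough that the residual is not noise),
    the fast one from the early residual.
    """
    span = float(p.max() - p.min())
    base0 = float(p.min()) - 0.05 * max(span, 1e-9)
    resid = np.clip(p - base0, 1e-12, None)
    n = len(tau)
    lo, hi = int(0.5 * n), max(int(0.9 * n), int(0.5 * n) + 2)
    k2, a2 = _loglinear(tau[lo:hi], resid[lo:hi])
    early = np.clip(resid[:max(n // 4, 2)]
                    - a2 * np.exp(-k2 * tau[:max(n // 4, 2)]), 1e-12, None)
    k1, a1 = _loglinear(tau[:max(n // 4, 2)], early)
    k1 = max(k1, k2 * 1.5, 1e-3)
    return np.array([max(a1, 1e-6), k1, max(a2, 1e-6), max(k2, 1e-4), base0])


def _loglinear(tau, y):
    slope, intercept = np.polyfit(tau, np.log(y), 1)
    return max(-slope, 1e-4), float(np.exp(intercept))


def fit_decay(trace: PressureTrace, t_cess_s: float,
              fit_window_s: float = 120.0, peak_window_s: float = 2.0,
              baseline: float | None = None, clock: str = "peak",
              n_restarts: int = 5, restart_seed: int = 0,
              min_samples: int = 50) -> DecayFit:
    """Fit the post-injection double-exponential pressure decay.

    The fit clock ``tau`` starts at the detected peak (``clock='peak'``,
    default) or at nominal cessation (``clock='cessation'``); samples with
    ``0 <= tau <= fit_window_s`` enter the fit (the peak sample itself
    anchors the total amplitude A1 + A2).  ``baseline`` pins the
    offset term; by default it is estimated jointly (free), which makes the
    model well-posed on gauges with a nonzero resting offset.

    Raises :class:`FitError` (carrying the best candidate) if no restart
    converges; a flat trace converges to A1 = A2 = 0 and is flagged via
    ``DecayFit.identifiable``.
    """
    peak_p, t_peak = max_pressure(trace, t_cess_s, peak_window_s)
    # decay starts once the pump has stopped AND the peak has passed: a
    # noise-inflated peak detected before cessation must not drag rising-
    # phase samples into the decay fit
    t0 = max(t_peak, t_cess_s) if clock == "peak" else t_cess_s
    sel = (trace.time_s >= t0 - 1e-9) & (trace.time_s <= t0 + fit_window_s + 1e-9)
    tau = trace.time_s[sel] - t0
    p = trace.pressure_kpa[sel]
    if tau.size < min_samples:
        raise AnalysisError(
            f"only {tau.size} samples in the {fit_window_s:g} s fit window "
            f"(need >= {min_samples})")

    x0 = _peel_initial(tau, p)
    fixed_base = baseline is not None
    if fixed_base:
        x0[4] = baseline

    lower = np.array([0.0, 1e-6, 0.0, 1e-6, -np.inf])
    upper = np.array([np.inf, np.inf, np.inf, np.inf, np.inf])
    if fixed_base:
        lower[4], upper[4] = baseline - 1e-12, baseline + 1e-12

    rng = np.random.default_rng(restart_seed)
    best = None
    for attempt in range(n_restarts + 1):
        start = x0.copy()
        if attempt > 0:  # jittered multiplicative restarts, seeded
            start[:4] = x0[:4] * np.exp(rng.normal(0.0, 0.3, size=4))
            start = np.clip(start, lower + 1e-12, None)
        res = least_squares(lambda q: _decay_model(q, tau) - p, start,
                            bounds=(lower, upper), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, res)
    rss, res = best
    a1, k1, a2, k2, base = res.x
    if k1 < k2:  # order components fast-first
        a1, k1, a2, k2 = a2, k2, a1, k1
    amp = a1 + a2
    keff = (a1 * k1 + a2 * k2) / amp if amp > 0 else np.nan
    fit = DecayFit(A1_kpa=float(a1), A2_kpa=float(a2),
                   k1_per_s=float(k1), k2_per_s=float(k2),
                   keff_per_s=float(keff), baseline_kpa=float(base),
                   rss_kpa2=rss, converged=bool(res.success),
                   t_peak_s=t_peak, n_samples=int(tau.size))
    if not res.success:
        raise FitError("decay fit did not converge in any restart", best=fit)
    return fit


def effective_decay_constant(fit: DecayFit) -> float:
    """Amplitude-weighted mean rate constant (1/s).

    ``keff = (A1*k1 + A2*k2) / (A1 + A2)``; undefined (error) when both
    amplitudes are zero.
    """
    amp = fit.A1_kpa + fit.A2_kpa
    if amp <= 0:
        raise AnalysisError("keff undefined: A1 + A2 = 0 (flat trace)")
    return (fit.A1_kpa * fit.k1_per_s + fit.A2_kpa * fit.k2_per_s) / amp


# ---------------------------------------------------------------------------
# Trace I/O: 2-column CSV (time_s, pressure_kpa) + optional JSON sidecar
# holding injection markers, units and provenance.

def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_trace(trace: PressureTrace, path, spec: dict | None = None) -> Path:
    """Write a trace as CSV plus a JSON sidecar with markers (and,
    optionally, the generating spec)."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.time_s,
                  "pressure_kpa": trace.pressure_kpa}).to_csv(
        path, index=False, float_format="%.10g")
    side = {"units": "kpa", "rate_hz": trace.rate_hz,
            "t_start_s": trace.t_start_s, "t_cess_s": trace.t_cess_s}
    if spec is not None:
        side["spec"] = spec
    _sidecar_path(path).write_text(json.dumps(side, indent=2))
    return path


def read_trace(path, units: str | None = None) -> PressureTrace:
    """Read a pressure trace from CSV (+ sidecar if present).

    ``units`` overrides the sidecar's unit label ('kpa', 'psi', 'mmhg');
    values are converted to kPa on read.  Non-monotone or non-uniform
    timestamps and NaNs fail with the offending row index.
    """
    path = Path(path)
    table = pd.read_csv(path)
    cols = {c.lower(): c for c in table.columns}
    tcol = next((cols[c] for c in cols if c.startswith("time")), None)
    pcol = next((cols[c] for c in cols if c.startswith("pressure")), None)
    if tcol is None or pcol is None:
        raise TraceFormatError(
            f"need time/pressure columns, found {list(table.columns)}")
    t = table[tcol].to_numpy(dtype=float)
    p = table[pcol].to_numpy(dtype=float)
    for name, arr in (("time", t), ("pressure", p)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise TraceFormatError(f"non-finite {name} value", row=int(bad[0]))
    side = {}
    if _sidecar_path(path).exists():
        side = json.loads(_sidecar_path(path).read_text())
    if units is None:
        units = side.get("units")
        if units is None:
            # bare CSV without sidecar: infer from the column name, else kPa
            units = "kpa"
            for u in ("psi", "mmhg"):
                if u in pcol.lower():
                    units = u
    p = pressure_to_kpa(p, units)
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise TraceFormatError("time not strictly increasing",
                               row=int(bad[0]) + 1)
    rate = side.get("rate_hz") or 1.0 / float(np.median(dt))
    try:
        return PressureTrace(t, p, rate_hz=rate,
                             t_start_s=side.get("t_start_s"),
                             t_cess_s=side.get("t_cess_s"))
    except ValueError as exc:
        raise TraceFormatError(str(exc)) from exc


def analyze_trace(trace: PressureTrace, protocol: InjectionProtocol,
                  t_start_s: float | None = None, **fit_kwargs) -> dict:
    """Full single-trace analysis -> JSON-ready record.

    Uses the trace's embedded start marker unless ``t_start_s`` overrides
    it; computes cessation from the protocol, the peak within 2 s, the
    decay fit and keff.
    """
    if t_start_s is None:
        t_start_s = trace.t_start_s if trace.t_start_s is not None else 0.0
    t_cess = cessation_time(protocol, t_start_s)
    peak, t_peak = max_pressure(trace, t_cess)
    fit = fit_decay(trace, t_cess, **fit_kwargs)
    rec = asdict(fit)
    rec.update(max_pressure_kpa=peak, t_peak_s=t_peak, t_cess_s=t_cess,
               volume_ml=protocol.volume_ml,
               flow_rate_ml_min=protocol.flow_rate_ml_min)
    return rec
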