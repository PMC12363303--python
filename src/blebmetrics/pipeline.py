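"""In-silico replication of the full injection study design.

The study design: two injection volumes (4.5 and 9 mL at 10 mL/min), each
with and without co-formulated hyaluronidase (HLN), n = 3 replicates per
arm, CT scans at baseline, 5, 30, 60, 90, 120, 180 and 600 s plus a
continuous pressure recording.  ``run_experiment`` generates each
replicate synthetically, runs the full analysis chain and aggregates four
endpoints per replicate:

* bleb surface area at the 600 s scan (10 min post-injection),
* skin-distension volume averaged over the 90-120 s window,
* peak pressure within 2 s of cessation,
* effective pressure-decay constant keff.

Group statistics follow the original reporting: per-arm mean +/- sample
s.d., and two-sided two-sample Student's t-tests (pooled variance,
alpha = 0.05) comparing +/- HLN within each volume.  A Welch variant is
available behind a flag.  Everything is reproducible from the configured
seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import distension as dist
from . import morphometry as morpho
from . import pressure as press
from .errors import AnalysisError
from .synthdata import (DispersionModel, PhantomSpec, PressureSimSpec,
                        generate_phantom_series, generate_pressure_trace)
from .types import InjectionProtocol

#: CT scan schedule (s relative to injection start).
DEFAULT_SCAN_TIMES_S = [0.0, 5.0, 30.0, 60.0, 90.0, 120.0, 180.0, 600.0]


@dataclass
class Arm:
    volume_ml: float
    hln: bool
    n: int = 3


@dataclass
class ExperimentConfig:
    """Study configuration plus generator and analysis settings.

    The phantom/pressure parameters below are the templates from which each
    arm's generator specs are derived; injection volume scales the bleb and
    cap linearly in volume, HLN multiplies lateral dispersion by
    ``hln_dispersion_factor`` (flattening the cap by the same factor) and
    pressure amplitudes by ``hln_pressure_factor``.
    """

    arms: list[Arm] = field(default_factory=lambda: [
        Arm(4.5, False), Arm(4.5, True), Arm(9.0, False), Arm(9.0, True)])
    scan_times_s: list[float] = field(
        default_factory=lambda: list(DEFAULT_SCAN_TIMES_S))
    base_seed: int = 0
    # phantom template (see synthdata.PhantomSpec for geometry semantics)
    grid_shape: tuple[int, int, int] = (72, 64, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    contrast_hu: float = 3000.0
    background_hu: float = 50.0
    noise_sd_hu: float = 20.0
    base_bleb_axes: tuple[float, float, float] = (16.0, 12.0, 5.6)
    base_cap_axes: tuple[float, float, float] = (12.0, 10.0, 3.5)
    growth_mm: tuple[float, float, float] = (3.0, 3.0, 0.5)
    growth_tau_s: float = 120.0
    hln_dispersion_factor: float = 1.5
    # pressure template
    flow_rate_ml_min: float = 10.0
    base_A1_kpa: float = 10.0
    base_A2_kpa: float = 5.0
    k1_per_s: float = 0.4
    k2_per_s: float = 0.04
    pressure_noise_sd_kpa: float = 0.1
    pressure_baseline_kpa: float = 2.0
    hln_pressure_factor: float = 0.6
    #: Inter-replicate (inter-animal) variability: lognormal coefficient of
    #: variation applied per replicate to bleb/cap axes and pressure
    #: amplitudes.  Small relative to the HLN effect, mirroring a design
    #: where n = 3 per arm suffices for significance.
    replicate_cv: float = 0.02
    # analysis settings
    threshold: float | str = "auto"
    min_height_mm: float = 0.5
    distension_window_s: tuple[float, float] = (90.0, 120.0)
    alpha: float = 0.05
    welch: bool = False

    def __post_init__(self):
        if len({(a.volume_ml, a.hln) for a in self.arms}) != len(self.arms):
            raise ValueError("duplicate arms in config")

    def replicate_seed(self, arm_index: int, replicate: int) -> int:
        """Unique, reproducible per-replicate seed (< 2^31)."""
        return (self.base_seed * 1_000_003 + arm_index * 1_009
                + replicate) % (2 ** 31)


#: Reference volume for scaling generator templates between arms.
_REFERENCE_VOLUME_ML = 4.5


def arm_specs(cfg: ExperimentConfig, arm: Arm, seed: int):
    """Generator specs for one replicate of one arm.

    The bleb and cap scale with injected volume (linear-in-volume, i.e.
    each semi-axis scales with the cube root); HLN boosts lateral growth
    and lowers the pressure amplitudes.
    """
    s = (arm.volume_ml / _REFERENCE_VOLUME_ML) ** (1.0 / 3.0)
    rng = np.random.default_rng([seed, 1])  # inter-animal size jitter
    jb = np.exp(rng.normal(0.0, cfg.replicate_cv, size=3))
    jc = np.exp(rng.normal(0.0, cfg.replicate_cv, size=3))
    jp = float(np.exp(rng.normal(0.0, cfg.replicate_cv)))
    bleb = tuple(x * s * j for x, j in zip(cfg.base_bleb_axes, jb))
    cap = tuple(x * s * j for x, j in zip(cfg.base_cap_axes, jc))
    extent = [n * sp for n, sp in zip(cfg.grid_shape, cfg.spacing)]
    spec = PhantomSpec(
        grid_shape=tuple(cfg.grid_shape), spacing=tuple(cfg.spacing),
        background_hu=cfg.background_hu, contrast_hu=cfg.contrast_hu,
        bleb_center=(extent[0] / 2, extent[1] / 2, 20.0),
        bleb_axes=bleb, cap_axes=cap, noise_sd=cfg.noise_sd_hu, seed=seed)
    model = DispersionModel(
        initial_axes=bleb, growth_mm=cfg.growth_mm, tau_s=cfg.growth_tau_s,
        hln_factor=cfg.hln_dispersion_factor if arm.hln else 1.0)
    protocol = InjectionProtocol(arm.volume_ml, cfg.flow_rate_ml_min,
                                 hln=arm.hln)
    pf = (cfg.hln_pressure_factor if arm.hln else 1.0) * \
        (arm.volume_ml / _REFERENCE_VOLUME_ML) * jp
    psim = PressureSimSpec(
        protocol=protocol, baseline_kpa=cfg.pressure_baseline_kpa,
        A1_kpa=cfg.base_A1_kpa * pf, A2_kpa=cfg.base_A2_kpa * pf,
        k1_per_s=cfg.k1_per_s, k2_per_s=cfg.k2_per_s,
        noise_sd=cfg.pressure_noise_sd_kpa, rate_hz=10.0,
        duration_s=protocol.duration_s + 150.0, seed=seed)
    return spec, model, psim


def _run_replicate(cfg: ExperimentConfig, arm: Arm, seed: int) -> dict:
    spec, model, psim = arm_specs(cfg, arm, seed)

    pre, frames = generate_phantom_series(spec, model, cfg.scan_times_s)
    seed_voxel = tuple(int(c / sp) for c, sp in
                       zip(spec.bleb_center, spec.spacing))
    table = morpho.surface_area_timeseries(
        [(t, vol) for t, vol, _ in frames], seed_voxel, cfg.threshold)
    last = table[table.ok].iloc[-1]
    if last.time_s != cfg.scan_times_s[-1]:
        raise AnalysisError("final scan failed morphometry")

    pre_surface = dist.extract_skin_surface(pre)
    measurements = [
        dist.measure_distension(pre_surface, dist.extract_skin_surface(vol),
                                cfg.min_height_mm, time_s=t)
        for t, vol, _ in frames]
    distension_ml = dist.distension_summary(measurements,
                                            cfg.distension_window_s)

    trace = generate_pressure_trace(psim)
    t_cess = press.cessation_time(psim.protocol, psim.t_start_s)
    peak, _ = press.max_pressure(trace, t_cess)
    fit = press.fit_decay(trace, t_cess)

    return {
        "volume_ml": arm.volume_ml, "hln": arm.hln, "seed": seed,
        "surface_area_mm2": float(last.surface_area_mm2),
        "bleb_volume_ml": float(last.volume_ml),
        "distension_ml": float(distension_ml),
        "max_pressure_kpa": float(peak),
        "keff_per_s": press.effective_decay_constant(fit),
        "ok": True, "note": "",
    }


#: Endpoints compared between +/- HLN arms.
ENDPOINTS = ("surface_area_mm2", "distension_ml", "max_pressure_kpa",
             "keff_per_s")


@dataclass
class GroupComparison:
    """One two-sample t-test between arm endpoint vectors."""

    endpoint: str
    group_x: str
    group_y: str
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    n_x: int
    n_y: int
    t_statistic: float
    df: float
    p_value: float
    alpha: float
    significant: bool


def two_sample_t(x, y, alpha: float = 0.05, welch: bool = False,
                 endpoint: str = "", group_x: str = "x",
                 group_y: str = "y") -> GroupComparison:
    """Two-sided two-sample Student's t-test (pooled variance by default).

    ``welch=True`` drops the equal-variance assumption.  Degenerate zero
    pooled variance: equal means give t = 0, p = 1; unequal means are an
    error (no variability to test against).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise AnalysisError("each group needs at least 2 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise AnalysisError("non-finite endpoint values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            t_stat, df, p = 0.0, float(x.size + y.size - 2), 1.0
        else:
            raise AnalysisError(
                "zero variance in both groups with unequal means")
    else:
        res = stats.ttest_ind(x, y, equal_var=not welch)
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(
        endpoint=endpoint, group_x=group_x, group_y=group_y,
        mean_x=float(x.mean()), mean_y=float(y.mean()),
        sd_x=float(x.std(ddof=1)), sd_y=float(y.std(ddof=1)),
        n_x=int(x.size), n_y=int(y.size),
        t_statistic=t_stat, df=df, p_value=p,
        alpha=alpha, significant=bool(p < alpha))


def summarize_arm(values) -> tuple[float, float, int]:
    """(mean, sample s.d., n); s.d. is NaN for n = 1 (undefined)."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise AnalysisError("cannot summarize an empty arm")
    sd = float(v.std(ddof=1)) if v.size > 1 else float("nan")
    return float(v.mean()), sd, int(v.size)


@dataclass
class ExperimentResult:
    results: pd.DataFrame
    arm_summaries: pd.DataFrame
    comparisons: list[GroupComparison]
    notices: list[str]

    def comparison(self, endpoint: str, volume_ml: float) -> GroupComparison:
        for c in self.comparisons:
            if c.endpoint == endpoint and f"{volume_ml:g}" in c.group_x:
                return c
        raise KeyError((endpoint, volume_ml))


def run_experiment(cfg: ExperimentConfig,
                   out_dir=None) -> ExperimentResult:
    """Run the full in-silico study and aggregate group statistics.

    Per-replicate failures are recorded (``ok = False`` rows) without
    aborting the arm; an arm aborts only if every replicate fails.  When
    ``out_dir`` is given, writes ``results.csv``, ``comparisons.json`` and
    ``log.json`` (seeds, config) there.
    """
    rows, notices = [], []
    for ai, arm in enumerate(cfg.arms):
        arm_rows = []
        for rep in range(arm.n):
            seed = cfg.replicate_seed(ai, rep)
            try:
                arm_rows.append(_run_replicate(cfg, arm, seed))
            except AnalysisError as exc:
                arm_rows.append({
                    "volume_ml": arm.volume_ml, "hln": arm.hln, "seed": seed,
                    "ok": False, "note": f"{type(exc).__name__}: {exc}"})
        if not any(r["ok"] for r in arm_rows):
            raise AnalysisError(
                f"all replicates failed in arm volume={arm.volume_ml} "
                f"hln={arm.hln}: {arm_rows[0]['note']}")
        rows.extend(arm_rows)
    results = pd.DataFrame(rows)

    summaries = []
    ok = results[results.ok]
    for (vol, hln), grp in ok.groupby(["volume_ml", "hln"]):
        for ep in ENDPOINTS:
            mean, sd, n = summarize_arm(grp[ep])
            summaries.append({"volume_ml": vol, "hln": hln, "endpoint": ep,
                              "mean": mean, "sd": sd, "n": n})
    arm_summaries = pd.DataFrame(summaries)

    comparisons = []
    for vol in sorted({a.volume_ml for a in cfg.arms}):
        ctrl = ok[(ok.volume_ml == vol) & (~ok.hln)]
        hln = ok[(ok.volume_ml == vol) & (ok.hln)]
        if ctrl.empty or hln.empty:
            continue
        if len(ctrl) < 2 or len(hln) < 2:
            notices.append(
                f"statistics skipped for volume {vol:g} mL: fewer than 2 "
                f"replicates per group")
            continue
        for ep in ENDPOINTS:
            try:
                comparisons.append(two_sample_t(
                    hln[ep], ctrl[ep], alpha=cfg.alpha, welch=cfg.welch,
                    endpoint=ep, group_x=f"{vol:g} mL +HLN",
                    group_y=f"{vol:g} mL -HLN"))
            except AnalysisError as exc:
                notices.append(
                    f"t-test failed for {ep} at {vol:g} mL: {exc}")

    result = ExperimentResult(results, arm_summaries, comparisons, notices)
    if out_dir is not None:
        _write_outputs(result, cfg, Path(out_dir))
    return result


def _write_outputs(result: ExperimentResult, cfg: ExperimentConfig,
                   out: Path):
    out.mkdir(parents=True, exist_ok=True)
    result.results.to_csv(out / "results.csv", index=False)
    result.arm_summaries.to_csv(out / "arm_summaries.csv", index=False)
    (out / "comparisons.json").write_text(json.dumps(
        [asdict(c) for c in result.comparisons], indent=2))
    log = {"config": _jsonable(asdict(cfg)),
           "seeds": [int(s) for s in result.results.seed],
           "notices": result.notices}
    (out / "log.json").write_text(json.dumps(log, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def null_rejection_rate(n_experiments: int = 500, n_per_arm: int = 20,
                        alpha: float = 0.05, seed: int = 0,
                        volume_ml: float = 4.5) -> float:
    """Type-I error calibration of the group comparison under the null.

    Both arms use identical generators (same injection, same noise) with
    distinct seeds; the replicate endpoint is the peak pressure of a
    simulated noisy trace.  Returns the fraction of experiments where the
    two-sided pooled t-test rejects at ``alpha`` — nominally ~5%.
    """
    proto = InjectionProtocol(volume_ml, 10.0)
    t_cess = proto.duration_s
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_experiments):
        groups = []
        for _g in range(2):
            vals = []
            for _r in range(n_per_arm):
                s = int(rng.integers(0, 2 ** 31 - 1))
                trace = generate_pressure_trace(PressureSimSpec(
                    protocol=proto, baseline_kpa=2.0, A1_kpa=6.0, A2_kpa=3.0,
                    k1_per_s=0.4, k2_per_s=0.04, noise_sd=0.05,
                    rate_hz=10.0, duration_s=t_cess + 125.0, seed=s))
                vals.append(press.max_pressure(trace, t_cess)[0])
            groups.append(vals)
        cmp = two_sample_t(groups[0], groups[1], alpha=alpha)
        rejections += cmp.significant
    return rejections / n_experiments
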