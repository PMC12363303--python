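"""Phantom and pressure-trace generator behaviour against analytic truth."""

import numpy as np
import pytest

from blebmetrics import (DispersionModel, PhantomSpec, PressureSimSpec,
                         InjectionProtocol, ellipsoid_surface_area,
                         generate_phantom_pair, generate_phantom_series,
                         generate_pressure_trace)
from blebmetrics.errors import GeometryError


def test_no_cap_means_pre_post_differ_only_inside_bleb(clean_spec):
    spec = PhantomSpec(noise_sd=0.0, cap_axes=(0.0, 0.0, 0.0))
    pre, post, truth = generate_phantom_pair(spec)
    outside = ~truth.bleb_mask
    np.testing.assert_array_equal(pre.values[outside], post.values[outside])
    assert (post.values[truth.bleb_mask] == spec.contrast_hu).all()


def test_rasterized_volume_close_to_analytic_ellipsoid():
    spec = PhantomSpec(noise_sd=0.0, bleb_axes=(20.0, 15.0, 8.0),
                       bleb_center=(36.0, 32.0, 24.0))
    _, _, truth = generate_phantom_pair(spec)
    analytic = 4.0 / 3.0 * np.pi * 20 * 15 * 8 / 1000.0
    assert truth.bleb_voxel_volume_ml == pytest.approx(analytic, rel=0.05)


@pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (1.0, 1.0, 3.0)])
def test_seeded_reproducibility(spacing):
    spec = PhantomSpec(noise_sd=15.0, seed=7, spacing=spacing)
    a = generate_phantom_pair(spec)
    b = generate_phantom_pair(spec)
    np.testing.assert_array_equal(a[0].values, b[0].values)
    np.testing.assert_array_equal(a[1].values, b[1].values)


def test_rasterization_error_shrinks_with_spacing():
    """Voxel-count volume converges to the analytic ellipsoid volume."""
    analytic = 4.0 / 3.0 * np.pi * 10 * 8 * 6 / 1000.0
    errors = []
    for sp in (2.0, 1.0, 0.5):
        shape = (int(72 / sp), int(64 / sp), int(48 / sp))
        spec = PhantomSpec(grid_shape=shape, spacing=(sp, sp, sp),
                           bleb_axes=(10.0, 8.0, 6.0), noise_sd=0.0)
        _, _, truth = generate_phantom_pair(spec)
        errors.append(abs(truth.bleb_voxel_volume_ml - analytic) / analytic)
    assert errors[0] >= errors[1] >= errors[2]
    assert errors[2] < 0.02


def test_bleb_outside_grid_is_rejected():
    with pytest.raises(GeometryError):
        PhantomSpec(bleb_center=(36.0, 32.0, 44.0))  # deep face clipped
    with pytest.raises(GeometryError):
        PhantomSpec(cap_axes=(12.0, 10.0, 9.0))  # taller than the air gap


def test_series_zero_growth_is_time_invariant(clean_spec):
    model = DispersionModel(initial_axes=clean_spec.bleb_axes,
                            growth_mm=(0.0, 0.0, 0.0))
    _, frames = generate_phantom_series(clean_spec, model,
                                        [0.0, 30.0, 600.0])
    ref = frames[0][1].values
    for _, vol, _ in frames[1:]:
        np.testing.assert_array_equal(vol.values, ref)


def test_hln_series_has_strictly_larger_truth_surface_area(clean_spec):
    times = [0.0, 5.0, 30.0, 120.0, 600.0]
    kwargs = dict(initial_axes=clean_spec.bleb_axes, growth_mm=(3.0, 3.0, 0.5))
    _, plain = generate_phantom_series(
        clean_spec, DispersionModel(**kwargs, hln_factor=1.0), times)
    _, hln = generate_phantom_series(
        clean_spec, DispersionModel(**kwargs, hln_factor=1.5), times)
    for (t, _, tr_p), (_, _, tr_h) in zip(plain, hln):
        s_p = ellipsoid_surface_area(*tr_p.bleb_axes_mm)
        s_h = ellipsoid_surface_area(*tr_h.bleb_axes_mm)
        if t == 0:
            assert s_h == pytest.approx(s_p)
        else:
            assert s_h > s_p


def test_single_time_series_matches_pair(noisy_spec):
    pre_p, post_p, truth_p = generate_phantom_pair(noisy_spec)
    model = DispersionModel(initial_axes=noisy_spec.bleb_axes)
    pre_s, frames = generate_phantom_series(noisy_spec, model, [0.0])
    np.testing.assert_array_equal(pre_p.values, pre_s.values)
    np.testing.assert_array_equal(post_p.values, frames[0][1].values)
    np.testing.assert_array_equal(truth_p.bleb_mask, frames[0][2].bleb_mask)


def test_series_growth_volume_nondecreasing(clean_spec):
    model = DispersionModel(initial_axes=clean_spec.bleb_axes)
    _, frames = generate_phantom_series(
        clean_spec, model, [0.0, 5.0, 30.0, 60.0, 90.0, 120.0, 180.0, 600.0])
    vols = [tr.bleb_voxel_volume_ml for _, _, tr in frames]
    assert all(b >= a for a, b in zip(vols, vols[1:]))


class TestPressureTrace:
    def test_peak_value_at_cessation(self, noiseless_sim):
        trace = generate_pressure_trace(noiseless_sim)
        i = np.argmin(np.abs(trace.time_s - trace.t_cess_s))
        assert trace.pressure_kpa[i] == pytest.approx(
            noiseless_sim.baseline_kpa + noiseless_sim.A1_kpa
            + noiseless_sim.A2_kpa)

    def test_single_exponential_closed_form(self, protocol_4p5):
        spec = PressureSimSpec(protocol=protocol_4p5, baseline_kpa=1.0,
                               A1_kpa=10.0, A2_kpa=0.0, k1_per_s=0.5,
                               k2_per_s=0.01, noise_sd=0.0, duration_s=180.0)
        trace = generate_pressure_trace(spec)
        i = np.argmin(np.abs(trace.time_s - (trace.t_cess_s + 2.0)))
        assert trace.pressure_kpa[i] == pytest.approx(
            1.0 + 10.0 * np.exp(-1.0), rel=1e-12)

    def test_noise_mean_residual_obeys_clt_bound(self, noiseless_sim,
                                                 protocol_4p5):
        sd = 0.3
        noisy = PressureSimSpec(protocol=protocol_4p5, A1_kpa=10.0,
                                A2_kpa=5.0, k1_per_s=0.5, k2_per_s=0.05,
                                noise_sd=sd, duration_s=180.0, seed=3)
        clean = generate_pressure_trace(noiseless_sim)
        trace = generate_pressure_trace(noisy)
        resid = trace.pressure_kpa[:1000] - clean.pressure_kpa[:1000]
        assert abs(resid.mean()) < 4 * sd / np.sqrt(1000)

    def test_continuous_at_cessation(self, noiseless_sim):
        trace = generate_pressure_trace(noiseless_sim)
        i = np.argmin(np.abs(trace.time_s - trace.t_cess_s))
        dt = 1.0 / noiseless_sim.rate_hz
        peak = noiseless_sim.A1_kpa + noiseless_sim.A2_kpa
        max_step = max(peak / noiseless_sim.protocol.duration_s,
                       noiseless_sim.A1_kpa * noiseless_sim.k1_per_s
                       + noiseless_sim.A2_kpa * noiseless_sim.k2_per_s) * dt
        assert abs(trace.pressure_kpa[i + 1] - trace.pressure_kpa[i]) \
            <= max_step * 1.001

    def test_first_order_rise_also_reaches_peak_at_cessation(self,
                                                             protocol_4p5):
        spec = PressureSimSpec(protocol=protocol_4p5, noise_sd=0.0,
                               duration_s=180.0, rise_model="first_order",
                               rise_tau_s=8.0)
        trace = generate_pressure_trace(spec)
        i = np.argmin(np.abs(trace.time_s - trace.t_cess_s))
        assert trace.pressure_kpa[i] == pytest.approx(
            spec.baseline_kpa + spec.A1_kpa + spec.A2_kpa)
        assert np.argmax(trace.pressure_kpa) == i

    def test_invalid_specs_rejected(self, protocol_4p5):
        with pytest.raises(ValueError):
            PressureSimSpec(protocol=protocol_4p5, k1_per_s=0.01,
                            k2_per_s=0.5, duration_s=180.0)
        with pytest.raises(ValueError):
            PressureSimSpec(protocol=protocol_4p5, duration_s=100.0)
        with pytest.raises(ValueError):
            InjectionProtocol(volume_ml=-1.0, flow_rate_ml_min=10.0)
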