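# blebmetrics

Quantitative analysis of **large-volume subcutaneous (SC) injections** from
CT imaging and inline pressure recordings — for preclinical drug-delivery
researchers studying how injectate volume and co-formulated hyaluronidase
(HLN) affect depot dispersion, skin distension and injection pressure.

When several millilitres are injected under the skin, the fluid forms a
*bleb* whose spread, surface bulge and pressure history are the measurable
correlates of tolerability and absorption. `blebmetrics` implements the
complete measurement chain:

* **Bleb morphometry** — seeded connected-component threshold segmentation
  of the contrast-loaded bleb, semi-axes *a* ≥ *b* ≥ *c* as half the
  axis-aligned extents, and the ellipsoid surface-area approximation
  (dispersion metric)

  S ≈ 4π [ ((ab)^1.6 + (ac)^1.6 + (bc)^1.6) / 3 ]^(1/1.6).

* **Skin distension** — overlay of pre- and post-injection scans as skin
  depth maps; the region raised above the original surface is modelled as
  a half-ellipsoid, V ≈ (2/3)πabc, averaged over the 90–120 s
  post-injection plateau.

* **Pressure analysis** — pump cessation from protocol arithmetic
  (t = volume / flow rate; 27 s and 54 s for 4.5 and 9 mL at 10 mL/min),
  peak pressure within ±2 s of cessation, and a double-exponential fit to
  the 2 min decay, P(τ) = baseline + A₁e^(−k₁τ) + A₂e^(−k₂τ), summarized
  by the effective decay constant k_eff = (A₁k₁ + A₂k₂)/(A₁ + A₂).

* **Synthetic phantoms & traces** — ground-truth-labelled layered-slab CT
  phantoms with a growing ellipsoidal bleb and half-ellipsoidal skin cap,
  plus simulated pressure recordings (10 Hz, ramp–peak–biexponential
  decay), so the whole chain is testable without any acquisition.

* **Study pipeline** — the full in-silico design (4.5 / 9 mL × ±HLN,
  n = 3, scans at baseline–600 s), per-arm mean ± s.d. and two-sample
  Student's t-tests.

See `docs/methods.md` for models, assumptions and numerical details.

## Worked example

```python
import blebmetrics as bm

# phantom with a 4.5 mL-scale bleb and a (10, 8, 4) mm skin cap
spec = bm.PhantomSpec(noise_sd=20.0, cap_axes=(10.0, 8.0, 4.0), seed=7)
pre, post, truth = bm.generate_phantom_pair(spec)

mask = bm.segment_bleb(post, seed_point=(36, 32, 20), threshold="auto")
a, b, c = bm.measure_semi_axes(mask)
print(f"bleb semi-axes: a={a:.1f} b={b:.1f} c={c:.1f} mm")
print(f"surface area:   {bm.ellipsoid_surface_area(a, b, c):.0f} mm^2")
print(f"bleb volume:    {bm.mask_volume_ml(mask):.2f} mL "
      f"(analytic truth {truth.bleb_analytic_volume_ml:.2f} mL)")

m = bm.measure_distension(bm.extract_skin_surface(pre),
                          bm.extract_skin_surface(post), min_height_mm=0.5)
print(f"distension:     a={m.a_mm:.1f} b={m.b_mm:.1f} c={m.c_mm:.1f} mm, "
      f"V={m.volume_ml:.2f} mL")

proto = bm.InjectionProtocol(volume_ml=4.5, flow_rate_ml_min=10.0)
sim = bm.PressureSimSpec(protocol=proto, noise_sd=0.3, duration_s=180.0,
                         seed=7)
trace = bm.generate_pressure_trace(sim)
t_cess = bm.cessation_time(proto)          # 27.0 s
peak, t_peak = bm.max_pressure(trace, t_cess)
fit = bm.fit_decay(trace, t_cess)
print(f"cessation at {t_cess:.0f} s; peak {peak:.2f} kPa at {t_peak:.1f} s")
print(f"decay fit: A1={fit.A1_kpa:.2f} k1={fit.k1_per_s:.3f}  "
      f"A2={fit.A2_kpa:.2f} k2={fit.k2_per_s:.3f}  "
      f"keff={fit.keff_per_s:.3f} 1/s")
```

Output:

```text
bleb semi-axes: a=16.0 b=12.0 c=6.0 mm
surface area:   1589 mm^2
bleb volume:    4.46 mL (analytic truth 4.50 mL)
distension:     a=10.0 b=8.0 c=4.0 mm, V=0.67 mL
cessation at 27 s; peak 15.16 kPa at 26.7 s
decay fit: A1=10.00 k1=0.489  A2=4.96 k2=0.051  keff=0.344 1/s
```

The segmentation recovers the true bleb (semi-axes 16, 12, 5.6 mm) to
within one voxel and its volume within 1%; the skin cap is recovered
exactly at this voxel size; and the decay fit recovers the simulated
parameters (A₁ = 10, k₁ = 0.5, A₂ = 5, k₂ = 0.05, k_eff = 0.35) to within
a few percent despite 2%-of-peak noise.

The same stages are available from the shell:

```sh
blebmetrics synth phantom  --config phantom.json --out phantom/
blebmetrics synth pressure --config sim.json     --out trace.csv
blebmetrics morpho     --post phantom/post_00_t0000s.nii.gz \
                       --seed-point 36,32,20 --out morpho.csv
blebmetrics distension --pre phantom/pre.nii.gz --post phantom/post_*.nii.gz \
                       --out distension.csv
blebmetrics pressure   --trace trace.csv --volume-ml 4.5 --out fit.json
blebmetrics run        --seed 1 --out results/
```

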