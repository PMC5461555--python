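# wnphase

Tools for a measurement problem in phase–perception research: when the
detection of a stimulus depends on the phase of an ongoing brain oscillation
at a known time and frequency, at what latency does a phase-opposition
analysis actually *measure* that dependence?  Studies of oscillatory phase
and perception typically report effects peaking 100 ms or more *before*
stimulus onset — even though the physiologically relevant phase should be
the one present while the stimulus is processed.  `wnphase` provides, on
fully synthetic data:

* the **phase-opposition statistics** used in this literature — intertrial
  phase clustering `ITPC = |n⁻¹ Σ exp(iφ_k)|`, the phase opposition sum
  `POS = ITPC_A + ITPC_B − 2·ITPC_all`, label-shuffle surrogate testing with
  calibrated p-values, grand averaging across channels and subjects,
  Bonferroni/FDR correction, cluster latencies, and median-latency
  confidence intervals;
* a **latency-distortion simulation**: Gaussian-noise trials with a cosine
  phase dependence of a binary outcome injected at +40 ms, plus a
  parameterised P1/N1 evoked potential.  The evoked response, combined with
  the finite wavelet window, displaces the measured phase effect toward —
  and into — the prestimulus window, by more the lower the frequency;
* a **white-noise (WN) reconstruction paradigm**: a synthetic observer with
  a known impulse-response function (IRF), white-noise luminance sequences
  with embedded mean-gray targets, IRF estimation by cross-correlation,
  reconstruction of the stimulus-driven signal by convolution (which, by
  construction, contains no target-evoked response), cross-validated
  reconstruction-vs-recording correlations, classification images, and
  phase-binned performance — the route by which the true latency of a phase
  effect can be recovered free of evoked-response bias.

Audience: researchers who analyse oscillatory phase effects on behaviour and
want to quantify (or escape) the latency bias of their measurement chain.

## Worked example

```python
import numpy as np
from wnphase import StudyConfig, run_frequency, surrogate_pos
from wnphase.signal_models import build_simulated_dataset
from wnphase.spectral import make_wavelet_plan, single_freq_wavelet

# 500 noise trials, outcome drawn from the 7.08 Hz band phase at +40 ms
ds = build_simulated_dataset(7.08, with_erp=False, seed=7)
plan = make_wavelet_plan()                      # 3->8 cycles over 3-100 Hz
coeffs, _ = single_freq_wavelet(ds.signals.data[:, 0, :], 500.0, 7.08,
                                float(plan.cycles_at(7.08)))
res = surrogate_pos(np.angle(coeffs[:, ds.signals.index_of(40.0)]),
                    ds.labels, n_perm=1000, seed=0)
print(f"POS at the injection point: {res.pos:.3f}  (z = {res.z:.1f}, p = {res.p:.2e})")

# the same protocol with the evoked potential added: the measured latency
# of the (still +40 ms) phase effect migrates into the prestimulus window
row = run_frequency(7.08, StudyConfig(n_datasets=20, seed=42))
d = row.latency_dist
print(f"7.08 Hz, ERP included: median latency {d.median:.1f} ms "
      f"(95% CI {d.ci_low:.1f} to {d.ci_high:.1f}, {d.n}/20 datasets significant)")
```

prints

```
POS at the injection point: 0.290  (z = 8.9, p = 6.16e-06)
7.08 Hz, ERP included: median latency -79.5 ms (95% CI -96.0 to -63.1, 18/20 datasets significant)
```

The first line shows the injected phase dependence recovered decisively at
its true time.  The second shows the distortion: with an outcome-independent
P1/N1 response added after labelling, the largest significant
phase-opposition cluster centres around −80 ms — some 120 ms *before* the
moment at which the outcome was actually decided.  Without the ERP
(`with_erp=False` in `StudyConfig`) the median latency brackets +40 ms at
every frequency.

A command-line interface mirrors the library:

```sh
wnphase simulate-latency --freqs 7.08,39.44 --n-datasets 20 --seed 1 --out study.json
wnphase make-fixtures --tiny --seed 3 --out fixtures/
wnphase estimate-irf --eeg fixtures/recorded.h5 --sequences fixtures/sequences.csv --out irf.h5
wnphase reconstruct --irf irf.h5 --sequences fixtures/sequences.csv --out recon.h5
```

See `docs/methods.md` for the model, parameter and calibration details, and
for what the synthetic data do and do not emulate.

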