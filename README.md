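# pcss — steady-state background phase errors in phase-contrast MRI

Phase-contrast (PC) MRI encodes through-plane velocity into the signal
phase of a steady-state gradient-echo (GRE) sequence: two acquisitions with
different bipolar-gradient moments are subtracted, and a phase difference
of π corresponds to the velocity-encoding parameter venc. The measurement
is contaminated by spatially varying *background phases* from concomitant
fields and eddy currents. These are routinely removed by fitting a
second-order polynomial to stationary tissue and extrapolating it into the
vessel.

`pcss` simulates a third, less familiar contribution: the flow-encoding
gradients alternate the per-TR net phase and thereby *disrupt the GRE
steady state*, producing an extra, sequence- and tissue-dependent phase
error φ_S. The package provides:

- **`pcss.bloch`** — an isochromat Bloch engine for one voxel: RF
  excitation with a realistic slice profile (the Fourier transform of the
  pulse envelope), relaxation, per-TR phase precession, and 2π gradient
  spoiling over an intravoxel spoiler coordinate.
- **`pcss.sequence`** — prospectively triggered PC-GRE schedules: FISP
  (gradient-spoiled) vs FLASH (additional quadratic 50° RF spoiling),
  flow encoding interleaved every TR or every cardiac (ECG) cycle with a
  steady-state trigger; phase-contrast series and steady-state deviation
  metrics in %venc.
- **`pcss.phantom`** — a synthetic-data generator: 2D phantom scenes
  (homogeneous gel discs P1/P2 with T1/T2 = 720/40 and 2000/160 ms, or an
  in-vivo-like pulsatile-vessel scene) rendered per pixel into complex
  per-cardiac-phase image stacks under a smooth polynomial background-phase
  field, with ground truth.
- **`pcss.correction`** — static-tissue masking (20% magnitude / 10%
  temporal-SD thresholds), second-order polynomial background fit,
  subtraction, and ROI flow rates in mL/s.
- **`pcss.experiments` / `pcss` CLI** — scripted reproductions of the
  simulation panels and the end-to-end demonstration that the polynomial
  correction inherits φ_S and biases flow depending on the sequence mode.

## Worked example

Steady-state deviation of a TR-interleaved FISP acquisition at a 5 %venc
injected background phase (TR 6.8 ms, flip 10°, T1/T2 = 2000/160 ms,
150 TRs per 1020 ms cycle):

```python
from pcss import (P2_TISSUE, BackgroundPhase, SequenceConfig,
                  phase_contrast, run_sequence, steady_state_deviation)

cfg = SequenceConfig(contrast="FISP", interleave="TR", n_cycles=4)
bg = BackgroundPhase(5.0)                      # injected phase, %venc
series = phase_contrast(run_sequence(cfg, P2_TISSUE, bg), cfg)
print(f"{steady_state_deviation(series, bg, n_avg=20):+.4f} %venc")
```

```
+2.0646 %venc
```

The gradient-spoiled sequence *overestimates* a 5 %venc background phase by
about 2 %venc — surviving transverse coherences carry the alternating
encoding phase between repetitions. Repeating with
`contrast="FLASH"` and a 20 %venc input gives `-0.0640 %venc`: RF spoiling
damps the coherences and the error drops by two orders of magnitude.

The same comparison from the shell:

```bash
pcss simulate --contrast FISP --interleave TR --phi 5 --cycles 4 --out fisp.csv
# steady-state deviation: +2.0646 %venc (140 pairs)
pcss sweep --contrast FLASH --phi-list "-20,-10,-5,-2,2,5,10,20" --cycles 4 --out flash.csv
pcss reproduce fig3 --out out/        # deviation-vs-input curves + plot
pcss reproduce bias --out out/        # four-mode correction-bias report
```

`pcss reproduce bias` renders the pulsatile-vessel scene under all four
sequence modes, runs the static-tissue correction and reports corrected
mean flows: ECG-interleaved FISP corrects the flow *upward* relative to
FLASH, TR-interleaved FISP *downward* — the polynomial fit faithfully
removes the eddy-current-like field but also extrapolates the
tissue-specific steady-state error into the vessel.

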