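# Methods

## Model

A single imaged voxel is represented by an ensemble of isochromats indexed
by two internal coordinates:

- a **through-slice position**, which maps to a per-isochromat flip-angle
  scale taken from the excitation pulse's slice profile. In the small-tip
  approximation the profile is the Fourier transform of the RF envelope;
  it is evaluated exactly (dense DFT) at positions sampled symmetrically
  over the region where the profile exceeds 1% of its central value, and
  normalized to 1 at the slab centre. Sidelobe scales may be negative.
- an **intravoxel spoiler coordinate** u ∈ [0, 1): one gradient spoiler
  adds transverse phase 2π·u. The increment is identical every repetition,
  so spoiler phase accumulates and transverse coherence pathways survive —
  the defining difference between gradient spoiling (FISP) and ideal
  spoiling.

Each repetition applies, in order: RF rotation by the per-isochromat flip
angle about a transverse axis at the RF phase; the injected background
phase (flow-encoded repetitions only) as a rotation about z; relaxation to
the echo time TE; the demodulated echo sample (receiver phase = RF phase);
relaxation to the end of TR; the 2π spoiler. FLASH adds the standard
quadratic RF-spoiling schedule φ_k = φ_{k−1} + k·50°; FISP uses constant
RF phase. Relaxation is lumped into two intervals per TR (intra-pulse
relaxation is neglected; pulses are short against T2). Because relaxation
and all z-rotations commute, the placement of the phase injection and the
spoiler within the TR affects nothing except whether the injection precedes
the echo sample.

**Placement of the injected phase.** The spurious background phase of the
flow-encoded acquisition is injected *between excitation and the echo*,
where the bipolar encoding gradients physically act. This makes an ideally
spoiled (memoryless) sequence measure exactly the injected phase — the
definition of the "input background phase" — and makes every deviation
reported by the package a pure steady-state (coherence) effect. Injecting
the phase after the echo instead would leave an ideally spoiled sequence
blind to it and contradict the observed robustness of RF-spoiled
TR-interleaved acquisitions.

Phases are reported in percent of venc (π radians ≡ 100 %venc), which makes
all results venc-independent; cm/s values are obtained by scaling with the
configured venc.

## Sequence schedules

A cardiac cycle is `n_tr_per_cycle` repetitions (default 150 at TR 6.8 ms ≈
1020 ms): `n_trigger_tr` (default 10) steady-state-trigger repetitions
followed by the acquisition window (140 TRs). TR-interleaved mode
alternates compensated/encoded every repetition, including through the
trigger. ECG-interleaved mode holds one encoding per cycle; because the
switch happens at the end of the acquisition window, the leading trigger
TRs of a cycle already carry that cycle's encoding. Cycle 0 is compensated.

Phase contrast is Δφ = arg(S_enc · conj(S_comp)), wrapped to (−π, π]:
TR mode pairs consecutive in-window repetitions within a cycle; ECG mode
pairs in-window TR j of an encoded cycle with TR j of the preceding
compensated cycle. The first two cycles are discarded as warm-up
(configurable). The steady-state deviation is the mean measured-minus-
injected phase over the last 20 encoding pairs.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `tr_ms`, `te_ms` | 6.8, TR/2 | repetition / echo time. TE placement does not affect phase-contrast results (z-rotations commute with relaxation); it only scales magnitudes. |
| `flip_deg` | 10 | nominal on-resonance flip angle |
| `rf_spoil_increment_deg` | 0 (FISP) / 50 (FLASH) | quadratic RF-spoiling increment |
| `n_tr_per_cycle`, `n_trigger_tr` | 150, 10 | cycle structure (1020 ms cardiac interval) |
| `venc_cms` | 30 (phantoms) / 60 (vessel scene) | velocity encoding |
| `n_slice`, `n_spoiler` | 33, 200 | isochromat discretization (below) |
| mask thresholds | 0.20 / 0.10 | magnitude and temporal-SD fractions for the static mask |

## Numerical choices

**Spoiler discretization.** With n discrete spoiler coordinates the
accumulated spoiler phase wraps every n repetitions, which refocuses
spurious stimulated echoes and corrupts long-coherence (FISP) results: the
TR-interleaved FISP deviation at a 5 %venc input reads 1.46 %venc at
n = 20 but 2.06 %venc for n ≥ 200, converged to < 0.001 %venc between
n = 200, 300 and 400. The default is `n_spoiler = 200`. The slice axis
converges much faster: n_slice = 17, 33 and 65 agree to < 0.001 %venc; the
default is 33.

**RF pulse and slice-profile sensitivity.** The exact excitation pulse of
the reference experiments is not modelled; the default is a plausible
reconstruction (Hann-windowed sinc, time-bandwidth 2, 1 ms). The slice
profile is the *dominant* driver of the steady-state phase error: with an
ideal (flat) profile the TR-interleaved FISP deviation at 5 %venc collapses
from ≈ 2.06 to ≈ 0.01 %venc, because a voxel with a single flip angle
produces coherences whose phase errors largely cancel, while the
distribution of flip angles across the slab biases the net phase. Across
reasonable pulse choices (Hann/Hamming/rectangular window, time-bandwidth
2–4) the FISP deviation at 5 %venc spans 2.05–2.36 %venc and the FLASH
deviation magnitude at 20 %venc spans 0.063–0.15 %venc; reported FLASH
residuals should therefore be read as order-of-magnitude statements.

**Exact vs approximate invariants.** Without RF spoiling, the zero-input
phase contrast vanishes to machine precision and the deviation curve is
exactly odd in the injected phase (phase-conjugation symmetry of the
dynamics). RF spoiling breaks both exactly but not practically: the
demodulated FLASH signal retains a small TR-to-TR ripple even in the
pseudo-steady state, leaving a zero-input phase contrast of ≲ 0.03 %venc
(TR-interleaved) / ≲ 0.13 %venc (ECG-interleaved) at converged
discretization, and an odd-symmetry residual of ≲ 0.003 %venc. Tests
assert machine-precision identities for FISP and these bounded residuals
for FLASH.

**Degenerate inputs.** T2 > T1 tissue pairs are rejected (or skipped with a
warning in sweeps); ECG-interleaved runs require at least two cycles; an
odd acquisition window in TR mode drops the unpaired trailing sample with a
warning; static-mask fits require ≥ 6 non-degenerate pixels and raise on a
rank-deficient polynomial design. In the static mask, pixels whose
temporal SD is below an absolute floor (1e-9 cm/s) always count as static,
so the relative SD threshold remains meaningful on noiseless synthetic
data.

## Synthetic scenes: what they emulate and what they do not

`make_scene` provides two phantom presets (115 mm homogeneous gel discs,
shifted 120 mm in-plane, T1/T2 = 720/40 ms for P1 and 2000/160 ms for P2)
and an in-vivo-like `vessel_demo` (muscle-equivalent disc containing a
5 mm-radius vessel with a pulsatile arterial waveform peaking at 45 cm/s
under a 60 cm/s venc). The background-phase field is a second-order
polynomial, zero at the isocenter and spanning roughly ±10 %venc across the
field of view — a stand-in of realistic magnitude for combined
concomitant-field and eddy-current phase, not a physical computation of
either. Rendering runs the single-voxel engine per pixel; pixels with the
same tissue and the same background phase (quantized to 0.05 %venc by
default) share one simulation, and a flag disables this cache for exact
pixelwise checks. Complex Gaussian noise is optional and seeded.

The renderer does not model coil sensitivities, k-space sampling or
reconstruction, partial-volume effects, phase wrapping (vessel velocities
must stay below venc), table vibration, in-plane flow, or the interaction
of through-plane flow with the steady state. In the correction-bias
experiment the vessel is rendered in *fresh-spin* mode — its magnetization
is replaced by equilibrium spins every repetition, the limit of strong
inflow — so the vessel measures the injected phase exactly and the
demonstrated flow bias is attributable entirely to the static-tissue fit
inheriting the steady-state error of the background tissue. Consequently,
passing tests show that the correction logic and the coherence dynamics
behave as described, not that the specific flow-rate magnitudes transfer to
any in-vivo measurement.

## Correction pipeline

Static tissue is masked by time-averaged magnitude ≥ 20% of the image
maximum and temporal SD of the velocity ≤ 10% of the image's maximum SD.
The SD criterion is applied to the velocity series (a magnitude-SD switch
exists): the mask must reject pulsatile flow because the fit targets the
phase. A second-order 2D polynomial (basis 1, x, y, x², xy, y²; pixel-
centre coordinates normalized by half the field of view, shared verbatim
with the renderer so truth fields are recovered exactly) is fitted by
unweighted least squares to the time-averaged phase difference of masked
pixels (magnitude weighting available behind a flag), extrapolated over
the grid, converted to cm/s and subtracted from every cardiac phase. ROI
flow is Σ v · pixel-area in mL/s, per phase and heart-phase-averaged.
No phase unwrapping is performed; synthetic truth keeps |φ| < π.

## Known limitations

- The reconstructed RF pulse (and hence the absolute size of the FLASH
  residuals) is an assumption; only orders of magnitude are robust.
- Flow effects on the steady state are deliberately excluded; the
  fresh-spin vessel is the opposite limit.
- Time-resolved (per-phase) polynomial fits are available only as an
  experimental flag and make no quantitative claims.
- Experiments use reduced isochromat counts and scene resolutions chosen
  so orderings are stable (the package's own defaults remain the converged
  values above).
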