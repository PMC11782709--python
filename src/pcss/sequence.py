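"""Prospectively triggered phase-contrast GRE schedules on the Bloch engine.

A cardiac cycle is modelled as ``n_tr_per_cycle`` repetitions: the first
``n_trigger_tr`` are steady-state-trigger repetitions (RF and gradients play
but no data is kept) and the remaining ones form the acquisition window.
Flow encoding alternates either every TR (``TR``-interleaved) or every cycle
(``ECG``-interleaved, where the trigger TRs at the start of a cycle already
carry that cycle's encoding because the switch happens at the end of the
previous acquisition window).

The spurious background phase of the flow-encoded acquisition is injected as
a single per-TR phase rotation of all isochromats between excitation and the
echo sample, so that an ideally spoiled (memoryless) sequence measures
exactly the injected phase; the flow-compensated acquisition carries zero
input phase. Deviations of the measured phase contrast from the injected
value are then entirely the steady-state contribution of surviving
transverse coherences.

Phases are expressed throughout in percent of venc: a phase difference of
``pi`` corresponds to 100 %venc, i.e. a velocity of venc. Results in %venc
are venc-independent by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bloch import (
    IsochromatEnsemble,
    RFPulseSpec,
    TissueProperties,
    apply_rf,
    equilibrium_ensemble,
    ernst_signal,
    precess_phase,
    read_signal,
    relax,
    spoil_gradient,
    windowed_sinc_pulse,
    zero_transverse,
)

__all__ = [
    "SequenceConfig",
    "BackgroundPhase",
    "SignalTrace",
    "PhaseContrastSeries",
    "run_sequence",
    "phase_contrast",
    "steady_state_deviation",
    "sweep_background",
    "sweep_relaxation",
    "ideal_spoiled_reference",
]

COMPENSATED, ENCODED = 0, 1


@dataclass(frozen=True)
class SequenceConfig:
    """Timing, contrast and interleaving of the PC-GRE sequence.

    Defaults correspond to the study conditions: TR 6.8 ms (150 TR per
    1020 ms cardiac cycle), flip 10 degrees, 10 trigger TRs followed by a
    140-TR acquisition window, quadratic RF-spoiling increment 50 degrees
    for FLASH and none for FISP.
    """

    tr_ms: float = 6.8
    te_ms: float | None = None  # default TR/2
    flip_deg: float = 10.0
    contrast: str = "FISP"  # FISP (gradient spoiled) or FLASH (+RF spoiled)
    rf_spoil_increment_deg: float | None = None  # default by contrast
    interleave: str = "TR"  # TR or ECG
    n_tr_per_cycle: int = 150
    n_trigger_tr: int = 10
    n_cycles: int = 6
    venc_cms: float = 30.0
    n_slice: int = 33
    n_spoiler: int = 200
    warmup_cycles: int = 2
    perfect_spoiling: bool = False  # test-only: zero Mxy every TR
    pulse: RFPulseSpec | None = None  # default windowed sinc at flip_deg

    def __post_init__(self) -> None:
        if self.contrast not in ("FISP", "FLASH"):
            raise ValueError(f"contrast must be FISP or FLASH, got {self.contrast!r}")
        if self.interleave not in ("TR", "ECG"):
            raise ValueError(f"interleave must be TR or ECG, got {self.interleave!r}")
        if self.rf_spoil_increment_deg is None:
            object.__setattr__(
                self,
                "rf_spoil_increment_deg",
                0.0 if self.contrast == "FISP" else 50.0,
            )
        if (self.rf_spoil_increment_deg == 0.0) != (self.contrast == "FISP"):
            raise ValueError(
                "rf_spoil_increment_deg must be 0 exactly for FISP contrast"
            )
        if self.te_ms is None:
            object.__setattr__(self, "te_ms", self.tr_ms / 2.0)
        if not 0 < self.te_ms < self.tr_ms:
            raise ValueError(f"TE must lie in (0, TR), got {self.te_ms}")
        if not 0 <= self.n_trigger_tr < self.n_tr_per_cycle:
            raise ValueError("n_trigger_tr must be < n_tr_per_cycle")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.pulse is None:
            object.__setattr__(self, "pulse", windowed_sinc_pulse(self.flip_deg))

    @property
    def n_tr_total(self) -> int:
        return self.n_cycles * self.n_tr_per_cycle

    def replace(self, **kw) -> "SequenceConfig":
        # rf increment and TE defaults must be re-derived when the contrast
        # or timing changes
        if "contrast" in kw and "rf_spoil_increment_deg" not in kw:
            kw["rf_spoil_increment_deg"] = None
        if "tr_ms" in kw and "te_ms" not in kw:
            kw["te_ms"] = None
        if "flip_deg" in kw and "pulse" not in kw:
            kw["pulse"] = None
        return replace(self, **kw)


@dataclass(frozen=True)
class BackgroundPhase:
    """Injected background phase of the flow-encoded acquisition.

    Expressed as percent of venc; 100 %venc corresponds to ``pi`` radians.
    The flow-compensated acquisition carries zero input phase by definition.
    """

    phi_pct_venc: float

    @property
    def phi_rad(self) -> float:
        return self.phi_pct_venc / 100.0 * np.pi


@dataclass
class SignalTrace:
    """Per-TR demodulated echo samples of one simulation run."""

    cycle: np.ndarray  # cycle index per TR
    tr_in_cycle: np.ndarray  # 0 .. n_tr_per_cycle - 1
    encoded: np.ndarray  # bool: flow-encoded (True) / compensated (False)
    in_window: np.ndarray  # bool: inside the acquisition window
    signal: np.ndarray  # complex echo sample
    config: SequenceConfig

    def __len__(self) -> int:
        return self.signal.size

    @property
    def time_ms(self) -> np.ndarray:
        """Echo time of each TR from the start of its cycle."""
        return self.tr_in_cycle * self.config.tr_ms + self.config.te_ms

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycle,
                "tr_in_cycle": self.tr_in_cycle,
                "encoded": self.encoded,
                "in_window": self.in_window,
                "signal": self.signal,
            }
        )


@dataclass
class PhaseContrastSeries:
    """Per-cardiac-phase phase-difference trace.

    ``pct_venc`` and ``velocity_cms`` are consistent through the configured
    venc (``v = dphi / pi * venc``).
    """

    time_ms: np.ndarray  # time of the encoding pair within its cycle
    cycle: np.ndarray  # cycle index of the encoded member of each pair
    dphi_rad: np.ndarray  # phase difference, wrapped to (-pi, pi]
    magnitude: np.ndarray  # mean |S| of the pair
    venc_cms: float

    def __len__(self) -> int:
        return self.dphi_rad.size

    @property
    def pct_venc(self) -> np.ndarray:
        return self.dphi_rad / np.pi * 100.0

    @property
    def velocity_cms(self) -> np.ndarray:
        return self.dphi_rad / np.pi * self.venc_cms

    def last_cycles(self, n: int) -> "PhaseContrastSeries":
        """Restrict to entries from the last ``n`` cycles present."""
        cycles = np.unique(self.cycle)
        keep = np.isin(self.cycle, cycles[-n:])
        return PhaseContrastSeries(
            time_ms=self.time_ms[keep],
            cycle=self.cycle[keep],
            dphi_rad=self.dphi_rad[keep],
            magnitude=self.magnitude[keep],
            venc_cms=self.venc_cms,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.time_ms,
                "cycle": self.cycle,
                "dphi_rad": self.dphi_rad,
                "pct_venc": self.pct_venc,
                "velocity_cms": self.velocity_cms,
                "magnitude": self.magnitude,
            }
        )


def rf_phase_schedule(n: int, increment_deg: float) -> np.ndarray:
    """Quadratic RF-spoiling phase schedule in degrees (not wrapped).

    ``phi_0 = 0`` and ``phi_k = phi_{k-1} + k * increment``, the standard
    recurrence for a quadratic phase increment; the receiver is demodulated
    with the same phase.
    """
    return np.cumsum(np.arange(n) * increment_deg)


def encoding_labels(config: SequenceConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-TR (cycle, tr_in_cycle, encoded) label arrays for a run.

    TR mode alternates the encoding every repetition (the steady-state
    trigger keeps alternating); ECG mode holds one encoding per cycle, and
    because the switch happens at the end of the acquisition window the
    leading trigger TRs of a cycle already carry that cycle's encoding.
    Cycle 0 is flow-compensated in both modes (window TR 0 is compensated
    in TR mode since the window length is even).
    """
    cyc = np.repeat(np.arange(config.n_cycles), config.n_tr_per_cycle)
    tic = np.tile(np.arange(config.n_tr_per_cycle), config.n_cycles)
    if config.interleave == "TR":
        enc = tic % 2 == 1
    else:
        enc = cyc % 2 == 1
    return cyc, tic, enc


def run_sequence(
    config: SequenceConfig,
    tissue: TissueProperties,
    bg: BackgroundPhase,
    extra_encoded_phase_rad: np.ndarray | None = None,
    fresh_spins: bool = False,
) -> SignalTrace:
    """Drive the Bloch engine through the full triggered schedule.

    Starting from thermal equilibrium, each TR applies: RF excitation (with
    the quadratic RF-spoiling phase schedule ``phi_k = phi_{k-1} + k * inc``
    for FLASH, constant 0 for FISP), the injected background phase (on
    flow-encoded TRs only), relaxation to TE, the echo sample demodulated at
    the exciting RF phase, relaxation to the end of TR, and the 2*pi
    gradient spoiler.

    Parameters
    ----------
    extra_encoded_phase_rad :
        Optional per-TR additional phase (radians) applied on flow-encoded
        TRs, e.g. the flow phase ``pi * v(t) / venc`` of a pulsatile vessel.
        Length must equal the total TR count.
    fresh_spins :
        If True the ensemble is reset to equilibrium before every
        excitation, emulating complete inflow replacement of the vessel
        spins; the measured phase then equals the injected phase exactly.
    """
    if config.interleave == "ECG" and config.n_cycles < 2:
        raise ValueError(
            "ECG-interleaved runs need n_cycles >= 2 for a compensated/encoded pair"
        )
    cyc, tic, enc = encoding_labels(config)
    n_total = config.n_tr_total
    if extra_encoded_phase_rad is not None:
        extra = np.asarray(extra_encoded_phase_rad, dtype=float)
        if extra.shape != (n_total,):
            raise ValueError(
                f"extra_encoded_phase_rad must have length {n_total}, got {extra.shape}"
            )
    else:
        extra = None

    ens = equilibrium_ensemble(
        tissue, config.n_slice, config.n_spoiler, config.pulse
    )
    equil = ens.copy() if fresh_spins else None
    signals = np.empty(n_total, dtype=complex)
    te = config.te_ms
    t_rest = config.tr_ms - te
    rf_phases = rf_phase_schedule(n_total, config.rf_spoil_increment_deg)
    for k in range(n_total):
        rf_phase = rf_phases[k]
        if fresh_spins:
            ens.m[:] = equil.m
        apply_rf(ens, rf_phase)
        if enc[k]:
            phi = bg.phi_rad + (extra[k] if extra is not None else 0.0)
            if phi != 0.0:
                precess_phase(ens, phi)
        relax(ens, te)
        signals[k] = read_signal(ens, rf_phase)
        relax(ens, t_rest)
        spoil_gradient(ens)
        if config.perfect_spoiling:
            zero_transverse(ens)
    return SignalTrace(
        cycle=cyc,
        tr_in_cycle=tic,
        encoded=enc,
        in_window=tic >= config.n_trigger_tr,
        signal=signals,
        config=config,
    )


def phase_contrast(
    trace: SignalTrace,
    config: SequenceConfig | None = None,
    discard_cycles: int | None = None,
) -> PhaseContrastSeries:
    """Phase-difference series from a signal trace.

    TR mode pairs consecutive in-window (compensated, encoded) repetitions
    within a cycle; ECG mode pairs in-window TR ``j`` of each encoded cycle
    with TR ``j`` of the preceding compensated cycle. The difference is
    ``arg(S_enc * conj(S_comp))``, wrapped to (-pi, pi], so it converges to
    ``+phi`` in the perfect-spoiling limit. The first ``discard_cycles``
    warm-up cycles (default: the config's ``warmup_cycles``) contribute no
    pairs.
    """
    config = config or trace.config
    if discard_cycles is None:
        discard_cycles = config.warmup_cycles
    sig, inw, enc = trace.signal, trace.in_window, trace.encoded
    cyc, t = trace.cycle, trace.time_ms
    times, cycles, dphi, mag = [], [], [], []
    if config.interleave == "TR":
        idx = np.flatnonzero(inw & (cyc >= discard_cycles))
        i = 0
        while i + 1 < idx.size:
            a, b = idx[i], idx[i + 1]
            if cyc[a] != cyc[b] or enc[a] or not enc[b]:
                i += 1
                continue
            d = np.angle(sig[b] * np.conj(sig[a]))
            times.append(0.5 * (t[a] + t[b]))
            cycles.append(cyc[b])
            dphi.append(d)
            mag.append(0.5 * (abs(sig[a]) + abs(sig[b])))
            i += 2
        # a trailing in-window compensated TR without an encoded partner
        if i < idx.size and not enc[idx[i]]:
            warnings.warn("dropping unpaired trailing compensated TR", stacklevel=2)
    else:
        n_per = config.n_tr_per_cycle
        for c in range(max(1, discard_cycles), config.n_cycles):
            if cyc[cyc == c].size == 0:
                continue
            if not enc[c * n_per]:
                continue  # pair is formed at the encoded cycle
            for j in range(config.n_trigger_tr, n_per):
                a = (c - 1) * n_per + j  # compensated cycle
                b = c * n_per + j  # encoded cycle
                d = np.angle(sig[b] * np.conj(sig[a]))
                times.append(t[b])
                cycles.append(c)
                dphi.append(d)
                mag.append(0.5 * (abs(sig[a]) + abs(sig[b])))
    if not dphi:
        raise ValueError("trace contains no complete encoding pair after warm-up")
    return PhaseContrastSeries(
        time_ms=np.asarray(times),
        cycle=np.asarray(cycles, dtype=int),
        dphi_rad=np.asarray(dphi),
        magnitude=np.asarray(mag),
        venc_cms=config.venc_cms,
    )


def steady_state_deviation(
    series: PhaseContrastSeries, bg: BackgroundPhase, n_avg: int = 20
) -> float:
    """Mean deviation (in %venc) of the measured phase contrast from the
    injected background phase over the last ``n_avg`` encoding pairs."""
    if len(series) < n_avg:
        raise ValueError(
            f"series has {len(series)} entries, need at least n_avg = {n_avg}"
        )
    return float(np.mean(series.pct_venc[-n_avg:]) - bg.phi_pct_venc)


def sweep_background(
    config: SequenceConfig,
    tissue: TissueProperties,
    phi_list: Sequence[float],
    n_avg: int = 20,
) -> pd.DataFrame:
    """Run the sequence once per injected phase (in %venc).

    Returns a DataFrame with columns ``phi_pct_venc``,
    ``deviation_pct_venc`` and ``series`` (the full
    :class:`PhaseContrastSeries`), rows in the order given.
    """
    if len(phi_list) == 0:
        raise ValueError("phi_list must be non-empty")
    rows = []
    for phi in phi_list:
        bg = BackgroundPhase(phi)
        series = phase_contrast(run_sequence(config, tissue, bg), config)
        rows.append(
            {
                "phi_pct_venc": phi,
                "deviation_pct_venc": steady_state_deviation(series, bg, n_avg),
                "series": series,
            }
        )
    return pd.DataFrame(rows)


def perturbation_metrics(series: PhaseContrastSeries, bg: BackgroundPhase) -> dict:
    """Amplitude and end-of-cycle deviation of the last cycle's trace."""
    last = series.last_cycles(1)
    dev = last.pct_venc - bg.phi_pct_venc
    return {
        "amplitude_pct_venc": float(np.max(np.abs(dev))),
        "final_deviation_pct_venc": float(dev[-1]),
    }


def sweep_relaxation(
    config: SequenceConfig,
    t1_list: Sequence[float],
    t2_list: Sequence[float],
    bg: BackgroundPhase,
    n_avg: int = 20,
) -> pd.DataFrame:
    """Sweep the tissue relaxation times at a fixed injected phase.

    Runs every (T1, T2) combination; pairs with T2 > T1 are skipped with a
    warning. Columns: ``t1_ms``, ``t2_ms``, ``deviation_pct_venc``,
    ``amplitude_pct_venc``, ``final_deviation_pct_venc``, ``series``.
    """
    if len(t1_list) == 0 or len(t2_list) == 0:
        raise ValueError("relaxation lists must be non-empty")
    rows = []
    for t1 in t1_list:
        for t2 in t2_list:
            if t2 > t1:
                warnings.warn(
                    f"skipping unphysical pair T1={t1} ms < T2={t2} ms", stacklevel=2
                )
                continue
            tissue = TissueProperties(t1_ms=t1, t2_ms=t2)
            series = phase_contrast(run_sequence(config, tissue, bg), config)
            row = {
                "t1_ms": t1,
                "t2_ms": t2,
                "deviation_pct_venc": steady_state_deviation(series, bg, n_avg),
                "series": series,
            }
            row.update(perturbation_metrics(series, bg))
            rows.append(row)
    return pd.DataFrame(rows)


def ideal_spoiled_reference(
    config: SequenceConfig, tissue: TissueProperties, bg: BackgroundPhase
) -> PhaseContrastSeries:
    """Analytic memoryless reference: the phase contrast an ideally spoiled
    sequence would measure.

    Magnitude is the Ernst steady-state value with T2 decay to TE; the phase
    equals the injected phase in every cardiac phase. Used as an oracle in
    tests and as the no-steady-state-effect baseline.
    """
    mag = ernst_signal(config.flip_deg, config.tr_ms, tissue) * np.exp(
        -config.te_ms / tissue.t2_ms
    )
    n_win = config.n_tr_per_cycle - config.n_trigger_tr
    if config.interleave == "TR":
        n_pairs = n_win // 2
        j = config.n_trigger_tr + 2 * np.arange(n_pairs)
        times = (j + 0.5) * config.tr_ms + config.te_ms
        cycles = np.full(n_pairs, config.n_cycles - 1)
    else:
        j = config.n_trigger_tr + np.arange(n_win)
        times = j * config.tr_ms + config.te_ms
        cycles = np.full(n_win, config.n_cycles - 1)
    return PhaseContrastSeries(
        time_ms=times,
        cycle=cycles,
        dphi_rad=np.full(times.size, bg.phi_rad),
        magnitude=np.full(times.size, mag),
        venc_cms=config.venc_cms,
    )
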