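"""Isochromat-level Bloch dynamics for a single imaged voxel.

The voxel is represented by an ensemble of isochromats spanning two internal
coordinates:

* a through-slice position, which maps to a per-isochromat flip-angle scale
  taken from the excitation pulse's slice profile (small-tip approximation:
  the profile is the Fourier transform of the RF envelope), and
* an intravoxel spoiler coordinate ``u`` in ``[0, 1)``, which controls the
  phase a 2*pi gradient spoiler imparts each repetition.

All operators act on the magnetization vectors in place and return the
ensemble, so they can be chained in a tight simulation loop; use
:meth:`IsochromatEnsemble.copy` when the previous state must be preserved.
Magnetization is stored as an ``(n, 3)`` float array in units of ``M0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TissueProperties",
    "RFPulseSpec",
    "IsochromatEnsemble",
    "hard_pulse",
    "windowed_sinc_pulse",
    "make_slice_profile",
    "equilibrium_ensemble",
    "apply_rf",
    "relax",
    "precess_phase",
    "spoil_gradient",
    "zero_transverse",
    "read_signal",
    "ernst_signal",
]


@dataclass(frozen=True)
class TissueProperties:
    """Relaxation properties of the simulated tissue.

    Parameters
    ----------
    t1_ms, t2_ms :
        Longitudinal / transverse relaxation times in milliseconds.
    m0 :
        Equilibrium magnetization in arbitrary units.
    """

    t1_ms: float
    t2_ms: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        if not self.t1_ms > 0:
            raise ValueError(f"T1 must be positive, got {self.t1_ms}")
        if not self.t2_ms > 0:
            raise ValueError(f"T2 must be positive, got {self.t2_ms}")
        if self.t2_ms > self.t1_ms:
            raise ValueError(
                f"T2 ({self.t2_ms} ms) must not exceed T1 ({self.t1_ms} ms)"
            )
        if not self.m0 > 0:
            raise ValueError(f"M0 must be positive, got {self.m0}")


# Gelatinous phantom tissues: P1 is an agar / pineapple-juice-doped water gel,
# P2 an agar / tap-water gel with long relaxation times.
P1_TISSUE = TissueProperties(t1_ms=720.0, t2_ms=40.0)
P2_TISSUE = TissueProperties(t1_ms=2000.0, t2_ms=160.0)


@dataclass(frozen=True)
class RFPulseSpec:
    """Sampled excitation pulse envelope plus prescribed on-resonance flip.

    ``envelope`` holds complex amplitude samples on a uniform time grid of
    spacing ``dt_ms`` centred on the pulse; only its shape matters — the
    slice profile is normalized to the profile's central value.
    """

    envelope: np.ndarray
    dt_ms: float
    nominal_flip_deg: float

    def __post_init__(self) -> None:
        env = np.atleast_1d(np.asarray(self.envelope, dtype=complex))
        if env.size == 0:
            raise ValueError("RF pulse envelope must be non-empty")
        if not 0.0 < self.nominal_flip_deg <= 90.0:
            raise ValueError(
                f"nominal flip must lie in (0, 90] degrees, got {self.nominal_flip_deg}"
            )
        if not self.dt_ms > 0:
            raise ValueError("dt_ms must be positive")
        object.__setattr__(self, "envelope", env)

    @property
    def duration_ms(self) -> float:
        return self.envelope.size * self.dt_ms

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times centred on the pulse midpoint."""
        n = self.envelope.size
        return (np.arange(n) - (n - 1) / 2.0) * self.dt_ms


def hard_pulse(flip_deg: float) -> RFPulseSpec:
    """Single-sample (delta) pulse; its slice profile is flat."""
    return RFPulseSpec(envelope=np.ones(1), dt_ms=1e-3, nominal_flip_deg=flip_deg)


def windowed_sinc_pulse(
    flip_deg: float,
    time_bandwidth: float = 2.0,
    duration_ms: float = 1.0,
    n_samples: int = 256,
    window: str = "hann",
) -> RFPulseSpec:
    """Windowed-sinc excitation pulse.

    The default (time-bandwidth 2, 1 ms, Hann apodization) is a plausible
    reconstruction of a fast-GRE excitation pulse; see the methods note for
    the sensitivity of the simulated phase errors to this choice.
    """
    t = np.linspace(-duration_ms / 2, duration_ms / 2, n_samples)
    windows = {
        "hann": np.hanning,
        "hamming": np.hamming,
        "none": np.ones,
    }
    try:
        w = windows[window](n_samples)
    except KeyError:
        raise ValueError(f"unknown window {window!r}") from None
    env = np.sinc(time_bandwidth * t / duration_ms) * w
    return RFPulseSpec(
        envelope=env, dt_ms=t[1] - t[0], nominal_flip_deg=flip_deg
    )


def make_slice_profile(
    pulse: RFPulseSpec,
    n_slice: int,
    support_cutoff: float = 0.01,
    n_freq: int = 4001,
    return_positions: bool = False,
) -> np.ndarray:
    """Per-position relative flip scales across the excited slab.

    Small-tip approximation: the excitation profile across the slice is the
    Fourier transform of the RF envelope evaluated over frequency (i.e.
    through-slice position under the slice-select gradient). ``n_slice``
    positions are sampled symmetrically over the region where the profile
    magnitude is at least ``support_cutoff`` of its central value; the
    returned scales are normalized so the slab-centre value is exactly 1.
    Sidelobe scales may be negative.
    """
    if n_slice < 1:
        raise ValueError("n_slice must be >= 1")
    env = pulse.envelope
    if env.size == 1:
        scales = np.ones(n_slice)
        if return_positions:
            return scales, np.zeros(n_slice)
        return scales
    t = pulse.times_ms

    def dft(freqs: np.ndarray) -> np.ndarray:
        return env @ np.exp(-2j * np.pi * np.outer(t, freqs))

    centre = dft(np.array([0.0]))[0]
    # locate the support on a dense grid over the full sampling bandwidth,
    # then evaluate the transform exactly at the sampled slab positions
    bw = 1.0 / pulse.dt_ms
    f = np.linspace(-bw / 2, bw / 2, n_freq)
    prof = (dft(f) / centre).real
    support = np.abs(prof) >= support_cutoff
    if not support.any():
        raise ValueError("slice profile has empty support at the given cutoff")
    half = max(-f[support].min(), f[support].max())
    if n_slice == 1:
        positions = np.array([0.0])
    else:
        positions = np.linspace(-half, half, n_slice)
    scales = (dft(positions) / centre).real
    if return_positions:
        return scales, positions
    return scales


@dataclass
class IsochromatEnsemble:
    """The simulated voxel: a bank of magnetization vectors.

    ``m`` has shape ``(n, 3)`` with columns (Mx, My, Mz) in units of ``M0``;
    ``slice_coord`` is the normalized through-slice position, ``flip_scale``
    the corresponding relative flip angle, and ``spoiler_coord`` the
    intravoxel position ``u`` such that one gradient spoiler adds phase
    ``2*pi*u``.
    """

    m: np.ndarray
    slice_coord: np.ndarray
    flip_scale: np.ndarray
    spoiler_coord: np.ndarray
    tissue: TissueProperties
    nominal_flip_deg: float

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if self.m.ndim != 2 or self.m.shape[1] != 3:
            raise ValueError("m must have shape (n, 3)")
        n = self.m.shape[0]
        for name in ("slice_coord", "flip_scale", "spoiler_coord"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)

    @property
    def n(self) -> int:
        return self.m.shape[0]

    def copy(self) -> "IsochromatEnsemble":
        return IsochromatEnsemble(
            m=self.m.copy(),
            slice_coord=self.slice_coord.copy(),
            flip_scale=self.flip_scale.copy(),
            spoiler_coord=self.spoiler_coord.copy(),
            tissue=self.tissue,
            nominal_flip_deg=self.nominal_flip_deg,
        )

    def to_npz(self, path) -> None:
        """Serialize the ensemble state for debugging."""
        np.savez(
            path,
            m=self.m,
            slice_coord=self.slice_coord,
            flip_scale=self.flip_scale,
            spoiler_coord=self.spoiler_coord,
            t1_ms=self.tissue.t1_ms,
            t2_ms=self.tissue.t2_ms,
            m0=self.tissue.m0,
            nominal_flip_deg=self.nominal_flip_deg,
        )

    @classmethod
    def from_npz(cls, path) -> "IsochromatEnsemble":
        d = np.load(path)
        return cls(
            m=d["m"],
            slice_coord=d["slice_coord"],
            flip_scale=d["flip_scale"],
            spoiler_coord=d["spoiler_coord"],
            tissue=TissueProperties(
                t1_ms=float(d["t1_ms"]), t2_ms=float(d["t2_ms"]), m0=float(d["m0"])
            ),
            nominal_flip_deg=float(d["nominal_flip_deg"]),
        )


def equilibrium_ensemble(
    tissue: TissueProperties,
    n_slice: int,
    n_spoiler: int,
    pulse: RFPulseSpec,
    support_cutoff: float = 0.01,
) -> IsochromatEnsemble:
    """Fresh ensemble at thermal equilibrium, ``(0, 0, M0)`` everywhere.

    The ``n_slice * n_spoiler`` isochromats form the outer product of the
    slice-profile positions and the uniformly spaced spoiler coordinates
    ``{k / n_spoiler}``.
    """
    if n_slice < 1 or n_spoiler < 1:
        raise ValueError("n_slice and n_spoiler must be >= 1")
    scales = make_slice_profile(pulse, n_slice, support_cutoff=support_cutoff)
    if n_slice == 1:
        positions = np.array([0.0])
    else:
        positions = np.linspace(-1.0, 1.0, n_slice)
    u = np.arange(n_spoiler) / n_spoiler
    sc, uu = np.meshgrid(positions, u, indexing="ij")
    fs = np.repeat(scales, n_spoiler)
    n = n_slice * n_spoiler
    m = np.zeros((n, 3))
    m[:, 2] = tissue.m0
    return IsochromatEnsemble(
        m=m,
        slice_coord=sc.ravel(),
        flip_scale=fs,
        spoiler_coord=uu.ravel(),
        tissue=tissue,
        nominal_flip_deg=pulse.nominal_flip_deg,
    )


def apply_rf(ens: IsochromatEnsemble, rf_phase_deg: float) -> IsochromatEnsemble:
    """Excite: rotate each isochromat by its own flip angle.

    The rotation axis lies in the transverse plane at azimuth
    ``rf_phase_deg``; the convention is fixed so that a 90 degree flip at
    phase 0 takes +z to +y (phase-contrast differences are independent of
    this handedness choice).
    """
    alpha = np.deg2rad(ens.nominal_flip_deg) * ens.flip_scale
    ca, sa = np.cos(alpha), np.sin(alpha)
    ph = np.deg2rad(rf_phase_deg)
    cp, sp = np.cos(ph), np.sin(ph)
    mx, my, mz = ens.m[:, 0], ens.m[:, 1], ens.m[:, 2]
    # rotate frame so the RF axis is +x, tip about it, rotate back
    x1 = cp * mx + sp * my
    y1 = -sp * mx + cp * my
    y2 = ca * y1 + sa * mz
    z2 = -sa * y1 + ca * mz
    ens.m[:, 0] = cp * x1 - sp * y2
    ens.m[:, 1] = sp * x1 + cp * y2
    ens.m[:, 2] = z2
    return ens


def relax(ens: IsochromatEnsemble, dt_ms: float) -> IsochromatEnsemble:
    """Free relaxation for ``dt_ms``: T2 decay of Mxy, T1 recovery of Mz."""
    if dt_ms < 0:
        raise ValueError(f"relaxation interval must be non-negative, got {dt_ms}")
    if dt_ms == 0:
        return ens
    e2 = np.exp(-dt_ms / ens.tissue.t2_ms)
    e1 = np.exp(-dt_ms / ens.tissue.t1_ms)
    ens.m[:, 0] *= e2
    ens.m[:, 1] *= e2
    ens.m[:, 2] = ens.tissue.m0 + (ens.m[:, 2] - ens.tissue.m0) * e1
    return ens


def precess_phase(ens: IsochromatEnsemble, phi_rad) -> IsochromatEnsemble:
    """Rotate every transverse component by ``phi_rad`` about +z.

    ``phi_rad`` may be a scalar (applied to all isochromats) or a per-
    isochromat array. Positive ``phi`` takes +x toward +y.
    """
    c, s = np.cos(phi_rad), np.sin(phi_rad)
    mx = ens.m[:, 0].copy()
    ens.m[:, 0] = c * mx - s * ens.m[:, 1]
    ens.m[:, 1] = s * mx + c * ens.m[:, 1]
    return ens


def spoil_gradient(ens: IsochromatEnsemble) -> IsochromatEnsemble:
    """One 2*pi gradient spoiler: add phase ``2*pi*u`` per isochromat.

    The increment is identical every call, so spoiler phase accumulates
    across repetitions and transverse coherence pathways survive — this is
    what distinguishes gradient spoiling from ideal (perfect) spoiling.
    """
    return precess_phase(ens, 2.0 * np.pi * ens.spoiler_coord)


def zero_transverse(ens: IsochromatEnsemble) -> IsochromatEnsemble:
    """Test-only perfect spoiling: discard all transverse magnetization."""
    ens.m[:, 0] = 0.0
    ens.m[:, 1] = 0.0
    return ens


def read_signal(ens: IsochromatEnsemble, receiver_phase_deg: float = 0.0) -> complex:
    """Demodulated echo sample: mean transverse magnetization.

    For RF-spoiled sequences the receiver phase must equal the exciting RF
    phase so the quadratic spoiling phase is demodulated from the signal.
    """
    s = (ens.m[:, 0] + 1j * ens.m[:, 1]).mean()
    return s * np.exp(-1j * np.deg2rad(receiver_phase_deg))


def ernst_signal(flip_deg: float, tr_ms: float, tissue: TissueProperties) -> float:
    """Steady-state signal magnitude of an ideally spoiled GRE at the echo
    of the excitation (no T2 decay): ``M0 sin(a) (1 - E1) / (1 - E1 cos(a))``.
    """
    e1 = np.exp(-tr_ms / tissue.t1_ms)
    a = np.deg2rad(flip_deg)
    return float(tissue.m0 * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a)))
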