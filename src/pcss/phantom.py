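"""Synthetic phantom scenes and per-pixel rendering of PC-MRI image stacks.

A scene is a 2D tissue-label map with relaxation properties per label, a
smooth second-order polynomial background-phase field (in %venc), and an
optional vessel with a pulsatile through-plane velocity waveform. Rendering
runs the single-voxel sequence simulation for every non-air pixel with that
pixel's injected background phase (plus the flow phase inside the vessel)
and assembles complex per-cardiac-phase image stacks for both encodings,
together with ground-truth maps.

Coordinate convention (shared with the correction module): pixel centres,
origin at the scanner isocenter (the grid centre), x to the right and y
down, normalized by half the field of view, so both coordinates span
(-1, 1) across the grid.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bloch import P1_TISSUE, P2_TISSUE, TissueProperties
from .sequence import BackgroundPhase, SequenceConfig, run_sequence

__all__ = [
    "PolynomialField",
    "PhantomScene",
    "ImageStack",
    "normalized_grid",
    "design_matrix",
    "make_scene",
    "render_timeseries",
    "save_stack",
    "load_stack",
    "export_nifti",
]

#: coefficient order of the second-order 2D polynomial
COEFF_NAMES = ("c00", "c10", "c01", "c20", "c11", "c02")


def normalized_grid(ny: int, nx: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized pixel-centre coordinates, origin at the grid centre.

    Returns ``(x, y)`` arrays of shape ``(ny, nx)``; x runs right, y runs
    down, both normalized by half the field of view (values in (-1, 1)).
    """
    x = (2.0 * (np.arange(nx) + 0.5) - nx) / nx
    y = (2.0 * (np.arange(ny) + 0.5) - ny) / ny
    return np.meshgrid(x, y, indexing="xy")


def design_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Second-order polynomial basis ``[1, x, y, x^2, xy, y^2]`` as columns."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


@dataclass(frozen=True)
class PolynomialField:
    """Second-order 2D polynomial field.

    ``phi(x, y) = c00 + c10 x + c01 y + c20 x^2 + c11 x y + c02 y^2`` with
    the normalized coordinates of :func:`normalized_grid`. ``units`` is
    ``"pct_venc"`` for background-phase fields (the default) or ``"rad"``.
    """

    coeffs: np.ndarray
    units: str = "pct_venc"

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        if c.shape != (6,):
            raise ValueError(f"need 6 coefficients {COEFF_NAMES}, got shape {c.shape}")
        object.__setattr__(self, "coeffs", c)

    @classmethod
    def from_named(cls, units: str = "pct_venc", **named: float) -> "PolynomialField":
        unknown = set(named) - set(COEFF_NAMES)
        if unknown:
            raise ValueError(f"unknown coefficients {sorted(unknown)}")
        return cls(
            coeffs=np.array([named.get(k, 0.0) for k in COEFF_NAMES]), units=units
        )

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = self.coeffs
        return (
            c[0]
            + c[1] * x
            + c[2] * y
            + c[3] * x * x
            + c[4] * x * y
            + c[5] * y * y
        )

    def on_grid(self, ny: int, nx: int) -> np.ndarray:
        return self.evaluate(*normalized_grid(ny, nx))


@dataclass(frozen=True)
class PhantomScene:
    """2D scene description for the renderer.

    ``tissue_map`` holds integer labels (0 = air / background, rendered as
    zero signal); every non-zero label must appear in ``tissue_table``.
    The optional vessel carries the periodic through-plane velocity waveform
    ``(waveform_time_ms, waveform_cms)`` sampled over one cardiac cycle.
    ``noise_sigma`` is the standard deviation of the complex Gaussian noise
    added per real/imaginary component, relative to M0.
    """

    tissue_map: np.ndarray
    tissue_table: dict
    bg_field: PolynomialField
    pixel_size_mm: float
    vessel_mask: np.ndarray | None = None
    waveform_time_ms: np.ndarray | None = None
    waveform_cms: np.ndarray | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        tm = np.asarray(self.tissue_map, dtype=int)
        object.__setattr__(self, "tissue_map", tm)
        labels = set(np.unique(tm)) - {0}
        missing = labels - set(self.tissue_table)
        if missing:
            raise ValueError(f"tissue_map labels {sorted(missing)} not in tissue_table")
        bg = self.bg_field.on_grid(*tm.shape)
        if np.any(np.abs(bg) > 100.0):
            raise ValueError("background-phase field exceeds 100 %venc on the grid")
        if self.vessel_mask is not None:
            vm = np.asarray(self.vessel_mask, dtype=bool)
            if vm.shape != tm.shape:
                raise ValueError("vessel_mask shape must match tissue_map")
            object.__setattr__(self, "vessel_mask", vm)
            if self.waveform_time_ms is None or self.waveform_cms is None:
                raise ValueError("a vessel requires a velocity waveform")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tissue_map.shape

    @property
    def fov_mm(self) -> tuple[float, float]:
        ny, nx = self.shape
        return ny * self.pixel_size_mm, nx * self.pixel_size_mm

    def velocity_at(self, t_ms: np.ndarray, period_ms: float) -> np.ndarray:
        """Vessel velocity at times within the cycle (periodic interpolation)."""
        if self.waveform_time_ms is None:
            return np.zeros_like(np.asarray(t_ms, dtype=float))
        return np.interp(
            np.asarray(t_ms, dtype=float) % period_ms,
            self.waveform_time_ms,
            self.waveform_cms,
        )


def _disc(ny: int, nx: int, pixel_mm: float, centre_mm, radius_mm: float) -> np.ndarray:
    x, y = normalized_grid(ny, nx)
    # de-normalize to millimetres
    xm = x * nx * pixel_mm / 2.0
    ym = y * ny * pixel_mm / 2.0
    cx, cy = centre_mm
    return (xm - cx) ** 2 + (ym - cy) ** 2 <= radius_mm**2


# Default background-phase field for the phantom presets: zero at isocenter,
# growing with off-centre distance to roughly +/-10 %venc across the FOV, a
# plausible stand-in for combined concomitant-field and eddy-current phase.
_DEFAULT_BG = PolynomialField.from_named(c10=6.0, c01=2.5, c20=3.0, c11=1.0, c02=1.5)


def _pulse_waveform(period_ms: float = 1020.0, n: int = 64):
    """Pulsatile arterial-like waveform: early systolic peak over a small
    baseline flow, peak 45 cm/s (below the default in-vivo venc of 60)."""
    t = np.linspace(0.0, period_ms, n)
    v = 5.0 + 40.0 * np.exp(-(((t - 150.0) / 80.0) ** 2))
    return t, v


def make_scene(preset: str, n: int | None = None, **overrides) -> PhantomScene:
    """Build a preset scene, optionally overriding any field.

    ``n`` sets the grid resolution (pixels per side) at fixed field of
    view; remaining keyword arguments override :class:`PhantomScene`
    fields.

    Presets
    -------
    ``P1_offcenter`` / ``P2_offcenter``
        A homogeneous 115 mm gel disc shifted 120 mm in-plane from the
        isocenter (FOV 370 mm, 64 x 64), with the default smooth
        background-phase field. P1: T1/T2 = 720/40 ms; P2: 2000/160 ms.
    ``vessel_demo``
        An in-vivo-like scene: a muscle-equivalent disc at the isocenter
        containing a small vessel with a pulsatile through-plane waveform.
    """
    if preset in ("P1_offcenter", "P2_offcenter"):
        ny = nx = n or 64
        pixel = 370.0 / nx
        disc = _disc(ny, nx, pixel, centre_mm=(120.0, 0.0), radius_mm=57.5)
        tissue = P1_TISSUE if preset.startswith("P1") else P2_TISSUE
        scene = PhantomScene(
            tissue_map=disc.astype(int),
            tissue_table={1: tissue},
            bg_field=_DEFAULT_BG,
            pixel_size_mm=pixel,
        )
    elif preset == "vessel_demo":
        ny = nx = n or 48
        pixel = 160.0 / nx
        body = _disc(ny, nx, pixel, centre_mm=(0.0, 0.0), radius_mm=65.0)
        vessel = _disc(ny, nx, pixel, centre_mm=(25.0, 10.0), radius_mm=5.0)
        tmap = np.where(vessel, 2, np.where(body, 1, 0))
        wt, wv = _pulse_waveform()
        scene = PhantomScene(
            tissue_map=tmap,
            tissue_table={
                1: TissueProperties(t1_ms=900.0, t2_ms=50.0),  # muscle-like
                2: TissueProperties(t1_ms=1650.0, t2_ms=180.0),  # blood-like
            },
            bg_field=_DEFAULT_BG,
            pixel_size_mm=pixel,
            vessel_mask=vessel,
            waveform_time_ms=wt,
            waveform_cms=wv,
        )
    else:
        raise ValueError(f"unknown preset {preset!r}")
    if overrides:
        scene = dataclasses.replace(scene, **overrides)
    return scene


@dataclass
class ImageStack:
    """Complex per-cardiac-phase image stacks for both encodings.

    ``comp`` and ``enc`` have shape ``(n_phases, ny, nx)``. Ground-truth
    maps from the renderer: ``truth_bg_pct`` is the injected background
    phase (%venc) per pixel and ``truth_velocity_cms`` the vessel velocity
    per phase and pixel (zero outside the vessel).
    """

    comp: np.ndarray
    enc: np.ndarray
    phase_times_ms: np.ndarray
    venc_cms: float
    tr_ms: float
    pixel_size_mm: float
    truth_bg_pct: np.ndarray | None = None
    truth_velocity_cms: np.ndarray | None = None

    @property
    def n_phases(self) -> int:
        return self.comp.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.comp.shape[1:]

    def magnitude(self) -> np.ndarray:
        """Mean magnitude of the two encodings per phase and pixel."""
        return 0.5 * (np.abs(self.comp) + np.abs(self.enc))

    def phase_difference_rad(self) -> np.ndarray:
        return np.angle(self.enc * np.conj(self.comp))

    def phase_pct_venc(self) -> np.ndarray:
        return self.phase_difference_rad() / np.pi * 100.0

    def velocity_cms(self) -> np.ndarray:
        return self.phase_difference_rad() / np.pi * self.venc_cms

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_size_mm**2


def _extract_pairs(trace, config: SequenceConfig):
    """Last acquisition window's (compensated, encoded) complex samples.

    Returns ``(times_ms, enc_times_ms, s_comp, s_enc)`` for the final
    encoded window: in TR mode the alternating pairs of the last cycle, in
    ECG mode the last encoded cycle paired TR-by-TR with its preceding
    compensated cycle. ``enc_times_ms`` is the echo time of each pair's
    flow-encoded member — the instant the vessel velocity is sampled.
    """
    sig, cyc, tic = trace.signal, trace.cycle, trace.tr_in_cycle
    inw, enc = trace.in_window, trace.encoded
    t = trace.time_ms
    if config.interleave == "TR":
        sel = np.flatnonzero((cyc == config.n_cycles - 1) & inw)
        comp_idx = sel[~enc[sel]]
        enc_idx = sel[enc[sel]]
        n = min(comp_idx.size, enc_idx.size)
        comp_idx, enc_idx = comp_idx[:n], enc_idx[:n]
        times = 0.5 * (t[comp_idx] + t[enc_idx])
    else:
        c_enc = config.n_cycles - 1
        if not enc[c_enc * config.n_tr_per_cycle]:
            c_enc -= 1
        sel_e = np.flatnonzero((cyc == c_enc) & inw)
        sel_c = np.flatnonzero((cyc == c_enc - 1) & inw)
        comp_idx, enc_idx = sel_c, sel_e
        times = t[enc_idx]
    return times, t[enc_idx], sig[comp_idx], sig[enc_idx]


def _decimate(times, enc_times, s_comp, s_enc, n_phases):
    """Average consecutive pairs down to ``n_phases`` cardiac phases."""
    n = times.size
    if n_phases is None or n_phases == n:
        return times, enc_times, s_comp, s_enc
    if n % n_phases != 0:
        raise ValueError(
            f"{n} encoding pairs cannot be decimated evenly to {n_phases} phases"
        )
    f = n // n_phases
    return (
        times.reshape(n_phases, f).mean(axis=1),
        enc_times.reshape(n_phases, f).mean(axis=1),
        s_comp.reshape(n_phases, f).mean(axis=1),
        s_enc.reshape(n_phases, f).mean(axis=1),
    )


def render_timeseries(
    scene: PhantomScene,
    config: SequenceConfig,
    n_phases: int | None = 35,
    cache_quantum_pct: float = 0.05,
    use_cache: bool = True,
    fresh_spin_vessel: bool = False,
) -> ImageStack:
    """Render the scene into complex image stacks per encoding.

    Every non-air pixel is simulated with the single-voxel engine under its
    local injected background phase; pixels with the same tissue and the
    same background phase (quantized to ``cache_quantum_pct`` when
    ``use_cache`` is on) share one simulation. Vessel pixels additionally
    accrue the flow phase ``pi * v(t) / venc`` on flow-encoded repetitions;
    with ``fresh_spin_vessel`` their magnetization is replaced by fresh
    equilibrium spins every TR (complete inflow), which suppresses
    steady-state effects in the vessel entirely.

    The acquisition window's encoding pairs are decimated to ``n_phases``
    cardiac phases by complex averaging (``None`` disables decimation).
    Complex Gaussian noise of standard deviation ``scene.noise_sigma`` is
    added per component, pixel, phase and encoding using ``scene.seed``.
    """
    ny, nx = scene.shape
    x, y = normalized_grid(ny, nx)
    bg_map = scene.bg_field.evaluate(x, y)
    period_ms = config.n_tr_per_cycle * config.tr_ms

    vessel = (
        scene.vessel_mask
        if scene.vessel_mask is not None
        else np.zeros((ny, nx), dtype=bool)
    )
    if scene.waveform_cms is not None:
        vmax = float(np.max(np.abs(scene.waveform_cms)))
        if vmax >= config.venc_cms:
            raise ValueError(
                f"vessel velocity peak {vmax} cm/s reaches venc {config.venc_cms}; "
                "phase wrapping is not modelled"
            )
        tr_times = trace_times = (
            np.tile(np.arange(config.n_tr_per_cycle), config.n_cycles) * config.tr_ms
            + config.te_ms
        )
        v_per_tr = scene.velocity_at(trace_times, period_ms)
        extra_flow = np.pi * v_per_tr / config.venc_cms
    else:
        extra_flow = None

    def quantize(v: float) -> float:
        if not use_cache:
            return float(v)
        return float(np.round(v / cache_quantum_pct) * cache_quantum_pct)

    # group pixels by (label, quantized bg, vessel?) so identical voxels
    # share one Bloch simulation
    groups: dict = {}
    for iy, ix in zip(*np.nonzero(scene.tissue_map)):
        key = (
            int(scene.tissue_map[iy, ix]),
            quantize(bg_map[iy, ix]),
            bool(vessel[iy, ix]),
        )
        groups.setdefault(key, []).append((iy, ix))

    first = True
    comp = enc = times = None
    for key in sorted(groups):
        label, qbg, is_vessel = key
        tissue = scene.tissue_table[label]
        trace = run_sequence(
            config,
            tissue,
            BackgroundPhase(qbg),
            extra_encoded_phase_rad=extra_flow if is_vessel else None,
            fresh_spins=fresh_spin_vessel and is_vessel,
        )
        t, t_enc, sc, se = _decimate(*_extract_pairs(trace, config), n_phases)
        if first:
            times, enc_times = t, t_enc
            comp = np.zeros((t.size, ny, nx), dtype=complex)
            enc = np.zeros_like(comp)
            first = False
        for iy, ix in groups[key]:
            comp[:, iy, ix] = sc
            enc[:, iy, ix] = se
    if first:
        raise ValueError("scene contains no non-air pixels")

    truth_v = np.zeros((times.size, ny, nx))
    if vessel.any() and scene.waveform_cms is not None:
        # velocity as sampled by the flow-encoded echo of each pair
        v_phase = scene.velocity_at(enc_times, period_ms)
        truth_v[:, vessel] = v_phase[:, None]

    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        shape = comp.shape
        for arr in (comp, enc):
            arr += rng.normal(scale=scene.noise_sigma, size=shape)
            arr += 1j * rng.normal(scale=scene.noise_sigma, size=shape)

    return ImageStack(
        comp=comp,
        enc=enc,
        phase_times_ms=times,
        venc_cms=config.venc_cms,
        tr_ms=config.tr_ms,
        pixel_size_mm=scene.pixel_size_mm,
        truth_bg_pct=np.where(scene.tissue_map > 0, bg_map, 0.0),
        truth_velocity_cms=truth_v,
    )


_REQUIRED_META = ("venc_cms", "tr_ms", "pixel_size_mm", "phase_times_ms")


def save_stack(stack: ImageStack, path) -> None:
    """Lossless round-trip container: ``.npz`` arrays + JSON sidecar.

    ``path`` is the basename; ``<path>.npz`` holds the complex arrays and
    ground-truth maps, ``<path>.json`` the acquisition metadata.
    """
    path = Path(path)
    arrays = {"comp": stack.comp, "enc": stack.enc}
    if stack.truth_bg_pct is not None:
        arrays["truth_bg_pct"] = stack.truth_bg_pct
    if stack.truth_velocity_cms is not None:
        arrays["truth_velocity_cms"] = stack.truth_velocity_cms
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "venc_cms": stack.venc_cms,
        "tr_ms": stack.tr_ms,
        "pixel_size_mm": stack.pixel_size_mm,
        "phase_times_ms": stack.phase_times_ms.tolist(),
        "encodings": ["compensated", "encoded"],
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_stack(path) -> ImageStack:
    """Load a stack written by :func:`save_stack`; validates the sidecar."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in _REQUIRED_META:
        if key not in meta:
            raise ValueError(f"sidecar missing required field {key!r}")
    d = np.load(path.with_suffix(".npz"))
    return ImageStack(
        comp=d["comp"],
        enc=d["enc"],
        phase_times_ms=np.asarray(meta["phase_times_ms"]),
        venc_cms=float(meta["venc_cms"]),
        tr_ms=float(meta["tr_ms"]),
        pixel_size_mm=float(meta["pixel_size_mm"]),
        truth_bg_pct=d["truth_bg_pct"] if "truth_bg_pct" in d else None,
        truth_velocity_cms=(
            d["truth_velocity_cms"] if "truth_velocity_cms" in d else None
        ),
    )


def export_nifti(stack: ImageStack, prefix) -> list[Path]:
    """NIfTI export: magnitude/phase volume pairs per encoding + sidecar.

    Phase volumes are stored in radians, wrapped to (-pi, pi]. Returns the
    written paths.
    """
    import nibabel as nib

    prefix = Path(prefix)
    affine = np.diag([stack.pixel_size_mm, stack.pixel_size_mm, 1.0, 1.0])
    written = []
    for name, arr in (("comp", stack.comp), ("enc", stack.enc)):
        # (nphase, ny, nx) -> (nx, ny, 1, nphase) spatial-first layout
        vol = np.transpose(arr, (2, 1, 0))[:, :, None, :]
        for kind, data in (("mag", np.abs(vol)), ("phase", np.angle(vol))):
            p = prefix.parent / f"{prefix.name}_{name}_{kind}.nii"
            nib.save(nib.Nifti1Image(data.astype(np.float64), affine), p)
            written.append(p)
    meta = {
        "venc_cms": stack.venc_cms,
        "tr_ms": stack.tr_ms,
        "pixel_size_mm": stack.pixel_size_mm,
        "phase_times_ms": stack.phase_times_ms.tolist(),
        "encodings": ["compensated", "encoded"],
        "phase_units": "rad",
    }
    p = prefix.parent / f"{prefix.name}_meta.json"
    p.write_text(json.dumps(meta, indent=1))
    written.append(p)
    return written
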