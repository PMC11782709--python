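import numpy as np
import pytest

from pcss import P1_TISSUE, P2_TISSUE, SequenceConfig, TissueProperties
from pcss.phantom import PhantomScene, PolynomialField


@pytest.fixture(scope="session")
def p1():
    return P1_TISSUE


@pytest.fixture(scope="session")
def p2():
    return P2_TISSUE


@pytest.fixture
def fast_tr_config():
    """TR-interleaved config with reduced isochromat counts for speed."""
    return SequenceConfig(
        contrast="FISP", interleave="TR", n_slice=17, n_spoiler=50, n_cycles=4
    )


@pytest.fixture
def fast_ecg_config():
    return SequenceConfig(
        contrast="FISP", interleave="ECG", n_slice=17, n_spoiler=50, n_cycles=6
    )


@pytest.fixture
def tiny_config():
    """Very small schedule for pairing / identity checks."""
    return SequenceConfig(
        contrast="FISP",
        interleave="TR",
        n_tr_per_cycle=12,
        n_trigger_tr=2,
        n_cycles=4,
        n_slice=3,
        n_spoiler=8,
    )


def small_scene(ny=6, nx=6, bg=(0.0, 0.0, 0.0, 0.0, 0.0, 0.0), **kw) -> PhantomScene:
    """Two-tissue checkerboard scene with one air corner."""
    tmap = np.ones((ny, nx), dtype=int)
    tmap[ny // 2 :, :] = 2
    tmap[0, 0] = 0
    defaults = dict(
        tissue_map=tmap,
        tissue_table={
            1: TissueProperties(t1_ms=720.0, t2_ms=40.0),
            2: TissueProperties(t1_ms=2000.0, t2_ms=160.0),
        },
        bg_field=PolynomialField(np.asarray(bg, dtype=float)),
        pixel_size_mm=2.0,
    )
    defaults.update(kw)
    return PhantomScene(**defaults)
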