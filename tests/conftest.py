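from pathlib import Path

import pytest

from irpdx import synthio, xenodeconv
from irpdx.somatic import read_variant_tsv

DATA = Path(__file__).parent / "data"

TOY_PURITY = {"T1": 0.5, "T2": 0.8}


@pytest.fixture(scope="session")
def toy_table():
    """20-variant toy call table with one planted violation per filter rule."""
    return read_variant_tsv(DATA / "toy_variants.tsv", normal="N", purity=dict(TOY_PURITY))


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size study conditions for fast unit tests."""
    return synthio.SynthConfig(seed=7, n_cells=600, cells_per_condition=120)


@pytest.fixture(scope="session")
def state_adata(small_config):
    """QC'd, normalised planted state mixture (small)."""
    adata = synthio.gen_state_mixture_counts(small_config)
    adata, _ = xenodeconv.qc_filter(adata)
    return xenodeconv.normalize_log(adata)
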