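import numpy as np
import pytest

from evopool.synthetic_data import (
    LayoutConfig,
    generate_founder_panel,
    generate_genome_layout,
    generate_pooled_experiment,
)
from evopool.variant_filters import LineGroup


@pytest.fixture(scope="session")
def small_layout():
    """5-chromosome synthetic genome with 200 annotated genes."""
    return generate_genome_layout(LayoutConfig(), seed=11)


@pytest.fixture(scope="session")
def small_panel(small_layout):
    layout, _ = small_layout
    return generate_founder_panel(205, 20_000, layout, seed=12)


@pytest.fixture(scope="session")
def pooled_fixture(tmp_path_factory, small_layout, small_panel):
    """Synthetic pooled experiment written as one multi-sample VCF."""
    layout, genes = small_layout
    out = tmp_path_factory.mktemp("pooled")
    paths, truth = generate_pooled_experiment(
        layout, small_panel, seed=13, out_dir=out, genes=genes
    )
    return {"layout": layout, "genes": genes, "paths": paths, "truth": truth, "out": out}


@pytest.fixture(scope="session")
def line_group():
    return LineGroup.default()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
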