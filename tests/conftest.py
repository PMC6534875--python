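import numpy as np
import pandas as pd
import pytest

from quantiseq.synthetic import make_fixtures


@pytest.fixture(scope="session")
def bundle():
    """Deterministic synthetic fixture bundle shared across the suite."""
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def compendium(bundle):
    return bundle.compendium


@pytest.fixture(scope="session")
def signature_standin(bundle):
    """Synthetic 170-gene signature stand-in (10 cell types)."""
    return bundle.signature


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_expression_tsv(path, frame: pd.DataFrame, gene_col: str = "GENE") -> None:
    out = frame.copy()
    out.index.name = gene_col
    out.to_csv(path, sep="\t")
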