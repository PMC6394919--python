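import numpy as np
import pandas as pd
import pytest

from genopred import preprocess, synthio
from genopred.datatypes import GenotypeMatrix


def make_matrix(values, birth_year=None, fractional=False):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return GenotypeMatrix(
        values=values,
        individual_ids=[f"i{k}" for k in range(n)],
        marker_ids=[f"m{k}" for k in range(m)],
        birth_year=birth_year,
        fractional=fractional,
    )


@pytest.fixture(scope="session")
def polygenic_study():
    arch = synthio.TraitArchitecture(kind="polygenic", h2=0.5)
    return synthio.simulate_study(300, 200, arch, missing_rate=0.02, seed=42)


@pytest.fixture(scope="session")
def complete_panel(polygenic_study):
    """QC'd, imputed genotypes with aligned y* from the polygenic study."""
    g, _ = preprocess.filter_markers(polygenic_study.genotypes)
    g = preprocess.filter_samples(g)
    g = preprocess.impute_missing(g)
    adj = preprocess.adjust_phenotype(polygenic_study.phenotypes)
    y = pd.Series(adj.y_star, index=adj.ids).loc[g.individual_ids].to_numpy()
    return g, y
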