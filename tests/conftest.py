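import numpy as np
import pandas as pd
import pytest

from rangeshift.datatypes import GenotypeMatrix, OTUTable


def make_genotypes(calls, sites, coverage=None):
    """Build a GenotypeMatrix from a plain list-of-lists of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_loci = calls.shape
    locus_ids = np.array([f"L{i + 1:03d}" for i in range(n_loci)], object)
    meta = pd.DataFrame(
        {"coverage": coverage if coverage is not None else np.full(n_loci, 50.0)},
        index=pd.Index(locus_ids, name="locus"),
    )
    return GenotypeMatrix(
        calls=calls,
        locus_ids=locus_ids,
        individual_ids=np.array([f"i{j}" for j in range(n_ind)], object),
        sites=np.asarray(sites, object),
        locus_meta=meta,
    )


def make_otu_table(counts: dict, groups: dict, controls=(), match_rows=()):
    """Build an OTUTable from {otu: {sample: count}} and {sample: group}."""
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    df = df[list(groups)]
    meta = pd.DataFrame(
        {"group": [groups[s] for s in df.columns],
         "is_control": [s in controls for s in df.columns]},
        index=pd.Index(df.columns, name="sample"),
    )
    match = pd.DataFrame(list(match_rows), columns=["otu_a", "otu_b", "pct_identity"])
    return OTUTable(counts=df, sample_meta=meta, match_list=match)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
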