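import numpy as np
import pandas as pd
import pytest

from imhaseq import diffexpr as de
from imhaseq import synthetic as syn

COHORT_SEED = 20201022  # fixed study seed for the shared fixtures


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort: spec, CBC records, counts, metadata."""
    spec = syn.default_cohort_spec()
    cbcs = syn.simulate_cbc(spec, COHORT_SEED)
    cm = syn.simulate_expression(cbcs, spec, COHORT_SEED + 1)
    meta = syn.cohort_metadata(cbcs)
    return {"spec": spec, "cbcs": cbcs, "cm": cm, "meta": meta}


@pytest.fixture(scope="session")
def de_pipeline(cohort):
    """Prefiltered counts, size factors, VST, and NB test results."""
    cm = de.prefilter(cohort["cm"])
    sf = de.size_factors(cm)
    vst = de.vst(cm, sf)
    res = de.nb_test(cm, cohort["meta"]["group"], sf)
    return {"cm": cm, "sf": sf, "vst": vst, "res": res}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_counts(arr, genes=None, samples=None, lengths=None):
    """Helper: build a CountMatrix from a plain array."""
    from imhaseq.io import CountMatrix

    arr = np.asarray(arr, dtype=np.int64)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=genes, columns=samples)
    if lengths is not None:
        lengths = pd.Series(np.asarray(lengths, dtype=float), index=genes)
    return CountMatrix(df, gene_lengths=lengths)
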