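import logging

import numpy as np
import pandas as pd
import pytest

from leukomics.io import OmicsMatrix, SampleMetadata, collapse_replicates, align_samples
from leukomics.simulate import SimulationConfig, simulate_cohort

logging.getLogger("leukomics").setLevel(logging.ERROR)


def make_matrix(values, genes=None, samples=None, kind="protein_log2ratio"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"S{i + 1}" for i in range(values.shape[1])]
    return OmicsMatrix(pd.DataFrame(values, index=genes, columns=samples), kind=kind)


def make_metadata(samples, lineages=None, replicate_of=None):
    lineages = lineages or ["B"] * len(samples)
    rep = replicate_of or {}
    df = pd.DataFrame({
        "lineage": lineages,
        "subtype": ["s1"] * len(samples),
        "replicate_of": [rep.get(s, np.nan) for s in samples],
    }, index=pd.Index(samples, name="sample_id"))
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (seed 7): raw layers plus ground truth."""
    protein, mrna, meta, truth = simulate_cohort(SimulationConfig(seed=7))
    return {"protein": protein, "mrna": mrna, "meta": meta, "truth": truth}


@pytest.fixture(scope="session")
def collapsed_cohort(default_cohort):
    """Replicates collapsed and layers sample-aligned (64 matched samples)."""
    protein = collapse_replicates(default_cohort["protein"], default_cohort["meta"])
    prot_a, mrna_a, shared = align_samples(protein, default_cohort["mrna"])
    return {"protein": prot_a, "mrna": mrna_a, "shared": shared,
            "meta": default_cohort["meta"], "truth": default_cohort["truth"]}
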