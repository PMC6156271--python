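"""Shared fixtures: simulated reference databases and community datasets.

The two large simulated datasets (clean-recovery and QC-challenge) are
session-scoped because the alignment search over them dominates suite
runtime; every test using them sees the identical frozen conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import microcensus as mc

#: Reference database used by all simulation-driven tests: 1000 bp records
#: (metagenome-style 16S genes) keep the Smith-Waterman cost moderate.
REF_KW = dict(n_bacteria=12, n_archaea=4, length=1000, seed=7)


@pytest.fixture(scope="session")
def refs() -> mc.ReferenceSet:
    return mc.generate_reference_db(**REF_KW)


@pytest.fixture(scope="session")
def env_db(refs) -> mc.ReferenceSet:
    return mc.generate_environmental_db(refs, 16, seed=8)


def _records_table(dataset: mc.EnvironmentDataset) -> pd.DataFrame:
    records = dataset.metadata.set_index("query_id")
    records["length"] = [len(dataset.sequences[q]) for q in records.index]
    return records


@pytest.fixture(scope="session")
def recovery_dataset(refs):
    """Clean community, truth proportions 0.2/0.3/0.5, n=300, one sample."""
    spec = mc.CommunitySpec(environment="soil", n_samples=1,
                            n_seqs_per_sample=300,
                            bin_proportions=(0.2, 0.3, 0.5), seed=42)
    dataset = mc.generate_environment_dataset(spec, refs)
    hits = mc.search_all(dataset.sequences, refs)
    return dataset, hits


@pytest.fixture(scope="session")
def qc_dataset(refs, env_db):
    """Community with injected artifacts: 540 clean, 60 chimeras, 200 fragments."""
    spec = mc.CommunitySpec(environment="sediment", n_samples=1,
                            n_seqs_per_sample=800,
                            bin_proportions=(0.2, 0.3, 0.5),
                            chimera_rate=0.075, short_fragment_rate=0.25,
                            seed=43)
    dataset = mc.generate_environment_dataset(spec, refs)
    hits = mc.search_all(dataset.sequences, refs)
    records = _records_table(dataset)
    h = hits.set_index("query_id")
    screened = {
        qid: dataset.sequences[qid]
        for qid in records.index
        if bool(h.loc[qid, "no_hit"])
        or float(h.loc[qid, "qlen_aligned"]) / records.loc[qid, "length"] < 0.90
    }
    hits_env = mc.search_all(screened, env_db) if screened else None
    report = mc.run_qc(records, hits, hits_env)
    return dataset, hits, report


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
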