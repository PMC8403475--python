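import numpy as np
import pandas as pd
import pytest

from dietquant import BiasModel, ReadCountTable, build_design

VOLE_TAXA = ("Trifolium", "Salix", "Avenella")


@pytest.fixture(scope="session")
def vole_design():
    """The three-taxon 60/30/10 rotation design with 9 animals, 3 replicates."""
    return build_design(VOLE_TAXA)


@pytest.fixture
def quiet_bias():
    """No contamination, no aberrant replicates: noise from counting only."""
    return BiasModel(contaminant_rate=0.0, outlier_replicate_rate=0.0)


def make_table(counts: dict, motus: dict | None = None, sample_type="faeces") -> ReadCountTable:
    """Build a small ReadCountTable from {(sample, rep): {motu: count}}.

    ``motus`` optionally overrides (taxon, best_identity, clean_status)
    per motu id; defaults to a clean MOTU named after itself.
    """
    frame = pd.DataFrame(counts).fillna(0).astype(np.int64)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["sample", "replicate"])
    motu_ids = list(frame.index)
    meta = {m: ((m, 1.0, "ok") if motus is None else motus.get(m, (m, 1.0, "ok")))
            for m in motu_ids}
    motu_df = pd.DataFrame(
        [meta[m] for m in motu_ids],
        index=pd.Index(motu_ids, name="motu_id"),
        columns=["taxon", "best_identity", "clean_status"],
    )
    sample_ids = list(dict.fromkeys(frame.columns.get_level_values(0)))
    samples = pd.DataFrame(
        {
            "sample_type": sample_type,
            "mixture": "",
            "animal": "",
            "status": "ok",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ReadCountTable(counts=frame, motus=motu_df, samples=samples)


@pytest.fixture
def small_table():
    """Three samples x two replicates over three MOTUs, clean and distinct."""
    return make_table(
        {
            ("s1", 1): {"a": 80, "b": 15, "c": 5},
            ("s1", 2): {"a": 82, "b": 13, "c": 5},
            ("s2", 1): {"a": 10, "b": 70, "c": 20},
            ("s2", 2): {"a": 12, "b": 68, "c": 20},
            ("s3", 1): {"a": 30, "b": 10, "c": 60},
            ("s3", 2): {"a": 28, "b": 12, "c": 60},
        }
    )
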