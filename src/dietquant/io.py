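"""Readers, writers and configuration shared by all pipeline stages.

Interchange formats are deliberately plain text:

* replicate-level count tables — tab-separated, one row per MOTU with
  columns ``motu_id, taxon, best_identity, clean_status`` followed by one
  ``sample:replicate`` count column per PCR replicate, plus a
  ``*.samples.tsv`` sidecar declaring sample metadata and the replicate
  columns each sample owns;
* composition matrices (expected biomass, RRA) — CSV, samples x taxa;
* ground-truth records — YAML;
* MOTU sequences — FASTA (optional, for format completeness).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ReadCountTable, TableValidationError, validate_composition

META_COLUMNS = ["motu_id", "taxon", "best_identity", "clean_status"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """All tunable thresholds and sizes of the analysis, in one place."""

    low_freq_threshold: float = 0.01
    low_freq_per_replicate: bool = False
    min_identity: float = 0.85
    outlier_alpha: float = 0.05
    outlier_floor_factor: float = 5.0
    outlier_max_iter: int = 10
    n_perm: int = 1000
    n_boot: int = 1000
    ci_level: float = 0.95
    tol: float = 1e-8
    max_iter: int = 10_000
    taxon_map: dict = field(default_factory=dict)
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        checks = [
            (0.0 <= self.low_freq_threshold < 1.0, "low_freq_threshold in [0, 1)"),
            (0.0 <= self.min_identity <= 1.0, "min_identity in [0, 1]"),
            (0.0 < self.outlier_alpha < 1.0, "outlier_alpha in (0, 1)"),
            (self.outlier_floor_factor >= 0, "outlier_floor_factor >= 0"),
            (self.outlier_max_iter >= 1, "outlier_max_iter >= 1"),
            (self.n_perm >= 1, "n_perm >= 1"),
            (self.n_boot >= 1, "n_boot >= 1"),
            (0.0 < self.ci_level < 1.0, "ci_level in (0, 1)"),
            (self.tol > 0, "tol > 0"),
            (self.max_iter >= 1, "max_iter >= 1"),
        ]
        for ok, what in checks:
            if not ok:
                raise ConfigError(f"configuration requires {what}")
        if not isinstance(self.taxon_map, dict):
            raise ConfigError("taxon_map must be a mapping taxon -> taxon or 'DROP'")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(
                f"{path}: unknown config keys {sorted(unknown)}; known keys: {sorted(known)}"
            )
        return cls(**raw)

    def to_file(self, path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# -- replicate-level count tables ---------------------------------------------


def _sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".samples.tsv")


def write_count_table(table: ReadCountTable, path) -> None:
    """Write the TSV dialect plus its ``*.samples.tsv`` metadata sidecar."""
    path = Path(path)
    out = table.motus.reset_index()
    out.columns = META_COLUMNS
    counts = table.counts.copy()
    counts.columns = [f"{s}:{r}" for s, r in counts.columns]
    out = pd.concat([out, counts.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)
    samples = table.samples.copy()
    reps = {
        s: ",".join(str(r) for s2, r in table.counts.columns if s2 == s)
        for s in table.samples.index
    }
    samples["replicates"] = [reps.get(s, "") for s in samples.index]
    samples.reset_index(names="sample_id").to_csv(_sidecar(path), sep="\t", index=False)


def read_count_table(path) -> ReadCountTable:
    """Read a count table written by :func:`write_count_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise TableValidationError(
            f"missing sample metadata sidecar {sidecar.name} next to {path.name}"
        )
    frame = pd.read_csv(path, sep="\t", dtype={"clean_status": str, "taxon": str})
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise TableValidationError(f"{path}: missing metadata columns {missing}")
    count_cols = [c for c in frame.columns if c not in META_COLUMNS]
    bad = [c for c in count_cols if ":" not in c]
    if bad:
        raise TableValidationError(
            f"{path}: count columns must be named 'sample:replicate'; got {bad}"
        )
    for c in count_cols:
        col = frame[c]
        if not np.issubdtype(col.dtype, np.number) or not np.allclose(col, np.round(col)):
            raise TableValidationError(f"{path}: column {c!r} holds non-integer counts")
        neg = col[col < 0]
        if not neg.empty:
            line = int(neg.index[0]) + 2  # header is line 1
            raise TableValidationError(
                f"{path}:{line}: negative count in column {c!r}, motu "
                f"{frame.loc[neg.index[0], 'motu_id']!r}"
            )
    motus = frame[META_COLUMNS].set_index("motu_id")
    counts = frame[count_cols].astype(np.int64)
    counts.index = motus.index

    def _rep(label: str):
        s, r = label.rsplit(":", 1)
        return (s, int(r) if r.isdigit() else r)

    counts.columns = pd.MultiIndex.from_tuples(
        [_rep(c) for c in count_cols], names=["sample", "replicate"]
    )
    samples = pd.read_csv(sidecar, sep="\t", dtype=str).fillna("").set_index("sample_id")
    declared = {
        s: [int(r) if r.isdigit() else r for r in row.split(",") if r != ""]
        for s, row in samples["replicates"].items()
    }
    expected = [(s, r) for s in samples.index for r in declared[s]]
    got = list(counts.columns)
    if sorted(map(str, got)) != sorted(map(str, expected)):
        miss = sorted(set(map(str, expected)) - set(map(str, got)))
        extra = sorted(set(map(str, got)) - set(map(str, expected)))
        raise TableValidationError(
            f"{path}: replicate columns disagree with {sidecar.name} "
            f"(missing {miss}, undeclared {extra})"
        )
    samples = samples.drop(columns=["replicates"])
    return ReadCountTable(counts=counts, motus=motus, samples=samples)


# -- composition matrices ------------------------------------------------------


def write_composition_csv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(Path(path), index_label="sample_id")


def read_composition_csv(path) -> pd.DataFrame:
    """Read a samples x taxa CSV; rows within 1e-6 of unit sum are
    renormalised, anything further off is rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise TableValidationError(f"{path}: empty file")
    frame = pd.read_csv(path, index_col=0)
    if frame.empty:
        raise TableValidationError(f"{path}: no composition rows")
    return validate_composition(frame, renorm_atol=1e-6)


# -- ground truth --------------------------------------------------------------


def write_truth_record(truth, path) -> None:
    from .synthetic import TruthRecord  # deferred to avoid an import cycle

    assert isinstance(truth, TruthRecord)
    data = {
        "seed": truth.seed,
        "taxa": list(truth.true_compositions.columns),
        "true_compositions": {
            s: [float(v) for v in row]
            for s, row in truth.true_compositions.iterrows()
        },
        "expected_compositions": {
            s: [float(v) for v in row]
            for s, row in truth.expected_compositions.iterrows()
        },
        "implied_B": {
            stype: {str(j): [float(v) for v in row] for j, row in B.iterrows()}
            for stype, B in truth.implied_B.items()
        },
        "outlier_replicates": [[s, int(r)] for s, r in truth.outlier_replicates],
        "contaminant_motus": list(truth.contaminant_motus),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_truth_record(path):
    from .synthetic import TruthRecord

    data = yaml.safe_load(Path(path).read_text())
    taxa = data["taxa"]
    true_df = pd.DataFrame.from_dict(data["true_compositions"], orient="index", columns=taxa)
    exp_df = pd.DataFrame.from_dict(
        data["expected_compositions"], orient="index", columns=taxa
    )
    implied = {
        stype: pd.DataFrame.from_dict(rows, orient="index", columns=taxa)
        for stype, rows in data["implied_B"].items()
    }
    return TruthRecord(
        true_compositions=true_df,
        expected_compositions=exp_df,
        implied_B=implied,
        seed=int(data["seed"]),
        outlier_replicates=[(s, r) for s, r in data["outlier_replicates"]],
        contaminant_motus=list(data["contaminant_motus"]),
    )


def write_motu_fasta(table: ReadCountTable, path, seed: int = 0) -> None:
    """Emit placeholder barcode sequences for each MOTU (synthetic; the
    simulator models tables, not sequences)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(seed)
    records = []
    for motu_id, row in table.motus.iterrows():
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(45, 57))))
        records.append(
            SeqRecord(
                Seq(seq),
                id=str(motu_id),
                description=f"taxon={row['taxon']} best_identity={row['best_identity']}",
            )
        )
    seqio_write(records, str(path), "fasta")
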