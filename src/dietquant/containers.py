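"""Shared in-memory containers for the metabarcoding pipeline.

The pipeline moves through three table shapes:

* :class:`ReadCountTable` — MOTU x (sample, PCR replicate) integer read
  counts, plus MOTU metadata (taxon assignment, best reference identity,
  clean-status flag) and sample metadata (type, meal mixture, animal).
* :class:`MeanCountTable` — MOTU x sample real-valued counts after the
  surviving PCR replicates of each sample have been averaged.
* Composition matrices — plain :class:`pandas.DataFrame` objects with one
  row per sample on the unit simplex (expected biomass or relative read
  abundance), validated by :func:`validate_composition`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: clean-status values a MOTU record may carry ("flagged" marks a likely
#: PCR/sequencing artefact identified upstream).
CLEAN_STATUSES = ("ok", "flagged")

#: recognised sample types of a feeding trial.
SAMPLE_TYPES = ("single_plant", "meal_mixture", "faeces")

MOTU_COLUMNS = ("taxon", "best_identity", "clean_status")
SAMPLE_COLUMNS = ("sample_type", "mixture", "animal")


class TableValidationError(ValueError):
    """A table violates the dialect contract (shape, dtype or metadata)."""


def _check_motus(motus: pd.DataFrame) -> None:
    missing = [c for c in MOTU_COLUMNS if c not in motus.columns]
    if missing:
        raise TableValidationError(f"MOTU metadata lacks columns {missing}")
    if motus.index.has_duplicates:
        dup = motus.index[motus.index.duplicated()].tolist()
        raise TableValidationError(f"duplicate motu_id entries: {dup}")
    ident = motus["best_identity"].to_numpy(dtype=float)
    if np.any((ident < 0) | (ident > 1)):
        bad = motus.index[(ident < 0) | (ident > 1)].tolist()
        raise TableValidationError(f"best_identity outside [0, 1] for {bad}")
    if motus["taxon"].astype(str).str.len().eq(0).any():
        raise TableValidationError("empty taxon label in MOTU metadata")
    bad_status = set(motus["clean_status"]) - set(CLEAN_STATUSES)
    if bad_status:
        raise TableValidationError(f"unknown clean_status values: {sorted(bad_status)}")


@dataclass
class ReadCountTable:
    """Replicate-level read counts with MOTU and sample metadata.

    Parameters
    ----------
    counts
        Integer counts, index = motu_id, columns = MultiIndex
        ``(sample, replicate)`` with integer replicate labels.
    motus
        One row per motu_id with columns ``taxon``, ``best_identity``,
        ``clean_status``.
    samples
        One row per sample_id with columns ``sample_type``, ``mixture``,
        ``animal``; samples dropped during filtering stay here with a
        non-"ok" ``status`` column entry.
    """

    counts: pd.DataFrame
    motus: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.counts.columns, pd.MultiIndex) or self.counts.columns.nlevels != 2:
            raise TableValidationError(
                "count columns must be a (sample, replicate) MultiIndex"
            )
        _check_motus(self.motus)
        if not self.counts.index.equals(self.motus.index):
            raise TableValidationError("count rows and MOTU metadata rows disagree")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise TableValidationError(f"sample metadata lacks columns {missing}")
        bad_types = set(self.samples["sample_type"]) - set(SAMPLE_TYPES)
        if bad_types:
            raise TableValidationError(f"unknown sample_type values: {sorted(bad_types)}")
        declared = set(self.samples.index)
        used = set(self.counts.columns.get_level_values(0))
        undeclared = used - declared
        if undeclared:
            raise TableValidationError(
                f"count columns reference undeclared samples: {sorted(undeclared)}"
            )
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise TableValidationError("replicate counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            motu_i, col_i = np.argwhere(values < 0)[0]
            cell = (self.counts.index[motu_i], self.counts.columns[col_i])
            raise TableValidationError(f"negative count at {cell}")

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list:
        return list(dict.fromkeys(self.counts.columns.get_level_values(0)))

    def replicates_of(self, sample_id) -> list:
        return [r for s, r in self.counts.columns if s == sample_id]

    def replicate_frequencies(self) -> pd.DataFrame:
        """Per-replicate relative frequencies (columns with zero total -> 0)."""
        totals = self.counts.sum(axis=0)
        safe = totals.replace(0, 1)
        return self.counts.div(safe, axis=1)

    def copy(self) -> "ReadCountTable":
        return ReadCountTable(
            self.counts.copy(), self.motus.copy(), self.samples.copy()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReadCountTable):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.motus.equals(other.motus)
            and self.samples.equals(other.samples)
        )


@dataclass
class MeanCountTable:
    """Per-sample mean counts (MOTU x sample) after replicate averaging."""

    counts: pd.DataFrame  # float, index motu_id, columns sample_id
    motus: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        _check_motus(self.motus)
        if not self.counts.index.equals(self.motus.index):
            raise TableValidationError("count rows and MOTU metadata rows disagree")
        if (self.counts.to_numpy() < 0).any():
            raise TableValidationError("negative mean count")

    def copy(self) -> "MeanCountTable":
        return MeanCountTable(self.counts.copy(), self.motus.copy(), self.samples.copy())


def validate_composition(
    matrix: pd.DataFrame, *, atol: float = 1e-9, renorm_atol: float | None = None
) -> pd.DataFrame:
    """Check that every row of ``matrix`` lies on the unit simplex.

    Rows summing to 1 within ``renorm_atol`` (when given) are renormalised;
    anything further off, or any negative entry, is rejected. All-zero rows
    are always invalid.
    """
    values = matrix.to_numpy(dtype=float)
    if values.size == 0:
        raise TableValidationError("empty composition matrix")
    if (values < 0).any():
        row = matrix.index[np.argwhere(values < 0)[0][0]]
        raise TableValidationError(f"negative composition entry in row {row!r}")
    sums = values.sum(axis=1)
    tol = renorm_atol if renorm_atol is not None else atol
    bad = np.abs(sums - 1.0) > tol
    if bad.any():
        row = matrix.index[np.argmax(bad)]
        raise TableValidationError(
            f"composition row {row!r} sums to {sums[np.argmax(bad)]:.6g}, not 1"
        )
    out = matrix.astype(float)
    if renorm_atol is not None:
        out = out.div(sums, axis=0)
    return out
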