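"""Post-demultiplexing cleaning cascade: replicate counts -> per-sample RRA.

The stages, in pipeline order:

1. :func:`drop_flagged` — remove MOTUs flagged upstream as PCR/sequencing
   artefacts (the clean-status flag is consumed as input, not recomputed).
2. :func:`detect_outlier_replicates` — iteratively remove aberrant PCR
   replicates by comparing each replicate's Euclidean distance to its
   sample mean against the spread of between-sample distances.
3. :func:`average_replicates` — arithmetic mean of surviving replicates.
4. :func:`filter_low_frequency` — zero within-sample relative frequencies
   strictly below a threshold (default 1%).
5. :func:`filter_identity` — keep MOTUs whose best reference identity is
   at or above a threshold (default 85%, inclusive).
6. :func:`apply_taxon_map` — merge or drop taxa (e.g. fold a suspected
   field-sampling stray into its look-alike diet species).
7. :func:`to_rra` — normalise to relative read abundance per sample.

:func:`run_filter_pipeline` chains them and keeps a per-stage audit of
MOTU / sample / replicate / read counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MeanCountTable, ReadCountTable, TableValidationError


class FilterError(ValueError):
    """A filter received input it cannot meaningfully process."""


def drop_flagged(table: ReadCountTable) -> ReadCountTable:
    """Remove MOTUs whose clean status is "flagged"."""
    keep = table.motus["clean_status"] != "flagged"
    if not keep.any():
        warnings.warn("every MOTU is flagged; downstream stages will see an empty table",
                      stacklevel=2)
    return ReadCountTable(
        counts=table.counts.loc[keep.to_numpy()].copy(),
        motus=table.motus.loc[keep.to_numpy()].copy(),
        samples=table.samples.copy(),
    )


@dataclass
class OutlierLog:
    """Removals performed by the replicate-outlier filter."""

    removals: pd.DataFrame  # iteration, sample, replicate, distance, threshold
    discarded_samples: list = field(default_factory=list)
    iterations: int = 0


def _replicate_stats(counts: pd.DataFrame, active: list) -> tuple[dict, pd.Series]:
    """Sample mean frequency vectors and replicate-to-mean distances."""
    totals = counts.sum(axis=0)
    freq = counts.div(totals.replace(0, 1), axis=1)
    means: dict = {}
    dists = {}
    for sample in active:
        cols = [c for c in counts.columns if c[0] == sample]
        sub = freq[cols]
        mean = sub.mean(axis=1)
        means[sample] = mean.to_numpy()
        for c in cols:
            dists[c] = float(np.linalg.norm(sub[c].to_numpy() - means[sample]))
    return means, pd.Series(dists)


def detect_outlier_replicates(
    table: ReadCountTable,
    alpha: float = 0.05,
    max_iter: int = 10,
    floor_factor: float = 5.0,
) -> tuple[ReadCountTable, OutlierLog]:
    """Iteratively remove PCR replicates inconsistent with their sample.

    Each replicate is converted to relative frequencies and its Euclidean
    distance to the mean of its sample's surviving replicates is compared
    with the distribution of pairwise distances between sample means. A
    replicate is flagged when its within-sample distance reaches the
    ``alpha`` lower-tail quantile of that between-sample distribution
    *and* exceeds ``floor_factor`` times the median within-sample
    distance. The second condition keeps the filter sane in designs where
    many samples share a composition (as feeding trials do by
    construction), which pushes the low between-sample quantile down to
    the replicate-noise scale. Flagged replicates are removed worst-first,
    one per sample per iteration, and the procedure repeats until nothing
    is flagged. Samples left with fewer than two replicates are discarded.
    """
    if not 0 < alpha < 1:
        raise FilterError("alpha must lie in (0, 1)")
    n_multi = sum(len(table.replicates_of(s)) >= 2 for s in table.sample_ids)
    if len(table.sample_ids) < 2 or n_multi < 2:
        raise FilterError(
            "outlier detection needs at least 2 samples with >= 2 replicates each"
        )
    counts = table.counts.copy()
    removals = []
    iterations = 0
    for iteration in range(1, max_iter + 1):
        active = [
            s
            for s in dict.fromkeys(counts.columns.get_level_values(0))
            if sum(1 for c in counts.columns if c[0] == s) >= 2
        ]
        if len(active) < 2:
            break
        means, within = _replicate_stats(counts, active)
        mean_mat = np.array([means[s] for s in active])
        diff = mean_mat[:, None, :] - mean_mat[None, :, :]
        pair = np.linalg.norm(diff, axis=2)[np.triu_indices(len(active), k=1)]
        threshold = max(
            float(np.quantile(pair, alpha)),
            floor_factor * float(np.median(within)),
        )
        flagged = within[(within >= threshold) & (within > 0)]
        if flagged.empty:
            break
        iterations = iteration
        # worst replicate per sample, one removal per sample per iteration
        worst = flagged.groupby(lambda c: c[0]).idxmax()
        for sample, col in worst.items():
            removals.append(
                {
                    "iteration": iteration,
                    "sample": sample,
                    "replicate": col[1],
                    "distance": float(flagged[col]),
                    "threshold": threshold,
                }
            )
            counts = counts.drop(columns=[col])
    samples = table.samples.copy()
    discarded = [
        s
        for s in table.sample_ids
        if sum(1 for c in counts.columns if c[0] == s) < 2
    ]
    if discarded:
        counts = counts.drop(
            columns=[c for c in counts.columns if c[0] in discarded]
        )
        samples.loc[discarded, "status"] = "discarded_outlier_filter"
    log = OutlierLog(
        removals=pd.DataFrame(
            removals, columns=["iteration", "sample", "replicate", "distance", "threshold"]
        ),
        discarded_samples=discarded,
        iterations=iterations,
    )
    return ReadCountTable(counts=counts, motus=table.motus.copy(), samples=samples), log


def average_replicates(table: ReadCountTable) -> MeanCountTable:
    """Arithmetic mean of the surviving replicate counts, per sample and MOTU."""
    mean = table.counts.T.groupby(level=0).mean().T
    mean = mean[[s for s in table.sample_ids if s in mean.columns]]
    return MeanCountTable(
        counts=mean.astype(float), motus=table.motus.copy(), samples=table.samples.copy()
    )


def filter_low_frequency(table: MeanCountTable, threshold: float = 0.01) -> MeanCountTable:
    """Zero cells whose within-sample relative frequency is strictly below
    ``threshold``; drop MOTUs that become zero in every sample."""
    if threshold < 0:
        raise FilterError("threshold must be >= 0")
    counts = table.counts.copy()
    totals = counts.sum(axis=0)
    share = counts.div(totals.replace(0, 1), axis=1)
    counts[share < threshold] = 0.0
    keep = counts.sum(axis=1) > 0
    return MeanCountTable(
        counts=counts.loc[keep.to_numpy()],
        motus=table.motus.loc[keep.to_numpy()].copy(),
        samples=table.samples.copy(),
    )


def filter_low_frequency_replicates(
    table: ReadCountTable, threshold: float = 0.01
) -> ReadCountTable:
    """Per-replicate variant of the low-frequency filter (pre-averaging)."""
    counts = table.counts.copy()
    totals = counts.sum(axis=0)
    share = counts.div(totals.replace(0, 1), axis=1)
    counts[share < threshold] = 0
    keep = counts.sum(axis=1) > 0
    return ReadCountTable(
        counts=counts.loc[keep.to_numpy()],
        motus=table.motus.loc[keep.to_numpy()].copy(),
        samples=table.samples.copy(),
    )


def filter_identity(table: MeanCountTable, min_identity: float = 0.85) -> MeanCountTable:
    """Keep MOTUs with best reference identity >= ``min_identity`` (inclusive)."""
    keep = table.motus["best_identity"] >= min_identity
    if not keep.any():
        raise FilterError(
            f"no MOTU reaches identity {min_identity}; table would be empty"
        )
    return MeanCountTable(
        counts=table.counts.loc[keep.to_numpy()].copy(),
        motus=table.motus.loc[keep.to_numpy()].copy(),
        samples=table.samples.copy(),
    )


DROP = "DROP"


def apply_taxon_map(table: MeanCountTable, mapping: dict | None) -> MeanCountTable:
    """Merge and drop taxa; counts of merged taxa are summed.

    ``mapping`` sends a taxon label to a replacement label or to
    :data:`DROP`; unmapped taxa keep their own label. MOTUs sharing a final
    label are collapsed into one row (the output is indexed by taxon).
    """
    mapping = mapping or {}
    final = table.motus["taxon"].map(lambda t: mapping.get(t, t))
    keep = final != DROP
    counts = table.counts.loc[keep.to_numpy()]
    labels = final[keep]
    grouped = counts.groupby(labels.to_numpy()).sum()
    order = list(dict.fromkeys(labels))
    grouped = grouped.loc[order]
    identity = table.motus.loc[keep.to_numpy(), "best_identity"].groupby(
        labels.to_numpy()
    ).max()
    motus = pd.DataFrame(
        {
            "taxon": order,
            "best_identity": identity.loc[order].to_numpy(),
            "clean_status": "ok",
        },
        index=pd.Index(order, name="motu_id"),
    )
    grouped.index = motus.index
    return MeanCountTable(counts=grouped, motus=motus, samples=table.samples.copy())


def to_rra(
    table: MeanCountTable, taxon_order: list | None = None
) -> tuple[pd.DataFrame, list]:
    """Normalise mean counts to relative read abundance per sample.

    Returns the sample x taxon composition matrix plus the ids of samples
    discarded for having zero retained reads. Columns follow
    ``taxon_order`` (absent taxa appear as zero columns) with any extra
    retained taxa appended.
    """
    by_taxon = table.counts.groupby(table.motus["taxon"].to_numpy()).sum().T
    totals = by_taxon.sum(axis=1)
    discarded = list(by_taxon.index[totals <= 0])
    kept = by_taxon.loc[totals > 0]
    if kept.empty:
        raise FilterError("every sample has zero retained reads")
    rra = kept.div(kept.sum(axis=1), axis=0)
    if taxon_order is not None:
        extras = [t for t in rra.columns if t not in taxon_order]
        rra = rra.reindex(columns=list(taxon_order) + extras, fill_value=0.0)
    return rra, discarded


@dataclass
class FilterReport:
    """Per-stage accounting of the cleaning cascade."""

    audit: pd.DataFrame
    outlier_log: OutlierLog
    discarded_samples: dict  # sample_id -> reason


def _audit_row(stage: str, counts: pd.DataFrame, replicate_level: bool) -> dict:
    if replicate_level:
        samples = len(set(counts.columns.get_level_values(0)))
        replicates = counts.shape[1]
    else:
        samples = counts.shape[1]
        replicates = counts.shape[1]
    return {
        "stage": stage,
        "n_motus": int((counts.sum(axis=1) > 0).sum()),
        "n_samples": samples,
        "n_replicates": replicates,
        "total_reads": float(counts.to_numpy().sum()),
    }


def run_filter_pipeline(
    table: ReadCountTable,
    *,
    low_freq_threshold: float = 0.01,
    low_freq_per_replicate: bool = False,
    min_identity: float = 0.85,
    outlier_alpha: float = 0.05,
    outlier_floor_factor: float = 5.0,
    outlier_max_iter: int = 10,
    taxon_map: dict | None = None,
    taxon_order: list | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run the full cascade and return (RRA matrix, per-stage audit report)."""
    audit = [_audit_row("input", table.counts, True)]
    t1 = drop_flagged(table)
    audit.append(_audit_row("drop_flagged", t1.counts, True))
    t2, outlier_log = detect_outlier_replicates(
        t1, alpha=outlier_alpha, max_iter=outlier_max_iter, floor_factor=outlier_floor_factor
    )
    audit.append(_audit_row("outlier_replicates", t2.counts, True))
    if low_freq_per_replicate:
        t2 = filter_low_frequency_replicates(t2, low_freq_threshold)
    t3 = average_replicates(t2)
    audit.append(_audit_row("average_replicates", t3.counts, False))
    if not low_freq_per_replicate:
        t4 = filter_low_frequency(t3, low_freq_threshold)
    else:
        t4 = t3
    audit.append(_audit_row("low_frequency", t4.counts, False))
    t5 = filter_identity(t4, min_identity)
    audit.append(_audit_row("identity", t5.counts, False))
    t6 = apply_taxon_map(t5, taxon_map)
    audit.append(_audit_row("taxon_map", t6.counts, False))
    rra, zero_samples = to_rra(t6, taxon_order)
    audit.append(
        {
            "stage": "rra",
            "n_motus": int((rra.to_numpy().sum(axis=0) > 0).sum()),
            "n_samples": rra.shape[0],
            "n_replicates": rra.shape[0],
            "total_reads": float(t6.counts.to_numpy().sum()),
        }
    )
    discarded = {s: "outlier_filter" for s in outlier_log.discarded_samples}
    discarded.update({s: "zero_reads" for s in zero_samples})
    report = FilterReport(
        audit=pd.DataFrame(audit), outlier_log=outlier_log, discarded_samples=discarded
    )
    return rra, report
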