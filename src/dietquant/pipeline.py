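"""End-to-end feeding-trial analysis.

Chains the filtering cascade with two compositional regressions — relative
read abundance of the meal mixtures against their known biomass
composition (molecular bias only), and RRA of faecal samples against the
same expected compositions (molecular bias plus digestion) — and collects
permutation p-values, bootstrap intervals, leave-one-out cross-validation
and ternary-plot coordinates into one report. Single-plant reference
samples are filtered and purity-checked but excluded from both
regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import filtering, regression
from .containers import ReadCountTable, validate_composition
from .io import PipelineConfig
from .synthetic import TrialDesign


class StudyError(ValueError):
    pass


def build_expected_matrix(samples: pd.DataFrame, design: TrialDesign) -> pd.DataFrame:
    """Expected biomass composition per sample from its mixture label.

    ``samples`` needs columns ``sample_type`` and ``mixture``; single-plant
    samples map to the vertex composition of their taxon.
    """
    rows = {}
    for sample_id, meta in samples.iterrows():
        label = meta["mixture"]
        if meta["sample_type"] == "single_plant":
            if label not in design.taxa:
                raise StudyError(f"sample {sample_id!r}: unknown taxon {label!r}")
            comp = np.zeros(len(design.taxa))
            comp[design.taxa.index(label)] = 1.0
        else:
            if label not in design.mixtures:
                raise StudyError(f"sample {sample_id!r}: unknown mixture {label!r}")
            comp = design.mixture_composition(label)
        rows[sample_id] = comp
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=list(design.taxa))
    return validate_composition(matrix)


def ternary_xy(composition) -> tuple[float, float]:
    """Map a 3-part composition (a, b, c) to 2-D ternary plot coordinates."""
    a, b, c = (float(v) for v in composition)
    total = a + b + c
    return 0.5 * (2 * b + c) / total, (np.sqrt(3) / 2) * c / total


@dataclass
class RegressionBlock:
    """One fitted regression with its inference, or why it is not estimable."""

    estimable: bool
    n: int
    fit: regression.RegressionFit | None = None
    permutation: regression.PermutationResult | None = None
    bootstrap: regression.BootstrapResult | None = None
    cv: regression.CVResult | None = None
    reason: str = ""


@dataclass
class AnalysisReport:
    """Everything :func:`run_study` computes."""

    config: PipelineConfig
    seed: int
    meal: RegressionBlock
    faeces: RegressionBlock
    expected: pd.DataFrame
    rra: pd.DataFrame
    ternary: pd.DataFrame
    purity: pd.DataFrame
    filter_report: filtering.FilterReport
    dropped_offdesign_share: pd.Series

    def to_text(self) -> str:
        lines = [
            "Feeding-trial compositional analysis",
            f"seed: {self.seed}",
            f"thresholds: low_freq={self.config.low_freq_threshold} "
            f"identity={self.config.min_identity} outlier_alpha={self.config.outlier_alpha}",
            f"resampling: n_perm={self.config.n_perm} n_boot={self.config.n_boot} "
            f"level={self.config.ci_level}",
            "",
        ]
        for name, block in (("Meal mixtures ~ expected", self.meal),
                            ("Faeces ~ expected", self.faeces)):
            lines.append(f"== {name} (n={block.n}) ==")
            if not block.estimable:
                lines.append(f"not estimable: {block.reason}")
                lines.append("")
                continue
            lines.append("B matrix (rows: expected taxa, cols: RRA taxa):")
            lines.append(block.fit.B.round(4).to_string())
            lines.append(
                f"KL objective={block.fit.objective:.6g} "
                f"iterations={block.fit.n_iter} converged={block.fit.converged}"
            )
            if block.permutation is not None:
                lines.append(
                    f"permutation test: p={block.permutation.p_value:.4g} "
                    f"(n_perm={block.permutation.n_perm})"
                )
            if block.bootstrap is not None:
                lines.append(f"{block.bootstrap.level:.0%} bootstrap CIs (lower | upper):")
                lines.append(block.bootstrap.lower.round(3).to_string())
                lines.append(block.bootstrap.upper.round(3).to_string())
            if block.cv is not None:
                lines.append(f"LOOCV RMSE: {block.cv.rmse:.4f}")
            lines.append("")
        lines.append("== Single-plant purity (off-target RRA share) ==")
        lines.append(self.purity.round(4).to_string() if not self.purity.empty else "(none)")
        lines.append("")
        lines.append("== Filtering audit ==")
        lines.append(self.filter_report.audit.to_string(index=False))
        if self.filter_report.discarded_samples:
            lines.append(f"discarded samples: {self.filter_report.discarded_samples}")
        return "\n".join(lines) + "\n"


def _fit_block(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    config: PipelineConfig,
    *,
    seeds: tuple[int, int],
    with_cv: bool,
) -> RegressionBlock:
    n = Y.shape[0]
    if n < 3:
        return RegressionBlock(
            estimable=False, n=n, reason=f"only {n} retained samples (need >= 3)"
        )
    fit = regression.fit(Y, X, tol=config.tol, max_iter=config.max_iter)
    perm = regression.permutation_test(
        Y, X, n_perm=config.n_perm, seed=seeds[0], tol=config.tol, max_iter=config.max_iter
    )
    boot = regression.bootstrap_ci(
        Y,
        X,
        n_boot=config.n_boot,
        level=config.ci_level,
        seed=seeds[1],
        tol=config.tol,
        max_iter=config.max_iter,
    )
    cv = regression.loocv(Y, X, tol=config.tol, max_iter=config.max_iter) if with_cv else None
    return RegressionBlock(
        estimable=True, n=n, fit=fit, permutation=perm, bootstrap=boot, cv=cv
    )


def run_study(
    table: ReadCountTable,
    design: TrialDesign,
    config: PipelineConfig | None = None,
    *,
    prefiltered_rra: pd.DataFrame | None = None,
) -> AnalysisReport:
    """Filter a trial dataset and fit both regressions.

    When ``prefiltered_rra`` is given (e.g. a deposited, already-filtered
    dataset) the cleaning cascade is skipped and the supplied RRA matrix is
    used directly; its index must match ``table.samples``.
    """
    config = config or PipelineConfig()
    taxa = list(design.taxa)
    if prefiltered_rra is not None:
        rra = validate_composition(prefiltered_rra, renorm_atol=1e-6)
        filter_report = filtering.FilterReport(
            audit=pd.DataFrame(
                [
                    {
                        "stage": "prefiltered_input",
                        "n_motus": rra.shape[1],
                        "n_samples": rra.shape[0],
                        "n_replicates": rra.shape[0],
                        "total_reads": float("nan"),
                    }
                ]
            ),
            outlier_log=filtering.OutlierLog(
                removals=pd.DataFrame(
                    columns=["iteration", "sample", "replicate", "distance", "threshold"]
                )
            ),
            discarded_samples={},
        )
    else:
        rra, filter_report = filtering.run_filter_pipeline(
            table,
            low_freq_threshold=config.low_freq_threshold,
            low_freq_per_replicate=config.low_freq_per_replicate,
            min_identity=config.min_identity,
            outlier_alpha=config.outlier_alpha,
            outlier_floor_factor=config.outlier_floor_factor,
            outlier_max_iter=config.outlier_max_iter,
            taxon_map=config.taxon_map,
            taxon_order=taxa,
        )

    # restrict to the design's taxa for regression; record what that drops
    offdesign = [c for c in rra.columns if c not in taxa]
    dropped_share = (
        rra[offdesign].sum(axis=1) if offdesign else pd.Series(0.0, index=rra.index)
    )
    core = rra.reindex(columns=taxa, fill_value=0.0)
    core = core.div(core.sum(axis=1), axis=0)

    meta = table.samples.loc[[s for s in core.index if s in table.samples.index]]
    types = meta["sample_type"]
    plant_ids = types.index[types == "single_plant"]
    meal_ids = types.index[types == "meal_mixture"]
    faeces_ids = types.index[types == "faeces"]

    purity_rows = []
    for s in plant_ids:
        taxon = meta.loc[s, "mixture"]
        own = core.loc[s, taxon] if taxon in core.columns else 0.0
        purity_rows.append(
            {"sample": s, "taxon": taxon, "own_share": own, "off_target": 1.0 - own}
        )
    purity = pd.DataFrame(purity_rows, columns=["sample", "taxon", "own_share", "off_target"])

    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    blocks = {}
    for name, ids, seed_pair, with_cv in (
        ("meal", meal_ids, (int(seeds[0]), int(seeds[1])), False),
        ("faeces", faeces_ids, (int(seeds[2]), int(seeds[3])), True),
    ):
        Y = core.loc[ids]
        if Y.shape[0] >= 3:
            X = build_expected_matrix(meta.loc[ids], design)
            blocks[name] = _fit_block(Y, X, config, seeds=seed_pair, with_cv=with_cv)
        else:
            blocks[name] = RegressionBlock(
                estimable=False,
                n=Y.shape[0],
                reason=f"only {Y.shape[0]} retained samples (need >= 3)",
            )

    expected_all = build_expected_matrix(meta, design)
    tern_rows = []
    if len(taxa) == 3:
        for s in core.index:
            ex, ey = ternary_xy(expected_all.loc[s])
            rx, ry = ternary_xy(core.loc[s])
            tern_rows.append(
                {
                    "sample": s,
                    "sample_type": meta.loc[s, "sample_type"],
                    "expected_x": ex,
                    "expected_y": ey,
                    "rra_x": rx,
                    "rra_y": ry,
                }
            )
    ternary = pd.DataFrame(
        tern_rows,
        columns=["sample", "sample_type", "expected_x", "expected_y", "rra_x", "rra_y"],
    )

    return AnalysisReport(
        config=config,
        seed=config.seed,
        meal=blocks["meal"],
        faeces=blocks["faeces"],
        expected=expected_all,
        rra=core,
        ternary=ternary,
        purity=purity,
        filter_report=filter_report,
        dropped_offdesign_share=dropped_share,
    )


def ternary_coordinates(report: AnalysisReport) -> pd.DataFrame:
    """Ternary-plot coordinate table (expected and RRA) per retained sample."""
    return report.ternary.copy()
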