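"""Feeding-trial simulator with known ground truth.

Emulates the structure of a quantitative metabarcoding feeding trial: a
small set of plant taxa is combined into meal mixtures by cyclic rotation
of a base biomass composition (e.g. 60/30/10%), fed to animals, and each
resulting sample (single-plant reference, meal mixture, or faeces) is
amplified in several PCR replicates and sequenced.

The generator starts at the MOTU-table level (no raw reads, chimeras or
tag jumps): for every replicate a sequencing depth is drawn log-normally,
a replicate composition is drawn from a Dirichlet around the bias-distorted
truth, and integer counts are multinomial at that depth. Taxon-specific
amplification and digestion factors reproduce systematic under-recovery
(the "one taxon barely amplifies" failure mode); low-level contaminant
MOTUs and occasional aberrant PCR replicates supply the noise the
downstream filters must catch. Every dataset carries a
:class:`TruthRecord` so parameter-recovery tests can score the pipeline
against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np
import pandas as pd

from .containers import ReadCountTable, SAMPLE_TYPES

#: Non-diet MOTUs injected as low-level contamination: taxa a rodent
#: facility plausibly carries over from pre-trial food or field sampling.
CONTAMINANT_CATALOGUE = ("Festuca", "Maleae", "Avena", "Vaccinium", "Betula")


class DesignError(ValueError):
    """Invalid trial design or bias model."""


@dataclass(frozen=True)
class TrialDesign:
    """Layout of a feeding trial.

    ``mixtures`` maps a mixture name to its expected biomass composition
    (fractions per taxon, same order as ``taxa``); each of
    ``animals_per_mixture`` animals contributes one faecal sample per
    mixture, amplified in ``pcr_replicates`` PCR replicates.
    """

    taxa: tuple
    mixtures: dict
    animals_per_mixture: int = 9
    pcr_replicates: int = 3
    sample_types: tuple = SAMPLE_TYPES

    def __post_init__(self) -> None:
        if self.pcr_replicates < 1:
            raise DesignError("pcr_replicates must be >= 1")
        if self.animals_per_mixture < 0:
            raise DesignError("animals_per_mixture must be >= 0")
        if len(set(self.taxa)) != len(self.taxa):
            raise DesignError("taxon names must be unique")
        unknown = set(self.sample_types) - set(SAMPLE_TYPES)
        if unknown:
            raise DesignError(f"unknown sample types: {sorted(unknown)}")
        for name, comp in self.mixtures.items():
            comp = np.asarray(comp, dtype=float)
            if comp.shape != (len(self.taxa),):
                raise DesignError(
                    f"mixture {name!r} has {comp.size} parts for {len(self.taxa)} taxa"
                )
            if (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-12:
                raise DesignError(
                    f"mixture {name!r} is not a simplex composition (sum={comp.sum()!r})"
                )

    def mixture_composition(self, name: str) -> np.ndarray:
        return np.asarray(self.mixtures[name], dtype=float)


@dataclass(frozen=True)
class BiasModel:
    """Distortion parameters between ingested biomass and sequenced reads.

    ``amplification_factor`` gives per-taxon relative read recovery per
    unit biomass (marker copy number x PCR efficiency); ``digestion_factor``
    multiplies additionally in faeces samples only (differential survival
    through the gut). ``overdispersion`` is the Dirichlet precision of
    replicate-to-replicate noise (larger = tighter replicates);
    ``depth_log_mean``/``depth_log_sd`` parameterise the log-normal
    per-replicate read depth; ``contaminant_rate`` is the expected read
    fraction from non-diet MOTUs; ``outlier_replicate_rate`` the chance a
    replicate amplifies from a corrupted composition.
    """

    amplification_factor: dict = field(default_factory=dict)
    digestion_factor: dict = field(default_factory=dict)
    overdispersion: float = 200.0
    depth_log_mean: float = log(18_000.0)
    depth_log_sd: float = 0.35
    contaminant_rate: float = 0.005
    outlier_replicate_rate: float = 0.02

    def __post_init__(self) -> None:
        for label, factors in (
            ("amplification_factor", self.amplification_factor),
            ("digestion_factor", self.digestion_factor),
        ):
            for taxon, value in factors.items():
                if not value > 0:
                    raise DesignError(f"{label}[{taxon!r}] must be strictly positive")
        if not self.overdispersion > 0:
            raise DesignError("overdispersion must be > 0")
        if not 0.0 <= self.contaminant_rate <= 0.2:
            raise DesignError("contaminant_rate must lie in [0, 0.2]")
        if not 0.0 <= self.outlier_replicate_rate <= 1.0:
            raise DesignError("outlier_replicate_rate must lie in [0, 1]")
        if not self.depth_log_sd >= 0:
            raise DesignError("depth_log_sd must be >= 0")

    def factors(self, taxa, sample_type: str) -> np.ndarray:
        amp = np.array([self.amplification_factor.get(t, 1.0) for t in taxa])
        if sample_type == "faeces":
            amp = amp * np.array([self.digestion_factor.get(t, 1.0) for t in taxa])
        return amp


@dataclass
class TruthRecord:
    """Ground truth of a simulated trial, for parameter-recovery scoring."""

    true_compositions: pd.DataFrame  # sample x taxon, post-bias pre-noise
    expected_compositions: pd.DataFrame  # sample x taxon, design biomass
    implied_B: dict  # sample_type -> DataFrame fitted on noiseless distortions
    seed: int
    outlier_replicates: list = field(default_factory=list)  # (sample, replicate)
    contaminant_motus: list = field(default_factory=list)


def build_design(
    taxa,
    proportions=(0.6, 0.3, 0.1),
    animals_per_mixture: int = 9,
    pcr_replicates: int = 3,
    sample_types: tuple = SAMPLE_TYPES,
) -> TrialDesign:
    """Build a rotation design: one mixture per cyclic shift of the base.

    With taxa (Trifolium, Salix, Avenella) and base (0.6, 0.3, 0.1) this
    yields mixtures T60_S30_A10, T10_S60_A30 and T30_S10_A60 — each taxon
    takes each biomass share once across the trial.
    """
    taxa = tuple(taxa)
    base = np.asarray(proportions, dtype=float)
    if len(taxa) != base.size:
        raise DesignError(f"{len(taxa)} taxa but {base.size} proportions")
    if (base < 0).any() or abs(base.sum() - 1.0) > 1e-12:
        raise DesignError(
            f"base proportions must be non-negative and sum to 1 (got sum={base.sum()})"
        )
    initials = [t[0].upper() for t in taxa]
    if len(set(initials)) != len(initials):
        initials = list(taxa)  # fall back to full names on initial clashes
    mixtures: dict = {}
    for shift in range(len(taxa)):
        comp = np.roll(base, shift)
        name = "_".join(
            f"{ini}{int(round(100 * p))}" for ini, p in zip(initials, comp)
        )
        mixtures[name] = comp
    return TrialDesign(
        taxa=taxa,
        mixtures=mixtures,
        animals_per_mixture=animals_per_mixture,
        pcr_replicates=pcr_replicates,
        sample_types=tuple(sample_types),
    )


def distort(expected, bias: BiasModel, taxa, sample_type: str) -> np.ndarray:
    """Deterministically bias a composition: p_j * a_j (* d_j in faeces), renormalised."""
    p = np.asarray(expected, dtype=float)
    w = p * bias.factors(taxa, sample_type)
    total = w.sum()
    if total < 1e-12:
        raise DesignError("distorted composition is numerically all-zero")
    return w / total


def _vertex_heavy(rng: np.random.Generator, d: int, vertex_weight: float = 0.85) -> np.ndarray:
    """A composition piled onto one random vertex (used for aberrant replicates)."""
    v = np.zeros(d)
    v[rng.integers(d)] = 1.0
    return vertex_weight * v + (1.0 - vertex_weight) * rng.dirichlet(np.ones(d))


def _dirichlet_structural(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw in which zero concentrations stay exactly zero."""
    g = rng.gamma(np.maximum(alpha, 0.0))
    g[alpha <= 0] = 0.0
    total = g.sum()
    if total == 0:  # pathological tiny-alpha draw; fall back to the mean direction
        return alpha / alpha.sum()
    return g / total


def _sample_frame(design: TrialDesign) -> pd.DataFrame:
    rows = []
    if "single_plant" in design.sample_types:
        for taxon in design.taxa:
            rows.append((f"plant_{taxon}", "single_plant", taxon, ""))
    if "meal_mixture" in design.sample_types:
        for name in design.mixtures:
            rows.append((f"meal_{name}", "meal_mixture", name, ""))
    if "faeces" in design.sample_types:
        for name in design.mixtures:
            for a in range(1, design.animals_per_mixture + 1):
                rows.append((f"faeces_{name}_a{a:02d}", "faeces", name, f"a{a:02d}"))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "sample_type", "mixture", "animal"]
    ).set_index("sample_id")
    frame["status"] = "ok"
    return frame


def _expected_composition(design: TrialDesign, sample_type: str, mixture: str) -> np.ndarray:
    if sample_type == "single_plant":
        comp = np.zeros(len(design.taxa))
        comp[design.taxa.index(mixture)] = 1.0
        return comp
    return design.mixture_composition(mixture)


def simulate_trial(
    design: TrialDesign, bias: BiasModel, seed: int
) -> tuple[ReadCountTable, TruthRecord]:
    """Simulate a full feeding trial; byte-identical replay for the same seed."""
    if seed is None:
        raise DesignError("a seed is required: simulations must be replayable")
    from . import regression  # local import; regression does not import back

    rng = np.random.default_rng(seed)
    samples = _sample_frame(design)
    taxa = list(design.taxa)
    d = len(taxa)

    diet_ids = [f"motu_{t}" for t in taxa]
    cont_ids = [f"motu_{c}" for c in CONTAMINANT_CATALOGUE]
    use_contaminants = bias.contaminant_rate > 0
    motu_rows = [(m, t, 1.0, "ok") for m, t in zip(diet_ids, taxa)]
    if use_contaminants:
        cont_identity = rng.uniform(0.7, 1.0, size=len(cont_ids))
        cont_weights = rng.dirichlet(np.ones(len(cont_ids)))
        motu_rows += [
            (m, c, round(float(i), 4), "ok")
            for m, c, i in zip(cont_ids, CONTAMINANT_CATALOGUE, cont_identity)
        ]
    motus = pd.DataFrame(
        motu_rows, columns=["motu_id", "taxon", "best_identity", "clean_status"]
    ).set_index("motu_id")

    true_rows, expected_rows = {}, {}
    outliers: list = []
    columns: dict = {}
    for sample_id, meta in samples.iterrows():
        expected = _expected_composition(design, meta["sample_type"], meta["mixture"])
        truth = distort(expected, bias, taxa, meta["sample_type"])
        true_rows[sample_id] = truth
        expected_rows[sample_id] = expected
        for rep in range(1, design.pcr_replicates + 1):
            depth = max(1, int(round(rng.lognormal(bias.depth_log_mean, bias.depth_log_sd))))
            if rng.random() < bias.outlier_replicate_rate:
                comp = _vertex_heavy(rng, d)
                outliers.append((sample_id, rep))
            else:
                comp = _dirichlet_structural(rng, bias.overdispersion * truth)
            n_cont = rng.binomial(depth, bias.contaminant_rate) if use_contaminants else 0
            diet_counts = rng.multinomial(depth - n_cont, comp)
            col = np.concatenate(
                [diet_counts, rng.multinomial(n_cont, cont_weights)]
                if use_contaminants
                else [diet_counts]
            )
            columns[(sample_id, rep)] = col

    counts = pd.DataFrame(columns, index=motus.index)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["sample", "replicate"])
    table = ReadCountTable(counts=counts, motus=motus, samples=samples)

    expected_df = pd.DataFrame.from_dict(expected_rows, orient="index", columns=taxa)
    true_df = pd.DataFrame.from_dict(true_rows, orient="index", columns=taxa)
    mixture_expected = pd.DataFrame(
        {name: design.mixture_composition(name) for name in design.mixtures}, index=taxa
    ).T
    implied = {}
    for stype in ("meal_mixture", "faeces"):
        distorted = pd.DataFrame(
            {
                name: distort(design.mixture_composition(name), bias, taxa, stype)
                for name in design.mixtures
            },
            index=taxa,
        ).T
        # ordering-level accuracy is all the recovery tests need here
        implied[stype] = regression.fit(
            distorted, mixture_expected, tol=1e-9, max_iter=10_000
        ).B
    truth = TruthRecord(
        true_compositions=true_df,
        expected_compositions=expected_df,
        implied_B=implied,
        seed=int(seed),
        outlier_replicates=outliers,
        contaminant_motus=cont_ids if use_contaminants else [],
    )
    return table, truth


def spike_outlier(
    table: ReadCountTable,
    sample_id,
    replicate_id,
    severity: float,
    seed: int,
) -> ReadCountTable:
    """Corrupt one PCR replicate towards a random vertex-heavy composition.

    The replicate's observed composition becomes
    ``(1 - severity) * original + severity * vertex_heavy`` (mixing applied
    to diet MOTUs; non-diet shares scale with 1 - severity) and counts are
    re-drawn multinomially at the same depth. All other cells are untouched.
    """
    if not 0.0 <= severity <= 1.0:
        raise DesignError("severity must lie in [0, 1]")
    key = (sample_id, replicate_id)
    if key not in table.counts.columns:
        raise DesignError(f"no replicate {replicate_id!r} for sample {sample_id!r}")
    rng = np.random.default_rng(seed)
    out = table.copy()
    col = out.counts[key].to_numpy()
    depth = int(col.sum())
    if depth == 0:
        return out
    orig = col / depth
    # vertex-heavy target over MOTUs assigned to diet taxa (identity == 1)
    diet_mask = (out.motus["best_identity"].to_numpy() >= 1.0)
    if not diet_mask.any():
        diet_mask = np.ones(len(orig), dtype=bool)
    target = np.zeros_like(orig)
    target[diet_mask] = _vertex_heavy(rng, int(diet_mask.sum()))
    mixed = (1.0 - severity) * orig + severity * target
    mixed = mixed / mixed.sum()
    new_col = rng.multinomial(depth, mixed)
    out.counts[key] = new_col
    return out
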