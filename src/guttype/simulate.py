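"""Synthetic fecal-microbiota cohorts with enterotype-like structure.

Each sample is drawn from a finite mixture of community archetypes: an
archetype index is sampled from the mixing proportions, a composition from a
Dirichlet centered on the archetype mean (the concentration parameter sets
how tightly samples hug the mean), and reads from a multinomial at a library
depth drawn from a rounded Normal clamped at 100 reads.  The defaults emulate
a nationwide adult cohort: 516 subjects across seven regions of Japan
(Hokkaido 38, Tohoku 40, Kanto 193, Chubu 49, Kansai 49, Chugoku-Shikoku 48,
Kyushu 99), 325 females / 191 males, ages 21-88, 66 bacterial families, and
library depths of 10,252 +/- 2,406 reads per sample.

Ordinal questionnaire items are coupled to chosen families through a Gaussian
copula: a latent normal is correlated with the normal scores of the mean rank
of the coupled families' relative abundances, with the latent correlation
calibrated from the target Kendall tau by Greiner's relation
tau = (2/pi) arcsin(rho), then discretized into equal-probability ordinal
levels.  Discretization attenuates the realized tau-b slightly; the target is
met on the continuous (latent) side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .abundance import AbundanceTable

__all__ = [
    "EnterotypeArchetype",
    "QuestionnaireCoupling",
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "ConfigurationError",
    "generate_cohort",
    "generate_questionnaire",
    "archetype_composition",
    "study_families",
    "study_archetypes",
    "default_config",
    "STUDY_FAMILIES",
    "REGION_COUNTS",
    "GENDER_COUNTS",
]

#: The ten families that carry named roles in the analysis: the four major
#: ordination determinants, the fifth most abundant family, the three
#: bowel-movement-associated families, and the two diet-associated families.
STUDY_FAMILIES = (
    "Bacteroidaceae",
    "Lachnospiraceae",
    "Ruminococcaceae",
    "Prevotellaceae",
    "Bifidobacteriaceae",
    "Christensenellaceae",
    "Mogibacteriaceae",
    "Rikenellaceae",
    "Lactobacillaceae",
    "Bacillaceae",
)

REGION_COUNTS = {
    "Hokkaido": 38,
    "Tohoku": 40,
    "Kanto": 193,
    "Chubu": 49,
    "Kansai": 49,
    "Chugoku-Shikoku": 48,
    "Kyushu": 99,
}

GENDER_COUNTS = {"female": 325, "male": 191}

DEPTH_MEAN = 10252.0
DEPTH_SD = 2406.0
MIN_DEPTH = 100
DEFAULT_N_TAXA = 66


class ConfigurationError(ValueError):
    """The generator configuration violates its invariants."""


def study_families(n_taxa: int = DEFAULT_N_TAXA) -> list[str]:
    """Taxon labels: the ten named families first, then synthetic fillers."""
    if n_taxa < 1:
        raise ConfigurationError("n_taxa must be positive")
    named = list(STUDY_FAMILIES[:n_taxa])
    fillers = [f"Family{i:03d}" for i in range(len(named) + 1, n_taxa + 1)]
    return named + fillers


@dataclass
class EnterotypeArchetype:
    """A community archetype: a mean composition and a Dirichlet precision."""

    name: str
    mean_composition: np.ndarray
    concentration: float

    def __post_init__(self) -> None:
        self.mean_composition = np.asarray(self.mean_composition, dtype=float)
        if (self.mean_composition < 0).any():
            raise ConfigurationError(f"archetype {self.name}: negative mean composition")
        if abs(self.mean_composition.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"archetype {self.name}: mean composition sums to "
                f"{self.mean_composition.sum():.12f}, not 1"
            )
        if self.concentration <= 0:
            raise ConfigurationError(f"archetype {self.name}: concentration must be > 0")


@dataclass
class QuestionnaireCoupling:
    """One ordinal item coupled to a set of taxa at a target Kendall tau."""

    item: str
    taxa: tuple[str, ...]
    target_tau: float
    levels: int = 5

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        if abs(self.target_tau) >= 1:
            raise ConfigurationError(f"{self.item}: |target tau| must be < 1")
        if self.levels < 2:
            raise ConfigurationError(f"{self.item}: ordinal levels must be >= 2")


@dataclass
class SyntheticCohortConfig:
    n_samples: int = 516
    archetypes: list[EnterotypeArchetype] = field(default_factory=list)
    mixing_proportions: np.ndarray | None = None
    depth_mean: float = DEPTH_MEAN
    depth_sd: float = DEPTH_SD
    n_taxa: int = DEFAULT_N_TAXA
    metadata_strata: dict[str, dict[str, int]] = field(
        default_factory=lambda: {"region": dict(REGION_COUNTS), "gender": dict(GENDER_COUNTS)}
    )
    questionnaire_couplings: list[QuestionnaireCoupling] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ConfigurationError("n_samples must be positive")
        if not self.archetypes:
            raise ConfigurationError("at least one archetype is required")
        if self.mixing_proportions is None:
            self.mixing_proportions = np.full(len(self.archetypes), 1.0 / len(self.archetypes))
        self.mixing_proportions = np.asarray(self.mixing_proportions, dtype=float)
        if len(self.mixing_proportions) != len(self.archetypes):
            raise ConfigurationError("mixing_proportions length must match archetypes")
        if abs(self.mixing_proportions.sum() - 1.0) > 1e-9 or (self.mixing_proportions < 0).any():
            raise ConfigurationError("mixing_proportions must be nonnegative and sum to 1")
        if self.depth_mean <= 0 or self.depth_sd < 0:
            raise ConfigurationError("depth_mean must be > 0 and depth_sd >= 0")
        for arch in self.archetypes:
            if arch.mean_composition.size != self.n_taxa:
                raise ConfigurationError(
                    f"archetype {arch.name} has {arch.mean_composition.size} taxa, "
                    f"config expects {self.n_taxa}"
                )


@dataclass
class SyntheticCohort:
    counts: AbundanceTable
    metadata: pd.DataFrame
    true_labels: np.ndarray  # 1-based archetype index per sample
    config: SyntheticCohortConfig
    true_tau: dict[str, dict[str, float]] = field(default_factory=dict)


def archetype_composition(
    dominant: dict[str, float],
    taxa: Sequence[str],
    tail_decay: float = 0.85,
) -> np.ndarray:
    """Mean composition with the given dominant fractions; the remaining mass
    is spread over the other taxa with geometrically decaying weights (a
    crude but serviceable stand-in for the long tail of rare families)."""
    taxa = list(taxa)
    mass = sum(dominant.values())
    if mass >= 1.0:
        raise ConfigurationError("dominant fractions must sum to < 1")
    unknown = [t for t in dominant if t not in taxa]
    if unknown:
        raise LookupError(f"dominant taxa not in taxon list: {unknown}")
    rest = [t for t in taxa if t not in dominant]
    weights = tail_decay ** np.arange(len(rest))
    weights = weights / weights.sum() * (1.0 - mass)
    comp = np.empty(len(taxa))
    tail = dict(zip(rest, weights))
    for i, taxon in enumerate(taxa):
        comp[i] = dominant.get(taxon, tail.get(taxon, 0.0))
    comp = comp / comp.sum()
    return comp


def study_archetypes(n_taxa: int = DEFAULT_N_TAXA, concentration: float = 35.0):
    """Two archetypes mirroring the classic Bacteroides- and Prevotella-driven
    community configurations, with the bowel-movement-associated families
    (Christensenellaceae, Mogibacteriaceae, Rikenellaceae) jointly elevated in
    the Prevotella-poor archetype so that they correlate positively with each
    other across the cohort."""
    taxa = study_families(n_taxa)
    bacteroides = archetype_composition(
        {
            "Bacteroidaceae": 0.40,
            "Lachnospiraceae": 0.19,
            "Ruminococcaceae": 0.17,
            "Prevotellaceae": 0.005,
            "Bifidobacteriaceae": 0.05,
            "Christensenellaceae": 0.008,
            "Mogibacteriaceae": 0.004,
            "Rikenellaceae": 0.025,
            "Lactobacillaceae": 0.002,
            "Bacillaceae": 0.0005,
        },
        taxa,
    )
    prevotella = archetype_composition(
        {
            "Bacteroidaceae": 0.15,
            "Lachnospiraceae": 0.14,
            "Ruminococcaceae": 0.12,
            "Prevotellaceae": 0.33,
            "Bifidobacteriaceae": 0.04,
            "Christensenellaceae": 0.001,
            "Mogibacteriaceae": 0.0005,
            "Rikenellaceae": 0.004,
            "Lactobacillaceae": 0.002,
            "Bacillaceae": 0.0005,
        },
        taxa,
    )
    return [
        EnterotypeArchetype("Bacteroides-type", bacteroides, concentration),
        EnterotypeArchetype("Prevotella-type", prevotella, concentration),
    ]


def default_config(seed: int = 0) -> SyntheticCohortConfig:
    """Study-scale default: 516 subjects, 66 families, two loose archetypes
    (73% Bacteroides-type / 27% Prevotella-type), study depths and strata, and
    the three reported questionnaire couplings."""
    return SyntheticCohortConfig(
        n_samples=516,
        archetypes=study_archetypes(),
        mixing_proportions=np.array([0.73, 0.27]),
        questionnaire_couplings=[
            QuestionnaireCoupling(
                "Q7",
                ("Christensenellaceae", "Mogibacteriaceae", "Rikenellaceae"),
                target_tau=-0.26,
                levels=5,
            ),
            QuestionnaireCoupling("Q13", ("Lactobacillaceae",), target_tau=0.25, levels=5),
            QuestionnaireCoupling("Q21", ("Bacillaceae",), target_tau=0.34, levels=5),
        ],
        seed=seed,
    )


def _allocate_strata(counts: dict[str, int], n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact per-stratum labels scaled to n by largest remainder, shuffled."""
    labels = list(counts)
    total = sum(counts.values())
    quotas = {lab: counts[lab] * n / total for lab in labels}
    alloc = {lab: int(np.floor(q)) for lab, q in quotas.items()}
    shortfall = n - sum(alloc.values())
    by_remainder = sorted(labels, key=lambda lab: quotas[lab] - alloc[lab], reverse=True)
    for lab in by_remainder[:shortfall]:
        alloc[lab] += 1
    pool = np.array([lab for lab in labels for _ in range(alloc[lab])], dtype=object)
    return rng.permutation(pool)


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Draw a cohort from the archetype mixture; deterministic given the seed.

    Per sample: archetype ~ mixing proportions; composition ~
    Dirichlet(concentration x archetype mean); depth ~ round(Normal(mean, sd))
    clamped at 100 reads; counts ~ Multinomial(depth, composition).  Row sums
    equal the drawn depths exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    taxa = study_families(config.n_taxa)
    labels = rng.choice(len(config.archetypes), size=n, p=config.mixing_proportions)
    depths = np.round(rng.normal(config.depth_mean, config.depth_sd, size=n))
    depths = np.maximum(depths, MIN_DEPTH).astype(int)
    counts = np.empty((n, config.n_taxa), dtype=int)
    for i in range(n):
        arch = config.archetypes[labels[i]]
        alpha = np.maximum(arch.concentration * arch.mean_composition, 1e-9)
        composition = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(depths[i], composition)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    table = AbundanceTable(
        data=pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"), columns=taxa),
        kind="counts",
        level="family",
    )
    metadata = _generate_metadata(config, sample_ids, rng)
    cohort = SyntheticCohort(
        counts=table,
        metadata=metadata,
        true_labels=labels + 1,
        config=config,
    )
    if config.questionnaire_couplings:
        cohort.metadata = generate_questionnaire(
            cohort, config.questionnaire_couplings, seed=config.seed + 1
        )
    return cohort


def _generate_metadata(
    config: SyntheticCohortConfig, sample_ids: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    n = len(sample_ids)
    meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    strata = config.metadata_strata or {}
    if "region" in strata:
        meta["region"] = _allocate_strata(strata["region"], n, rng)
    if "gender" in strata:
        meta["gender"] = _allocate_strata(strata["gender"], n, rng)
    # ages 21-88 with the study-wide mean/SD; BMI chosen so that roughly 80%
    # of subjects are lean (< 25) and ~2.5% obese (> 30)
    meta["age"] = np.clip(np.round(rng.normal(52.4, 13.4, size=n)), 21, 88).astype(int)
    meta["bmi"] = np.round(np.clip(rng.normal(22.0, 4.0, size=n), 14.0, 45.0), 1)
    return meta


def generate_questionnaire(
    cohort: SyntheticCohort,
    couplings: Sequence[QuestionnaireCoupling],
    seed: int,
) -> pd.DataFrame:
    """Add ordinal item scores coupled to taxa via a Gaussian copula.

    For each coupling, the per-sample mean rank of the coupled taxa's relative
    abundances is mapped to normal scores z_x; the latent item variable is
    rho * z_x + sqrt(1 - rho^2) * eps with rho = sin(pi * tau / 2), then cut
    at equal-probability normal quantiles into 1..levels.  Deterministic given
    the seed.
    """
    rng = np.random.default_rng(seed)
    counts = cohort.counts.data
    totals = counts.sum(axis=1)
    rel = counts.div(totals, axis=0)
    n = rel.shape[0]
    metadata = cohort.metadata.copy()
    for coupling in couplings:
        missing = [t for t in coupling.taxa if t not in rel.columns]
        if missing:
            raise LookupError(f"{coupling.item}: unknown taxa {missing}")
        ranks = np.column_stack(
            [sps.rankdata(rel[t].to_numpy()) for t in coupling.taxa]
        ).mean(axis=1)
        z_x = sps.norm.ppf((sps.rankdata(ranks) - 0.5) / n)
        z_x = z_x / z_x.std()  # ties (undetected taxa) compress midrank scores
        rho = np.sin(np.pi * coupling.target_tau / 2.0)
        latent = rho * z_x + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        cuts = sps.norm.ppf(np.arange(1, coupling.levels) / coupling.levels)
        metadata[coupling.item] = np.searchsorted(cuts, latent) + 1
        cohort.true_tau.setdefault(coupling.item, {})
        for taxon in coupling.taxa:
            cohort.true_tau[coupling.item][taxon] = coupling.target_tau
    return metadata
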