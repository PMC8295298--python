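"""Seeded synthetic case-control cohorts with implanted gene effects.

The generator emulates the statistical structure the association pipeline
assumes: a biobank-style cohort with low-prevalence binary phenotypes
(cancer-like, 1-20% cases), rare-to-common coding variants with per-allele
damage probabilities concentrated near 0 and 1, a covariate set of sex plus
numeric (standard normal, principal-component-like) and one-hot categorical
(batch/centre-like) covariates, and genes carrying dominant, recessive
(including compound-heterozygous), additive, or null effects on disease.

Genotypes are Hardy-Weinberg draws, ``dosage ~ Binomial(2, freq)`` per
variant, with no linkage disequilibrium.  Phenotypes are implanted through
a latent-event logistic model: each alternate allele of variant *v*
independently damages its gene copy with probability ``d_v``; a dominant
effect contributes its log-odds when the gene has >= 1 damaging event, a
recessive effect when >= 2, and an additive effect proportionally to the
event count.  The intercept is calibrated by bisection so the realized
prevalence matches the requested baseline.  The latent event counts are
logged so that recovery tests can condition on simulation truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "GeneEffectSpec",
    "PhenotypeSpec",
    "SimulationConfig",
    "FilterReport",
    "SyntheticCohort",
    "generate_cohort",
    "implant_phenotypes",
    "apply_cohort_filters",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class GeneEffectSpec:
    """A causal (or null) gene effect on one phenotype.

    ``odds_ratio`` applies per qualifying unit of latent damage: to the
    indicator of >= 1 damaging event (dominant), >= 2 (recessive), or to
    the event count (additive).  ``direction="protective"`` inverts the
    log-odds sign.
    """

    gene_id: str
    mode: str = "null"
    odds_ratio: float = 1.0
    direction: str = "risk"

    def __post_init__(self):
        if self.mode not in ("dominant", "recessive", "additive", "null"):
            raise ConfigError(f"mode: unknown effect mode {self.mode!r}")
        if self.odds_ratio <= 0:
            raise ConfigError("odds_ratio: must be > 0")
        if self.direction not in ("risk", "protective"):
            raise ConfigError(f"direction: must be risk|protective, got {self.direction!r}")
        if self.mode == "null":
            self.odds_ratio = 1.0

    @property
    def log_or(self) -> float:
        b = math.log(self.odds_ratio)
        return -b if self.direction == "protective" else b


@dataclass
class PhenotypeSpec:
    """A binary phenotype: baseline prevalence, optional sex restriction,
    causal gene effects and covariate effects (coefficients by column name)."""

    name: str
    baseline_prevalence: float
    sex_restricted: str | None = None
    causal_effects: list = field(default_factory=list)
    covariate_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.baseline_prevalence < 1.0):
            raise ConfigError("baseline_prevalence: must lie in (0, 1)")
        if self.sex_restricted not in (None, "none", "male", "female"):
            raise ConfigError(
                f"sex_restricted: must be none|male|female, got {self.sex_restricted!r}"
            )
        if self.sex_restricted == "none":
            self.sex_restricted = None
        self.causal_effects = [
            e if isinstance(e, GeneEffectSpec) else GeneEffectSpec(**e)
            for e in self.causal_effects
        ]


DEFAULT_ALLELE_FREQ_SPEC = {
    "kind": "mixture_loguniform",
    "rare_fraction": 0.7,
    "rare_range": (1e-3, 0.01),
    "common_range": (0.01, 0.5),
}
# bimodal: most variants nearly benign, a minority nearly certain to damage
DEFAULT_DAMAGE_PROB_SPEC = {
    "kind": "beta_mixture",
    "weights": (0.6, 0.4),
    "alphas": (0.6, 8.0),
    "betas": (8.0, 0.6),
}


@dataclass
class SimulationConfig:
    """Full description of a synthetic cohort.

    Defaults give a scaled-down biobank: 5,000 individuals, 50 genes of 4
    variants each across 2 chromosomes, sex + 4 numeric + 2 categorical
    covariates, and a single 5%-prevalence phenotype with no genetic
    effects.
    """

    n_individuals: int = 5_000
    n_genes: int = 50
    variants_per_gene: int | dict = 4
    allele_freq_spec: dict = field(default_factory=lambda: dict(DEFAULT_ALLELE_FREQ_SPEC))
    damage_prob_spec: dict = field(default_factory=lambda: dict(DEFAULT_DAMAGE_PROB_SPEC))
    n_numeric_covariates: int = 4
    n_categorical_covariates: int = 2
    categorical_levels: tuple = (3, 4)
    phenotypes: list = field(default_factory=list)
    seed: int = 0
    n_chromosomes: int = 2
    gene_spacing: int = 2_000_000
    cds_length: int = 10_000

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ConfigError("n_individuals: must be >= 1")
        if self.n_genes < 1:
            raise ConfigError("n_genes: must be >= 1")
        if isinstance(self.variants_per_gene, int) and self.variants_per_gene < 1:
            raise ConfigError("variants_per_gene: must be >= 1")
        if self.n_numeric_covariates < 0 or self.n_categorical_covariates < 0:
            raise ConfigError("covariate counts: must be >= 0")
        if self.n_categorical_covariates > len(self.categorical_levels):
            raise ConfigError(
                "categorical_levels: need one level count per categorical covariate"
            )
        if any(l < 2 for l in self.categorical_levels[: self.n_categorical_covariates]):
            raise ConfigError("categorical_levels: each must be >= 2")
        self.phenotypes = [
            p if isinstance(p, PhenotypeSpec) else PhenotypeSpec(**p)
            for p in self.phenotypes
        ]

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _draw_allele_freqs(spec: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec.get("kind")
    if kind == "mixture_loguniform":
        frac = spec.get("rare_fraction", 0.7)
        lo1, hi1 = spec.get("rare_range", (1e-3, 0.01))
        lo2, hi2 = spec.get("common_range", (0.01, 0.5))
        if not (0 <= frac <= 1) or not (0 < lo1 <= hi1 <= 0.5) or not (0 < lo2 <= hi2 <= 0.5):
            raise ConfigError("allele_freq_spec: ranges must lie in (0, 0.5]")
        rare = rng.random(size) < frac
        f = np.empty(size)
        f[rare] = np.exp(rng.uniform(np.log(lo1), np.log(hi1), rare.sum()))
        f[~rare] = np.exp(rng.uniform(np.log(lo2), np.log(hi2), (~rare).sum()))
        return f
    if kind == "fixed":
        v = float(spec["value"])
        if not (0 < v <= 0.5):
            raise ConfigError("allele_freq_spec: fixed value must lie in (0, 0.5]")
        return np.full(size, v)
    raise ConfigError(f"allele_freq_spec: unknown kind {kind!r}")


def _draw_damage_probs(spec: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec.get("kind")
    if kind == "beta_mixture":
        w = np.asarray(spec.get("weights", (0.5, 0.5)), float)
        a = np.asarray(spec.get("alphas"), float)
        b = np.asarray(spec.get("betas"), float)
        if len(w) != len(a) or len(a) != len(b) or np.any(w < 0) or w.sum() <= 0:
            raise ConfigError("damage_prob_spec: weights/alphas/betas mismatch")
        comp = rng.choice(len(w), size=size, p=w / w.sum())
        return rng.beta(a[comp], b[comp])
    if kind == "fixed":
        v = float(spec["value"])
        if not (0 <= v <= 1):
            raise ConfigError("damage_prob_spec: fixed value must lie in [0, 1]")
        return np.full(size, v)
    raise ConfigError(f"damage_prob_spec: unknown kind {kind!r}")


@dataclass
class SyntheticCohort:
    """Generated tables: individuals (sex + covariates), variants, dosages,
    and gene coordinates."""

    individuals: pd.DataFrame
    variants: pd.DataFrame
    dosages: pd.DataFrame
    gene_coords: pd.DataFrame
    config: SimulationConfig

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.individuals.columns if c != "individual_id"]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.individuals.to_csv(out / "covariates.tsv", sep="\t")
        self.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
        self.dosages.to_csv(out / "dosages.tsv", sep="\t")
        self.gene_coords.to_csv(out / "gene_coords.tsv", sep="\t", index=False)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort, deterministic given ``config.seed``.

    Genes are laid out round-robin over ``n_chromosomes`` chromosomes at
    ``gene_spacing`` intervals; variant positions are uniform within each
    gene's CDS; dosages are Binomial(2, freq) per variant.
    """
    rng = np.random.default_rng(config.seed)
    n, G = config.n_individuals, config.n_genes

    gene_ids = [f"GENE{i + 1:04d}" for i in range(G)]
    per_chrom_counter: dict[str, int] = {}
    rows = []
    for i, g in enumerate(gene_ids):
        chrom = f"chr{1 + i % config.n_chromosomes}"
        k = per_chrom_counter.get(chrom, 0)
        per_chrom_counter[chrom] = k + 1
        start = 1_000_000 + k * config.gene_spacing
        rows.append(
            {"gene_id": g, "chrom": chrom, "cds_start": start,
             "cds_end": start + config.cds_length - 1}
        )
    gene_coords = pd.DataFrame(rows)

    if isinstance(config.variants_per_gene, dict):
        spec = config.variants_per_gene
        if spec.get("kind") != "poisson":
            raise ConfigError("variants_per_gene: unknown distribution kind")
        counts = np.maximum(
            spec.get("min", 1), rng.poisson(spec.get("mean", 3), G)
        )
    else:
        counts = np.full(G, int(config.variants_per_gene))

    vrows = []
    for g, row, c in zip(gene_ids, gene_coords.itertuples(), counts):
        pos = np.sort(rng.integers(row.cds_start, row.cds_end + 1, size=c))
        for j, p in enumerate(pos):
            vrows.append(
                {"variant_id": f"{g}_v{j + 1}", "chrom": row.chrom, "pos": int(p),
                 "gene_id": g, "ref": "A", "alt": "G"}
            )
    variants = pd.DataFrame(vrows)
    V = len(variants)
    variants["allele_freq"] = _draw_allele_freqs(config.allele_freq_spec, V, rng)
    variants["damage_prob"] = _draw_damage_probs(config.damage_prob_spec, V, rng)

    dosages = pd.DataFrame(
        rng.binomial(2, variants["allele_freq"].to_numpy(), size=(n, V)),
        index=pd.Index([f"IND{i + 1:06d}" for i in range(n)], name="individual_id"),
        columns=variants["variant_id"],
    )

    ind = pd.DataFrame(index=dosages.index)
    ind["sex"] = rng.integers(0, 2, n)  # 1 = male
    for j in range(config.n_numeric_covariates):
        ind[f"pc{j + 1}"] = rng.standard_normal(n)
    for j in range(config.n_categorical_covariates):
        levels = config.categorical_levels[j]
        draw = rng.integers(0, levels, n)
        for lvl in range(1, levels):  # reference level dropped
            ind[f"cat{j + 1}_l{lvl}"] = (draw == lvl).astype(int)

    return SyntheticCohort(
        individuals=ind, variants=variants, dosages=dosages,
        gene_coords=gene_coords, config=config,
    )


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Bisection for c with mean(sigmoid(c + eta)) = target."""

    def mean_prev(c):
        return float(1.0 / (1.0 + np.exp(-(c + eta))).mean())

    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_prev(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def implant_phenotypes(
    cohort: SyntheticCohort,
    phenotypes: list[PhenotypeSpec] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw case/control labels and return them with the latent-truth log.

    Returns ``(labels, truth_log)``: labels has one 0/1 column per
    phenotype (NaN for individuals excluded by a sex restriction);
    truth_log has one row per (individual, causal gene) with the simulated
    number of damaging events, enabling recovery tests conditioned on
    truth.
    """
    phenotypes = phenotypes if phenotypes is not None else cohort.config.phenotypes
    seed = seed if seed is not None else cohort.config.seed + 1
    rng = np.random.default_rng(seed)
    n = len(cohort.individuals)
    variants = cohort.variants.set_index("variant_id")
    known_genes = set(cohort.variants["gene_id"])

    causal_genes = sorted(
        {e.gene_id for ph in phenotypes for e in ph.causal_effects}
    )
    unknown = [g for g in causal_genes if g not in known_genes]
    if unknown:
        raise ConfigError(f"causal_effects: unresolvable gene ids {unknown}")

    # latent damaging-event counts per (individual, causal gene), shared
    # across phenotypes: the genetics does not depend on the phenotype
    events = {}
    for g in causal_genes:
        cols = cohort.variants.loc[cohort.variants.gene_id == g, "variant_id"]
        d = variants.loc[cols, "damage_prob"].to_numpy()
        gmat = cohort.dosages[cols].to_numpy()
        events[g] = rng.binomial(gmat.astype(int), d).sum(axis=1)

    labels = pd.DataFrame(index=cohort.individuals.index)
    for ph in phenotypes:
        eta = np.zeros(n)
        for col, beta in ph.covariate_effects.items():
            if col not in cohort.individuals.columns:
                raise ConfigError(f"covariate_effects: unknown covariate {col!r}")
            x = cohort.individuals[col].to_numpy(dtype=float)
            sd = x.std()
            eta += beta * ((x - x.mean()) / sd if sd > 0 else 0.0)
        for eff in ph.causal_effects:
            ev = events[eff.gene_id]
            if eff.mode == "dominant":
                eta += eff.log_or * (ev >= 1)
            elif eff.mode == "recessive":
                eta += eff.log_or * (ev >= 2)
            elif eff.mode == "additive":
                eta += eff.log_or * ev

        eligible = np.ones(n, dtype=bool)
        if ph.sex_restricted == "male":
            eligible = cohort.individuals["sex"].to_numpy() == 1
        elif ph.sex_restricted == "female":
            eligible = cohort.individuals["sex"].to_numpy() == 0

        c = _calibrate_intercept(eta[eligible], ph.baseline_prevalence)
        prob = 1.0 / (1.0 + np.exp(-(c + eta)))
        y = np.where(eligible, rng.random(n) < prob, np.nan)
        labels[ph.name] = y

    truth_rows = []
    for g in causal_genes:
        truth_rows.append(
            pd.DataFrame(
                {
                    "individual_id": cohort.individuals.index,
                    "gene_id": g,
                    "n_damaging_events": events[g],
                }
            )
        )
    truth_log = (
        pd.concat(truth_rows, ignore_index=True)
        if truth_rows
        else pd.DataFrame(columns=["individual_id", "gene_id", "n_damaging_events"])
    )
    return labels, truth_log


@dataclass
class FilterReport:
    """Accounting of ordered cohort exclusions.

    Each individual is counted under the *first* reason that flags it, so
    the per-reason counts partition the excluded set and
    ``remaining + sum(excluded) == total`` always holds.
    """

    total: int
    excluded_per_reason: dict
    remaining: int

    def __post_init__(self):
        if self.remaining != self.total - sum(self.excluded_per_reason.values()):
            raise ValueError("filter report does not conserve individuals")
        if self.total < 0 or self.remaining < 0 or any(
            v < 0 for v in self.excluded_per_reason.values()
        ):
            raise ValueError("counts must be non-negative")


def apply_cohort_filters(table: pd.DataFrame, reasons: list[str]) -> FilterReport:
    """Count exclusions first-match-wins over ordered boolean flag columns."""
    for r in reasons:
        if r not in table.columns:
            raise ValueError(f"unknown exclusion reason {r!r}")
    remaining_mask = np.ones(len(table), dtype=bool)
    excluded = {}
    for r in reasons:
        flag = table[r].to_numpy(dtype=bool) & remaining_mask
        excluded[r] = int(flag.sum())
        remaining_mask &= ~flag
    return FilterReport(
        total=len(table),
        excluded_per_reason=excluded,
        remaining=int(remaining_mask.sum()),
    )
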