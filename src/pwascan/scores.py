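"""Per-individual, per-gene functional effect scores.

Each alternate allele of a coding variant *v* is modelled as an independent
Bernoulli event that abolishes the function of the encoded protein copy with
probability ``d_v`` (the variant's damage probability, the complement of a
functional-retention score).  For one individual, with hard-called genotypes
``g_v`` in {0, 1, 2} over the variants of a gene, the gene's

* **dominant effect score** is the probability of *zero* damaging events,
  ``s_dom = prod_v (1 - d_v) ** g_v``, and the
* **recessive effect score** is the probability of *at most one* damaging
  event, ``s_rec = s_dom + P(exactly one)``.

Lower scores therefore mean more expected damage: ``1 - s_dom`` is the
probability of at least one damaged gene copy (a dominant-type loss) and
``1 - s_rec`` the probability of at least two (homozygous or
compound-heterozygous, a recessive-type loss).  A gene with no observed
variants scores ``(1.0, 1.0)``.  Phase is ignored: two heterozygous variants
count as two independent potential hits regardless of haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EffectScoreMatrix",
    "damage_from_retention",
    "hard_call",
    "score_gene",
    "score_matrix",
]


def damage_from_retention(retention):
    """Convert a functional-retention probability into a damage probability.

    A predictor that scores the probability of the gene *retaining* its
    function in the presence of a variant is converted to the per-allele
    damage probability ``d = 1 - retention``.
    """
    r = np.asarray(retention, dtype=float)
    if np.any((r < 0.0) | (r > 1.0) | ~np.isfinite(r)):
        raise ValueError("retention scores must lie in [0, 1]")
    out = 1.0 - r
    return float(out) if np.isscalar(retention) else out


def hard_call(dosage, het_low: float = 0.5, het_high: float = 1.5):
    """Call fractional alternate-allele dosages in [0, 2] to {0, 1, 2}.

    The heterozygous band is closed on the left: ``het_low <= dosage <
    het_high`` calls 1; below calls 0; at or above ``het_high`` calls 2.
    """
    if not (0.0 <= het_low < het_high <= 2.0):
        raise ValueError("require 0 <= het_low < het_high <= 2")
    d = np.asarray(dosage, dtype=float)
    if np.any((d < 0.0) | (d > 2.0) | ~np.isfinite(d)):
        raise ValueError("dosages must lie in [0, 2]")
    g = np.where(d < het_low, 0, np.where(d < het_high, 1, 2))
    return int(g) if np.isscalar(dosage) else g


def score_gene(alleles: Iterable[tuple[int, float]]) -> tuple[float, float]:
    """Score one gene for one individual from (genotype, damage) pairs.

    Parameters
    ----------
    alleles
        Iterable of ``(g, d)`` pairs, one per variant in the gene: ``g`` the
        hard-called genotype in {0, 1, 2} and ``d`` the per-allele damage
        probability in [0, 1].

    Returns
    -------
    (s_dom, s_rec)
        Probability of zero damaging events and of at most one, under
        independent Bernoulli(d) damage per alternate allele.
    """
    ds: list[float] = []
    for g, d in alleles:
        if g not in (0, 1, 2):
            raise ValueError(f"genotype must be in {{0, 1, 2}}, got {g!r}")
        if not (0.0 <= d <= 1.0):
            raise ValueError(f"damage probability must be in [0, 1], got {d!r}")
        ds.extend([float(d)] * int(g))
    if not ds:
        return 1.0, 1.0
    d_arr = np.array(ds)
    q = 1.0 - d_arr
    p0 = float(np.prod(q))
    # P(exactly one): sum over alleles of d_a * prod_{b != a} (1 - d_b),
    # computed by explicit leave-one-out products so d = 1 stays exact.
    p1 = 0.0
    for a in range(len(d_arr)):
        p1 += d_arr[a] * float(np.prod(np.delete(q, a)))
    s_dom = min(max(p0, 0.0), 1.0)
    s_rec = min(max(p0 + p1, 0.0), 1.0)
    return s_dom, s_rec


@dataclass
class EffectScoreMatrix:
    """Individuals x genes effect scores, one layer per inheritance model.

    Attributes
    ----------
    dominant, recessive
        DataFrames indexed by individual id with one column per gene;
        every cell satisfies ``0 <= dominant <= recessive <= 1``.
    n_missing
        Per-gene count of missing genotype entries that were treated as
        homozygous reference during scoring.
    """

    dominant: pd.DataFrame
    recessive: pd.DataFrame
    n_missing: pd.Series = field(default=None)

    def __post_init__(self):
        if self.n_missing is None:
            self.n_missing = pd.Series(0, index=self.dominant.columns)
        if not self.dominant.index.equals(self.recessive.index) or not (
            self.dominant.columns.equals(self.recessive.columns)
        ):
            raise ValueError("dominant and recessive layers must be aligned")

    @property
    def individuals(self) -> pd.Index:
        return self.dominant.index

    @property
    def genes(self) -> pd.Index:
        return self.dominant.columns

    def validate(self) -> None:
        """Raise if any cell violates 0 <= s_dom <= s_rec <= 1."""
        dom, rec = self.dominant.to_numpy(), self.recessive.to_numpy()
        if np.any(dom < -1e-12) or np.any(rec > 1 + 1e-12):
            raise ValueError("scores outside [0, 1]")
        if np.any(dom > rec + 1e-12):
            raise ValueError("dominant score exceeds recessive score")

    def to_long(self) -> pd.DataFrame:
        dom = self.dominant.stack()
        rec = self.recessive.stack()
        out = pd.DataFrame(
            {"dominant_score": dom, "recessive_score": rec}
        ).reset_index()
        out.columns = ["individual_id", "gene_id", "dominant_score", "recessive_score"]
        return out

    def to_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EffectScoreMatrix":
        long = pd.read_csv(path, sep="\t")
        dom = long.pivot(
            index="individual_id", columns="gene_id", values="dominant_score"
        )
        rec = long.pivot(
            index="individual_id", columns="gene_id", values="recessive_score"
        )
        return cls(dominant=dom, recessive=rec)


def score_matrix(
    dosages: pd.DataFrame,
    variants: pd.DataFrame,
    het_low: float = 0.5,
    het_high: float = 1.5,
) -> EffectScoreMatrix:
    """Score every (individual, gene) cell of a cohort.

    Parameters
    ----------
    dosages
        Individuals x variants DataFrame of alternate-allele dosages in
        [0, 2]; NaN marks a missing genotype, treated as homozygous
        reference and counted in ``n_missing`` for its gene.
    variants
        Variant table with columns ``variant_id``, ``gene_id`` and
        ``damage_prob``; every variant column of `dosages` must appear.

    Notes
    -----
    Vectorised over individuals per gene; alleles with ``d == 1`` are
    damaging with certainty and handled exactly (a single such allele forces
    ``s_dom = 0``; two or more force ``s_rec = 0``).
    """
    vt = variants.set_index("variant_id")
    unknown = [v for v in dosages.columns if v not in vt.index]
    if unknown:
        raise ValueError(f"variants absent from the variant table: {unknown}")

    n = len(dosages)
    genes = list(dict.fromkeys(vt.loc[dosages.columns, "gene_id"]))
    dom = np.ones((n, len(genes)))
    rec = np.ones((n, len(genes)))
    n_missing = pd.Series(0, index=pd.Index(genes, name="gene_id"))

    by_gene: dict[str, list[str]] = {}
    for v in dosages.columns:
        by_gene.setdefault(vt.at[v, "gene_id"], []).append(v)

    for j, gene in enumerate(genes):
        cols = by_gene[gene]
        raw = dosages[cols].to_numpy(dtype=float)
        miss = ~np.isfinite(raw)
        n_missing[gene] = int(miss.sum())
        raw = np.where(miss, 0.0, raw)
        G = hard_call(raw, het_low, het_high)
        d = vt.loc[cols, "damage_prob"].to_numpy(dtype=float)
        if np.any((d < 0) | (d > 1)):
            raise ValueError(f"damage probabilities outside [0, 1] in gene {gene}")

        certain = d >= 1.0
        z = G[:, certain].sum(axis=1) if certain.any() else np.zeros(n, dtype=int)
        Gs, ds = G[:, ~certain], d[~certain]
        q = 1.0 - ds
        with np.errstate(divide="ignore"):
            logq = np.log(q)
        p0_sub = np.exp(Gs @ logq) if Gs.shape[1] else np.ones(n)
        ratio = np.divide(ds, q, out=np.zeros_like(ds), where=q > 0)
        s = Gs @ ratio if Gs.shape[1] else np.zeros(n)
        p0 = np.where(z == 0, p0_sub, 0.0)
        p1 = np.where(z == 0, p0_sub * s, np.where(z == 1, p0_sub, 0.0))
        dom[:, j] = p0
        rec[:, j] = np.minimum(p0 + p1, 1.0)

    out = EffectScoreMatrix(
        dominant=pd.DataFrame(dom, index=dosages.index, columns=genes),
        recessive=pd.DataFrame(rec, index=dosages.index, columns=genes),
        n_missing=n_missing,
    )
    out.validate()
    return out
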