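"""Merging significant associations into unique genomic regions.

Each significant variant-level hit seeds a closed 1-based interval of
``[pos - flank, pos + flank]`` (1,000,001 bp at the default 500 kb flank)
and each significant gene seeds ``[cds_start - flank, cds_end + flank]``;
overlapping intervals on the same chromosome are merged transitively to a
fixed point, carrying their member hits, phenotypes and method provenance.
Regions are then classified by method support (GWAS / PWAS / both), by the
inheritance modes of their member genes, and as *solitons* — regions whose
PWAS signal is confined to exactly one gene at very strong significance —
which are the regions least confounded by linkage disequilibrium.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import pandas as pd

from .association import SignificanceConfig

__all__ = [
    "GenomicInterval",
    "CancerRegion",
    "seed_intervals",
    "merge_intervals",
    "classify_region",
    "cancer_type_overlap_counts",
    "regions_to_bed",
    "regions_to_table",
]

DEFAULT_FLANK = 500_000


@dataclass(frozen=True)
class GenomicInterval:
    """Closed, 1-based genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"require 1 <= start <= end, got {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        # closed convention: a shared endpoint is a 1 bp overlap
        return self.chrom == other.chrom and (
            self.start <= other.end and other.start <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class CancerRegion:
    """A merged genomic region with its member associations.

    ``member_variants`` holds ``(variant_id, phenotype, p)`` tuples and
    ``member_genes`` holds ``(gene_id, phenotype, q, inheritance)`` tuples;
    ``phenotypes`` is the union of member phenotypes.  Classification fields
    are filled by :func:`classify_region`; evidence fields by
    :mod:`pwascan.evidence`.
    """

    interval: GenomicInterval
    member_variants: list = field(default_factory=list)
    member_genes: list = field(default_factory=list)
    phenotypes: set = field(default_factory=set)
    method_support: str | None = None
    inheritance_mode: str | None = None
    soliton: bool = False
    panel_genes: dict = field(default_factory=dict)
    catalogue_genes: dict = field(default_factory=dict)
    gene_level_evidence: dict = field(default_factory=dict)

    @property
    def region_id(self) -> str:
        return str(self.interval)


def seed_intervals(
    gwas_hits: pd.DataFrame | None,
    pwas_genes: pd.DataFrame | None,
    gene_coords: pd.DataFrame | None = None,
    flank: int = DEFAULT_FLANK,
) -> list[CancerRegion]:
    """Turn significant hits into flanked single-member proto-regions.

    ``gwas_hits`` needs columns ``variant_id, chrom, pos, phenotype, p``;
    ``pwas_genes`` needs ``gene_id, phenotype, q, inheritance`` and gene
    CDS coordinates are looked up in ``gene_coords`` (columns ``gene_id,
    chrom, cds_start, cds_end``).  Intervals are clipped at position 1.
    """
    seeds: list[CancerRegion] = []
    if gwas_hits is not None and len(gwas_hits):
        for row in gwas_hits.itertuples():
            iv = GenomicInterval(
                str(row.chrom), max(1, int(row.pos) - flank), int(row.pos) + flank
            )
            seeds.append(
                CancerRegion(
                    interval=iv,
                    member_variants=[(row.variant_id, row.phenotype, float(row.p))],
                    phenotypes={row.phenotype},
                )
            )
    if pwas_genes is not None and len(pwas_genes):
        if gene_coords is None:
            raise ValueError("gene_coords required to seed gene-level hits")
        gc = gene_coords.set_index("gene_id")
        missing = [g for g in pwas_genes["gene_id"] if g not in gc.index]
        if missing:
            raise ValueError(f"missing gene coordinates for: {sorted(set(missing))}")
        for row in pwas_genes.itertuples():
            g = gc.loc[row.gene_id]
            iv = GenomicInterval(
                str(g["chrom"]),
                max(1, int(g["cds_start"]) - flank),
                int(g["cds_end"]) + flank,
            )
            seeds.append(
                CancerRegion(
                    interval=iv,
                    member_genes=[
                        (
                            row.gene_id,
                            row.phenotype,
                            float(row.q),
                            getattr(row, "inheritance", "none"),
                        )
                    ],
                    phenotypes={row.phenotype},
                )
            )
    return seeds


def merge_intervals(seeds: list[CancerRegion]) -> list[CancerRegion]:
    """Transitively merge overlapping proto-regions per chromosome.

    Closed-interval convention: intervals sharing an endpoint overlap by
    one base pair and merge.  Output is sorted by (chromosome, start) and
    pairwise disjoint; member lists and phenotype sets are unioned.
    """
    by_chrom: dict[str, list[CancerRegion]] = {}
    for s in seeds:
        by_chrom.setdefault(s.interval.chrom, []).append(s)
    out: list[CancerRegion] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda r: (r.interval.start, r.interval.end))
        current: CancerRegion | None = None
        for r in group:
            if current is not None and r.interval.start <= current.interval.end:
                current = CancerRegion(
                    interval=GenomicInterval(
                        chrom,
                        current.interval.start,
                        max(current.interval.end, r.interval.end),
                    ),
                    member_variants=current.member_variants + r.member_variants,
                    member_genes=current.member_genes + r.member_genes,
                    phenotypes=current.phenotypes | r.phenotypes,
                )
            else:
                if current is not None:
                    out.append(current)
                current = CancerRegion(
                    interval=r.interval,
                    member_variants=list(r.member_variants),
                    member_genes=list(r.member_genes),
                    phenotypes=set(r.phenotypes),
                )
        if current is not None:
            out.append(current)
    return out


def classify_region(
    region: CancerRegion, config: SignificanceConfig | None = None
) -> CancerRegion:
    """Fill method support, inheritance mode and the soliton flag.

    A region is a soliton when (i) exactly one distinct gene in it is
    PWAS-significant and (ii) that gene's best q-value is below the strict
    soliton threshold.
    """
    config = config or SignificanceConfig()
    has_gwas = bool(region.member_variants)
    has_pwas = bool(region.member_genes)
    region.method_support = (
        "both" if has_gwas and has_pwas else ("GWAS" if has_gwas else "PWAS")
    )

    modes = {m for (_, _, _, m) in region.member_genes if m in ("dominant", "recessive", "both")}
    if not modes:
        region.inheritance_mode = "n/a"
    elif modes == {"dominant"}:
        region.inheritance_mode = "dominant"
    elif modes == {"recessive"}:
        region.inheritance_mode = "recessive"
    else:
        region.inheritance_mode = "both"

    genes = {g for (g, _, _, _) in region.member_genes}
    if len(genes) == 1:
        best_q = min(q for (_, _, q, _) in region.member_genes)
        region.soliton = best_q < config.soliton_q_threshold
    else:
        region.soliton = False
    return region


def cancer_type_overlap_counts(
    regions: list[CancerRegion],
) -> tuple[dict[frozenset, int], dict[str, int]]:
    """Partition regions by exact phenotype combination.

    Returns ``(exact, inclusive)``: exact-match counts per observed
    phenotype set (these sum to the number of regions) and, per single
    phenotype, the total number of regions whose combination includes it.
    """
    exact: Counter = Counter(frozenset(r.phenotypes) for r in regions)
    inclusive: Counter = Counter()
    for r in regions:
        for p in r.phenotypes:
            inclusive[p] += 1
    return dict(exact), dict(inclusive)


def regions_to_bed(regions: list[CancerRegion], path) -> None:
    """Write regions as BED (0-based half-open; start-1, end unchanged)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.interval.chrom}\t{r.interval.start - 1}\t{r.interval.end}\t{r.region_id}\n")


def regions_to_table(regions: list[CancerRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append(
            {
                "region_id": r.region_id,
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "length": r.interval.length,
                "n_variants": len(r.member_variants),
                "n_genes": len({g for (g, _, _, _) in r.member_genes}),
                "phenotypes": ",".join(sorted(r.phenotypes)),
                "method_support": r.method_support,
                "inheritance_mode": r.inheritance_mode,
                "soliton": r.soliton,
            }
        )
    return pd.DataFrame(rows)
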