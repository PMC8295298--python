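"""Annotation of regions and genes against external gene lists.

Two kinds of external resource are distinguished: clinical *panels* (gene
lists used diagnostically) and driver *catalogues* (research compilations
of cancer genes).  A region is supported by a resource when it contains at
least one listed gene (placed by coordinates), regardless of whether that
gene is itself significant; for soliton tables a stricter gene-level rule
is used — only evidence matching the exact significant gene counts.
Identifier matching is case-insensitive on symbols, with an optional alias
map for symbol drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .regions import CancerRegion

__all__ = [
    "GenePanel",
    "annotate_regions",
    "support_summary",
    "report_fractions",
    "load_alias_map",
]

EVIDENCE_CATEGORIES = ("panels only", "drivers only", "both", "none")


@dataclass(frozen=True)
class GenePanel:
    """A named set of gene identifiers (upper-cased for matching)."""

    name: str
    genes: frozenset
    id_space: str = "symbol"

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"panel {self.name!r} is empty")

    @classmethod
    def from_file(cls, path, name: str | None = None, alias_map: dict | None = None):
        symbols = []
        with open(path) as fh:
            for line in fh:
                s = line.strip()
                if s and not s.startswith("#"):
                    symbols.append(s)
        genes = frozenset(_canon(s, alias_map) for s in symbols)
        return cls(name=name or str(path), genes=genes)

    def __contains__(self, symbol: str) -> bool:
        return _canon(symbol) in self.genes


def _canon(symbol: str, alias_map: dict | None = None) -> str:
    s = str(symbol).strip().upper()
    if alias_map:
        s = alias_map.get(s, s)
    return s


def load_alias_map(path) -> dict:
    """Read an alias->canonical TSV (two columns) into an upper-cased map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["alias", "canonical"])
    return {str(a).upper(): str(c).upper() for a, c in zip(df.alias, df.canonical)}


def annotate_regions(
    regions: list[CancerRegion],
    panels: list[GenePanel],
    catalogues: list[GenePanel],
    gene_coords: pd.DataFrame,
    alias_map: dict | None = None,
) -> tuple[list[CancerRegion], list[str]]:
    """Attach panel/catalogue evidence to each region.

    Listed genes are placed into regions by CDS-interval overlap with the
    region interval.  Fills ``panel_genes`` / ``catalogue_genes`` (resource
    name -> set of contained listed genes) and ``gene_level_evidence``
    (resource name -> listed genes that are themselves significant members
    of the region, the soliton-table rule).  Returns the regions and a list
    of warnings for listed genes without coordinates.
    """
    gc = gene_coords.copy()
    gc["_canon"] = [_canon(g, alias_map) for g in gc["gene_id"]]
    placed = gc.set_index("_canon")
    warnings: list[str] = []

    all_resources = [(p, "panel") for p in panels] + [(c, "catalogue") for c in catalogues]
    for res, _ in all_resources:
        for g in res.genes:
            if _canon(g, alias_map) not in placed.index:
                warnings.append(f"{res.name}: no coordinates for gene {g}")

    for region in regions:
        iv = region.interval
        region.panel_genes = {}
        region.catalogue_genes = {}
        region.gene_level_evidence = {}
        member_genes = {_canon(g, alias_map) for (g, _, _, _) in region.member_genes}
        for res, kind in all_resources:
            inside = set()
            for g in res.genes:
                key = _canon(g, alias_map)
                if key not in placed.index:
                    continue
                row = placed.loc[key]
                if (
                    str(row["chrom"]) == iv.chrom
                    and int(row["cds_start"]) <= iv.end
                    and int(row["cds_end"]) >= iv.start
                ):
                    inside.add(key)
            target = region.panel_genes if kind == "panel" else region.catalogue_genes
            if inside:
                target[res.name] = inside
            exact = inside & member_genes
            if exact:
                region.gene_level_evidence[res.name] = exact
    return regions, warnings


def _evidence_category(region: CancerRegion) -> str:
    has_panel = bool(region.panel_genes)
    has_driver = bool(region.catalogue_genes)
    if has_panel and has_driver:
        return "both"
    if has_panel:
        return "panels only"
    if has_driver:
        return "drivers only"
    return "none"


def support_summary(regions: list[CancerRegion]) -> pd.DataFrame:
    """Cross-tabulate regions by method support x evidence category.

    The cell counts partition the region set (they sum to ``len(regions)``).
    """
    idx = ["GWAS", "PWAS", "both"]
    out = pd.DataFrame(0, index=pd.Index(idx, name="method_support"),
                       columns=list(EVIDENCE_CATEGORIES))
    for r in regions:
        if r.method_support not in idx:
            raise ValueError("regions must be classified before summarising")
        out.loc[r.method_support, _evidence_category(r)] += 1
    return out


def report_fractions(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half away from zero."""
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    pct = 100.0 * numerator / denominator
    return int(math.floor(pct + 0.5)) if pct >= 0 else -int(math.floor(-pct + 0.5))
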