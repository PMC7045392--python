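"""Replication-transcription head-on collision scoring and
expression/copy-number correlation.

With a single predominant replication origin on a circular chromosome,
forks travel clockwise over one half-circle and counterclockwise over
the other. A gene transcribed against the local fork direction sits on
the lagging strand and suffers head-on collisions; the fractional score
P(HO) is the coverage-weighted fraction of such transcription in a
region: P(HO) = sum(lagging-strand RNA coverage) / total RNA coverage.

The positional analysis smooths per-gene log2 fold changes against
oriC-recentered gene midpoints with LOESS and correlates RNA and DNA
fold-change profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import ChromosomeMap, GeneRecord

log = logging.getLogger(__name__)

__all__ = [
    "CollisionScore",
    "classify_head_on",
    "head_on_fraction",
    "logfc_per_gene",
    "positional_smooth_and_correlate",
]


@dataclass
class CollisionScore:
    region: tuple[int, int]
    origin_used: int
    gene_class_filter: str
    p_ho: float
    n_genes: int
    total_coverage: float


class AmbiguousGeneError(ValueError):
    """Gene midpoint exactly at the origin or its antipode."""


def classify_head_on(gene: GeneRecord, origin: int, chrom: ChromosomeMap) -> str:
    """Classify a gene as ``"head_on"`` or ``"co_directional"``.

    The fork moving clockwise from ``origin`` covers the arc up to the
    origin's antipode; a '+'-strand gene (transcribed toward increasing
    coordinates) on that arc is co-directional, and on the opposite arc
    head-on. Midpoints exactly at the origin or antipode are ambiguous.
    """
    L = chrom.length
    d = (gene.midpoint - origin) % L
    if d == 0 or d == L / 2:
        raise AmbiguousGeneError(
            f"gene {gene.gene_id}: midpoint exactly at origin or antipode"
        )
    fork_clockwise = d < L / 2
    transcribed_clockwise = gene.strand == "+"
    return "co_directional" if fork_clockwise == transcribed_clockwise else "head_on"


def _in_region(midpoint: float, region: tuple[int, int], L: int) -> bool:
    lo, hi = region
    if lo <= hi:
        return lo <= midpoint <= hi
    return midpoint >= lo or midpoint <= hi  # region wraps the origin of coords


def _passes_filter(gene: GeneRecord, gene_class_filter: str, five_s_only: bool) -> bool:
    if gene_class_filter == "all":
        return True
    if gene_class_filter == "rRNA":
        if gene.gene_class != "rRNA":
            return False
        if five_s_only:
            return "5s" in gene.product.lower()
        return True
    if gene_class_filter == "mRNA":
        return gene.gene_class == "mRNA"
    if gene_class_filter == "essential-mRNA":
        return gene.gene_class == "mRNA" and gene.essential
    raise ValueError(f"unknown gene class filter {gene_class_filter!r}")


def head_on_fraction(
    expression: dict[str, float],
    genes: list[GeneRecord],
    region: tuple[int, int],
    origin: int,
    chrom: ChromosomeMap,
    gene_class_filter: str = "all",
    five_s_only: bool = False,
    per_kb: bool = False,
) -> CollisionScore:
    """P(HO) over genes whose midpoints fall inside ``region``.

    ``expression`` maps gene_id to summed RNA coverage. ``per_kb``
    length-normalizes coverage per gene before summing. Ambiguous genes
    (midpoint at origin/antipode) are excluded with a warning.
    """
    total = 0.0
    lagging = 0.0
    n_used = 0
    for gene in genes:
        if gene.gene_id not in expression:
            continue
        if not _in_region(gene.midpoint, region, chrom.length):
            continue
        if not _passes_filter(gene, gene_class_filter, five_s_only):
            continue
        cov = float(expression[gene.gene_id])
        if per_kb:
            cov = cov / (gene.length / 1000.0)
        try:
            cls = classify_head_on(gene, origin, chrom)
        except AmbiguousGeneError:
            log.warning("excluding gene %s: midpoint at origin/antipode", gene.gene_id)
            continue
        total += cov
        if cls == "head_on":
            lagging += cov
        n_used += 1
    if total <= 0:
        raise ValueError("zero total coverage in region after filtering")
    return CollisionScore(
        region=region, origin_used=origin, gene_class_filter=gene_class_filter,
        p_ho=lagging / total, n_genes=n_used, total_coverage=total,
    )


def logfc_per_gene(counts_a: dict[str, float], counts_b: dict[str, float]) -> dict[str, float]:
    """Per-gene log2 fold change of a over b, library-size normalized.

    Both libraries are scaled to the mean of the two totals, then
    logFC = log2((a + 0.5) / (b + 0.5)). Used for positional analysis
    only; it is not a differential-expression test.
    """
    shared = sorted(set(counts_a) & set(counts_b))
    if not shared:
        raise ValueError("no shared genes between the two count tables")
    ta = sum(counts_a[g] for g in shared)
    tb = sum(counts_b[g] for g in shared)
    if ta <= 0 or tb <= 0:
        raise ValueError("each condition needs at least one nonzero count")
    target = (ta + tb) / 2.0
    sa, sb = target / ta, target / tb
    return {
        g: float(np.log2((counts_a[g] * sa + 0.5) / (counts_b[g] * sb + 0.5)))
        for g in shared
    }


def positional_smooth_and_correlate(
    logfc_rna: dict[str, float],
    logfc_dna: dict[str, float],
    genes: list[GeneRecord],
    chrom: ChromosomeMap,
    span: float = 0.3,
) -> tuple[float, float]:
    """Pearson correlation of raw and LOESS-smoothed fold-change profiles.

    Both per-gene vectors are smoothed against the oriC-recentered gene
    midpoint before the second correlation; smoothing averages out
    gene-level variation and exposes the positional (copy-number-driven)
    component.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    shared = [g for g in logfc_rna if g in logfc_dna and g in gene_by_id]
    if len(shared) < 30:
        raise ValueError("need at least 30 shared genes")
    x = chrom.recenter(np.array([gene_by_id[g].midpoint for g in shared]))
    ra = np.array([logfc_rna[g] for g in shared])
    da = np.array([logfc_dna[g] for g in shared])
    if ra.std() == 0 or da.std() == 0:
        raise ValueError("zero variance in a fold-change vector")
    pearson_raw = float(np.corrcoef(ra, da)[0, 1])
    order = np.argsort(x, kind="stable")
    sm_r = lowess(ra[order], x[order], frac=span, it=1, return_sorted=False)
    sm_d = lowess(da[order], x[order], frac=span, it=1, return_sorted=False)
    if sm_r.std() == 0 or sm_d.std() == 0:
        return pearson_raw, float("nan")
    pearson_smoothed = float(np.corrcoef(sm_r, sm_d)[0, 1])
    return pearson_raw, pearson_smoothed
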