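"""Integrative analyses: CpG–TE overlap, randomized-background methylation
comparison, nearest-gene bystander analysis and TSS metaplots.

The background comparison samples repeat regions, not CpGs: an equal
number of background regions is drawn without replacement from the full
annotation, the CpGs inside each region set are collected, and the two
percent vectors are compared with a two-sided Mann–Whitney U test.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel, TERecord
from .stats import MannWhitneyResult, mann_whitney_u

logger = logging.getLogger(__name__)


def overlap_cpgs_tes(
    sites: pd.DataFrame, loci: list[TERecord]
) -> pd.DataFrame:
    """Every (CpG, locus) incidence with pos ∈ [start, end).

    ``sites`` needs chrom/pos columns or a (chrom, pos) MultiIndex.
    Returns a long DataFrame (chrom, pos, locus_index, family_name,
    te_class); a site inside several (possibly nested) loci appears
    once per locus.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, loc in enumerate(loci):
        trees[loc.chrom].addi(loc.start, loc.end, i)
    if {"chrom", "pos"}.issubset(sites.columns):
        chroms = sites["chrom"].to_numpy()
        positions = sites["pos"].to_numpy()
    else:
        chroms = sites.index.get_level_values(0).to_numpy()
        positions = sites.index.get_level_values(1).to_numpy()
    rows = []
    for chrom, pos in zip(chroms, positions):
        for iv in trees[chrom].at(pos):
            loc = loci[iv.data]
            rows.append((chrom, pos, iv.data, loc.family_name, loc.te_class))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "locus_index", "family_name", "te_class"]
    )


@dataclass
class BackgroundComparison:
    focal_family_set: tuple
    n_focal_regions: int
    n_background_regions: int
    focal_percents: np.ndarray
    background_percents: np.ndarray
    u_statistic: float
    p_value: float
    focal_median: float
    background_median: float
    draw_p_values: list = field(default_factory=list)


def _region_percents(
    regions: list[TERecord], sites: pd.DataFrame, percent_col: str
) -> np.ndarray:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, loc in enumerate(regions):
        trees[loc.chrom].addi(loc.start, loc.end, i)
    chroms = sites.index.get_level_values(0).to_numpy()
    positions = sites.index.get_level_values(1).to_numpy()
    pct = sites[percent_col].to_numpy()
    keep = [
        p
        for chrom, pos, p in zip(chroms, positions, pct)
        if trees[chrom].overlaps_point(pos)
    ]
    return np.asarray(keep, dtype=float)


def background_methylation_comparison(
    upregulated_families,
    all_loci: list[TERecord],
    sites: pd.DataFrame,
    percent_col: str = "percent_WT",
    n_draws: int = 1,
    seed: int = 0,
    exclude_focal: bool = False,
) -> BackgroundComparison:
    """Methylation of upregulated-family loci vs an equal random background.

    Focal regions are all genomic copies of the upregulated families;
    the background is an equal-size region sample drawn without
    replacement from all TE loci (focal loci eligible unless
    ``exclude_focal``).  CpG percents (``percent_col`` of the joint
    table) inside each region set are compared two-sided by
    Mann–Whitney U.  With ``n_draws`` > 1 the reported p is the median
    over draws (the first draw's vectors are kept for inspection).
    """
    fams = set(upregulated_families)
    focal = [l for l in all_loci if l.family_name in fams]
    if not focal:
        raise ValueError("focal family set matches no locus")
    pool = [
        l for l in all_loci if not (exclude_focal and l.family_name in fams)
    ]
    if len(pool) < len(focal):
        raise ValueError(
            f"background pool ({len(pool)}) smaller than focal set "
            f"({len(focal)})"
        )
    focal_pct = _region_percents(focal, sites, percent_col)
    rng = np.random.default_rng(seed)
    p_values, results = [], []
    first_bg = None
    for _ in range(max(1, n_draws)):
        idx = rng.choice(len(pool), size=len(focal), replace=False)
        bg = [pool[i] for i in idx]
        bg_pct = _region_percents(bg, sites, percent_col)
        if focal_pct.size == 0 or bg_pct.size == 0:
            raise ValueError("no CpGs fall inside one of the region sets")
        res = mann_whitney_u(focal_pct, bg_pct)
        p_values.append(res.p_value)
        results.append(res)
        if first_bg is None:
            first_bg = bg_pct
    med_idx = int(np.argsort(p_values)[len(p_values) // 2])
    return BackgroundComparison(
        focal_family_set=tuple(sorted(fams)),
        n_focal_regions=len(focal),
        n_background_regions=len(focal),
        focal_percents=focal_pct,
        background_percents=first_bg,
        u_statistic=results[med_idx].u_statistic,
        p_value=float(np.median(p_values)),
        focal_median=float(np.median(focal_pct)),
        background_median=float(np.median(first_bg)),
        draw_p_values=p_values,
    )


@dataclass(frozen=True)
class NearestGeneAssignment:
    te_locus: TERecord
    gene: GeneModel | None
    distance: float  # bp; 0 if overlapping; inf if unassigned


def nearest_gene(locus: TERecord, genes: list[GeneModel]) -> NearestGeneAssignment:
    """Nearest gene with no distance limit (same chromosome only).

    Distance is 0 for any overlap, otherwise the bp gap between the
    closest interval ends.  Ties break toward the lower gene start.  A
    locus on a chromosome without genes is reported unassigned.
    """
    if not genes:
        raise ValueError("need at least one gene")
    best: GeneModel | None = None
    best_d = float("inf")
    for g in genes:
        if g.chrom != locus.chrom:
            continue
        if g.start < locus.end and locus.start < g.end:
            d = 0.0
        elif g.start >= locus.end:
            d = float(g.start - locus.end)
        else:
            d = float(locus.start - g.end)
        if d < best_d or (d == best_d and best is not None and g.start < best.start):
            best, best_d = g, d
    return NearestGeneAssignment(locus, best, best_d)


def assign_nearest_genes(
    loci: list[TERecord], genes: list[GeneModel]
) -> list[NearestGeneAssignment]:
    return [nearest_gene(l, genes) for l in loci]


def bystander_test(
    family_name: str,
    assignments: list[NearestGeneAssignment],
    gene_diff: pd.DataFrame,
    te_diff: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict:
    """Neighbor-gene expression report for one TE family.

    Deduplicates the nearest-neighbor genes of the family's copies
    (several copies can flank one gene), then reports the fraction of
    neighbors significantly up (padj < alpha, l2fc > 0) and a
    Mann–Whitney comparison of neighbor-gene L2FC against all genes.
    """
    copies = [a for a in assignments
              if a.te_locus.family_name == family_name and a.gene is not None]
    if not copies:
        raise ValueError(f"family {family_name!r} has no assigned copies")
    neighbor_ids = sorted({a.gene.gene_id for a in copies})
    present = [g for g in neighbor_ids if g in gene_diff.index]
    sub = gene_diff.loc[present]
    n_up = int(((sub["padj"] < alpha) & (sub["l2fc"] > 0)).sum())
    neighbor_l2fc = sub["l2fc"].to_numpy()
    all_l2fc = gene_diff["l2fc"].to_numpy()
    if neighbor_l2fc.size and all_l2fc.size:
        mw: MannWhitneyResult | None = mann_whitney_u(neighbor_l2fc, all_l2fc)
    else:
        mw = None
    report = {
        "family_name": family_name,
        "n_copies": len(copies),
        "n_neighbor_genes": len(neighbor_ids),
        "neighbor_genes": neighbor_ids,
        "fraction_up": (n_up / len(present)) if present else float("nan"),
        "mean_neighbor_l2fc": (
            float(neighbor_l2fc.mean()) if neighbor_l2fc.size else float("nan")
        ),
        "mw_u": mw.u_statistic if mw else float("nan"),
        "mw_p": mw.p_value if mw else float("nan"),
    }
    if te_diff is not None and family_name in te_diff.index:
        report["family_l2fc"] = float(te_diff.loc[family_name, "l2fc"])
    return report


def bystander_report(
    family_names,
    assignments: list[NearestGeneAssignment],
    gene_diff: pd.DataFrame,
    te_diff: pd.DataFrame,
    alpha: float = 0.05,
):
    """Per-family bystander reports plus the family-vs-neighbor L2FC r."""
    from scipy import stats as sps

    reports = [
        bystander_test(f, assignments, gene_diff, te_diff, alpha)
        for f in family_names
    ]
    xs = [r["family_l2fc"] for r in reports if "family_l2fc" in r
          and np.isfinite(r["mean_neighbor_l2fc"])]
    ys = [r["mean_neighbor_l2fc"] for r in reports if "family_l2fc" in r
          and np.isfinite(r["mean_neighbor_l2fc"])]
    if len(xs) >= 2 and np.std(xs) > 0 and np.std(ys) > 0:
        r = float(sps.pearsonr(xs, ys).statistic)
    else:
        r = float("nan")
    return reports, r


@dataclass
class MetaProfile:
    window: int
    n_bins: int
    bin_centers: np.ndarray
    mean_percent: dict  # condition → per-bin mean (nan where empty)
    bin_counts: np.ndarray


def tss_metaplot(
    gene_set: list[GeneModel],
    sites: pd.DataFrame,
    window: int = 4000,
    n_bins: int = 80,
    percent_cols: tuple = ("percent_WT", "percent_mutant"),
) -> MetaProfile:
    """Mean methylation in bins of the ±window region around the TSS.

    The axis is strand-oriented: upstream negative, downstream
    positive; minus-strand genes are flipped.  Each (gene, CpG)
    incidence contributes once; empty bins carry NaN means and a zero
    count.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    width = 2 * window / n_bins
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in gene_set:
        by_chrom[g.chrom].append(g)
    chroms = sites.index.get_level_values(0).to_numpy()
    positions = sites.index.get_level_values(1).to_numpy()
    pct = {c: sites[c].to_numpy() for c in percent_cols if c in sites.columns}

    sums = {c: np.zeros(n_bins) for c in pct}
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in by_chrom:
        mask = chroms == chrom
        pos_c = positions[mask]
        pct_c = {c: v[mask] for c, v in pct.items()}
        for g in by_chrom[chrom]:
            offset = pos_c - g.tss if g.strand == "+" else g.tss - pos_c
            inside = (offset >= -window) & (offset < window)
            if not inside.any():
                continue
            bins = ((offset[inside] + window) / width).astype(int)
            np.clip(bins, 0, n_bins - 1, out=bins)
            np.add.at(counts, bins, 1)
            for c in pct:
                np.add.at(sums[c], bins, pct_c[c][inside])
    means = {
        c: np.where(counts > 0, sums[c] / np.maximum(counts, 1), np.nan)
        for c in pct
    }
    centers = -window + width * (np.arange(n_bins) + 0.5)
    return MetaProfile(window, n_bins, centers, means, counts)
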