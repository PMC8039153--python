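"""CpG call parsing, coverage filtering, state classification and context.

Condition-level methylation is computed from POOLED read counts within
each condition (percent = 100·ΣM/ΣT), mirroring the practice of merging
replicates to increase coverage.  A CpG enters the joint table only if
its pooled coverage reaches ``min_coverage`` in every condition.  States
follow strict thresholds: below ``low`` percent → unmethylated, above
``high`` → methylated, boundaries and everything between →
intermediate.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel

logger = logging.getLogger(__name__)

STATES = ("unmethylated", "intermediate", "methylated")
CONTEXTS = ("promoter", "exon", "intron", "intergenic")


def read_cpg_calls(path) -> pd.DataFrame:
    """Read a Bismark coverage file (1-based inclusive positions).

    Returns a DataFrame with chrom, pos (0-based), methylated, total and
    percent columns.  Percent is recomputed from the counts; a file
    percent inconsistent beyond 0.01 triggers a warning, the counts
    being authoritative.  Methylated > total is a hard error.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "percent", "meth", "unmeth"],
    )
    if df.empty:
        return pd.DataFrame(
            columns=["chrom", "pos", "methylated", "total", "percent"]
        )
    total = df["meth"] + df["unmeth"]
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        bad = int(np.argmax((df["meth"] < 0) | (df["unmeth"] < 0)))
        raise ValueError(f"{path}: negative read count at line {bad + 1}")
    pct = 100.0 * df["meth"] / total
    if (np.abs(pct - df["percent"]) > 0.01).any():
        logger.warning(
            "%s: percent column inconsistent with counts; recomputed", path
        )
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"] - 1,
            "methylated": df["meth"].astype(np.int64),
            "total": total.astype(np.int64),
            "percent": pct,
        }
    )


def filter_common_cpgs(
    samples: dict[str, pd.DataFrame],
    design: dict[str, str],
    min_coverage: int = 10,
) -> pd.DataFrame:
    """Pool counts per condition and keep CpGs covered in every condition.

    ``samples`` maps sample id to a read_cpg_calls frame.  A CpG is
    retained iff its pooled coverage within EACH condition is at least
    ``min_coverage``.  Returns a frame indexed by (chrom, pos) with
    meth_<cond>, total_<cond> and percent_<cond> columns.
    """
    conditions = sorted(set(design.values()))
    pooled: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        frames = [
            samples[s][["chrom", "pos", "methylated", "total"]]
            for s in samples
            if design[s] == cond
        ]
        if not frames:
            raise ValueError(f"no samples for condition {cond}")
        cat = pd.concat(frames).groupby(["chrom", "pos"]).sum()
        pooled[cond] = cat
    joint = pd.concat(
        {c: pooled[c] for c in conditions}, axis=1, join="inner"
    ).dropna()
    keep = np.ones(len(joint), dtype=bool)
    for cond in conditions:
        keep &= (joint[(cond, "total")] >= min_coverage).to_numpy()
    joint = joint[keep]
    out = pd.DataFrame(index=joint.index)
    for cond in conditions:
        m = joint[(cond, "methylated")].astype(np.int64)
        t = joint[(cond, "total")].astype(np.int64)
        out[f"meth_{cond}"] = m
        out[f"total_{cond}"] = t
        out[f"percent_{cond}"] = 100.0 * m / t
    return out


def classify_methylation(
    joint: pd.DataFrame, low: float = 20.0, high: float = 80.0
) -> pd.DataFrame:
    """Add a state_<cond> column per condition (strict thresholds)."""
    if low >= high:
        raise ValueError("low threshold must be below high threshold")
    out = joint.copy()
    for col in [c for c in joint.columns if c.startswith("percent_")]:
        cond = col[len("percent_"):]
        pct = joint[col].to_numpy()
        state = np.where(
            pct < low,
            "unmethylated",
            np.where(pct > high, "methylated", "intermediate"),
        )
        out[f"state_{cond}"] = state
    return out


def methylation_density(
    joint: pd.DataFrame, condition: str, bins: int = 10
):
    """Normalized histogram of per-CpG percents plus the grand mean.

    Default decile bins: the terminal bins then sit inside the
    unmethylated (<20%) and methylated (>80%) classification bands, so a
    bimodal methylome shows up as mass concentrated in bins 0 and 9.
    Returns (bin_edges, masses, grand_mean); masses sum to 1.
    """
    pct = joint[f"percent_{condition}"].to_numpy()
    if pct.size == 0:
        raise ValueError("no CpGs to build a density from")
    hist, edges = np.histogram(pct, bins=bins, range=(0.0, 100.0))
    masses = hist / hist.sum()
    return edges, masses, float(pct.mean())


def track_state_transitions(
    joint: pd.DataFrame,
    from_condition: str = "WT",
    to_condition: str = "mutant",
    bins: int = 50,
) -> dict:
    """Partition CpGs by their state in one condition; profile the other.

    For each state in ``from_condition``, reports the number of CpGs,
    the mean percent in ``to_condition`` and a normalized density of
    those percents.  Empty partitions are reported as empty.
    """
    state_col = f"state_{from_condition}"
    if state_col not in joint.columns:
        raise KeyError(f"run classify_methylation first ({state_col} missing)")
    pct_to = joint[f"percent_{to_condition}"]
    out = {}
    for state in STATES:
        sub = pct_to[joint[state_col] == state].to_numpy()
        if sub.size:
            hist, edges = np.histogram(sub, bins=bins, range=(0.0, 100.0))
            out[state] = {
                "n": int(sub.size),
                "mean": float(sub.mean()),
                "density": hist / hist.sum(),
                "bin_edges": edges,
            }
        else:
            out[state] = {"n": 0, "mean": float("nan"), "density": None,
                          "bin_edges": None}
    return out


def annotate_genomic_context(
    sites: pd.DataFrame,
    genes: list[GeneModel],
    promoter_up: int = 1000,
    promoter_down: int = 1000,
) -> pd.Series:
    """Label each site promoter / exon / intron / intergenic.

    Promoter = TSS − promoter_up … TSS + promoter_down on the gene's
    strand-oriented axis.  When a site overlaps several element types
    (across genes too) the precedence is promoter > exon > intron >
    intergenic.  ``sites`` needs chrom/pos columns or a (chrom, pos)
    MultiIndex.
    """
    prom_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    exon_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    body_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        if g.strand == "+":
            ps, pe = g.tss - promoter_up, g.tss + promoter_down + 1
        else:
            ps, pe = g.tss - promoter_down, g.tss + promoter_up + 1
        if pe > max(0, ps):
            prom_trees[g.chrom].addi(max(0, ps), pe, g.gene_id)
        for (s, e) in g.exons:
            exon_trees[g.chrom].addi(s, e, g.gene_id)
        body_trees[g.chrom].addi(g.start, g.end, g.gene_id)

    if {"chrom", "pos"}.issubset(sites.columns):
        chroms = sites["chrom"].to_numpy()
        positions = sites["pos"].to_numpy()
    else:
        chroms = sites.index.get_level_values(0).to_numpy()
        positions = sites.index.get_level_values(1).to_numpy()
    labels = []
    for chrom, pos in zip(chroms, positions):
        if prom_trees[chrom].overlaps_point(pos):
            labels.append("promoter")
        elif exon_trees[chrom].overlaps_point(pos):
            labels.append("exon")
        elif body_trees[chrom].overlaps_point(pos):
            labels.append("intron")
        else:
            labels.append("intergenic")
    return pd.Series(labels, index=sites.index, name="context")


def summarize_methylome(
    joint: pd.DataFrame, genome_cpg_total: int, condition: str = "WT"
) -> dict:
    """Table-2-style summary of a classified joint CpG table."""
    if genome_cpg_total <= 0:
        raise ValueError("genome_cpg_total must be positive")
    n_common = len(joint)
    out = {
        "n_common_cpgs": n_common,
        "fraction_of_genome_cpgs": n_common / genome_cpg_total,
    }
    for col in [c for c in joint.columns if c.startswith("state_")]:
        cond = col[len("state_"):]
        states = joint[col]
        out[f"n_methylated_{cond}"] = int((states == "methylated").sum())
        out[f"n_unmethylated_{cond}"] = int((states == "unmethylated").sum())
        out[f"n_intermediate_{cond}"] = int((states == "intermediate").sum())
    for col in [c for c in joint.columns if c.startswith("percent_")]:
        cond = col[len("percent_"):]
        out[f"grand_mean_percent_{cond}"] = (
            float(joint[col].mean()) if n_common else float("nan")
        )
    return out
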