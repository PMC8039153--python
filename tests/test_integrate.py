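"""CpG–TE overlap, background comparison, nearest gene, bystander,
metaplot — each against a brute-force or constructed oracle."""

import numpy as np
import pandas as pd
import pytest

from conftest import gene, te
from tequant.integrate import (
    assign_nearest_genes,
    background_methylation_comparison,
    bystander_report,
    bystander_test,
    nearest_gene,
    overlap_cpgs_tes,
    tss_metaplot,
)


def sites_frame(positions, pct_wt=None, chrom="chr1"):
    idx = pd.MultiIndex.from_arrays(
        [[chrom] * len(positions), list(positions)], names=["chrom", "pos"]
    )
    df = pd.DataFrame(index=idx)
    df["percent_WT"] = pct_wt if pct_wt is not None else 50.0
    df["percent_mutant"] = 30.0
    return df


# --- overlap ----------------------------------------------------------------


def test_site_outside_all_loci_unmapped():
    out = overlap_cpgs_tes(sites_frame([500]), [te("chr1", 0, 100)])
    assert out.empty


def test_nested_loci_map_site_to_both():
    loci = [te("chr1", 0, 1000, family="outer"),
            te("chr1", 400, 600, family="inner")]
    out = overlap_cpgs_tes(sites_frame([500]), loci)
    assert sorted(out["family_name"]) == ["inner", "outer"]


def test_overlap_matches_brute_force_pair_scan():
    rng = np.random.default_rng(0)
    for trial in range(100):
        loci = []
        for _ in range(int(rng.integers(1, 50))):
            s = int(rng.integers(0, 5000))
            loci.append(te("chr1", s, s + int(rng.integers(10, 400))))
        positions = sorted(set(rng.integers(0, 5500, size=500).tolist()))
        out = overlap_cpgs_tes(sites_frame(positions), loci)
        expected = sum(
            1
            for pos in positions
            for l in loci
            if l.start <= pos < l.end
        )
        assert len(out) == expected, trial


# --- background comparison --------------------------------------------------


def _uniform_sites(loci, per_locus=5, pct=50.0):
    positions, pcts = [], []
    for l in loci:
        step = max(1, l.length // per_locus)
        for k in range(per_locus):
            p = l.start + k * step
            if p < l.end:
                positions.append(p)
                pcts.append(pct)
    return sites_frame(positions, pcts)


def test_background_all_identical_percents_p_one():
    loci = [te("chr1", i * 100, i * 100 + 50,
               family=("hot" if i < 3 else f"bg{i}")) for i in range(10)]
    sites = _uniform_sites(loci, per_locus=3, pct=75.0)
    out = background_methylation_comparison(["hot"], loci, sites, seed=1)
    n1, n2 = len(out.focal_percents), len(out.background_percents)
    assert out.u_statistic == pytest.approx(n1 * n2 / 2)
    assert out.p_value == 1.0


def test_background_detects_separated_mixtures():
    """Beta(8,2)-like focal vs Beta(2,2)-like background: p < 0.05 in
    ≥95% of seeds."""
    rng = np.random.default_rng(1)
    hits = 0
    n_runs = 100
    for run in range(n_runs):
        loci, positions, pcts = [], [], []
        for i in range(40):
            fam = "hot" if i < 20 else f"bg{i}"
            s = i * 200
            loci.append(te("chr1", s, s + 100, family=fam))
            for j in range(5):
                positions.append(s + j * 10)
                pcts.append(
                    100 * (rng.beta(8, 2) if fam == "hot" else rng.beta(2, 2))
                )
        sites = sites_frame(positions, pcts)
        out = background_methylation_comparison(
            ["hot"], loci, sites, seed=run, exclude_focal=True
        )
        hits += out.p_value < 0.05
    assert hits >= 0.95 * n_runs


def test_background_small_groups_use_exact_enumeration():
    loci = [
        te("chr1", 0, 100, family="hot"),
        te("chr1", 200, 300, family="b1"),
    ]
    positions = [10, 20, 30, 40, 210, 220, 230, 240, 250]
    pcts = [90.0, 85.0, 80.0, 95.0, 20.0, 30.0, 10.0, 25.0, 15.0]
    sites = sites_frame(positions, pcts)
    out = background_methylation_comparison(
        ["hot"], loci, sites, seed=0, exclude_focal=True
    )
    # groups of 4 and 5 values → exact enumeration over C(9,4)=126 splits
    from tequant.stats import mann_whitney_u

    ref = mann_whitney_u(out.focal_percents, out.background_percents)
    assert ref.method == "exact"
    assert out.p_value == ref.p_value
    assert out.p_value == pytest.approx(2 / 126)


def test_background_null_calibration():
    """Focal families drawn from the same pool → ~5% rejections.

    1,000 seeded draws over a fixed null methylome; the rejection rate
    at 0.05 must stay within [0.03, 0.07].
    """
    from conftest import parse_cov
    from tequant.methylome import filter_common_cpgs
    from tequant.simulate import (
        SimConfig, generate_annotation, simulate_methylome,
    )

    cfg = SimConfig(seed=3, upregulated_families={})
    ann = generate_annotation(cfg)
    _, tes = ann
    samples = simulate_methylome(ann, cfg)
    parsed = {s: parse_cov(df) for s, df in samples.items()}
    joint = filter_common_cpgs(parsed, cfg.design, min_coverage=10)
    fams = sorted({t.family_name for t in tes})
    rng = np.random.default_rng(0)
    rejections = 0
    n_runs = 1000
    for i in range(n_runs):
        focal = list(rng.choice(fams, size=3, replace=False))
        out = background_methylation_comparison(
            focal, tes, joint, seed=10_000 + i
        )
        rejections += out.p_value < 0.05
    assert 0.03 <= rejections / n_runs <= 0.07


def test_background_pool_too_small_errors():
    loci = [te("chr1", 0, 100, family="hot"),
            te("chr1", 200, 300, family="hot")]
    with pytest.raises(ValueError, match="pool"):
        background_methylation_comparison(
            ["hot"], loci, sites_frame([10]), exclude_focal=True
        )


def test_focal_families_more_methylated_than_background(
    default_config, annotation, joint_table
):
    """Upregulated LTR families carry high-component methylation: the
    comparison reports a higher focal median and p < 0.05."""
    _, tes = annotation
    up = [f for f, l in default_config.upregulated_families.items() if l > 0]
    out = background_methylation_comparison(
        up, tes, joint_table, seed=0, n_draws=11
    )
    assert out.focal_median > out.background_median
    assert out.p_value < 0.05


# --- nearest gene -----------------------------------------------------------


def test_nearest_gene_overlap_distance_zero():
    g = gene("g1", "chr1", 100, 500)
    out = nearest_gene(te("chr1", 300, 400), [g])
    assert out.gene.gene_id == "g1" and out.distance == 0


def test_nearest_gene_picks_closer_side():
    left = gene("left", "chr1", 0, 100)
    right = gene("right", "chr1", 900, 1000)
    out = nearest_gene(te("chr1", 400, 450), [left, right])
    # 300 bp to left's end, 450 bp to right's start
    assert out.gene.gene_id == "left" and out.distance == 300


def test_single_gene_always_assigned_no_distance_limit():
    g = gene("g1", "chr1", 0, 10)
    out = nearest_gene(te("chr1", 900_000, 900_100), [g])
    assert out.gene.gene_id == "g1"


def test_cross_chromosome_never_nearest():
    g1 = gene("far", "chr1", 500_000, 501_000)
    g2 = gene("other", "chr2", 0, 100)
    out = nearest_gene(te("chr1", 0, 50), [g1, g2])
    assert out.gene.gene_id == "far"
    out2 = nearest_gene(te("chr3", 0, 50), [g1, g2])
    assert out2.gene is None


def test_nearest_gene_matches_brute_force():
    """Brute-force distance minimization on randomized toys."""
    rng = np.random.default_rng(2)
    for trial in range(100):
        genes = []
        for i in range(int(rng.integers(1, 100))):
            s = int(rng.integers(0, 100_000))
            genes.append(gene(f"g{i}", f"chr{rng.integers(1, 3)}", s,
                              s + int(rng.integers(100, 3000))))
        s = int(rng.integers(0, 100_000))
        locus = te(f"chr{rng.integers(1, 3)}", s, s + 200)
        got = nearest_gene(locus, genes)

        best, best_d = None, float("inf")
        for g in genes:
            if g.chrom != locus.chrom:
                continue
            if g.start < locus.end and locus.start < g.end:
                d = 0
            else:
                d = min(abs(g.start - locus.end), abs(locus.start - g.end))
            if d < best_d or (d == best_d and g.start < best.start):
                best, best_d = g, d
        if best is None:
            assert got.gene is None
        else:
            assert got.distance == best_d
            assert got.gene.gene_id == best.gene_id, trial


# --- bystander --------------------------------------------------------------


def _gene_diff(ids, l2fc, padj):
    return pd.DataFrame(
        {"l2fc": l2fc, "padj": padj}, index=pd.Index(ids, name="feature_id")
    )


def test_bystander_all_ns_fraction_zero():
    genes = [gene(f"g{i}", "chr1", i * 2000, i * 2000 + 500)
             for i in range(5)]
    loci = [te("chr1", i * 2000 + 600, i * 2000 + 700, family="fam")
            for i in range(5)]
    assignments = assign_nearest_genes(loci, genes)
    gd = _gene_diff([g.gene_id for g in genes], [0.1] * 5, [0.9] * 5)
    rep = bystander_test("fam", assignments, gd)
    assert rep["fraction_up"] == 0.0


def test_bystander_constructed_upregulated_neighbors():
    genes = [gene(f"g{i}", "chr1", i * 2000, i * 2000 + 500)
             for i in range(20)]
    loci = [te("chr1", i * 2000 + 600, i * 2000 + 700, family="fam")
            for i in range(5)]
    assignments = assign_nearest_genes(loci, genes)
    l2fc = [2.0 if i < 5 else 0.0 for i in range(20)]
    padj = [0.01 if i < 5 else 0.8 for i in range(20)]
    gd = _gene_diff([g.gene_id for g in genes], l2fc, padj)
    rep = bystander_test("fam", assignments, gd)
    assert rep["fraction_up"] == 1.0
    assert rep["mw_p"] < 0.05  # neighbours shifted vs all genes


def test_bystander_deduplicates_flanking_copies():
    g = gene("solo", "chr1", 1000, 2000)
    loci = [te("chr1", 500, 600, family="fam"),
            te("chr1", 2400, 2500, family="fam")]
    assignments = assign_nearest_genes(loci, [g])
    gd = _gene_diff(["solo"], [1.0], [0.01])
    rep = bystander_test("fam", assignments, gd)
    assert rep["n_copies"] == 2 and rep["n_neighbor_genes"] == 1


def test_bystander_unknown_family_errors():
    g = gene("g", "chr1", 0, 100)
    assignments = assign_nearest_genes([te("chr1", 200, 300)], [g])
    with pytest.raises(ValueError):
        bystander_test("absent", assignments, _gene_diff(["g"], [0.0], [1.0]))


def test_bystander_report_correlation():
    genes = [gene(f"g{i}", "chr1", i * 3000, i * 3000 + 500)
             for i in range(6)]
    fams = [f"fam{i}" for i in range(3)]
    loci = [
        te("chr1", i * 3000 + 600, i * 3000 + 700, family=fams[i % 3])
        for i in range(6)
    ]
    assignments = assign_nearest_genes(loci, genes)
    gd = _gene_diff([g.gene_id for g in genes],
                    [0.0, 1.0, 2.0, 0.0, 1.0, 2.0], [0.5] * 6)
    td = pd.DataFrame({"l2fc": [0.0, 1.0, 2.0]},
                      index=pd.Index(fams, name="feature_id"))
    reports, r = bystander_report(fams, assignments, gd, td)
    assert len(reports) == 3
    assert r == pytest.approx(1.0)  # constructed perfect correlation


# --- metaplot ---------------------------------------------------------------


def test_metaplot_uniform_field_is_flat():
    genes = [gene("g1", "chr1", 10_000, 12_000, strand="+"),
             gene("g2", "chr1", 30_000, 32_000, strand="-")]
    positions = list(range(5_000, 40_000, 37))
    sites = sites_frame(positions, [50.0] * len(positions))
    prof = tss_metaplot(genes, sites, window=4000, n_bins=80)
    populated = prof.mean_percent["percent_WT"][prof.bin_counts > 0]
    assert np.allclose(populated, 50.0)


def test_metaplot_step_flips_with_strand():
    """0% upstream / 100% downstream of every TSS must step at bin 0 for
    + and − strand genes alike."""
    plus = gene("p", "chr1", 50_000, 60_000, strand="+")   # TSS 50_000
    minus = gene("m", "chr1", 100_000, 110_000, strand="-")  # TSS 109_999
    positions, pcts = [], []
    for pos in range(46_000, 54_000, 40):
        positions.append(pos)
        pcts.append(0.0 if pos < 50_000 else 100.0)
    for pos in range(106_000, 114_000, 40):
        positions.append(pos)
        pcts.append(0.0 if pos > 109_999 else 100.0)
    sites = sites_frame(positions, pcts)
    prof = tss_metaplot([plus, minus], sites, window=4000, n_bins=80)
    means = prof.mean_percent["percent_WT"]
    half = prof.n_bins // 2
    upstream = means[:half][prof.bin_counts[:half] > 0]
    downstream = means[half:][prof.bin_counts[half:] > 0]
    assert np.allclose(upstream, 0.0)
    assert np.allclose(downstream, 100.0)


def test_metaplot_conserves_incidences(default_config, annotation,
                                       joint_table):
    genes, _ = annotation
    prof = tss_metaplot(genes, joint_table, window=4000, n_bins=80)
    chroms = joint_table.index.get_level_values(0).to_numpy()
    positions = joint_table.index.get_level_values(1).to_numpy()
    expected = 0
    for g in genes:
        mask = chroms == g.chrom
        off = (
            positions[mask] - g.tss if g.strand == "+"
            else g.tss - positions[mask]
        )
        expected += int(((off >= -4000) & (off < 4000)).sum())
    assert prof.bin_counts.sum() == expected


def test_metaplot_empty_gene_set_errors(joint_table):
    with pytest.raises(ValueError):
        tss_metaplot([], joint_table)
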