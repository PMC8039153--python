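"""Synthetic genomes, annotations, read placements and methylomes.

The generator emulates the statistical structure the downstream analyses
assume: a repeat complement dominated by DNA transposons with a minority
of LTR retroelements, negative-binomially distributed per-locus read
counts in which upregulation is concentrated in designated LTR families,
and a bimodal wild-type CpG methylome (most CpGs above 80% or below 20%
methylation) that collapses toward intermediate methylation in the
hypomethylated mutant through multiplicative retention at methylated
CpGs.

All randomness flows from one master seed through named substreams, one
per (generator, sample); adding samples never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .models import GeneModel, TERecord, TE_CLASSES

# substream identifiers (first element of the SeedSequence spawn key)
_STREAM_ANNOTATION = 0
_STREAM_READS = 1
_STREAM_METH = 2
_STREAM_GENES = 3
_STREAM_CPG_LAYOUT = 4

_FAMILY_PREFIX = {
    "DNA": "hAT",
    "LTR": "Gypsy",
    "LINE": "L1",
    "SINE": "DANA",
    "other": "REX",
}


def family_names(te_class: str, n: int) -> list[str]:
    """Deterministic family names for a class (e.g. Gypsy1_DR, Gypsy2_DR)."""
    prefix = _FAMILY_PREFIX[te_class]
    return [f"{prefix}{i + 1}_DR" for i in range(n)]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design downstream stages are tested
    against: two conditions (WT vs mutant) with replicate clutches,
    NB-distributed family expression with designated upregulated LTR
    families, and a bimodal WT methylome whose methylated mode retains
    roughly half its methylation in the mutant.
    """

    genome_length: int = 300_000  # bp per chromosome
    n_chromosomes: int = 2
    n_genes: int = 60
    n_te_loci: int = 400
    class_proportions: dict = field(
        default_factory=lambda: {
            "DNA": 0.55,
            "LTR": 0.20,
            "LINE": 0.15,
            "SINE": 0.05,
            "other": 0.05,
        }
    )
    n_families_per_class: int = 20
    # family → true L2FC in the mutant; negative values give
    # downregulation.  Default mirrors the study structure: strong
    # upregulation concentrated in LTR families, modest downregulation
    # scattered over DNA, LINE and LTR.
    upregulated_families: dict = field(
        default_factory=lambda: {
            "Gypsy1_DR": 2.0,
            "Gypsy2_DR": 2.5,
            "Gypsy3_DR": 3.0,
            "Gypsy4_DR": 1.5,
            "Gypsy5_DR": 2.0,
            "Gypsy6_DR": 2.5,
            "Gypsy7_DR": 1.5,
            "Gypsy8_DR": 2.0,
            "Gypsy9_DR": -1.0,
            "hAT1_DR": -1.0,
            "hAT2_DR": -1.0,
            "hAT3_DR": -1.0,
            "hAT4_DR": -1.0,
            "hAT5_DR": -1.0,
            "hAT6_DR": -1.0,
            "L11_DR": -1.0,
            "L12_DR": -1.0,
            "L13_DR": -1.0,
        }
    )
    nb_mean: float = 50.0
    nb_dispersion: float = 0.05
    n_replicates_per_condition: int = 3
    # (weight_high, (a_high, b_high), (a_low, b_low))
    wt_meth_mixture: tuple = (0.74, (20.0, 1.0), (1.0, 20.0))
    mutant_retention: float = 0.48
    cpg_coverage_mean: float = 20.0
    seed: int = 0

    # layout details not part of the statistical design
    n_cpgs: int = 8000
    gene_length_range: tuple = (2000, 6000)
    te_length_range: tuple = (200, 1500)
    read_length: int = 100
    promoter_cpg_weight: float = 3.0
    promoter_window: int = 1000
    upregulated_high_weight: float = 0.98
    gene_nb_mean: float = 100.0
    gene_up_fraction: float = 0.08
    gene_down_fraction: float = 0.04
    gene_de_l2fc: float = 2.5

    def __post_init__(self) -> None:
        props = self.class_proportions
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if any(not (0.0 <= v <= 1.0) for v in props.values()):
            raise ValueError("class_proportions must lie in [0, 1]")
        if any(c not in TE_CLASSES for c in props):
            raise ValueError(f"classes must be among {TE_CLASSES}")
        for name in (
            "genome_length",
            "n_chromosomes",
            "n_families_per_class",
            "n_replicates_per_condition",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_genes < 0 or self.n_te_loci < 0:
            raise ValueError("feature counts must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (0.0 <= self.mutant_retention <= 1.0):
            raise ValueError("mutant_retention must lie in [0, 1]")
        w, hi, lo = self.wt_meth_mixture
        if not (0.0 <= w <= 1.0):
            raise ValueError("mixture weight must lie in [0, 1]")
        if min(*hi, *lo) <= 0:
            raise ValueError("Beta parameters must be positive")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def sample_ids(self) -> list[str]:
        n = self.n_replicates_per_condition
        return [f"WT_{i + 1}" for i in range(n)] + [
            f"mut_{i + 1}" for i in range(n)
        ]

    @property
    def design(self) -> dict[str, str]:
        return {
            s: ("WT" if s.startswith("WT") else "mutant")
            for s in self.sample_ids
        }

    def to_dict(self) -> dict:
        return asdict(self)


class CapacityError(ValueError):
    """Raised when requested features cannot fit in the genome."""


def _rng(config: SimConfig, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(stream, index))
    )


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(config: SimConfig):
    """Generate non-overlapping gene models and TE loci.

    Genes are laid out without overlap on each chromosome; TE loci fall
    uniformly in intergenic and intronic space (never across an exon)
    and may overlap one another, as nested repeats do.  Each locus
    carries a family, a class and an integer Smith–Waterman score.
    Deterministic given ``config.seed``.
    """
    rng = _rng(config, _STREAM_ANNOTATION)
    genes = _place_genes(config, rng)
    tes = _place_tes(config, genes, rng)
    return genes, tes


def _place_genes(config: SimConfig, rng) -> list[GeneModel]:
    genes: list[GeneModel] = []
    if config.n_genes == 0:
        return genes
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    gidx = 0
    lo, hi = config.gene_length_range
    for chrom, n_c in zip(config.chrom_names, per_chrom):
        if n_c == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=n_c)
        slack = config.genome_length - int(lengths.sum()) - n_c
        if slack < 0:
            raise CapacityError(
                f"{n_c} genes of total length {lengths.sum()} do not fit on "
                f"{chrom} ({config.genome_length} bp)"
            )
        gaps = np.sort(rng.integers(0, slack + 1, size=n_c))
        gaps = np.diff(np.concatenate([[0], gaps]))
        pos = 0
        for length, gap in zip(lengths, gaps):
            start = pos + int(gap) + 1
            end = start + int(length)
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _make_exons(start, end, rng)
            genes.append(
                GeneModel(
                    gene_id=f"gene{gidx + 1:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=exons,
                )
            )
            gidx += 1
            pos = end
    return genes


def _make_exons(start: int, end: int, rng) -> tuple:
    """2–4 exons per gene; first and last segments are exonic."""
    length = end - start
    k = int(rng.integers(2, 5))
    n_cuts = 2 * k - 2
    if length <= n_cuts + 1:
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_cuts, replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    return tuple(
        (start + int(bounds[i]), start + int(bounds[i + 1]))
        for i in range(0, len(bounds) - 1, 2)
    )


def _allowed_regions(config: SimConfig, genes: list[GeneModel]):
    """Intergenic + intronic space: the exon complement per chromosome."""
    regions = []
    exons_by_chrom: dict[str, list] = {c: [] for c in config.chrom_names}
    for g in genes:
        exons_by_chrom[g.chrom].extend(g.exons)
    for chrom in config.chrom_names:
        pos = 0
        for (s, e) in sorted(exons_by_chrom[chrom]):
            if s > pos:
                regions.append((chrom, pos, s))
            pos = max(pos, e)
        if pos < config.genome_length:
            regions.append((chrom, pos, config.genome_length))
    return regions


def _place_tes(config: SimConfig, genes, rng) -> list[TERecord]:
    if config.n_te_loci == 0:
        return []
    regions = _allowed_regions(config, genes)
    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])
    fam_by_class = {
        c: family_names(c, config.n_families_per_class) for c in classes
    }
    lo, hi = config.te_length_range
    records = []
    class_counter = {c: 0 for c in classes}
    for i in range(config.n_te_loci):
        te_class = classes[int(rng.choice(len(classes), p=probs))]
        # cycle families within a class so every family gets copies
        fams = fam_by_class[te_class]
        family = fams[class_counter[te_class] % len(fams)]
        class_counter[te_class] += 1
        length = int(rng.integers(lo, hi + 1))
        fits = [r for r in regions if r[2] - r[1] >= length]
        if not fits:
            raise CapacityError(
                f"no intergenic/intronic region can hold a {length} bp TE "
                f"(locus {i + 1}/{config.n_te_loci})"
            )
        weights = np.array([r[2] - r[1] - length + 1 for r in fits], dtype=float)
        chrom, rs, re_ = fits[int(rng.choice(len(fits), p=weights / weights.sum()))]
        start = int(rng.integers(rs, re_ - length + 1))
        records.append(
            TERecord(
                chrom=chrom,
                start=start,
                end=start + length,
                strand="+" if rng.random() < 0.5 else "-",
                family_name=family,
                te_class=te_class,
                sw_score=int(rng.integers(300, 12000)),
            )
        )
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


# ---------------------------------------------------------------------------
# read placements


def _nb_draw(rng, mean: float, dispersion: float, size=None):
    """NB draw parametrised by mean and dispersion (var = m + a·m²)."""
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def simulate_read_placements(annotation, config: SimConfig) -> dict:
    """Per-sample read intervals over the TE loci.

    Each locus yields NB(nb_mean, nb_dispersion) reads per sample; in
    mutant samples, loci of designated upregulated families have their
    mean scaled by 2**(true L2FC).  Reads are fixed-length intervals
    placed uniformly inside their source locus.  Returns a dict mapping
    sample id to a BED6-like DataFrame.
    """
    _, tes = annotation
    out = {}
    for idx, sample in enumerate(config.sample_ids):
        rng = _rng(config, _STREAM_READS, idx)
        is_mut = config.design[sample] == "mutant"
        rows = []
        for locus_idx, locus in enumerate(tes):
            mean = config.nb_mean
            if is_mut and locus.family_name in config.upregulated_families:
                mean *= 2.0 ** config.upregulated_families[locus.family_name]
            count = int(_nb_draw(rng, mean, config.nb_dispersion))
            if count == 0:
                continue
            rlen = min(config.read_length, locus.length)
            starts = rng.integers(locus.start, locus.end - rlen + 1, size=count)
            # name records the source locus: exact provenance for testing
            for j, s in enumerate(starts):
                rows.append(
                    (locus.chrom, int(s), int(s) + rlen,
                     f"{sample}:L{locus_idx}:{j}", 0, "+")
                )
        out[sample] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        )
    return out


def simulate_gene_counts(annotation, config: SimConfig):
    """Gene-level NB count table with a sprinkling of true DEGs.

    Gene base means are log-normal around ``gene_nb_mean``; a fixed
    fraction of genes is assigned a true up- or down-shift of
    ``gene_de_l2fc`` in the mutant.  Returns (CountTable, true_l2fc
    Series).
    """
    from .models import CountTable

    genes, _ = annotation
    layout_rng = _rng(config, _STREAM_GENES, 2**20)
    n = len(genes)
    base = config.gene_nb_mean * np.exp(layout_rng.normal(0.0, 1.0, size=n))
    true_l2fc = np.zeros(n)
    n_up = int(round(config.gene_up_fraction * n))
    n_down = int(round(config.gene_down_fraction * n))
    de_idx = layout_rng.choice(n, size=n_up + n_down, replace=False)
    true_l2fc[de_idx[:n_up]] = config.gene_de_l2fc
    true_l2fc[de_idx[n_up:]] = -config.gene_de_l2fc

    cols = {}
    for idx, sample in enumerate(config.sample_ids):
        rng = _rng(config, _STREAM_GENES, idx)
        mean = base * (
            2.0**true_l2fc if config.design[sample] == "mutant" else 1.0
        )
        cols[sample] = _nb_draw(rng, mean, config.nb_dispersion)
    gene_ids = [g.gene_id for g in genes]
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="feature_id"))
    return (
        CountTable(counts, config.design),
        pd.Series(true_l2fc, index=gene_ids, name="true_l2fc"),
    )


# ---------------------------------------------------------------------------
# methylome


def _cpg_positions(config: SimConfig, genes, rng) -> pd.DataFrame:
    """CpG positions, denser (by promoter_cpg_weight) near promoters."""
    w = config.promoter_window
    promoters = []
    for g in genes:
        promoters.append(
            (g.chrom, max(0, g.tss - w), min(config.genome_length, g.tss + w))
        )
    prom_len = sum(e - s for _, s, e in promoters)
    total = config.n_chromosomes * config.genome_length
    prom_mass = config.promoter_cpg_weight * prom_len
    bg_mass = float(total)
    chroms, positions = [], []
    for _ in range(config.n_cpgs):
        if promoters and rng.random() < prom_mass / (prom_mass + bg_mass):
            c, s, e = promoters[int(rng.integers(len(promoters)))]
            chroms.append(c)
            positions.append(int(rng.integers(s, e)))
        else:
            chroms.append(config.chrom_names[int(rng.integers(config.n_chromosomes))])
            positions.append(int(rng.integers(config.genome_length)))
    df = pd.DataFrame({"chrom": chroms, "pos": positions})
    df = df.drop_duplicates().sort_values(["chrom", "pos"]).reset_index(drop=True)
    return df


def simulate_methylome(annotation, config: SimConfig) -> dict:
    """Per-sample Bismark-coverage-style CpG calls.

    WT per-CpG methylation comes from a two-component Beta mixture
    (high/low); CpGs inside loci of upregulated families draw the high
    component with elevated probability, so derepressed families sit in
    normally-methylated sequence.  Mutant methylation multiplies the WT
    value by ``mutant_retention`` at high-component CpGs and leaves
    low-component CpGs unchanged.  Read counts are binomial at
    zero-truncated Poisson coverage.
    """
    genes, tes = annotation
    layout_rng = _rng(config, _STREAM_CPG_LAYOUT)
    cpgs = _cpg_positions(config, genes, layout_rng)
    n = len(cpgs)

    in_focal = np.zeros(n, dtype=bool)
    up_fams = {f for f, l2fc in config.upregulated_families.items() if l2fc > 0}
    focal = [t for t in tes if t.family_name in up_fams]
    for t in focal:
        mask = (
            (cpgs["chrom"] == t.chrom)
            & (cpgs["pos"] >= t.start)
            & (cpgs["pos"] < t.end)
        )
        in_focal |= mask.to_numpy()

    w_high, (a_hi, b_hi), (a_lo, b_lo) = config.wt_meth_mixture
    p_high = np.where(in_focal, config.upregulated_high_weight, w_high)
    is_high = layout_rng.random(n) < p_high
    wt = np.where(
        is_high,
        layout_rng.beta(a_hi, b_hi, size=n),
        layout_rng.beta(a_lo, b_lo, size=n),
    )
    mut = np.where(is_high, wt * config.mutant_retention, wt)

    out = {}
    for idx, sample in enumerate(config.sample_ids):
        rng = _rng(config, _STREAM_METH, idx)
        truth = mut if config.design[sample] == "mutant" else wt
        cov = rng.poisson(config.cpg_coverage_mean, size=n)
        while (cov == 0).any():  # zero-truncated Poisson
            zeros = cov == 0
            cov[zeros] = rng.poisson(config.cpg_coverage_mean, size=int(zeros.sum()))
        meth = rng.binomial(cov, truth)
        pct = 100.0 * meth / cov
        out[sample] = pd.DataFrame(
            {
                "chrom": cpgs["chrom"],
                "start": cpgs["pos"] + 1,  # Bismark coverage: 1-based
                "end": cpgs["pos"] + 1,
                "percent": np.round(pct, 6),
                "count_methylated": meth,
                "count_unmethylated": cov - meth,
            }
        )
    return out


# ---------------------------------------------------------------------------
# writers (RepeatMasker-style TSV, BED, Bismark coverage)


def write_repeatmasker_tsv(records, path) -> None:
    """RepeatMasker-style TSV with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tstrand\trepeat_name\tclass_family\tsw_score\n")
        for r in records:
            cls = f"{r.te_class}/{r.family_name.split('_')[0]}"
            fh.write(
                f"{r.chrom}\t{r.start + 1}\t{r.end}\t{r.strand}\t"
                f"{r.family_name}\t{cls}\t{r.sw_score}\n"
            )


def write_genes_bed(genes, path) -> None:
    """BED12-like gene models (0-based half-open, exon block structure)."""
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )


def write_reads_bed(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", header=False, index=False)


def write_bismark_cov(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", header=False, index=False)
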