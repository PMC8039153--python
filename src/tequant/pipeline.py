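"""End-to-end orchestration: simulate/load → count → DE → methylome →
integrate, with a single config, structured logging and table-shaped
outputs (class × direction with chi-square, methylome summary, gene DEG
counts, background comparison, bystander report, TSS metaplot).

Every output file is stamped with the config hash and master seed;
rerunning with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, integrate, methylome, simulate, te_quant
from .models import CountTable
from .simulate import SimConfig

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """One document driving the whole pipeline.

    Exactly one of ``sim`` (synthetic-data block) or ``inputs`` (paths
    to annotation/reads/coverage files) must be set.
    """

    sim: SimConfig | None = None
    inputs: dict | None = None  # te_table, genes_bed?, reads{sample:path},
    #                             coverage{sample:path}, design{sample:cond}
    min_coverage: int = 10
    meth_low: float = 20.0
    meth_high: float = 80.0
    padj_cutoff: float = 0.05
    gene_l2fc_cutoff: float = 1.5
    te_l2fc_cutoff: float = 0.0
    promoter_window: int = 1000
    metaplot_window: int = 4000
    metaplot_bins: int = 80
    seed: int = 0
    outdir: str = "tequant_out"

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ConfigError("exactly one of sim / inputs must be given")
        if not (0 < self.padj_cutoff < 1):
            raise ConfigError("padj_cutoff must lie in (0, 1)")
        if not (0 <= self.meth_low < self.meth_high <= 100):
            raise ConfigError("need 0 ≤ meth_low < meth_high ≤ 100")
        if self.min_coverage < 0:
            raise ConfigError("min_coverage must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim_block = doc.pop("sim", None)
        sim = SimConfig(**sim_block) if sim_block is not None else None
        try:
            return cls(sim=sim, **doc)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        def _default(o):
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)

        d = self.to_dict()
        d.pop("outdir", None)  # output location is not part of run identity
        blob = json.dumps(d, sort_keys=True, default=_default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stamp(path: Path, config: PipelineConfig) -> None:
    text = path.read_text()
    path.write_text(
        f"# config_hash={config.hash()} seed={config.seed}\n{text}"
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; return the run report (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": {},
    }

    # --- stage: inputs -----------------------------------------------------
    stage = "synthetic_data" if config.sim else "load_inputs"
    try:
        if config.sim is not None:
            sim = config.sim
            annotation = simulate.generate_annotation(sim)
            genes, tes = annotation
            reads = simulate.simulate_read_placements(annotation, sim)
            meth_samples = simulate.simulate_methylome(annotation, sim)
            gene_counts, _ = simulate.simulate_gene_counts(annotation, sim)
            design = sim.design
            simulate.write_repeatmasker_tsv(tes, outdir / "te_annotation.tsv")
            simulate.write_genes_bed(genes, outdir / "genes.bed")
        else:
            inp = config.inputs
            tes = te_quant.read_repeatmasker(inp["te_table"])
            genes = read_genes_bed(inp["genes_bed"]) if inp.get("genes_bed") else []
            design = dict(inp["design"])
            reads = {
                s: te_quant.read_bed_reads(p)
                for s, p in inp.get("reads", {}).items()
            }
            meth_samples = {
                s: methylome.read_cpg_calls(p)
                for s, p in inp.get("coverage", {}).items()
            }
            gene_counts = None
            if inp.get("gene_counts"):
                gene_counts = CountTable.from_tsv(
                    inp["gene_counts"], inp["gene_design"]
                )
        report["stages"][stage] = {
            "n_genes": len(genes),
            "n_te_loci": len(tes),
            "n_read_samples": len(reads),
            "n_methylome_samples": len(meth_samples),
        }
        logger.info("stage %s: %s", stage, report["stages"][stage])
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # --- stage: te_quant ---------------------------------------------------
    try:
        locus_counts = te_quant.count_reads(reads, tes, design)
        fam_counts = te_quant.aggregate_families(locus_counts, tes)
        fam_counts.to_tsv(
            outdir / "family_counts.tsv", outdir / "design.tsv"
        )
        _stamp(outdir / "family_counts.tsv", config)
        n_reads = int(sum(len(df) for df in reads.values()))
        n_counted = int(locus_counts.counts.to_numpy().sum())
        report["stages"]["te_quant"] = {
            "n_reads": n_reads,
            "n_counted": n_counted,
            "n_families": len(fam_counts.feature_ids),
        }
        logger.info("stage te_quant: %s", report["stages"]["te_quant"])
    except Exception as exc:
        raise RuntimeError(f"stage te_quant failed: {exc}") from exc

    # --- stage: diffexpr ---------------------------------------------------
    try:
        class_of = te_quant.family_classes(tes)
        te_res = diffexpr.nb_wald_test(
            fam_counts,
            l2fc_threshold=config.te_l2fc_cutoff,
            condition_order=("WT", "mutant"),
            alpha=config.padj_cutoff,
        )
        te_res["te_class"] = [class_of.get(f, "other") for f in te_res.index]
        te_res.to_csv(outdir / "te_diffexpr.tsv", sep="\t")
        _stamp(outdir / "te_diffexpr.tsv", config)
        table1 = diffexpr.classify_te_direction(te_res, class_of)
        chi2, dof, chi2_p = (float("nan"), 0, float("nan"))
        if (table1.to_numpy().sum(axis=1) > 0).sum() >= 2:
            chi2, dof, chi2_p = diffexpr.class_composition_test(table1)
        table1.to_csv(outdir / "table1_class_direction.tsv", sep="\t")
        _stamp(outdir / "table1_class_direction.tsv", config)

        gene_res = None
        table3 = {}
        if gene_counts is not None:
            gene_res = diffexpr.nb_wald_test(
                gene_counts,
                l2fc_threshold=config.gene_l2fc_cutoff,
                condition_order=("WT", "mutant"),
                alpha=config.padj_cutoff,
            )
            gene_res.to_csv(outdir / "gene_diffexpr.tsv", sep="\t")
            _stamp(outdir / "gene_diffexpr.tsv", config)
            sig = gene_res["padj"] < config.padj_cutoff
            table3 = {
                "total_genes": int(len(gene_res)),
                "significant": int(sig.sum()),
                "significant_up": int(
                    (sig & (gene_res["l2fc"] > config.gene_l2fc_cutoff)).sum()
                ),
                "significant_down": int(
                    (sig & (gene_res["l2fc"] < -config.gene_l2fc_cutoff)).sum()
                ),
            }
            pd.Series(table3).to_csv(
                outdir / "table3_gene_degs.tsv", sep="\t", header=False
            )
            _stamp(outdir / "table3_gene_degs.tsv", config)
        report["stages"]["diffexpr"] = {
            "n_te_families_tested": int(len(te_res)),
            "chi2": chi2,
            "chi2_df": dof,
            "chi2_p": chi2_p,
            **table3,
        }
        logger.info("stage diffexpr: %s", report["stages"]["diffexpr"])
    except Exception as exc:
        raise RuntimeError(f"stage diffexpr failed: {exc}") from exc

    # --- stage: methylome --------------------------------------------------
    joint = None
    try:
        if meth_samples:
            meth_design = {s: design[s] for s in meth_samples}
            if config.sim is not None:
                parsed = {
                    s: pd.DataFrame(
                        {
                            "chrom": df["chrom"],
                            "pos": df["start"] - 1,
                            "methylated": df["count_methylated"],
                            "total": df["count_methylated"]
                            + df["count_unmethylated"],
                            "percent": df["percent"],
                        }
                    )
                    for s, df in meth_samples.items()
                }
            else:
                parsed = meth_samples
            joint = methylome.filter_common_cpgs(
                parsed, meth_design, min_coverage=config.min_coverage
            )
            joint = methylome.classify_methylation(
                joint, low=config.meth_low, high=config.meth_high
            )
            joint["context"] = methylome.annotate_genomic_context(
                joint, genes,
                promoter_up=config.promoter_window,
                promoter_down=config.promoter_window,
            )
            genome_total = (
                config.sim.n_cpgs if config.sim else max(len(joint), 1)
            )
            summary = methylome.summarize_methylome(joint, genome_total)
            joint.to_csv(outdir / "joint_cpg_table.tsv", sep="\t")
            _stamp(outdir / "joint_cpg_table.tsv", config)
            pd.Series(summary).to_csv(
                outdir / "table2_methylome_summary.tsv", sep="\t", header=False
            )
            _stamp(outdir / "table2_methylome_summary.tsv", config)
            report["stages"]["methylome"] = {
                "n_cpgs_retained": int(len(joint)),
                **{k: v for k, v in summary.items() if isinstance(v, int)},
            }
            logger.info("stage methylome: %s", report["stages"]["methylome"])
    except Exception as exc:
        raise RuntimeError(f"stage methylome failed: {exc}") from exc

    # --- stage: integrate --------------------------------------------------
    try:
        if joint is not None and len(joint):
            up_fams = [
                f for f in te_res.index if te_res.loc[f, "direction"] == "up"
            ]
            if config.sim is not None and not up_fams:
                up_fams = sorted(config.sim.upregulated_families)
            integ: dict = {}
            if up_fams:
                bc = integrate.background_methylation_comparison(
                    up_fams, tes, joint, seed=config.seed
                )
                integ.update(
                    n_focal_regions=bc.n_focal_regions,
                    focal_median=bc.focal_median,
                    background_median=bc.background_median,
                    mw_p=bc.p_value,
                )
                pd.DataFrame(
                    {
                        "group": ["focal"] * len(bc.focal_percents)
                        + ["background"] * len(bc.background_percents),
                        "percent": np.concatenate(
                            [bc.focal_percents, bc.background_percents]
                        ),
                    }
                ).to_csv(outdir / "background_comparison.tsv", sep="\t",
                         index=False)
                _stamp(outdir / "background_comparison.tsv", config)
            if genes and up_fams:
                assignments = integrate.assign_nearest_genes(
                    [t for t in tes if t.family_name in set(up_fams)], genes
                )
                if gene_res is not None:
                    reports, r = integrate.bystander_report(
                        sorted({a.te_locus.family_name for a in assignments}),
                        assignments, gene_res, te_res,
                        alpha=config.padj_cutoff,
                    )
                    pd.DataFrame(
                        [
                            {k: v for k, v in rep.items()
                             if k != "neighbor_genes"}
                            for rep in reports
                        ]
                    ).to_csv(outdir / "bystander_report.tsv", sep="\t",
                             index=False)
                    _stamp(outdir / "bystander_report.tsv", config)
                    integ["bystander_family_neighbor_r"] = r
            if genes:
                profile = integrate.tss_metaplot(
                    genes, joint,
                    window=config.metaplot_window,
                    n_bins=config.metaplot_bins,
                    percent_cols=tuple(
                        c for c in joint.columns if c.startswith("percent_")
                    ),
                )
                meta = pd.DataFrame({"bin_center": profile.bin_centers})
                for c, v in profile.mean_percent.items():
                    meta[f"mean_{c[len('percent_'):]}"] = v
                meta["n_cpgs"] = profile.bin_counts
                meta.to_csv(outdir / "tss_metaplot.tsv", sep="\t", index=False)
                _stamp(outdir / "tss_metaplot.tsv", config)
            report["stages"]["integrate"] = integ
            logger.info("stage integrate: %s", integ)
    except Exception as exc:
        raise RuntimeError(f"stage integrate failed: {exc}") from exc

    (outdir / "run_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str)
    )
    return report


def read_genes_bed(path) -> list:
    """Read BED12-like gene models written by the simulator."""
    from .models import GeneModel

    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, _, strand = f[:6]
            start, end = int(start), int(end)
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offs = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple(
                    (start + o, start + o + s) for o, s in zip(offs, sizes)
                )
            else:
                exons = ((start, end),)
            genes.append(
                GeneModel(
                    gene_id=name, chrom=chrom, start=start, end=end,
                    strand=strand, exons=exons,
                )
            )
    return genes
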