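import pandas as pd
import pytest

from tequant.models import GeneModel, TERecord
from tequant.simulate import (
    SimConfig,
    generate_annotation,
    simulate_methylome,
    simulate_read_placements,
)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def annotation(default_config):
    return generate_annotation(default_config)


@pytest.fixture(scope="session")
def read_sets(default_config, annotation):
    return simulate_read_placements(annotation, default_config)


@pytest.fixture(scope="session")
def methylome_samples(default_config, annotation):
    return simulate_methylome(annotation, default_config)


def parse_cov(df: pd.DataFrame) -> pd.DataFrame:
    """Bismark-coverage frame (as produced by the simulator) → internal."""
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"] - 1,
            "methylated": df["count_methylated"],
            "total": df["count_methylated"] + df["count_unmethylated"],
            "percent": df["percent"],
        }
    )


@pytest.fixture(scope="session")
def joint_table(default_config, methylome_samples):
    from tequant.methylome import classify_methylation, filter_common_cpgs

    parsed = {s: parse_cov(df) for s, df in methylome_samples.items()}
    joint = filter_common_cpgs(parsed, default_config.design, min_coverage=10)
    return classify_methylation(joint)


def te(chrom, start, end, family="famA", te_class="DNA", strand="+", sw=1000):
    return TERecord(chrom=chrom, start=start, end=end, strand=strand,
                    family_name=family, te_class=te_class, sw_score=sw)


def gene(gene_id, chrom, start, end, strand="+", exons=None):
    return GeneModel(gene_id=gene_id, chrom=chrom, start=start, end=end,
                     strand=strand,
                     exons=tuple(exons) if exons else ((start, end),))
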