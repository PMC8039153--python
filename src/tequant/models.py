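"""Core domain containers shared across the pipeline stages.

Coordinates are 0-based half-open everywhere inside the package; file
readers convert from 1-based inclusive dialects at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TE_CLASSES = ("DNA", "LTR", "LINE", "SINE", "other")


@dataclass(frozen=True)
class TERecord:
    """One annotated repeat locus: the unit of counting and overlap."""

    chrom: str
    start: int
    end: int
    strand: str
    family_name: str
    te_class: str
    sw_score: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Gene interval with strand-aware TSS and exon structure.

    ``tss`` equals ``start`` on the plus strand and ``end - 1`` on the
    minus strand.  Exons are sorted, non-overlapping and lie inside the
    gene body; everything in the body that is not exon is intron.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene interval {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = self.start
        for (s, e) in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise ValueError(
                    f"gene {self.gene_id}: exon ({s},{e}) outside body or "
                    "overlapping/unsorted"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


class CountTable:
    """Integer feature × sample matrix with a sample→condition design.

    Thin wrapper around a pandas DataFrame (features as index, samples as
    columns) plus a mapping of sample id to condition label.
    """

    def __init__(self, counts: pd.DataFrame, design: dict[str, str]):
        if counts.shape[1] != len(design):
            raise ValueError("design must name every sample column")
        missing = [s for s in counts.columns if s not in design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        arr = counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.integer)):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            counts = counts.round().astype(np.int64)
        if arr.size and (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.design = dict(design)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            c = self.design[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.design[s] == condition]

    def subset_samples(self, sample_ids: list[str]) -> "CountTable":
        return CountTable(
            self.counts[sample_ids], {s: self.design[s] for s in sample_ids}
        )

    def to_tsv(self, path, design_path=None) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature_id")
        if design_path is not None:
            pd.Series(self.design, name="condition").rename_axis(
                "sample_id"
            ).to_csv(design_path, sep="\t")

    @classmethod
    def from_tsv(cls, path, design_path) -> "CountTable":
        counts = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        design = (
            pd.read_csv(design_path, sep="\t", index_col=0, comment="#")
            .iloc[:, 0]
            .to_dict()
        )
        return cls(counts, design)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CountTable({len(self.feature_ids)} features × "
            f"{len(self.sample_ids)} samples, "
            f"conditions={self.conditions})"
        )
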