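"""TE annotation parsing, union-mode read counting and family rollup.

Counting follows HTSeq union semantics on unstranded features, with one
family-aware twist: a read overlapping several loci of the *same*
family is still counted (for the family's earliest-starting overlapped
locus), because quantification is by family; only reads touching two or
more different families are discarded as ambiguous.  Each read is
counted at most once.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import CountTable, TERecord, TE_CLASSES

logger = logging.getLogger(__name__)

_DROP_CLASSES = ("Simple_repeat", "Low_complexity")


def _map_class(class_family: str) -> str:
    """Map a RepeatMasker class/family string onto the 5-class vocabulary."""
    head = class_family.split("/")[0].strip()
    if head in ("DNA", "LTR", "LINE", "SINE"):
        return head
    return "other"


def read_repeatmasker(path) -> list[TERecord]:
    """Read a RepeatMasker-style TSV into TERecords.

    Expects tab-separated columns chrom, start, end, strand, repeat
    name, class/family, SW score with 1-based inclusive coordinates
    (converted to 0-based half-open).  Simple repeats and
    low-complexity records are dropped; classes outside
    {DNA, LTR, LINE, SINE} map to "other" with a warning.
    """
    records: list[TERecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ValueError(
                    f"{path}: malformed line {lineno}: expected 7 columns, "
                    f"got {len(parts)}"
                )
            chrom, start, end, strand, name, class_family, sw = parts[:7]
            try:
                start_i, end_i, sw_i = int(start), int(end), int(sw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed line {lineno}: {exc}"
                ) from None
            head = class_family.split("/")[0].strip()
            if head in _DROP_CLASSES:
                continue
            te_class = _map_class(class_family)
            if te_class == "other" and head not in TE_CLASSES:
                logger.warning(
                    "%s line %d: class %r mapped to 'other'",
                    path, lineno, class_family,
                )
            if strand not in ("+", "-"):
                strand = "unknown"
            records.append(
                TERecord(
                    chrom=chrom,
                    start=start_i - 1,  # 1-based inclusive → half-open
                    end=end_i,
                    strand=strand,
                    family_name=name,
                    te_class=te_class,
                    sw_score=sw_i,
                )
            )
    return records


def read_bed_reads(path) -> pd.DataFrame:
    """Read a BED6 (or BED3) file of read placements (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=[0, 1, 2],
    )
    return df


def _locus_id(locus: TERecord, index: int) -> str:
    return f"{locus.chrom}:{locus.start}-{locus.end}|{locus.family_name}|{index}"


def locus_ids(loci: list[TERecord]) -> list[str]:
    return [_locus_id(loc, i) for i, loc in enumerate(loci)]


def count_reads(
    reads_by_sample: dict, loci: list[TERecord], design: dict | None = None
) -> CountTable:
    """Union-mode counting of read intervals against TE loci.

    ``reads_by_sample`` maps sample id to a DataFrame with chrom/start/
    end columns.  A read overlapping exactly one family increments one
    locus (earliest start, then chromosome name, among same-family
    overlaps); a read touching two or more families counts nowhere.
    Strand is ignored.  Reads on chromosomes absent from the annotation
    are skipped and tallied in the log.
    """
    ids = locus_ids(loci)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, loc in enumerate(loci):
        trees[loc.chrom].addi(loc.start, loc.end, i)
    known_chroms = set(trees)

    columns = {}
    design = design or {s: s for s in reads_by_sample}
    for sample, reads in reads_by_sample.items():
        counts = np.zeros(len(loci), dtype=np.int64)
        skipped = 0
        chrom_arr = reads["chrom"].to_numpy()
        start_arr = reads["start"].to_numpy()
        end_arr = reads["end"].to_numpy()
        for chrom, start, end in zip(chrom_arr, start_arr, end_arr):
            if chrom not in known_chroms:
                skipped += 1
                continue
            hits = trees[chrom].overlap(start, end)
            if not hits:
                continue
            members = [iv.data for iv in hits]
            families = {loci[i].family_name for i in members}
            if len(families) > 1:
                continue  # ambiguous across families: counted nowhere
            target = min(members, key=lambda i: (loci[i].start, loci[i].chrom))
            counts[target] += 1
        if skipped:
            logger.warning(
                "sample %s: skipped %d reads on unknown chromosomes",
                sample, skipped,
            )
        columns[sample] = counts
    table = pd.DataFrame(columns, index=pd.Index(ids, name="feature_id"))
    return CountTable(table, design)


def aggregate_families(
    locus_counts: CountTable, loci: list[TERecord]
) -> CountTable:
    """Sum member locus counts to family level (lexicographic order)."""
    id_to_family = dict(zip(locus_ids(loci), (l.family_name for l in loci)))
    orphans = [f for f in locus_counts.feature_ids if f not in id_to_family]
    if orphans:
        raise KeyError(
            f"feature ids not resolvable to TE records: {orphans[:5]}"
        )
    fam = locus_counts.counts.groupby(
        [id_to_family[f] for f in locus_counts.feature_ids]
    ).sum()
    fam = fam.sort_index()
    fam.index.name = "feature_id"
    return CountTable(fam, locus_counts.design)


def family_classes(loci: list[TERecord]) -> dict[str, str]:
    """Family → class mapping from an annotation."""
    out: dict[str, str] = {}
    for loc in loci:
        prev = out.setdefault(loc.family_name, loc.te_class)
        if prev != loc.te_class:
            raise ValueError(
                f"family {loc.family_name} maps to classes {prev} and "
                f"{loc.te_class}"
            )
    return out


def enumerate_family_copies(family_name: str, loci: list[TERecord]):
    """All genomic copies of a family in genome order, plus the count."""
    members = [l for l in loci if l.family_name == family_name]
    if not members:
        counts = Counter(l.family_name for l in loci)
        near = [
            f for f in counts
            if f.lower().startswith(family_name[:3].lower())
        ]
        raise KeyError(
            f"family {family_name!r} not in annotation; nearest matches: "
            f"{sorted(near)[:5]}"
        )
    members.sort(key=lambda l: (l.chrom, l.start, l.end))
    return members, len(members)
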