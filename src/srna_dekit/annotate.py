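"""Annotation-class assignment of aligned reads from a GFF3 file.

A read is assigned class C when at least one of its genomic hits is fully
contained within a feature of type C.  Containment is strand-agnostic by
default because sRNAs arising from either strand of a locus (e.g. siRNAs
from double-stranded precursors) are of interest; strand-aware matching is
switchable.  Reads with no hit, or with hits but no containing feature, are
classified ``unannotated``.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
from intervaltree import IntervalTree

from .core import AlignmentSet, AnnotationClassification

__all__ = ["annotate_reads"]


def annotate_reads(
    alignments: AlignmentSet,
    gff: str | Path,
    wanted_types: set[str],
    strand_aware: bool = False,
) -> AnnotationClassification:
    """Classify each sequence by the feature types its hits fall inside.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention on load.
    """
    if not wanted_types:
        raise ValueError("wanted_types must be non-empty")
    db = gffutils.create_db(
        str(gff), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    trees: dict[str, IntervalTree] = {}
    for ft in sorted(wanted_types):
        for feat in db.features_of_type(ft):
            # GFF3 1-based inclusive [start, end] -> 0-based half-open
            trees.setdefault(feat.seqid, IntervalTree()).addi(
                feat.start - 1, feat.end, (ft, feat.strand)
            )

    classes: dict[str, set[str]] = {}
    for seq, hit_list in alignments.hits.items():
        labels: set[str] = set()
        for chrom, start, strand in hit_list:
            tree = trees.get(chrom)
            if tree is None:
                continue
            end = start + len(seq)
            for iv in tree.overlap(start, end):
                ftype, fstrand = iv.data
                if iv.begin <= start and iv.end >= end:
                    if strand_aware and fstrand in "+-" and fstrand != strand:
                        continue
                    labels.add(ftype)
        classes[seq] = labels or {AnnotationClassification.UNANNOTATED}
    return AnnotationClassification(classes)
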