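"""File I/O: FASTA read libraries, genomes, SAM/BED alignments, TSV writers.

Two FASTA dialects are accepted for reads: ``plain`` (one record per read,
identical sequences collapsed by summing) and ``count_suffix`` (already
collapsed, abundance encoded as the integer after the last ``-`` or ``_`` in
the header — the common collapsed-FASTA convention, e.g. ``>seq1-534``).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pysam
from Bio import SeqIO

from .core import (
    MAX_READ_LENGTH,
    MIN_READ_LENGTH,
    AlignmentSet,
    ExpressionMatrix,
    ReadLibrary,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta_counts",
    "write_fasta_counts",
    "read_genome_fasta",
    "load_alignments",
    "write_library_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

_COUNT_RE = re.compile(r"[-_](\d+)$")


class FastaParseError(ValueError):
    pass


def _clean_sequence(raw: str) -> str:
    """Uppercase and U->T; reject characters outside A/C/G/T/U/N."""
    seq = raw.upper().replace("U", "T")
    if not set(seq) <= set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise FastaParseError(f"invalid characters {bad} in sequence {raw!r}")
    return seq


def read_fasta_counts(
    path: str | Path,
    dialect: str = "plain",
    replicate_id: str | None = None,
    min_length: int = MIN_READ_LENGTH,
    max_length: int = MAX_READ_LENGTH,
) -> ReadLibrary:
    """Read adapter-trimmed sRNA reads from FASTA into a collapsed library.

    Identical sequences are collapsed with summed counts; U is normalized to
    T; sequences outside the accepted length window are dropped with a logged
    tally.  Reads containing N are dropped as unalignable.
    """
    path = Path(path)
    if dialect not in ("plain", "count_suffix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rid = replicate_id if replicate_id is not None else path.stem
    counts: dict[str, int] = {}
    dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(str(rec.seq))
        if dialect == "count_suffix":
            m = _COUNT_RE.search(rec.id)
            if not m:
                raise FastaParseError(
                    f"header {rec.id!r} has no trailing count (expected e.g. 'name-123')"
                )
            count = int(m.group(1))
        else:
            count = 1
        if count < 1:
            raise FastaParseError(f"header {rec.id!r} carries non-positive count {count}")
        if not (min_length <= len(seq) <= max_length) or "N" in seq:
            dropped += count
            continue
        counts[seq] = counts.get(seq, 0) + count
    if dropped:
        logger.info("%s: dropped %d reads outside %d-%d nt", path.name, dropped, min_length, max_length)
    return ReadLibrary(rid, counts, dropped_by_length=dropped)


def write_fasta_counts(library: ReadLibrary, path: str | Path) -> None:
    """Write a library in count_suffix dialect, sequences sorted lexicographically."""
    with open(path, "w") as fh:
        for i, seq in enumerate(sorted(library.counts)):
            fh.write(f">{library.replicate_id}_s{i}-{library.counts[seq]}\n{seq}\n")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Load a reference genome as chrom -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _load_sam(path: Path, library: ReadLibrary) -> tuple[dict, dict, int]:
    hits: dict[str, list[tuple[str, int, str]]] = {}
    lengths: dict[str, int] = {}
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        if sam.header.get("SQ"):
            lengths = {sq["SN"]: sq["LN"] for sq in sam.header["SQ"]}
        for rec in sam:
            if rec.is_unmapped:
                continue
            seq = rec.query_sequence
            if seq is None:
                skipped += 1
                continue
            seq = seq.upper().replace("U", "T")
            if rec.is_reverse:
                seq = _revcomp(seq)
            if seq not in library.counts:
                logger.warning("SAM record %s: sequence not in library, skipped", rec.query_name)
                continue
            # ungapped full-length records only: single M/= cigar op spanning the read
            cig = rec.cigartuples or []
            if len(cig) != 1 or cig[0][0] not in (0, 7) or cig[0][1] != len(seq):
                skipped += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            hits.setdefault(seq, []).append((rec.reference_name, rec.reference_start, strand))
    return hits, lengths, skipped


def _load_bed(path: Path, library: ReadLibrary) -> tuple[dict, int]:
    """BED records; the read sequence is encoded in the name field (column 4)."""
    hits: dict[str, list[tuple[str, int, str]]] = {}
    skipped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{ln}: BED record needs >= 4 columns (name = sequence)")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            seq = f[3].upper().replace("U", "T")
            strand = f[5] if len(f) >= 6 else "+"
            if seq not in library.counts:
                logger.warning("BED line %d: sequence not in library, skipped", ln)
                continue
            if end - start != len(seq):
                skipped += 1
                continue
            hits.setdefault(seq, []).append((chrom, start, strand))
    return hits, skipped


def load_alignments(path: str | Path, library: ReadLibrary) -> AlignmentSet:
    """Load precomputed alignments from SAM or BED.

    SAM POS (1-based) is converted to the internal 0-based convention by
    pysam; BED starts are used as-is.  Gapped, clipped or length-mismatched
    records are skipped with a tally; records whose sequence is not in the
    library are skipped with a warning.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        hits, skipped = _load_bed(path, library)
        lengths = {}
    else:
        hits, lengths, skipped = _load_sam(path, library)
    if skipped:
        logger.info("%s: skipped %d gapped/clipped/length-mismatched records", path.name, skipped)
    for seq in library.counts:
        hits.setdefault(seq, [])
    return AlignmentSet(hits, lengths)


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def write_library_tsv(library: ReadLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"sequence\t{library.replicate_id}\n")
        for seq in sorted(library.counts):
            fh.write(f"{seq}\t{library.counts[seq]}\n")


def write_matrix_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Sequence column then one column per replicate; rows sorted lexicographically."""
    df = matrix.values.sort_index()
    df.to_csv(path, sep="\t", index_label="sequence", float_format="%.6g")


def read_matrix_tsv(path: str | Path, hierarchy) -> ExpressionMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col="sequence")
    df.index = df.index.astype(str)
    return ExpressionMatrix(df, hierarchy)
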