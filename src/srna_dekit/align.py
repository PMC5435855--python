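"""Exact full-length short-read matching against a reference genome.

sRNA reads are short (15-35 nt) so exact, ungapped, full-length matching on
both strands is appropriate; all occurrences are reported.  The matcher
hashes the library's sequences (and their reverse complements) by length and
slides over each chromosome once per distinct read length, which is linear
in genome size and independent of library depth.
"""

from __future__ import annotations

from pathlib import Path

from .core import AlignmentSet, ReadLibrary
from .io import read_genome_fasta

__all__ = ["align_reads_exact", "reverse_complement"]

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def align_reads_exact(
    library: ReadLibrary, genome: dict[str, str] | str | Path
) -> AlignmentSet:
    """Find every exact full-length occurrence of each read on either strand.

    A '-' strand hit at (chrom, start) means the reverse complement of the
    read equals ``genome[chrom][start:start+len(read)]``.  Reads absent from
    the genome get an empty hit list.
    """
    if not isinstance(genome, dict):
        genome = read_genome_fasta(genome)
    hits: dict[str, list[tuple[str, int, str]]] = {s: [] for s in library.counts}
    by_len_fwd: dict[int, set[str]] = {}
    by_len_rc: dict[int, dict[str, str]] = {}
    for seq in library.counts:
        L = len(seq)
        by_len_fwd.setdefault(L, set()).add(seq)
        # genome substring == revcomp(read)  <=>  read matches '-' strand
        by_len_rc.setdefault(L, {})[reverse_complement(seq)] = seq

    for chrom, gseq in genome.items():
        g = gseq.upper()
        n = len(g)
        for L in by_len_fwd:
            if L > n:
                continue
            fwd = by_len_fwd[L]
            rc = by_len_rc[L]
            get_rc = rc.get
            for i in range(n - L + 1):
                sub = g[i : i + L]
                if sub in fwd:
                    hits[sub].append((chrom, i, "+"))
                r = get_rc(sub)
                if r is not None:
                    hits[r].append((chrom, i, "-"))
    return AlignmentSet(hits, {c: len(s) for c, s in genome.items()})
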