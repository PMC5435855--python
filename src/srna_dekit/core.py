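"""Core data model for collapsed small-RNA read libraries and expression matrices.

Small RNA (sRNA) sequencing yields millions of short (typically 18-30 nt)
reads; identical sequences are collapsed to a single entry with an abundance
count.  Throughout the package a *redundant* count means the total number of
reads including duplicates, while the *non-redundant* count is the number of
distinct sequences.  Internal genomic coordinates are 0-based half-open
everywhere; conversions happen only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReadLibrary",
    "SampleHierarchy",
    "ExpressionMatrix",
    "AlignmentSet",
    "AnnotationClassification",
    "ConfigurationError",
    "build_expression_matrix",
    "filter_matrix",
    "MIN_READ_LENGTH",
    "MAX_READ_LENGTH",
]

#: Read-length window applied at ingestion; brackets all sRNA size classes
#: of interest (18-30 nt, peak 21-24 nt) with margin.
MIN_READ_LENGTH = 15
MAX_READ_LENGTH = 35

_VALID_BASES = frozenset("ACGT")


class ConfigurationError(ValueError):
    """Raised when user-supplied configuration is inconsistent."""


@dataclass
class ReadLibrary:
    """One replicate's collapsed reads: sequence -> abundance count.

    Parameters
    ----------
    replicate_id
        Identifier of the replicate this library belongs to.
    counts
        Mapping from nucleotide sequence (A/C/G/T, length 15-35 after
        ingestion) to a strictly positive integer abundance.
    dropped_by_length
        Tally of reads discarded at ingestion because their length fell
        outside the accepted window.
    """

    replicate_id: str
    counts: dict[str, int] = field(default_factory=dict)
    dropped_by_length: int = 0

    def __post_init__(self) -> None:
        for seq, c in self.counts.items():
            if c < 1:
                raise ValueError(f"count for {seq!r} must be >= 1, got {c}")

    @property
    def redundant_total(self) -> int:
        """Total read count including duplicates."""
        return sum(self.counts.values())

    @property
    def nonredundant_total(self) -> int:
        """Number of distinct sequences."""
        return len(self.counts)

    def lengths(self) -> set[int]:
        return {len(s) for s in self.counts}

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class SampleHierarchy:
    """Ordered treatments, each with >= 1 replicate.

    The treatment order is experimental order (e.g. time points) and is used
    for consecutive-pair comparisons in the differential-expression call.
    """

    treatments: list[tuple[str, list[str]]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        if not self.treatments:
            raise ConfigurationError("hierarchy must contain at least one treatment")
        for tid, reps in self.treatments:
            if not reps:
                raise ConfigurationError(f"treatment {tid!r} has no replicates")
            for r in reps:
                if r in seen:
                    raise ConfigurationError(f"replicate id {r!r} is not unique")
                seen.add(r)

    @property
    def treatment_ids(self) -> list[str]:
        return [tid for tid, _ in self.treatments]

    @property
    def replicate_ids(self) -> list[str]:
        return [r for _, reps in self.treatments for r in reps]

    def replicates_of(self, treatment_id: str) -> list[str]:
        for tid, reps in self.treatments:
            if tid == treatment_id:
                return list(reps)
        raise KeyError(treatment_id)

    def treatment_of(self, replicate_id: str) -> str:
        for tid, reps in self.treatments:
            if replicate_id in reps:
                return tid
        raise KeyError(replicate_id)

    def replicate_pairs(self) -> list[tuple[str, str, str]]:
        """All within-treatment replicate pairs as (treatment, repA, repB)."""
        out = []
        for tid, reps in self.treatments:
            for i in range(len(reps)):
                for j in range(i + 1, len(reps)):
                    out.append((tid, reps[i], reps[j]))
        return out

    def to_dict(self) -> dict:
        return {"treatments": [{"id": t, "replicates": list(r)} for t, r in self.treatments]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SampleHierarchy":
        return cls([(t["id"], list(t["replicates"])) for t in d["treatments"]])


@dataclass
class ExpressionMatrix:
    """Unique sequences x replicates abundance table, raw or normalized.

    ``values`` is a pandas DataFrame indexed by sequence with one column per
    replicate, columns ordered as in the hierarchy.  Raw matrices hold
    integers, normalized ones reals; a sequence absent from a replicate has
    value exactly 0.
    """

    values: pd.DataFrame
    hierarchy: SampleHierarchy
    normalized_by: str = ""

    def __post_init__(self) -> None:
        hier_reps = self.hierarchy.replicate_ids
        if set(self.values.columns) != set(hier_reps):
            raise ConfigurationError(
                "matrix columns do not match hierarchy replicates: "
                f"columns={sorted(self.values.columns)} hierarchy={sorted(hier_reps)}"
            )
        self.values = self.values[hier_reps]
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def sequences(self) -> list[str]:
        return list(self.values.index)

    @property
    def replicate_ids(self) -> list[str]:
        return list(self.values.columns)

    def column_sums(self) -> pd.Series:
        return self.values.sum(axis=0)

    def with_values(self, new: pd.DataFrame, normalized_by: str) -> "ExpressionMatrix":
        return ExpressionMatrix(new, self.hierarchy, normalized_by)

    def library(self, replicate_id: str) -> ReadLibrary:
        """Extract one column as a ReadLibrary (nonzero entries only)."""
        col = self.values[replicate_id]
        col = col[col > 0]
        return ReadLibrary(replicate_id, {s: int(round(v)) for s, v in col.items()})


@dataclass
class AlignmentSet:
    """Per-sequence genomic hits.

    ``hits`` maps each sequence to a list of (chrom, start, strand) with
    0-based leftmost start; a hit on '-' means the reverse complement of the
    sequence matches the genome at that location.  Unmatched reads have an
    empty list.
    """

    hits: dict[str, list[tuple[str, int, str]]]
    genome_lengths: dict[str, int] = field(default_factory=dict)

    def n_hits(self, seq: str) -> int:
        return len(self.hits.get(seq, []))

    def matched_sequences(self) -> set[str]:
        return {s for s, h in self.hits.items() if h}


@dataclass
class AnnotationClassification:
    """Mapping from sequence to the set of annotation class labels it hits.

    Reads with no genomic hit, or whose hits fall in no annotated feature,
    carry exactly ``{"unannotated"}``.
    """

    classes: dict[str, set[str]]

    UNANNOTATED = "unannotated"

    def sequences_in_class(self, label: str) -> set[str]:
        return {s for s, cl in self.classes.items() if label in cl}


def build_expression_matrix(
    libraries: Sequence[ReadLibrary], hierarchy: SampleHierarchy
) -> ExpressionMatrix:
    """Assemble replicate libraries into a sequences x replicates matrix.

    The row set is the union of sequences over all libraries; entries missing
    from a library are exactly 0.  Column order follows the hierarchy; rows
    are sorted lexicographically for reproducible output.
    """
    lib_ids = [lib.replicate_id for lib in libraries]
    hier_ids = hierarchy.replicate_ids
    missing = set(hier_ids) - set(lib_ids)
    extra = set(lib_ids) - set(hier_ids)
    if missing or extra:
        raise ConfigurationError(
            f"libraries do not match hierarchy: missing={sorted(missing)} extra={sorted(extra)}"
        )
    all_seqs = sorted(set().union(*[set(lib.counts) for lib in libraries])) if libraries else []
    data = np.zeros((len(all_seqs), len(hier_ids)), dtype=np.int64)
    idx = {s: i for i, s in enumerate(all_seqs)}
    by_id = {lib.replicate_id: lib for lib in libraries}
    for j, rid in enumerate(hier_ids):
        for seq, c in by_id[rid].counts.items():
            data[idx[seq], j] = c
    df = pd.DataFrame(data, index=pd.Index(all_seqs, name="sequence"), columns=hier_ids)
    return ExpressionMatrix(df, hierarchy)


def filter_matrix(
    matrix: ExpressionMatrix,
    drop_replicates: Iterable[str] = (),
    size_range: tuple[int, int] | None = None,
) -> ExpressionMatrix:
    """Remove problematic replicates and/or size classes.

    Dropping all replicates of a treatment removes the treatment from the
    hierarchy.  ``size_range`` is an inclusive length interval; rows whose
    sequence length falls outside it are removed.  Remaining values are
    unchanged.
    """
    drop = set(drop_replicates)
    unknown = drop - set(matrix.replicate_ids)
    if unknown:
        raise ConfigurationError(f"unknown replicates to drop: {sorted(unknown)}")
    if size_range is not None and size_range[0] > size_range[1]:
        raise ConfigurationError(f"empty size range {size_range}")

    new_treatments = []
    for tid, reps in matrix.hierarchy.treatments:
        kept = [r for r in reps if r not in drop]
        if kept:
            new_treatments.append((tid, kept))
    if not new_treatments:
        raise ConfigurationError("dropping these replicates would empty the hierarchy")
    hierarchy = SampleHierarchy(new_treatments)
    values = matrix.values[hierarchy.replicate_ids]
    if size_range is not None:
        lo, hi = size_range
        keep = [s for s in values.index if lo <= len(s) <= hi]
        values = values.loc[keep]
    return ExpressionMatrix(values.copy(), hierarchy, matrix.normalized_by)
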