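"""Quality-check statistics and replicate-comparability diagnostics.

The checks characterize each library (size-class distributions, complexity,
positional nucleotide composition, genome-match percentages) and quantify
agreement between replicates (top-N Jaccard index, MA / Bland-Altman values,
per-size-class fold-change distributions, abundance-window summaries).  They
run identically on raw and normalized matrices, and can be restricted to one
annotation class.

Complexity of a size class is the ratio of unique (non-redundant) to total
(redundant) reads — values near 1 indicate a diverse set of low-abundance
sequences, low values a few dominant ones.  Replicates agree well when the
per-size fold-change distributions are tight and symmetric about 0 on the
log2 scale; the ``centering score`` (max over size classes of |median log2
fold change|) summarizes that in a single number.

Quartiles everywhere use linear interpolation (the common "type 7" rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import AlignmentSet, AnnotationClassification, ConfigurationError, ExpressionMatrix, ReadLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "size_class_distribution",
    "complexity_per_size",
    "jaccard_top_n",
    "ma_values",
    "fold_change_distribution_per_size",
    "centering_score",
    "genome_match_percent",
    "positional_composition",
    "abundance_window_summary",
    "qc_report",
    "QCReport",
]


def size_class_distribution(library: ReadLibrary, mode: str = "redundant") -> dict[int, int]:
    """Read counts per size class (nt).

    ``redundant`` counts every read copy; ``nonredundant`` counts distinct
    sequences.  The per-size counts partition the library.
    """
    if mode not in ("redundant", "nonredundant"):
        raise ValueError(f"unknown mode {mode!r}")
    out: dict[int, int] = {}
    for seq, c in library.counts.items():
        out[len(seq)] = out.get(len(seq), 0) + (c if mode == "redundant" else 1)
    return dict(sorted(out.items()))


def complexity_per_size(library: ReadLibrary) -> dict[int, float]:
    """Unique/total read ratio per size class; in (0, 1], 1 iff all counts are 1."""
    red = size_class_distribution(library, "redundant")
    nonred = size_class_distribution(library, "nonredundant")
    return {size: nonred[size] / red[size] for size in red if red[size] > 0}


def _top_n(library: ReadLibrary, n: int) -> set[str]:
    # ties at the n-th abundance broken lexicographically for determinism
    ranked = sorted(library.counts, key=lambda s: (-library.counts[s], s))
    return set(ranked[:n])


def jaccard_top_n(libA: ReadLibrary, libB: ReadLibrary, n: int = 500) -> float:
    """Jaccard index of the n most abundant sequence sets of two libraries."""
    if n <= 0:
        raise ConfigurationError(f"top-n must be positive, got {n}")
    for lib in (libA, libB):
        if lib.nonredundant_total < n:
            logger.info(
                "library %s has %d < %d unique sequences; using all",
                lib.replicate_id, lib.nonredundant_total, n,
            )
    a, b = _top_n(libA, n), _top_n(libB, n)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def ma_values(repA: np.ndarray, repB: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """MA (Bland-Altman) coordinates between two aligned abundance vectors.

    Per sequence with both abundances > 0: A = (a+b)/2, M = log2(b/a).
    Pairs containing a zero are excluded (no pseudo-count is added: a
    diagnostic should not fabricate fold changes) and tallied.

    Returns (A, M, n_excluded).
    """
    a = np.asarray(repA, dtype=float)
    b = np.asarray(repB, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    both = (a > 0) & (b > 0)
    excluded = int(((a > 0) | (b > 0)).sum() - both.sum())
    A = (a[both] + b[both]) / 2.0
    M = np.log2(b[both] / a[both])
    return A, M, excluded


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation (type 7)
    return float(q1), float(med), float(q3)


def fold_change_distribution_per_size(
    repA: ReadLibrary | Mapping[str, float], repB: ReadLibrary | Mapping[str, float]
) -> dict[int, tuple[float, float, float]]:
    """(Q1, median, Q3) of log2 fold changes between two replicates per size class.

    Only sequences nonzero in both replicates contribute; size classes with
    fewer than two shared sequences are omitted.
    """
    ca = repA.counts if isinstance(repA, ReadLibrary) else repA
    cb = repB.counts if isinstance(repB, ReadLibrary) else repB
    by_size: dict[int, list[float]] = {}
    for seq, va in ca.items():
        vb = cb.get(seq, 0)
        if va > 0 and vb > 0:
            by_size.setdefault(len(seq), []).append(np.log2(vb / va))
    return {
        size: _quartiles(np.array(ms))
        for size, ms in sorted(by_size.items())
        if len(ms) >= 2
    }


def centering_score(per_size_quartiles: Mapping[int, tuple[float, float, float]]) -> float:
    """Max over size classes of |median log2 fold change|; 0 = perfectly centered."""
    if not per_size_quartiles:
        return float("nan")
    return max(abs(q[1]) for q in per_size_quartiles.values())


def genome_match_percent(
    library: ReadLibrary, alignments: AlignmentSet, mode: str = "redundant"
) -> tuple[float, dict[int, float]]:
    """Percentage of reads with >= 1 genomic hit, overall and per size class.

    Redundant mode weights by abundance; nonredundant counts each distinct
    sequence once.
    """
    if mode not in ("redundant", "nonredundant"):
        raise ValueError(f"unknown mode {mode!r}")
    tot: dict[int, float] = {}
    hit: dict[int, float] = {}
    for seq, c in library.counts.items():
        w = c if mode == "redundant" else 1
        L = len(seq)
        tot[L] = tot.get(L, 0) + w
        if alignments.n_hits(seq) > 0:
            hit[L] = hit.get(L, 0) + w
    per_size = {L: 100.0 * hit.get(L, 0) / tot[L] for L in sorted(tot)}
    total = sum(tot.values())
    overall = 100.0 * sum(hit.values()) / total if total else 0.0
    return overall, per_size


def positional_composition(library: ReadLibrary) -> pd.DataFrame:
    """Count-weighted base frequency at each read position (1-based rows).

    Row r gives the frequency of A/C/G/T at position r among all reads of
    length >= r; rows sum to 1 where data exist.
    """
    if not library.counts:
        return pd.DataFrame(columns=list("ACGT"))
    max_len = max(len(s) for s in library.counts)
    counts = np.zeros((max_len, 4))
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for seq, c in library.counts.items():
        for i, b in enumerate(seq):
            counts[i, base_idx[b]] += c
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
    return pd.DataFrame(freqs, index=pd.RangeIndex(1, max_len + 1, name="position"),
                        columns=list("ACGT"))


def abundance_window_summary(matrix: ExpressionMatrix, window_width: float) -> pd.DataFrame:
    """Quartile summaries of nonzero abundances per abundance window per replicate.

    sRNA abundance distributions are dominated by low-abundance reads, so a
    single boxplot per sample is uninformative; bucketing abundances into
    ranges [k*w, (k+1)*w) lets replicate distributions be compared within
    each range.  Returns a tidy frame (replicate, window_lo, window_hi, n,
    q1, median, q3).
    """
    if window_width <= 0:
        raise ConfigurationError("window_width must be > 0")
    rows = []
    for rid in matrix.replicate_ids:
        col = matrix.values[rid].to_numpy(dtype=float)
        nz = col[col > 0]
        if nz.size == 0:
            continue
        buckets = np.floor(nz / window_width).astype(int)
        for k in np.unique(buckets):
            vals = nz[buckets == k]
            q1, med, q3 = _quartiles(vals)
            rows.append((rid, k * window_width, (k + 1) * window_width,
                         int(vals.size), q1, med, q3))
    return pd.DataFrame(rows, columns=["replicate", "window_lo", "window_hi",
                                       "n", "q1", "median", "q3"])


@dataclass
class QCReport:
    """Full quality-check report for one expression matrix."""

    size_class: pd.DataFrame           # replicate, size, redundant, nonredundant, complexity
    composition: pd.DataFrame          # replicate, position, A, C, G, T
    genome_match: pd.DataFrame | None  # replicate, mode, size ('all' = overall), percent
    jaccard: pd.DataFrame              # treatment, repA, repB, n, jaccard
    ma_points: pd.DataFrame            # treatment, repA, repB, A, M
    fold_change: pd.DataFrame          # treatment, repA, repB, size, q1, median, q3
    abundance_windows: pd.DataFrame
    centering_scores: dict[str, float] = field(default_factory=dict)
    annotation_class: str | None = None

    def summary(self) -> dict:
        return {
            "annotation_class": self.annotation_class,
            "centering_scores": self.centering_scores,
            "n_replicates": int(self.size_class["replicate"].nunique()) if len(self.size_class) else 0,
        }

    def write(self, out_dir) -> None:
        from pathlib import Path
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.size_class.to_csv(out / "size_class.tsv", sep="\t", index=False, float_format="%.6g")
        self.composition.to_csv(out / "composition.tsv", sep="\t", index=False, float_format="%.6g")
        if self.genome_match is not None:
            self.genome_match.to_csv(out / "genome_match.tsv", sep="\t", index=False, float_format="%.6g")
        self.jaccard.to_csv(out / "jaccard.tsv", sep="\t", index=False, float_format="%.6g")
        self.ma_points.to_csv(out / "ma_points.tsv", sep="\t", index=False, float_format="%.6g")
        self.fold_change.to_csv(out / "fold_change.tsv", sep="\t", index=False, float_format="%.6g")
        self.abundance_windows.to_csv(out / "abundance_windows.tsv", sep="\t", index=False, float_format="%.6g")
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


def qc_report(
    matrix: ExpressionMatrix,
    alignments: AlignmentSet | None = None,
    classification: AnnotationClassification | None = None,
    annotation_class: str | None = None,
    top_n: int = 500,
    abundance_window: float = 100.0,
) -> QCReport:
    """Assemble the full QC report, optionally restricted to one annotation class."""
    if annotation_class is not None:
        if classification is None:
            raise ConfigurationError("annotation_class requires a classification")
        keep = classification.sequences_in_class(annotation_class)
        seqs = [s for s in matrix.sequences if s in keep]
        matrix = ExpressionMatrix(matrix.values.loc[seqs].copy(), matrix.hierarchy,
                                  matrix.normalized_by)

    libs = {rid: matrix.library(rid) for rid in matrix.replicate_ids}

    sc_rows = []
    comp_rows = []
    gm_rows = []
    for rid, lib in libs.items():
        red = size_class_distribution(lib, "redundant")
        nonred = size_class_distribution(lib, "nonredundant")
        cx = complexity_per_size(lib)
        for size in sorted(red):
            sc_rows.append((rid, size, red[size], nonred.get(size, 0), cx.get(size, np.nan)))
        comp = positional_composition(lib)
        for pos, row in comp.iterrows():
            comp_rows.append((rid, pos, row["A"], row["C"], row["G"], row["T"]))
        if alignments is not None:
            for mode in ("redundant", "nonredundant"):
                overall, per_size = genome_match_percent(lib, alignments, mode)
                gm_rows.append((rid, mode, "all", overall))
                gm_rows.extend((rid, mode, str(s), p) for s, p in per_size.items())

    jac_rows = []
    ma_rows = []
    fc_rows = []
    scores: dict[str, float] = {}
    for tid, ra, rb in matrix.hierarchy.replicate_pairs():
        jac_rows.append((tid, ra, rb, top_n, jaccard_top_n(libs[ra], libs[rb], top_n)))
        A, M, _ = ma_values(matrix.values[ra].to_numpy(), matrix.values[rb].to_numpy())
        ma_rows.extend((tid, ra, rb, a, m) for a, m in zip(A, M))
        fc = fold_change_distribution_per_size(libs[ra], libs[rb])
        fc_rows.extend((tid, ra, rb, s, *q) for s, q in fc.items())
        scores[f"{tid}:{ra}|{rb}"] = centering_score(fc)

    return QCReport(
        size_class=pd.DataFrame(sc_rows, columns=["replicate", "size", "redundant",
                                                  "nonredundant", "complexity"]),
        composition=pd.DataFrame(comp_rows, columns=["replicate", "position", "A", "C", "G", "T"]),
        genome_match=pd.DataFrame(gm_rows, columns=["replicate", "mode", "size", "percent"])
        if alignments is not None else None,
        jaccard=pd.DataFrame(jac_rows, columns=["treatment", "repA", "repB", "n", "jaccard"]),
        ma_points=pd.DataFrame(ma_rows, columns=["treatment", "repA", "repB", "A", "M"]),
        fold_change=pd.DataFrame(fc_rows, columns=["treatment", "repA", "repB", "size",
                                                   "q1", "median", "q3"]),
        abundance_windows=abundance_window_summary(matrix, abundance_window),
        centering_scores=scores,
        annotation_class=annotation_class,
    )
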