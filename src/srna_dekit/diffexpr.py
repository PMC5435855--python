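"""Confidence-interval differential-expression calling with U/D/S patterns.

For each sequence and each treatment a confidence interval (CI) over the
replicate expression levels is built: the min-max interval when only two
replicates are available, otherwise a distribution-free Chebyshev interval
mean +/- k*sd (coverage >= 1 - 1/k**2).  Each comparison of an observed
against a reference treatment yields a directional descriptor: S when the
CIs overlap, U when the observed CI lies entirely above the reference, D
when entirely below.  The amplitude of a U/D call is the log2 offset fold
change (LOFC) on the proximate extremes — the closest ends of the two CIs —
with the dataset noise offset added to both terms so that low-abundance
variation cannot produce large fold changes:

    LOFC = log2((observed_proximal + offset) / (reference_proximal + offset))

U/D calls whose |LOFC| falls below the threshold (default 1, roughly the
smallest change detectable by Northern blot or qPCR) are demoted to S.
Concatenating the descriptors over ordered comparisons gives each sequence a
pattern string (e.g. "US"), used to cluster sequences with a shared
expression trajectory.  In lieu of a p-value, ranking is by the largest
|LOFC| among U/D comparisons only, so the top of the list is not populated
by large but insignificant fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConfigurationError, ExpressionMatrix

__all__ = [
    "ConfidenceInterval",
    "confidence_interval",
    "compare_intervals",
    "lofc",
    "call_descriptor",
    "call_de",
    "cluster_patterns",
]


@dataclass(frozen=True)
class ConfidenceInterval:
    lo: float
    hi: float
    method: str  # "chebyshev" or "minmax"

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"invalid interval [{self.lo}, {self.hi}]")

    @property
    def midpoint(self) -> float:
        return (self.lo + self.hi) / 2.0


def confidence_interval(values, k: float = 2.0) -> ConfidenceInterval:
    """Replicate CI: min-max for 2 replicates, Chebyshev mean +/- k*sd for >= 3.

    The Chebyshev interval is floored at 0 since abundances cannot be
    negative; sd is the sample standard deviation.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ConfigurationError("confidence interval needs >= 2 replicate values")
    if (v < 0).any():
        raise ValueError("abundances must be non-negative")
    if v.size == 2:
        return ConfidenceInterval(float(v.min()), float(v.max()), "minmax")
    mean, sd = float(v.mean()), float(v.std(ddof=1))
    return ConfidenceInterval(max(0.0, mean - k * sd), mean + k * sd, "chebyshev")


def compare_intervals(reference: ConfidenceInterval, observed: ConfidenceInterval) -> str:
    """Directional descriptor before the amplitude filter.

    Closed-interval semantics: touching endpoints overlap, hence S.  Exactly
    one of U/D/S holds for any pair.
    """
    if observed.lo > reference.hi:
        return "U"
    if observed.hi < reference.lo:
        return "D"
    return "S"


def lofc(observed_proximal: float, reference_proximal: float, offset: float) -> float:
    """log2 offset fold change of two proximal CI ends."""
    if offset <= 0:
        raise ValueError("offset must be > 0")
    return float(np.log2((observed_proximal + offset) / (reference_proximal + offset)))


def call_descriptor(
    reference: ConfidenceInterval,
    observed: ConfidenceInterval,
    offset: float,
    threshold: float = 1.0,
) -> tuple[str, float]:
    """(descriptor, LOFC) for one comparison.

    U/D requires disjoint CIs *and* |LOFC| on the proximate extremes at or
    above the threshold; otherwise the call is demoted to S.  For S calls
    the reported LOFC is informational only (computed on interval midpoints)
    and never participates in calling or ranking.
    """
    d = compare_intervals(reference, observed)
    if d == "U":
        v = lofc(observed.lo, reference.hi, offset)
    elif d == "D":
        v = lofc(observed.hi, reference.lo, offset)
    else:
        return "S", lofc(observed.midpoint, reference.midpoint, offset)
    if abs(v) < threshold:
        return "S", v
    return d, v


def _treatment_cis(
    matrix: ExpressionMatrix, ci_method: str, k: float
) -> dict[str, list[ConfidenceInterval]]:
    """Per-treatment CI for every sequence, in hierarchy order."""
    out: dict[str, list[ConfidenceInterval]] = {}
    for tid, reps in matrix.hierarchy.treatments:
        if len(reps) < 2:
            raise ConfigurationError(
                f"treatment {tid!r} has {len(reps)} replicate(s); CIs need >= 2"
            )
        vals = matrix.values[reps].to_numpy(dtype=float)
        cis = []
        for row in vals:
            if ci_method == "minmax" or (ci_method == "auto" and row.size == 2):
                cis.append(ConfidenceInterval(float(row.min()), float(row.max()), "minmax"))
            elif ci_method in ("auto", "chebyshev"):
                mean, sd = float(row.mean()), float(row.std(ddof=1))
                cis.append(
                    ConfidenceInterval(max(0.0, mean - k * sd), mean + k * sd, "chebyshev")
                )
            else:
                raise ConfigurationError(f"unknown CI method {ci_method!r}")
        out[tid] = cis
    return out


def call_de(
    matrix: ExpressionMatrix,
    offset: float,
    threshold: float = 1.0,
    scheme: str = "consecutive",
    reference: str | None = None,
    ci_method: str = "auto",
    k: float = 2.0,
) -> pd.DataFrame:
    """Differential-expression call table over all sequences.

    ``scheme='consecutive'`` compares each treatment to its predecessor in
    hierarchy order (suited to time series); ``scheme='vs_reference'``
    compares every other treatment to the named reference.  Returns one row
    per sequence with per-treatment CI bounds, per-comparison descriptor and
    LOFC, the concatenated pattern, a DE flag (any U/D), and the ranking key
    ``max_abs_lofc`` (max |LOFC| over U/D comparisons only); rows are sorted
    by it, descending.
    """
    treatments = matrix.hierarchy.treatment_ids
    if len(treatments) < 2:
        raise ConfigurationError("differential expression needs >= 2 treatments")
    if scheme == "consecutive":
        comparisons = list(zip(treatments[:-1], treatments[1:]))
    elif scheme == "vs_reference":
        if reference is None or reference not in treatments:
            raise ConfigurationError(f"unknown reference treatment {reference!r}")
        comparisons = [(reference, t) for t in treatments if t != reference]
    else:
        raise ConfigurationError(f"unknown comparison scheme {scheme!r}")

    cis = _treatment_cis(matrix, ci_method, k)
    rows = []
    for i, seq in enumerate(matrix.sequences):
        row: dict = {"sequence": seq}
        for tid in treatments:
            ci = cis[tid][i]
            row[f"{tid}_lo"] = ci.lo
            row[f"{tid}_hi"] = ci.hi
        pattern = []
        ranked = []
        for ref_t, obs_t in comparisons:
            d, v = call_descriptor(cis[ref_t][i], cis[obs_t][i], offset, threshold)
            row[f"{ref_t}_vs_{obs_t}_descriptor"] = d
            row[f"{ref_t}_vs_{obs_t}_lofc"] = v
            pattern.append(d)
            if d in "UD":
                ranked.append(abs(v))
        row["pattern"] = "".join(pattern)
        row["de_flag"] = bool(ranked)
        row["max_abs_lofc"] = max(ranked) if ranked else 0.0
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["max_abs_lofc", "sequence"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def cluster_patterns(
    calls: pd.DataFrame, min_size: int = 15, drop_all_s: bool = True
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Group sequences by exact pattern string.

    Returns (full, headline): ``full`` partitions every sequence by pattern;
    ``headline`` suppresses groups with <= min_size members and, when
    ``drop_all_s``, the all-S pattern (the vast majority of sequences are
    not differentially expressed between any treatments).
    """
    full: dict[str, list[str]] = {}
    for seq, pat in zip(calls["sequence"], calls["pattern"]):
        full.setdefault(pat, []).append(seq)
    headline = {
        pat: seqs
        for pat, seqs in full.items()
        if len(seqs) > min_size and not (drop_all_s and set(pat) == {"S"})
    }
    return full, headline
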