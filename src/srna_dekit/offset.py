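"""Noise-to-signal abundance threshold (offset) from strand-bias KL curves.

Degradation noise in sRNA libraries is low-abundance and shows no strand
preference at the locus level, whereas genuine sRNA loci are strand-biased
(and very sparse loci are trivially biased because one or two reads cannot
balance strands).  The estimator tiles the genome into fixed-length windows,
computes each window's total abundance and strand bias (plus fraction of
total), groups windows into abundance levels, and measures the Kullback-
Leibler divergence of each level's strand-bias histogram from the uniform
distribution.  The divergence is high at very low abundances (few incident
reads), dips where unbiased noise dominates, and rises again for genuinely
strand-biased signal; the offset is the abundance at the global minimum of
the LOESS-smoothed curve.  The dataset offset is the minimum over samples.

The resulting offset is used by the differential-expression caller as the
additive constant in the log2 offset fold change (LOFC), damping fold
changes computed from noise-range abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import AlignmentSet, ReadLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeWindow",
    "KLCurve",
    "OffsetResult",
    "window_profiles",
    "kl_divergence",
    "kl_curve",
    "loess_smooth",
    "estimate_offset",
    "estimate_offset_from_windows",
]


@dataclass
class GenomeWindow:
    """One genomic tile with strand-resolved sRNA abundance."""

    chrom: str
    start: int
    end: int
    plus_abundance: float = 0.0
    minus_abundance: float = 0.0

    @property
    def total(self) -> float:
        return self.plus_abundance + self.minus_abundance

    @property
    def strand_bias(self) -> float:
        """Fraction of the window's abundance on the plus strand, in [0, 1]."""
        t = self.total
        if t <= 0:
            raise ValueError("strand bias undefined for an empty window")
        return self.plus_abundance / t


@dataclass
class KLCurve:
    """Raw and smoothed KL divergence against abundance level, plus the offset."""

    abundance: np.ndarray
    raw_kl: np.ndarray
    smoothed_kl: np.ndarray
    offset: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "abundance": self.abundance,
            "raw_kl": self.raw_kl,
            "smoothed_kl": self.smoothed_kl,
        })


@dataclass
class OffsetResult:
    curves: dict[str, KLCurve]
    sample_offsets: dict[str, float]
    dataset_offset: float
    treatment_offsets: dict[str, float] = field(default_factory=dict)


def window_profiles(
    alignments: AlignmentSet,
    library: ReadLibrary,
    window_len: int = 1000,
) -> list[GenomeWindow]:
    """Tile every chromosome with fixed windows and accumulate strand abundances.

    Each genomic hit of a read contributes count / (number of hits of that
    read) to the strand-specific abundance of the unique window containing
    its 5'-most genomic coordinate, so multi-mapping reads conserve library
    totals.  Windows with zero abundance are excluded.
    """
    if window_len < 50:
        raise ValueError("window_len must be >= 50")
    acc: dict[tuple[str, int], list[float]] = {}
    for seq, count in library.counts.items():
        hit_list = alignments.hits.get(seq, [])
        if not hit_list:
            continue
        w = count / len(hit_list)
        for chrom, start, strand in hit_list:
            five_prime = start if strand == "+" else start + len(seq) - 1
            key = (chrom, five_prime // window_len)
            slot = acc.setdefault(key, [0.0, 0.0])
            slot[0 if strand == "+" else 1] += w
    windows = []
    for (chrom, k), (plus, minus) in sorted(acc.items()):
        start = k * window_len
        end = min(start + window_len, alignments.genome_lengths.get(chrom, start + window_len))
        windows.append(GenomeWindow(chrom, start, end, plus, minus))
    return windows


def kl_divergence(histogram: np.ndarray) -> float:
    """KL divergence (bits) of a probability histogram from the uniform distribution.

    D = sum over occupied bins of p_i * log2(p_i * B) for B bins; >= 0, and 0
    iff the histogram is uniform.
    """
    p = np.asarray(histogram, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("histogram must be a vector with >= 2 bins")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"histogram must sum to 1, got {p.sum()}")
    nz = p[p > 0]
    return float(np.sum(nz * np.log2(nz * p.size)))


def kl_curve(
    windows: list[GenomeWindow],
    n_bias_bins: int = 100,
    min_windows_per_level: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw (abundance level, KL) series from a set of nonzero windows.

    Windows are sorted by total abundance and grouped into consecutive
    levels of at least ``min_windows_per_level`` windows (the last level
    absorbs the remainder) so each strand-bias histogram is estimated from
    enough windows.  The abundance coordinate of a level is the median
    window total; its KL value is the divergence of the level's strand-bias
    histogram (``n_bias_bins`` equal bins on [0, 1]) from uniform.
    """
    if len(windows) < 2 * min_windows_per_level:
        raise ValueError(
            f"need >= {2 * min_windows_per_level} windows, got {len(windows)}"
        )
    totals = np.array([w.total for w in windows])
    biases = np.array([w.strand_bias for w in windows])
    order = np.argsort(totals, kind="stable")
    totals, biases = totals[order], biases[order]

    n_levels = len(windows) // min_windows_per_level
    edges = [i * min_windows_per_level for i in range(n_levels)] + [len(windows)]
    xs, ys = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        hist, _ = np.histogram(biases[lo:hi], bins=n_bias_bins, range=(0.0, 1.0))
        xs.append(float(np.median(totals[lo:hi])))
        ys.append(kl_divergence(hist / hist.sum()))
    return np.array(xs), np.array(ys)


def loess_smooth(x: np.ndarray, y: np.ndarray, span: float = 0.3) -> np.ndarray:
    """LOESS (degree-1 local regression, tricube weights) of y at each x.

    ``span`` is the fraction of points in each local neighbourhood.  With
    fewer than 5 points smoothing is meaningless and an error is raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("loess_smooth needs >= 5 points")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    if np.all(x == x[0]):
        raise ValueError("degenerate x values (all equal)")
    # at least 2 points per local fit
    frac = max(span, 2.0 / x.size)
    return lowess(y, x, frac=frac, it=0, return_sorted=False)


def _curve_offset(x: np.ndarray, smoothed: np.ndarray) -> float:
    """Abundance at the global minimum; ties resolved to the smallest abundance."""
    m = smoothed.min()
    cand = x[smoothed == m]
    if cand.size > 1:
        logger.info("multiple equal KL minima; taking the smallest abundance")
    return float(cand.min())


def estimate_offset_from_windows(
    windows_by_sample: dict[str, list[GenomeWindow]],
    n_bias_bins: int = 100,
    min_windows_per_level: int = 100,
    span: float = 0.3,
    treatment_of: dict[str, str] | None = None,
) -> OffsetResult:
    """Per-sample KL curves and offsets from precomputed window profiles.

    The per-sample offset is the abundance coordinate of the global minimum
    of the smoothed curve; the dataset offset is the minimum over samples.
    When fewer than 5 abundance levels are available the raw curve is used
    unsmoothed.
    """
    curves: dict[str, KLCurve] = {}
    offsets: dict[str, float] = {}
    for sid, windows in windows_by_sample.items():
        x, raw = kl_curve(windows, n_bias_bins, min_windows_per_level)
        if x.size >= 5 and np.unique(x).size > 1:
            smoothed = loess_smooth(x, raw, span)
            if not np.all(np.isfinite(smoothed)):  # heavily tied levels
                logger.info("%s: LOESS undefined on tied levels, using raw curve", sid)
                smoothed = raw.copy()
        else:
            logger.info("%s: %d abundance levels, skipping LOESS", sid, x.size)
            smoothed = raw.copy()
        off = _curve_offset(x, smoothed)
        curves[sid] = KLCurve(x, raw, smoothed, off)
        offsets[sid] = off
    dataset = min(offsets.values())
    treatment_offsets = {}
    if treatment_of:
        for sid, off in offsets.items():
            t = treatment_of.get(sid)
            if t is not None:
                treatment_offsets[t] = min(treatment_offsets.get(t, np.inf), off)
    return OffsetResult(curves, offsets, dataset, treatment_offsets)


def estimate_offset(
    alignments: AlignmentSet,
    libraries: dict[str, ReadLibrary],
    window_len: int = 1000,
    n_bias_bins: int = 100,
    min_windows_per_level: int = 100,
    span: float = 0.3,
    treatment_of: dict[str, str] | None = None,
) -> OffsetResult:
    """End-to-end offset estimation: window profiles per replicate, then KL curves."""
    windows = {
        sid: window_profiles(alignments, lib, window_len)
        for sid, lib in libraries.items()
    }
    return estimate_offset_from_windows(
        windows, n_bias_bins, min_windows_per_level, span, treatment_of
    )
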