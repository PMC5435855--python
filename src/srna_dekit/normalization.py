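"""The six count-normalization schemes selectable in the pipeline.

Scaling methods (total-count RPM/RPT, upper quartile, TMM, median-of-ratios)
rescale each replicate column by a single factor; rank-based adapted
quantile normalization imposes a common distribution of values with sRNA-
specific tie and zero rules; subsampling normalization draws reads without
replacement down to the minimum library size.

All methods preserve zeros exactly and never produce negative values.  For
scaling methods the normalization total T matters: scaling far below the
library sizes hides differential expression and scaling far above fabricates
it, so the default T is the mean of the column sums (the ``average`` mode);
``median`` and ``fixed:N`` are available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .core import ConfigurationError, ExpressionMatrix
from .qc import centering_score, fold_change_distribution_per_size

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationResult",
    "normalize_total_count",
    "normalize_upper_quartile",
    "normalize_tmm",
    "normalize_deseq",
    "normalize_quantile_adapted",
    "normalize_subsampling",
    "normalize",
    "evaluate_normalizations",
    "METHODS",
]


@dataclass
class NormalizationResult:
    matrix: ExpressionMatrix
    method: str
    scale_factors: dict[str, float] | None = None
    diagnostics: dict = field(default_factory=dict)


def _resolve_total(col_sums: pd.Series, total_mode: str | float) -> float:
    if isinstance(total_mode, (int, float)):
        return float(total_mode)
    if total_mode == "average":
        return float(col_sums.mean())
    if total_mode == "median":
        return float(col_sums.median())
    if isinstance(total_mode, str) and total_mode.startswith("fixed:"):
        return float(total_mode.split(":", 1)[1])
    raise ConfigurationError(f"unknown total mode {total_mode!r}")


def normalize_total_count(
    matrix: ExpressionMatrix, total_mode: str | float = "average"
) -> NormalizationResult:
    """Reads-per-total scaling: value' = value * T / column_sum."""
    sums = matrix.column_sums().astype(float)
    zero = sums[sums == 0]
    if len(zero):
        raise ConfigurationError(f"zero column sum in replicate(s) {list(zero.index)}")
    T = _resolve_total(sums, total_mode)
    out = matrix.values.astype(float) * (T / sums)
    factors = {rid: float(sums[rid] / T) for rid in matrix.replicate_ids}
    return NormalizationResult(matrix.with_values(out, "total_count"), "total_count", factors)


def _nonzero_upper_quartile(col: np.ndarray) -> float:
    nz = col[col > 0]
    if nz.size < 4:
        raise ConfigurationError(
            f"upper-quartile normalization needs >= 4 nonzero values, got {nz.size}"
        )
    return float(np.quantile(nz, 0.75))  # type-7 linear interpolation


def normalize_upper_quartile(
    matrix: ExpressionMatrix, total_mode: str | float | None = None
) -> NormalizationResult:
    """Scale each column by the 75th percentile of its nonzero values.

    sRNA matrices are zero-dominated, so the quartile of the full column is
    often 0; the upper quartile is therefore computed on nonzero values.
    By default columns are brought to T = mean of the upper quartiles.
    """
    vals = matrix.values.to_numpy(dtype=float)
    uqs = np.array([_nonzero_upper_quartile(vals[:, j]) for j in range(vals.shape[1])])
    T = float(uqs.mean()) if total_mode is None else _resolve_total(
        pd.Series(uqs, index=matrix.replicate_ids), total_mode
    )
    out = pd.DataFrame(vals * (T / uqs), index=matrix.values.index,
                       columns=matrix.values.columns)
    factors = {rid: float(uq / T) for rid, uq in zip(matrix.replicate_ids, uqs)}
    return NormalizationResult(matrix.with_values(out, "upper_quartile"), "upper_quartile", factors)


def _tmm_factor(obs: np.ndarray, ref: np.ndarray, trim_m: float, trim_a: float) -> float:
    """Trimmed mean of M-values factor of one column against the reference.

    M and A are computed on sequences nonzero in both columns (on library-
    scaled proportions), the extreme trim_m tails of M and trim_a tails of A
    are removed, and the factor is 2**(precision-weighted mean of the
    remaining M).
    """
    n_obs, n_ref = obs.sum(), ref.sum()
    both = (obs > 0) & (ref > 0)
    o, r = obs[both], ref[both]
    p_o, p_r = o / n_obs, r / n_ref
    M = np.log2(p_o / p_r)
    A = 0.5 * np.log2(p_o * p_r)
    # approximate asymptotic variance of M (delta method on binomial counts)
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    m_lo, m_hi = np.quantile(M, [trim_m, 1 - trim_m])
    a_lo, a_hi = np.quantile(A, [trim_a, 1 - trim_a])
    keep = (M >= m_lo) & (M <= m_hi) & (A >= a_lo) & (A <= a_hi)
    if keep.sum() < 10:
        warnings.warn("fewer than 10 sequences survive TMM trimming; using untrimmed mean")
        keep = np.ones_like(keep, dtype=bool)
    return float(2 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])))


def normalize_tmm(
    matrix: ExpressionMatrix,
    reference: str = "auto",
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    total_mode: str | float = "average",
) -> NormalizationResult:
    """Trimmed-mean-of-M-values scaling, robust to asymmetric DE.

    Factors are rescaled so their product is 1, then each column is divided
    by (factor * column_sum) and multiplied by the normalization total T.
    The automatic reference is the column whose nonzero upper quartile is
    closest to the mean of those quartiles.
    """
    vals = matrix.values.to_numpy(dtype=float)
    rids = matrix.replicate_ids
    if reference == "auto":
        uqs = np.array([_nonzero_upper_quartile(vals[:, j]) for j in range(vals.shape[1])])
        ref_j = int(np.argmin(np.abs(uqs - uqs.mean())))
    else:
        if reference not in rids:
            raise ConfigurationError(f"unknown reference column {reference!r}")
        ref_j = rids.index(reference)
    ref = vals[:, ref_j]
    if ref.sum() == 0:
        raise ConfigurationError("reference column is all zero")

    factors = np.array([
        1.0 if j == ref_j else _tmm_factor(vals[:, j], ref, trim_m, trim_a)
        for j in range(vals.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))  # product -> 1

    sums = vals.sum(axis=0)
    T = _resolve_total(pd.Series(sums, index=rids), total_mode)
    out = pd.DataFrame(vals / (factors * sums) * T, index=matrix.values.index,
                       columns=matrix.values.columns)
    return NormalizationResult(
        matrix.with_values(out, "tmm"), "tmm",
        {rid: float(f) for rid, f in zip(rids, factors)},
        {"reference": rids[ref_j]},
    )


def normalize_deseq(matrix: ExpressionMatrix) -> NormalizationResult:
    """Median-of-ratios size factors.

    Per column: the median, over sequences nonzero in every column, of the
    count divided by the sequence's geometric mean across columns; each
    column is divided by its factor.
    """
    vals = matrix.values.to_numpy(dtype=float)
    all_nz = (vals > 0).all(axis=1)
    if not all_nz.any():
        raise ConfigurationError(
            "no sequence is nonzero in all columns; filter the matrix (e.g. to "
            "abundant sequences) before median-of-ratios normalization"
        )
    sub = vals[all_nz]
    geo = np.exp(np.mean(np.log(sub), axis=1, keepdims=True))
    factors = np.median(sub / geo, axis=0)
    out = pd.DataFrame(vals / factors, index=matrix.values.index, columns=matrix.values.columns)
    return NormalizationResult(
        matrix.with_values(out, "deseq"), "deseq",
        {rid: float(f) for rid, f in zip(matrix.replicate_ids, factors)},
    )


def normalize_quantile_adapted(matrix: ExpressionMatrix) -> NormalizationResult:
    """Rank-based quantile normalization adapted for sRNA counts.

    Classic quantile normalization imposes the rank-wise mean distribution on
    every column.  Two sRNA-specific rules are added: (i) sequences tied at
    the same abundance within a column receive the same normalized value,
    the mean of the reference values at their ranks; (ii) a sequence absent
    from a column (abundance 0) stays exactly 0.
    """
    if len(matrix.replicate_ids) < 2:
        raise ConfigurationError("quantile normalization needs >= 2 columns")
    vals = matrix.values.to_numpy(dtype=float)
    n, k = vals.shape
    order = np.argsort(vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    reference = sorted_vals.mean(axis=1)  # rank-wise mean, zeros included

    out = np.empty_like(vals)
    for j in range(k):
        col_sorted = sorted_vals[:, j]
        assigned = np.empty(n)
        i = 0
        while i < n:
            h = i
            while h + 1 < n and col_sorted[h + 1] == col_sorted[i]:
                h += 1
            assigned[i : h + 1] = reference[i : h + 1].mean()  # tie rule (i)
            i = h + 1
        out[order[:, j], j] = assigned
    out[vals == 0] = 0.0  # zero rule (ii)
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return NormalizationResult(matrix.with_values(df, "quantile"), "quantile")


def _subsample_column(counts: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` reads without replacement from a collapsed count vector."""
    return rng.multivariate_hypergeometric(counts.astype(np.int64), size)


def normalize_subsampling(
    matrix: ExpressionMatrix,
    seed: int,
    n_boot: int = 100,
    alpha: float = 0.05,
    proportion_step: float = 0.1,
) -> NormalizationResult:
    """Subsample every column without replacement to the minimum library size.

    Step (i): each column is subsampled at decreasing proportions (1-step,
    1-2*step, ...) and the nonzero abundance distribution of each subsample
    is compared to the original with a two-sample KS test; the first
    proportion at which the distribution changes significantly (p < alpha)
    is recorded.  Step (ii): ``n_boot`` subsamples are drawn at the target
    size, pairwise KS distances between them are computed, and the medoid
    subsample (minimum summed distance to the others) is returned for each
    column; the column is flagged high-variability when the median pairwise
    distance exceeds the 95th percentile of the subsample-to-original
    distances.
    """
    vals = matrix.values.to_numpy(dtype=np.int64)
    sums = vals.sum(axis=0)
    target = int(sums.min())
    if target <= 0:
        raise ConfigurationError("minimum column sum is 0; cannot subsample")
    rng = np.random.default_rng(seed)
    out = np.empty_like(vals)
    diag: dict[str, dict] = {}
    for j, rid in enumerate(matrix.replicate_ids):
        col = vals[:, j]
        orig_nz = col[col > 0]
        # step (i): distribution stability along the proportion grid
        stop_proportion = None
        p = 1.0 - proportion_step
        while round(p * sums[j]) > target and p > 0:
            sub = _subsample_column(col, int(round(p * sums[j])), rng)
            if ks_2samp(sub[sub > 0], orig_nz).pvalue < alpha:
                stop_proportion = round(p, 10)
                break
            p -= proportion_step
        # step (ii): bootstrap at target, medoid selection
        boots = [_subsample_column(col, target, rng) for _ in range(n_boot)]
        boot_nz = [b[b > 0] for b in boots]
        dist = np.zeros((n_boot, n_boot))
        for a in range(n_boot):
            for b in range(a + 1, n_boot):
                d = ks_2samp(boot_nz[a], boot_nz[b]).statistic
                dist[a, b] = dist[b, a] = d
        to_orig = np.array([ks_2samp(bn, orig_nz).statistic for bn in boot_nz])
        pair = dist[np.triu_indices(n_boot, 1)]
        high_var = bool(np.median(pair) > np.quantile(to_orig, 0.95)) if pair.size else False
        medoid = int(np.argmin(dist.sum(axis=1)))
        out[:, j] = boots[medoid]
        diag[rid] = {
            "stopped_at_proportion": stop_proportion,
            "high_variability": high_var,
            "medoid_index": medoid,
        }
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return NormalizationResult(
        matrix.with_values(df, "subsample"), "subsample", None,
        {"target": target, "columns": diag},
    )


METHODS = ("rpt", "uq", "tmm", "deseq", "quantile", "subsample")


def normalize(
    matrix: ExpressionMatrix,
    method: str,
    total_mode: str | float = "average",
    seed: int = 0,
    **kwargs,
) -> NormalizationResult:
    """Dispatch to one of the six normalization methods by short name."""
    if method in ("rpt", "rpm", "total_count"):
        return normalize_total_count(matrix, total_mode)
    if method in ("uq", "upper_quartile"):
        return normalize_upper_quartile(matrix)
    if method == "tmm":
        return normalize_tmm(matrix, total_mode=total_mode, **kwargs)
    if method == "deseq":
        return normalize_deseq(matrix)
    if method == "quantile":
        return normalize_quantile_adapted(matrix)
    if method in ("subsample", "subsampling"):
        return normalize_subsampling(matrix, seed=seed, **kwargs)
    raise ConfigurationError(f"unknown normalization method {method!r}")


def evaluate_normalizations(
    matrix: ExpressionMatrix,
    methods: list[str],
    total_mode: str | float = "average",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, NormalizationResult]]:
    """Between-replicate fold-change evaluation of candidate normalizations.

    Replicates of the same treatment are not expected to differ, so a good
    normalization brings all per-size-class log2 fold-change distributions
    onto the 0 line.  Returns a tidy per-(method, treatment, size) quartile
    table, a ranking of methods by centering score (max |median|, lower is
    better; 'raw' included for reference), and the normalized results.
    """
    if not any(len(reps) >= 2 for _, reps in matrix.hierarchy.treatments):
        raise ConfigurationError("evaluation needs a treatment with >= 2 replicates")
    results: dict[str, NormalizationResult] = {}
    for m in methods:
        results[m] = normalize(matrix, m, total_mode=total_mode, seed=seed)

    rows = []
    scores = []
    for label, mat in [("raw", matrix)] + [(m, r.matrix) for m, r in results.items()]:
        worst = 0.0
        any_fc = False
        for tid, ra, rb in mat.hierarchy.replicate_pairs():
            ca = mat.values[ra][mat.values[ra] > 0].to_dict()
            cb = mat.values[rb][mat.values[rb] > 0].to_dict()
            fc = fold_change_distribution_per_size(ca, cb)
            rows.extend((label, tid, ra, rb, s, *q) for s, q in fc.items())
            if fc:
                any_fc = True
                worst = max(worst, centering_score(fc))
        scores.append((label, worst if any_fc else np.nan))
    evaluation = pd.DataFrame(rows, columns=["method", "treatment", "repA", "repB",
                                             "size", "q1", "median", "q3"])
    ranking = (
        pd.DataFrame(scores, columns=["method", "centering_score"])
        .sort_values(["centering_score", "method"], kind="stable")
        .reset_index(drop=True)
    )
    return evaluation, ranking, results
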