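"""Pairwise negative-binomial differential expression.

All C(6,2)=15 unordered group pairs are tested RNA by RNA with a Wald test
on the log2 fold change of pseudocounted, size-factor-normalised group
means.  The NB variance m + alpha*m^2 uses a method-of-moments dispersion
pooled across the two groups; p-values come from the standard normal and
are Benjamini-Hochberg adjusted within each pair.  Marker thresholds
downstream are q < 0.05 and |log2FC| > 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CountMatrix, SampleSheet

LN2 = np.log(2.0)

DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 10.0


@dataclass(frozen=True)
class DEResult:
    rna_id: str
    group_a: str
    group_b: str
    log2fc: float  # A over B
    p_value: float
    q_value: float
    mean_a: float
    mean_b: float
    dispersion: float


def enumerate_pairs(groups: Iterable[str]) -> list[tuple[str, str]]:
    """All unordered group pairs, canonically (alphabetically) ordered."""
    return list(combinations(sorted(set(groups)), 2))


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors; total-count scaling as fallback.

    The median-of-ratios estimator uses RNAs with nonzero counts in every
    sample; when none exist (or the median degenerates to zero) the
    per-sample totals scaled to geometric mean one are used instead.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.any():
        sub = mat[positive]
        log_geo = np.log(sub).mean(axis=1, keepdims=True)
        sf = np.exp(np.median(np.log(sub) - log_geo, axis=0))
        if np.all(sf > 0):
            return pd.Series(sf, index=counts.columns)
    totals = mat.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("cannot compute size factors: empty sample column")
    sf = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(sf, index=counts.columns)


def _clamp_dispersion(alpha: np.ndarray | float) -> np.ndarray | float:
    return np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CEIL)


def _moment_dispersion(norm_a: np.ndarray, norm_b: np.ndarray) -> np.ndarray:
    """Method-of-moments dispersion, averaged across the two groups.

    For each group, alpha = max(0, (s^2 - m) / m^2) on normalised counts
    (sample variance, ddof=1); the two estimates are averaged and clamped.
    Rows are RNAs.
    """
    out = np.zeros(norm_a.shape[0])
    for arr in (norm_a, norm_b):
        m = arr.mean(axis=1)
        s2 = arr.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (s2 - m) / np.square(m), 0.0)
        out += np.maximum(a, 0.0)
    return _clamp_dispersion(out / 2.0)


def estimate_dispersion(
    counts_a: Sequence[float] | np.ndarray,
    counts_b: Sequence[float] | np.ndarray,
    size_factors_a: Sequence[float] | None = None,
    size_factors_b: Sequence[float] | None = None,
) -> float:
    """Moment dispersion for one RNA across both groups."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if size_factors_a is not None:
        a = a / np.asarray(size_factors_a, dtype=float)
    if size_factors_b is not None:
        b = b / np.asarray(size_factors_b, dtype=float)
    return float(_moment_dispersion(a[None, :], b[None, :])[0])


def _wald_matrix(
    norm_a: np.ndarray,
    norm_b: np.ndarray,
    pseudocount: float,
    dispersion: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised NB Wald test over RNA rows.

    Returns (log2fc, p, mean_a, mean_b, dispersion).  The delta-method
    standard error of log2(mean + c) uses Var(mean) = (m + alpha*m^2)/n.
    """
    c = pseudocount
    n_a, n_b = norm_a.shape[1], norm_b.shape[1]
    mean_a = norm_a.mean(axis=1)
    mean_b = norm_b.mean(axis=1)
    if np.any(mean_a + c <= 0) or np.any(mean_b + c <= 0):
        raise ValueError(
            "fold change undefined: all-zero group with zero pseudocount"
        )
    alpha = _moment_dispersion(norm_a, norm_b) if dispersion is None else dispersion
    log2fc = np.log2(mean_a + c) - np.log2(mean_b + c)
    var_a = (mean_a + alpha * np.square(mean_a)) / n_a
    var_b = (mean_b + alpha * np.square(mean_b)) / n_b
    se2 = (
        var_a / np.square((mean_a + c) * LN2)
        + var_b / np.square((mean_b + c) * LN2)
    )
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
        z = np.where((se == 0) & (log2fc != 0), np.inf * np.sign(log2fc), z)
    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    return log2fc, p, mean_a, mean_b, np.broadcast_to(alpha, mean_a.shape)


def nb_wald_test(
    counts_a: Sequence[float] | np.ndarray,
    counts_b: Sequence[float] | np.ndarray,
    size_factors_a: Sequence[float] | None = None,
    size_factors_b: Sequence[float] | None = None,
    pseudocount: float = 0.5,
    dispersion: float | None = None,
) -> tuple[float, float]:
    """Wald test for one RNA: returns (log2fc A over B, two-sided p)."""
    if len(counts_a) < 2 or len(counts_b) < 2:
        raise ValueError("need at least 2 samples per group")
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if size_factors_a is not None:
        a = a / np.asarray(size_factors_a, dtype=float)
    if size_factors_b is not None:
        b = b / np.asarray(size_factors_b, dtype=float)
    disp = None if dispersion is None else _clamp_dispersion(np.array([dispersion]))
    log2fc, p, *_ = _wald_matrix(a[None, :], b[None, :], pseudocount, disp)
    return float(log2fc[0]), float(p[0])


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the original order."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    if n == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def pairwise_de(
    counts: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    group_a: str,
    group_b: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Test one group pair over all RNAs with counts in either group.

    RNAs with all-zero counts across both groups' samples are excluded
    before testing and before the BH adjustment.
    """
    cols = list(samples_a) + list(samples_b)
    sub = counts[cols]
    keep = sub.sum(axis=1) > 0
    sub = sub.loc[keep]
    sf = size_factors(sub)
    norm = sub / sf
    norm_a = norm[list(samples_a)].to_numpy()
    norm_b = norm[list(samples_b)].to_numpy()
    log2fc, p, mean_a, mean_b, disp = _wald_matrix(norm_a, norm_b, pseudocount)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "rna_id": sub.index,
            "group_a": group_a,
            "group_b": group_b,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "dispersion": disp,
        }
    ).reset_index(drop=True)


def run_all_pairs(
    counts: CountMatrix | pd.DataFrame,
    sample_sheet: SampleSheet,
    pseudocount: float = 0.5,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Differential expression for every unordered group pair.

    Technical replicates are excluded.  BH adjustment is applied within
    each pair across all tested RNAs.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    results: dict[tuple[str, str], pd.DataFrame] = {}
    for a, b in enumerate_pairs(sample_sheet.groups):
        samples_a = [s for s in sample_sheet.samples_for_group(a) if s in mat.columns]
        samples_b = [s for s in sample_sheet.samples_for_group(b) if s in mat.columns]
        if len(samples_a) < 2 or len(samples_b) < 2:
            raise ValueError(f"pair ({a}, {b}) has fewer than 2 samples per group")
        results[(a, b)] = pairwise_de(mat, samples_a, samples_b, a, b, pseudocount)
    return results
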