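"""Chance-level estimation, binomial confidence bounds and t-tests."""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GuessingEstimate", "empirical_guessing", "guessing_ci",
           "one_sample_test", "paired_test", "table_stats"]


@dataclass
class GuessingEstimate:
    """Empirical chance level from label permutations."""

    level: float
    n_permutations: int
    per_permutation: np.ndarray
    ci: tuple[float, float]
    m: int


def empirical_guessing(features: np.ndarray, labels: np.ndarray,
                       procedure, n_perm: int = 500, seed: int = 0,
                       alpha: float = 0.05) -> GuessingEstimate:
    """Mean accuracy of the classification procedure over permuted labels.

    ``procedure(features, permuted_labels, rng) -> accuracy`` must be the
    same classification procedure used on the real labels (see
    :func:`fingerdecode.decode.make_procedure`).
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    accs = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(labels.size)
        accs[i] = procedure(features, labels[perm], rng)
    ci = guessing_ci(labels.size, alpha)
    return GuessingEstimate(level=float(accs.mean()), n_permutations=n_perm,
                            per_permutation=accs, ci=ci, m=labels.size)


def guessing_ci(m: int, alpha: float = 0.05,
                p0: float = 0.5) -> tuple[float, float]:
    """Normal-approximation binomial interval around two-class chance:
    ``p0 +/- z_{1-alpha/2} * sqrt(p0 (1 - p0) / m)``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = sps.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(p0 * (1 - p0) / m)
    return (p0 - half, p0 + half)


def one_sample_test(accuracies: np.ndarray, guessing: float,
                    alternative: str = "greater") -> tuple[float, float]:
    """One-sample t-test of repetition accuracies against the chance level.

    Zero-variance accuracy distributions fall back to an exact comparison
    (p = 0 if the constant differs from the reference in the tested
    direction, else p = 1).
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least 2 repetition accuracies")
    if np.ptp(acc) == 0:
        warnings.warn("zero variance in accuracies: exact comparison",
                      RuntimeWarning)
        d = acc[0] - guessing
        if alternative == "greater":
            return (np.inf if d > 0 else -np.inf if d < 0 else 0.0,
                    0.0 if d > 0 else 1.0)
        return (np.inf if d != 0 else 0.0, 0.0 if d != 0 else 1.0)
    t, p = sps.ttest_1samp(acc, guessing, alternative=alternative)
    return float(t), float(p)


def paired_test(cond_a: np.ndarray, cond_b: np.ndarray) -> tuple[float, float]:
    """Paired t-test between two matched accuracy vectors."""
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diff = a - b
    if np.ptp(diff) == 0:
        warnings.warn("identical condition vectors: p = 1", RuntimeWarning)
        return (0.0, 1.0) if diff[0] == 0 else (np.inf, 0.0)
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def table_stats(matrix: np.ndarray, decimals: int = 2
                ) -> tuple[np.ndarray, np.ndarray]:
    """Column means and sample (n-1) standard deviations, rounded.

    Mirrors the summary rows of a subjects-by-conditions report table.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] == 0 or x.size == 0:
        raise ValueError("empty table")
    means = np.round(x.mean(axis=0), decimals)
    stds = np.round(x.std(axis=0, ddof=1), decimals)
    return means, stds
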