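"""Distances in statistic space, nearest-median classification, Mantel tests.

Each image-statistic set is a 2-parameter description of an image; after
z-scoring both parameters across the image set, the distance between two
images is the city-block (L1) distance |Δp1| + |Δp2|.  Category structure
is probed with a leave-one-out nearest-median classifier, confusions are
tested per category pair with binomial tail probabilities under a
Benjamini-Hochberg FDR threshold, and distance matrices are compared with
a seeded Mantel permutation test with percentile-bootstrap intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as iter_permutations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# parameter tables and distances


def normalize_params(table: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """z-score each parameter column (sample SD); idempotent.

    Raises on constant columns, which carry no distance information.
    """
    values = np.asarray(table, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("expected a 2D (images x parameters) table")
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(np.where(sd == 0)[0])
        raise ValueError(f"constant parameter column(s): {bad}")
    z = (values - values.mean(axis=0)) / sd
    if isinstance(table, pd.DataFrame):
        return pd.DataFrame(z, index=table.index, columns=table.columns)
    return z


def param_distance_matrix(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise L1 distances: d(i, j) = sum_k |p_k(i) - p_k(j)|."""
    values = np.asarray(table, dtype=np.float64)
    diffs = np.abs(values[:, None, :] - values[None, :, :])
    return diffs.sum(axis=2)


# ---------------------------------------------------------------------------
# leave-one-out nearest-median classification


@dataclass
class ClassificationResult:
    accuracy: float  # fraction of hits in [0, 1]
    hits: np.ndarray  # (n_images,) bool
    assigned: np.ndarray  # (n_images,) category assigned to each image
    confusion_counts: np.ndarray  # (n_cat, n_cat): [true, assigned] counts
    categories: np.ndarray

    @property
    def error_rate_matrix(self) -> np.ndarray:
        """Symmetric per-pair error rates with zero diagonal.

        Cell (i, j) is the fraction of stimuli of category i or j that were
        misclassified as the other; used for confusion-matrix comparisons.
        """
        counts = self.confusion_counts.astype(np.float64)
        n_per = counts.sum(axis=1)
        rates = np.zeros_like(counts)
        for a in range(len(self.categories)):
            for b in range(len(self.categories)):
                if a == b:
                    continue
                rates[a, b] = (counts[a, b] + counts[b, a]) / (n_per[a] + n_per[b])
        return rates


def loo_classify(
    table: pd.DataFrame | np.ndarray, labels: Sequence
) -> ClassificationResult:
    """Leave-one-out nearest-median classification in normalized space.

    For each stimulus, the median parameter vector of the remaining members
    of its own category and the medians of every other (full) category are
    computed; the stimulus is a hit iff the L1 distance to its own-category
    median is strictly smaller than to any other.  Ties count as misses;
    misses are attributed to the nearest wrong category.
    """
    values = np.asarray(table, dtype=np.float64)
    labels = np.asarray(labels)
    cats = np.unique(labels)
    medians = np.stack([np.median(values[labels == c], axis=0) for c in cats])

    n = len(values)
    hits = np.zeros(n, dtype=bool)
    assigned = np.empty(n, dtype=cats.dtype)
    conf = np.zeros((len(cats), len(cats)), dtype=np.int64)
    cat_index = {c: k for k, c in enumerate(cats)}

    for i in range(n):
        own = cat_index[labels[i]]
        own_rows_all = values[labels == labels[i]]
        # drop exactly one row equal to the held-out stimulus
        drop = int(np.argmax(np.all(own_rows_all == values[i], axis=1)))
        own_median = np.median(np.delete(own_rows_all, drop, axis=0), axis=0)
        d = np.abs(values[i] - medians).sum(axis=1)
        d[own] = np.abs(values[i] - own_median).sum()
        d_other = np.where(np.arange(len(cats)) == own, np.inf, d)
        nearest_other = int(np.argmin(d_other))
        if d[own] < d_other[nearest_other]:
            hits[i] = True
            assigned[i] = cats[own]
            conf[own, own] += 1
        else:
            assigned[i] = cats[nearest_other]
            conf[own, nearest_other] += 1

    return ClassificationResult(
        accuracy=float(hits.mean()),
        hits=hits,
        assigned=assigned,
        confusion_counts=conf,
        categories=cats,
    )


def binomial_fdr_threshold(
    hit_counts: np.ndarray,
    trials: np.ndarray | int,
    chance: float = 1.0 / 16.0,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Binomial tail probabilities per pair with a BH-FDR significance mask.

    Returns (p_values, significant_mask): p = P(X >= hits | trials, chance),
    masked by Benjamini-Hochberg at ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    hit_counts = np.asarray(hit_counts)
    trials = np.broadcast_to(np.asarray(trials), hit_counts.shape)
    if np.any(trials < 1):
        raise ValueError("each pair needs at least one trial")
    pvals = stats.binom.sf(hit_counts - 1, trials, chance)
    mask = multipletests(pvals.ravel(), alpha=alpha, method="fdr_bh")[0]
    return pvals, mask.reshape(hit_counts.shape)


# ---------------------------------------------------------------------------
# Mantel test and bootstrap


@dataclass
class MantelResult:
    r_m: float
    p_value: float
    n_permutations: int
    ci_low: float | None = None
    ci_high: float | None = None


def _check_distance_matrix(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(a, a.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(a), 0):
        raise ValueError(f"{name} must have a zero diagonal")
    return a


def mantel_test(
    a: np.ndarray,
    b: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | None = None,
    exact: bool = False,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r_m is the Pearson correlation of the off-diagonal upper triangles; the
    one-sided p-value counts simultaneous row/column permutations of ``b``
    whose correlation reaches the observed one, with the +1 correction
    p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations).  ``exact=True``
    enumerates all n! permutations (small matrices only) and reports the
    exact permutation fraction.
    """
    a = _check_distance_matrix(a, "a")
    b = _check_distance_matrix(b, "b")
    if a.shape != b.shape:
        raise ValueError("matrices must have the same shape")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    va, vb = a[iu], b[iu]
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero variance in off-diagonal entries")
    r_obs = float(np.corrcoef(va, vb)[0, 1])

    if exact:
        count = 0
        total = 0
        for perm in iter_permutations(range(n)):
            p = np.array(perm)
            r = np.corrcoef(va, b[np.ix_(p, p)][iu])[0, 1]
            count += r >= r_obs
            total += 1
        return MantelResult(r_obs, count / total, total)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        r = np.corrcoef(va, b[np.ix_(p, p)][iu])[0, 1]
        count += r >= r_obs
    p_value = (1 + count) / (1 + n_permutations)
    return MantelResult(r_obs, float(p_value), n_permutations)


def percentile_bootstrap_ci(
    values: np.ndarray,
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 10_000,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """2.5/97.5 percentile bootstrap interval of ``statistic`` over resamples."""
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("empty input")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot = np.array([statistic(values[row]) for row in idx])
    lo = (1 - level) / 2 * 100
    return float(np.percentile(boot, lo)), float(np.percentile(boot, 100 - lo))


def mantel_bootstrap_ci(
    a: np.ndarray,
    b: np.ndarray,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI of r_m over paired resampling of dissimilarities."""
    a = _check_distance_matrix(a, "a")
    b = _check_distance_matrix(b, "b")
    iu = np.triu_indices(a.shape[0], k=1)
    va, vb = a[iu], b[iu]
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    m = va.size
    for k in range(n_boot):
        idx = rng.integers(0, m, size=m)
        xa, xb = va[idx], vb[idx]
        if xa.std() == 0 or xb.std() == 0:
            boot[k] = 0.0
        else:
            boot[k] = np.corrcoef(xa, xb)[0, 1]
    return float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5))
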