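"""Distance-based permutation inference and ordination.

Implements the one-way PERMANOVA of Anderson's distance-based framework:
the total sum of squared inter-point distances is partitioned into
among- and within-group components,

    SS_T = (1/N) * sum_{i<j} d_ij^2
    SS_W = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_A = SS_T - SS_W
    pseudo-F = (SS_A / (a-1)) / (SS_W / (N-a)),

and the pseudo-F is referred to its permutation null: either every
distinct relabelling (exact, auto-selected for small designs) or random
relabellings with the (1 + count) / (1 + B) estimator.  With Euclidean
distances on univariate data the pseudo-F equals the classical one-way
ANOVA F, which the test suite exploits as an independent oracle.

Pairwise (two-group) contrasts report t = sqrt(pseudo-F).  PCA is by
eigendecomposition of the covariance — or, when normalised, the
correlation — matrix of the centred data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sympy.utilities.iterables import multiset_permutations

_TIE_RTOL = 1e-12  # relative slack when comparing permuted statistics


# ---------------------------------------------------------------------------
# transforms and distances
# ---------------------------------------------------------------------------

def log1p_transform(matrix: np.ndarray) -> np.ndarray:
    """Elementwise natural log(X + 1); the standard variance-stabilising
    transform applied before computing resemblance matrices."""
    x = np.asarray(matrix, dtype=float)
    if np.any(x < 0):
        raise ValueError("log1p_transform requires non-negative entries")
    return np.log1p(x)


def euclidean_distances(matrix: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance matrix between sample rows."""
    x = np.atleast_2d(np.asarray(matrix, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    return squareform(pdist(x, metric="euclidean"))


def _validate_distance_matrix(dist: np.ndarray) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return d


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationCount:
    """Cardinalities of the label-permutation null for given group sizes."""

    n_label_orderings: int   # N! orderings of the label vector
    n_distinct: int          # N! / prod(n_g!) distinct label assignments


def exact_permutation_count(sizes) -> PermutationCount:
    sizes = [int(s) for s in sizes]
    if not sizes:
        raise ValueError("empty group-size list")
    if any(s < 1 for s in sizes):
        raise ValueError("group sizes must be >= 1")
    if len(sizes) < 2:
        raise ValueError("a single group cannot be tested")
    n = sum(sizes)
    total = math.factorial(n)
    distinct = total
    for s in sizes:
        distinct //= math.factorial(s)
    return PermutationCount(n_label_orderings=total, n_distinct=distinct)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    ss_total: float
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    p_perm: float
    n_permutations: int
    method: str  # "exact" or "monte-carlo"
    seed: int | None


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    t_statistic: float
    p_perm: float
    n_permutations: int
    method: str
    seed: int | None


def _group_positions(groups) -> tuple[np.ndarray, list, list[np.ndarray]]:
    labels = np.asarray(groups)
    uniq = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    positions = [np.nonzero(labels == u)[0] for u in uniq]
    return labels, uniq, positions


def _ss_within(d2: np.ndarray, positions: list[np.ndarray]) -> float:
    ssw = 0.0
    for pos in positions:
        sub = d2[np.ix_(pos, pos)]
        ssw += sub.sum() / (2.0 * pos.size)
    return ssw


def _pseudo_f(ss_a: float, ss_w: float, df_a: int, df_w: int) -> float:
    if ss_w <= 0:
        return math.inf if ss_a > 0 else math.nan
    return (ss_a / df_a) / (ss_w / df_w)


def permanova_oneway(
    dist: np.ndarray,
    groups,
    n_permutations: int = 9999,
    seed: int | None = None,
    method: str = "auto",
) -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against group labels.

    ``method`` is ``"auto"`` (exact enumeration whenever the number of
    distinct label assignments does not exceed ``n_permutations``),
    ``"exact"`` or ``"monte-carlo"``.  Monte-Carlo p-values use the
    (1 + count) / (1 + B) estimator; exact p-values count the observed
    assignment once among all distinct assignments.  Permuted statistics
    tying the observed one count towards the p-value.
    """
    d = _validate_distance_matrix(dist)
    labels, uniq, positions = _group_positions(groups)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("group labels do not match the distance matrix")
    a = len(uniq)
    if a < 2:
        raise ValueError("need at least 2 groups")
    if n - a < 1:
        raise ValueError("residual degrees of freedom must be >= 1")

    d2 = d ** 2
    ss_t = d2.sum() / (2.0 * n)
    if ss_t == 0:
        raise ValueError("all pairwise distances are zero: pseudo-F undefined")
    ss_w = _ss_within(d2, positions)
    ss_a = ss_t - ss_w
    df_a, df_w = a - 1, n - a
    f_obs = _pseudo_f(ss_a, ss_w, df_a, df_w)

    # SS_T is permutation-invariant, so F_perm >= F_obs  <=>  SS_W_perm <= SS_W_obs
    ssw_cut = ss_w * (1.0 + _TIE_RTOL) + 1e-300
    counts = [pos.size for pos in positions]
    n_distinct = exact_permutation_count(counts).n_distinct

    if method == "auto":
        method = "exact" if n_distinct <= n_permutations else "monte-carlo"
    if method == "exact":
        code = np.concatenate([
            np.full(c, i, dtype=np.int8) for i, c in enumerate(counts)])
        hits = 0
        for perm in multiset_permutations(code.tolist()):
            perm = np.asarray(perm)
            pos_perm = [np.nonzero(perm == i)[0] for i in range(a)]
            if _ss_within(d2, pos_perm) <= ssw_cut:
                hits += 1
        p = hits / n_distinct
        n_used = n_distinct
    elif method == "monte-carlo":
        rng = np.random.default_rng(seed)
        b = int(n_permutations)
        perms = np.argsort(rng.random((b, n)), axis=1)
        ssw_perm = np.zeros(b)
        for pos in positions:
            idx = perms[:, pos]  # (b, n_g) permuted sample indices
            sub = d2[idx[:, :, None], idx[:, None, :]]
            ssw_perm += sub.sum(axis=(1, 2)) / (2.0 * pos.size)
        hits = int((ssw_perm <= ssw_cut).sum())
        p = (1.0 + hits) / (1.0 + b)
        n_used = b
    else:
        raise ValueError(f"unknown method {method!r}")

    return PermanovaResult(
        pseudo_f=f_obs, ss_total=ss_t, ss_among=ss_a, ss_within=ss_w,
        df_among=df_a, df_within=df_w, p_perm=p, n_permutations=n_used,
        method=method, seed=seed,
    )


def permanova_pairwise(
    dist: np.ndarray,
    groups,
    pair: tuple,
    n_permutations: int = 9999,
    seed: int | None = None,
    method: str = "auto",
) -> PairwiseResult:
    """Two-group contrast: restrict the distance matrix to ``pair`` and
    report t = sqrt(pseudo-F) with its permutation p-value."""
    labels = np.asarray(groups)
    ga, gb = pair
    ia = np.nonzero(labels == ga)[0]
    ib = np.nonzero(labels == gb)[0]
    if ia.size < 2 or ib.size < 2:
        raise ValueError("both groups need >= 2 samples for a pairwise test")
    idx = np.concatenate([ia, ib])
    sub = np.asarray(dist, dtype=float)[np.ix_(idx, idx)]
    sub_groups = np.concatenate([labels[ia], labels[ib]])
    res = permanova_oneway(sub, sub_groups, n_permutations, seed, method)
    return PairwiseResult(
        group_a=str(ga), group_b=str(gb),
        t_statistic=math.sqrt(res.pseudo_f), p_perm=res.p_perm,
        n_permutations=res.n_permutations, method=res.method, seed=seed,
    )


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray              # (n_samples, n_components)
    loadings: np.ndarray            # (n_variables, n_components)
    explained_fraction: np.ndarray  # non-increasing, sums to 1
    normalized: bool


def pca(matrix: np.ndarray, normalize: bool = True) -> PCAResult:
    """Principal component analysis of the sample rows.

    ``normalize=True`` analyses the correlation matrix (variables scaled
    to unit variance), appropriate when variables share units but differ
    in magnitude; ``False`` analyses the covariance matrix.
    """
    x = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    xc = x - x.mean(axis=0)
    if normalize:
        sd = xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant column under normalisation")
        xc = xc / sd
    cov = (xc.T @ xc) / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    # deterministic sign: dominant loading of each axis is positive
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    total = eigval.sum()
    return PCAResult(
        scores=xc @ eigvec, loadings=eigvec,
        explained_fraction=eigval / total, normalized=normalize,
    )
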