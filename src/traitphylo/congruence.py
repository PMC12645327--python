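"""Cross-phylogeny congruence statistics.

Given two trait systems observed on (a shared subset of) the same
societies, these tests ask whether their evolutionary histories agree:

* Mantel tests between patristic-distance matrices, either from consensus
  trees or averaged over posterior tree samples with per-tree depth
  normalisation (so deep trees do not dominate the average);
* a PCA projection of the binary tip data, whose first component is mapped
  onto the *other* dataset's trees and scored with Blomberg's K, a ratio of
  observed to Brownian-expected phylogenetic signal (K around 1 under
  Brownian motion, K > 1 for stronger-than-Brownian signal).

Permutation p-values use the inclusive estimator
p = (1 + #{null >= observed}) / (1 + permutations), so 999 permutations
give a floor of 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, ParameterError, ValidationError
from .traits import TraitMatrix
from .trees import TimeTree, normalise_by_depth, patristic_matrix, prune_tips


@dataclass
class MantelResult:
    """Raw cross-product statistic z, correlation r, and permutation p."""

    z: float
    r: float | None
    p: float
    permutations: int
    seed: int


@dataclass
class SignalResult:
    """Blomberg's K averaged over posterior trees, with permutation p."""

    k_mean: float
    p: float
    n_trees: int
    permutations: int
    seed: int
    component: int = 1


# ---------------------------------------------------------------------- #
# Distance matrices
# ---------------------------------------------------------------------- #


def posterior_mean_distances(
    trees: Sequence[TimeTree],
    taxa: Sequence[str],
    n: int | None = None,
    normalise: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Element-wise mean patristic matrix over a posterior tree sample.

    Subsamples ``n`` trees without replacement (seeded), optionally
    depth-normalises each tree, prunes to ``taxa`` and averages.
    """
    trees = list(trees)
    if n is None:
        n = len(trees)
    if n > len(trees):
        raise ParameterError(f"requested {n} trees but only {len(trees)} available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(trees), size=n, replace=False) if n < len(trees) else np.arange(n)
    acc = np.zeros((len(taxa), len(taxa)))
    for i in idx:
        t = trees[int(i)]
        if normalise:
            t = normalise_by_depth(t)
        if set(taxa) != set(t.tip_labels):
            t = prune_tips(t, set(taxa))
        acc += patristic_matrix(t, taxa)
    return acc / n


def write_distance_matrix(D: np.ndarray, taxa: Sequence[str], path: str) -> None:
    """Square CSV with a taxon header row/column."""
    import pandas as pd

    pd.DataFrame(np.asarray(D), index=list(taxa), columns=list(taxa)).to_csv(path)


def read_distance_matrix(path: str) -> tuple[np.ndarray, list[str]]:
    """Read a square CSV distance matrix; returns (matrix, taxon order)."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError("distance CSV must have matching row/column taxa")
    return df.to_numpy(dtype=float), [str(t) for t in df.index]


# ---------------------------------------------------------------------- #
# Mantel test
# ---------------------------------------------------------------------- #


def mantel_test(
    d_a: np.ndarray,
    d_b: np.ndarray,
    permutations: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Permutation Mantel test of association between two distance matrices.

    z is the sum over unordered pairs of element-wise products (the classic
    Mantel statistic, scale-dependent); r is the Pearson correlation over
    the same pairs. The null permutes rows and columns of ``d_b``
    simultaneously; the one-tailed p-value (positive association) is
    computed on z with the inclusive (1 + ...) estimator.
    """
    d_a = np.asarray(d_a, dtype=float)
    d_b = np.asarray(d_b, dtype=float)
    if d_a.shape != d_b.shape or d_a.ndim != 2 or d_a.shape[0] != d_a.shape[1]:
        raise ValidationError("distance matrices must be square and same shape")
    n = d_a.shape[0]
    if n < 4:
        raise ValidationError("Mantel test needs at least 4 taxa")
    if permutations < 99:
        raise ParameterError("use at least 99 permutations")
    iu = np.triu_indices(n, k=1)
    va, vb = d_a[iu], d_b[iu]
    z_obs = float(va @ vb)
    if va.std() == 0 or vb.std() == 0:
        r = None  # constant matrix: correlation undefined, z still meaningful
    else:
        r = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        z_perm = float(va @ d_b[np.ix_(perm, perm)][iu])
        if z_perm >= z_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + permutations)
    return MantelResult(z=z_obs, r=r, p=p, permutations=permutations, seed=seed)


def mantel_test_exact(d_a: np.ndarray, d_b: np.ndarray) -> tuple[float, float]:
    """Exact Mantel p by full enumeration of all n! relabelings (n <= 7).

    Returns (z, p). The observed identity permutation is part of the null
    set, so p matches the inclusive permutation estimator in the limit.
    """
    from itertools import permutations as iperm

    d_a = np.asarray(d_a, dtype=float)
    d_b = np.asarray(d_b, dtype=float)
    n = d_a.shape[0]
    if n > 7:
        raise ParameterError("exact enumeration limited to 7 taxa")
    iu = np.triu_indices(n, k=1)
    va = d_a[iu]
    z_obs = float(va @ d_b[iu])
    count = 0
    total = 0
    for perm in iperm(range(n)):
        z = float(va @ d_b[np.ix_(perm, perm)][iu])
        total += 1
        if z >= z_obs - 1e-12:
            count += 1
    return z_obs, count / total


# ---------------------------------------------------------------------- #
# PCA of binary tip data
# ---------------------------------------------------------------------- #


def first_principal_component(m: TraitMatrix) -> np.ndarray:
    """Per-taxon scores on the first principal component of the binary data.

    Missing entries are imputed by the character mean; columns are mean
    centred; the sign is fixed so the largest-magnitude character loading is
    positive, making scores reproducible across runs.
    """
    if m.n_taxa < 2 or m.n_characters < 2:
        raise DegenerateInputError("PCA needs at least 2 taxa and 2 characters")
    X = m.states.astype(float)
    X[X < 0] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[1]]
    X = X - X.mean(axis=0)
    if not np.any(X):
        raise DegenerateInputError("zero-variance matrix has no principal component")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    loadings = Vt[0]
    sign = 1.0 if loadings[np.argmax(np.abs(loadings))] >= 0 else -1.0
    return sign * U[:, 0] * s[0]


# ---------------------------------------------------------------------- #
# Blomberg's K
# ---------------------------------------------------------------------- #


def _tip_covariance(tree: TimeTree, taxa: Sequence[str]) -> np.ndarray:
    """Brownian-motion tip covariance: shared root-to-MRCA path length.

    Computed directly from the (possibly non-ultrametric) tree; entry (i, i)
    is the root-to-tip path length.
    """
    tips = {lab: tree.find_tip(lab) for lab in taxa}
    paths = {}
    for lab, tip in tips.items():
        path = []
        node = tip
        while node is not None:
            path.append(node)
            node = node.parent
        paths[lab] = path
    root_age = tree.root.age
    n = len(taxa)
    V = np.zeros((n, n))
    for i, a in enumerate(taxa):
        anc = {id(nd) for nd in paths[a]}
        V[i, i] = root_age - tips[a].age
        for j in range(i + 1, n):
            node = tips[taxa[j]]
            while id(node) not in anc:
                node = node.parent
            V[i, j] = V[j, i] = root_age - node.age
    return V


def blomberg_k(tree: TimeTree, x: dict[str, float] | Sequence[float], taxa: Sequence[str] | None = None) -> float:
    """Blomberg's K for a continuous trait on a tree.

    K = (MSE0/MSE) / E[MSE0/MSE], where MSE0 is the variance of the trait
    around the phylogenetically GLS-estimated ancestral mean, MSE is the
    error variance under the tree's Brownian covariance V, and the
    expectation E[MSE0/MSE] = (tr(V) - n / sum(V^-1)) / (n - 1) is the
    value implied by Brownian motion on that tree.
    """
    if isinstance(x, dict):
        taxa = list(x.keys())
        vec = np.array([x[t] for t in taxa], dtype=float)
    else:
        if taxa is None:
            raise ParameterError("taxa order required when x is a plain sequence")
        vec = np.asarray(x, dtype=float)
    n = len(vec)
    if n < 4:
        raise ValidationError("Blomberg's K needs at least 4 tips")
    if np.ptp(vec) == 0:
        raise DegenerateInputError("constant trait: K is undefined")
    if tree.depth <= 0:
        raise DegenerateInputError("zero-depth tree")
    V = _tip_covariance(tree, taxa)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise ParameterError(
            f"singular tip covariance (condition ~{np.linalg.cond(V):.3g})"
        ) from exc
    ones = np.ones(n)
    denom = ones @ Vinv @ ones
    a_hat = float(ones @ Vinv @ vec / denom)
    dev = vec - a_hat
    mse0 = float(dev @ dev) / (n - 1)
    mse = float(dev @ Vinv @ dev) / (n - 1)
    observed = mse0 / mse
    expected = (np.trace(V) - n / denom) / (n - 1)
    return float(observed / expected)


def k_over_posterior(
    trees: Sequence[TimeTree],
    x: dict[str, float],
    permutations: int = 999,
    seed: int = 0,
    component: int = 1,
) -> SignalResult:
    """Mean Blomberg's K over posterior trees with a tip-shuffle null.

    The same label shuffles are applied across all trees, and the null
    statistic is the shuffled mean K, so p answers: could a random
    assignment of these values to tips show this much average signal?
    """
    trees = list(trees)
    if not trees:
        raise ValidationError("empty tree list")
    taxa = list(x.keys())
    values = np.array([x[t] for t in taxa], dtype=float)
    # tip covariances depend only on the trees: precompute once and reuse
    # for every permutation of the trait values
    machinery = []
    for t in trees:
        if set(taxa) != set(t.tip_labels):
            t = prune_tips(t, set(taxa))
        V = _tip_covariance(t, taxa)
        Vinv = np.linalg.inv(V)
        ones = np.ones(len(taxa))
        denom = float(ones @ Vinv @ ones)
        expected = (np.trace(V) - len(taxa) / denom) / (len(taxa) - 1)
        machinery.append((Vinv, denom, expected))

    def mean_k(vec: np.ndarray) -> float:
        ks = []
        for Vinv, denom, expected in machinery:
            a_hat = float(Vinv.sum(axis=0) @ vec / denom)
            dev = vec - a_hat
            mse0 = float(dev @ dev)
            mse = float(dev @ Vinv @ dev)
            ks.append((mse0 / mse) / expected)
        return float(np.mean(ks))

    k_obs = mean_k(values)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(len(values))
        if mean_k(values[perm]) >= k_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + permutations)
    return SignalResult(
        k_mean=k_obs,
        p=p,
        n_trees=len(trees),
        permutations=permutations,
        seed=seed,
        component=component,
    )
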