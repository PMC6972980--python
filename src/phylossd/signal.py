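"""Phylogenetic signal statistics for species-level traits.

Implements four indices of phylogenetic signal — Moran's I on inverse
patristic distances, Abouheif's C_mean, Blomberg's K, and Pagel's lambda —
together with seeded trait-permutation significance tests and distance-class
correlograms.

Moran's I here is the spatial autocorrelation statistic transplanted to a
tree: with weights w_ij = 1/d_ij (d_ij the patristic distance between tips
i and j),

    I = (n / sum_ij w_ij) * sum_ij w_ij (y_i - ybar)(y_j - ybar)
                          / sum_i (y_i - ybar)^2 .

Positive I means closely related species have similar trait values (for an
SSD: similar sensitivities); the permutation null shuffles trait values
across tips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .data_io import DistanceMatrix, PhyloTree, ValidationError, cophenetic_matrix

__all__ = [
    "WeightMatrix",
    "SignalResult",
    "CorrelogramResult",
    "weights_from_distances",
    "morans_i",
    "morans_i_expectation",
    "permutation_test",
    "morans_i_test",
    "abouheif_proximity",
    "abouheif_cmean",
    "bm_covariance",
    "blomberg_k",
    "pagel_lambda",
    "correlogram",
]

Alternative = Literal["greater", "less", "two-sided"]


@dataclass
class WeightMatrix:
    """Nonnegative symmetric weights with a zero diagonal, in tip order."""

    labels: list[str]
    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        n = len(self.labels)
        if self.w.shape != (n, n):
            raise ValidationError("weight matrix shape does not match labels")
        if not np.all(np.isfinite(self.w)):
            raise ValidationError("weight matrix has non-finite entries")
        if np.any(np.diag(self.w) != 0):
            raise ValidationError("weight matrix diagonal must be zero")


@dataclass
class SignalResult:
    """One signal index with its permutation significance."""

    index_name: str
    value: float
    p_value: float
    n_perm: int
    seed: int
    alternative: str

    def to_dict(self) -> dict:
        return {
            "index": self.index_name,
            "value": self.value,
            "p": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "alternative": self.alternative,
        }


def weights_from_distances(
    D: DistanceMatrix, zero_policy: Literal["error", "epsilon"] = "error"
) -> WeightMatrix:
    """Inverse-distance weights w_ij = 1/d_ij, zero diagonal.

    A zero patristic distance between distinct tips makes 1/d undefined; the
    default policy is a hard error. ``zero_policy='epsilon'`` instead
    replaces offending distances by (min positive distance) * 1e-6.
    """
    d = D.d.copy()
    off = ~np.eye(D.n, dtype=bool)
    zeros = off & (d == 0)
    if zeros.any():
        if zero_policy == "error":
            pairs = [
                (D.labels[i], D.labels[j])
                for i, j in zip(*np.nonzero(zeros))
                if i < j
            ]
            raise ValidationError(
                f"zero patristic distance between distinct tips: {pairs}; "
                "use zero_policy='epsilon' to replace"
            )
        eps = d[off & (d > 0)].min() * 1e-6
        d[zeros] = eps
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]
    return WeightMatrix(list(D.labels), w)


def _centered(traits: Sequence[float]) -> np.ndarray:
    y = np.asarray(traits, dtype=float)
    if y.ndim != 1:
        raise ValidationError("traits must be a 1-D vector")
    z = y - y.mean()
    if not np.any(z != 0):
        raise ValidationError("zero trait variance: signal index undefined")
    return z


def morans_i(traits: Sequence[float], W: WeightMatrix | np.ndarray) -> float:
    """Moran's I of a trait vector under a pairwise weight matrix.

    ``traits`` must be aligned to the weight-matrix tip order. The index is
    invariant to affine trait transforms and to global rescaling of the
    weights (both cancel in the ratio).
    """
    w = W.w if isinstance(W, WeightMatrix) else np.asarray(W, dtype=float)
    z = _centered(traits)
    n = z.size
    if w.shape != (n, n):
        raise ValidationError("traits not aligned to weight matrix")
    s0 = w.sum()
    return float(n / s0 * (z @ w @ z) / (z @ z))


def morans_i_expectation(n: int) -> float:
    """Analytic null expectation E[I] = -1/(n-1). Diagnostic only."""
    return -1.0 / (n - 1)


def _moran_batch(Z: np.ndarray, w: np.ndarray) -> np.ndarray:
    # Z: (n, B) columns of centered traits; returns I per column.
    s0 = w.sum()
    n = Z.shape[0]
    num = np.einsum("ib,ib->b", Z, w @ Z)
    den = np.einsum("ib,ib->b", Z, Z)
    return n / s0 * num / den


def _p_from_null(obs: float, null: np.ndarray, alternative: str) -> float:
    """Add-one permutation p-value; p >= 1/(n_perm+1) by construction."""
    B = null.size
    if alternative == "greater":
        k = int(np.sum(null >= obs))
    elif alternative == "less":
        k = int(np.sum(null <= obs))
    elif alternative == "two-sided":
        center = float(np.median(null))
        k = int(np.sum(np.abs(null - center) >= abs(obs - center)))
    else:
        raise ValidationError(
            f"unknown alternative {alternative!r}; use greater/less/two-sided"
        )
    return (1 + k) / (B + 1)


def permutation_test(
    traits: Sequence[float],
    statistic: Callable[[np.ndarray], float],
    *,
    index_name: str,
    n_perm: int = 999,
    seed: int = 0,
    alternative: Alternative = "greater",
) -> SignalResult:
    """Seeded trait-permutation test for any scalar signal statistic.

    The observed statistic is compared with its distribution over random
    reassignments of trait values to tips. The add-one estimator
    p = (1 + #{stat_perm >= stat_obs}) / (n_perm + 1) never drops below
    1/(n_perm+1). Reproducible bit-for-bit given (seed, n_perm).
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    y = np.asarray(traits, dtype=float)
    _centered(y)  # validates variance
    obs = float(statistic(y))
    rng = np.random.default_rng(seed)
    # same permutation construction as the vectorized Moran path, so the two
    # engines agree bit-for-bit at equal (seed, n_perm)
    perm = np.argsort(rng.random((n_perm, y.size)), axis=1)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = statistic(y[perm[b]])
    p = _p_from_null(obs, null, alternative)
    return SignalResult(index_name, obs, p, n_perm, seed, alternative)


def morans_i_test(
    traits: Sequence[float],
    W: WeightMatrix,
    *,
    n_perm: int = 999,
    seed: int = 0,
    alternative: Alternative = "greater",
) -> SignalResult:
    """Permutation test for Moran's I (vectorized over permutations)."""
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    z = _centered(traits)
    n = z.size
    if W.w.shape != (n, n):
        raise ValidationError("traits not aligned to weight matrix")
    obs = morans_i(traits, W)
    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_perm, n)), axis=1)  # rows are permutations
    Z = z[perm].T  # (n, B)
    null = _moran_batch(Z, W.w)
    p = _p_from_null(obs, null, alternative)
    return SignalResult("moran_i", obs, p, n_perm, seed, alternative)


# --- Abouheif's C_mean ------------------------------------------------------

def abouheif_proximity(tree: PhyloTree) -> WeightMatrix:
    """Abouheif proximity matrix.

    For each pair of tips, the proximity is the product of 1/(number of
    direct descendants) over the internal nodes on the path between them
    (the two tips excluded, the MRCA included). Rows are normalized to sum
    to one. No branch lengths are used — the index depends on topology only.
    """
    labels = tree.tips
    n = len(labels)
    t = tree.tree
    # path to root for every leaf, as node lists
    leaves = {leaf.taxon.label: leaf for leaf in t.leaf_node_iter()}
    anc: dict[str, list] = {}
    for lab, leaf in leaves.items():
        chain = []
        node = leaf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        anc[lab] = chain
    ndesc = {}
    for node in t.preorder_node_iter():
        ndesc[node] = len(node.child_nodes())
    a = np.zeros((n, n))
    for i in range(n):
        ai = anc[labels[i]]
        seti = {id(x) for x in ai}
        for j in range(i + 1, n):
            aj = anc[labels[j]]
            mrca = next(x for x in aj if id(x) in seti)
            path_internals = (
                [x for x in ai[1:] if x is not mrca and id(x) not in {id(y) for y in aj}]
                + [x for x in aj[1:] if x is not mrca and id(x) not in seti]
                + [mrca]
            )
            prod = 1.0
            for node in path_internals:
                prod /= ndesc[node]
            a[i, j] = a[j, i] = prod
    rowsums = a.sum(axis=1, keepdims=True)
    a = a / rowsums
    a = (a + a.T) / 2  # symmetrize after row normalization
    return WeightMatrix(labels, a)


def abouheif_cmean(traits: Sequence[float], tree: PhyloTree) -> float:
    """Abouheif's C_mean: Moran's I under the Abouheif proximity matrix."""
    return morans_i(traits, abouheif_proximity(tree))


# --- Brownian-motion covariance and model-based indices ---------------------

def bm_covariance(tree: PhyloTree) -> np.ndarray:
    """Brownian-motion trait covariance implied by the tree.

    C[i, j] is the shared path length from the root to the MRCA of tips i
    and j; C[i, i] is the root-to-tip depth. Under BM with rate sigma^2 the
    tip traits are multivariate normal with covariance sigma^2 * C.
    """
    labels = tree.tips
    n = len(labels)
    t = tree.tree
    depth: dict[int, float] = {id(t.seed_node): 0.0}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    leaves = {leaf.taxon.label: leaf for leaf in t.leaf_node_iter()}
    anc: dict[str, dict[int, float]] = {}
    for lab, leaf in leaves.items():
        chain: dict[int, float] = {}
        node = leaf
        while node is not None:
            chain[id(node)] = depth[id(node)]
            node = node.parent_node
        anc[lab] = chain
    C = np.zeros((n, n))
    for i in range(n):
        ci = anc[labels[i]]
        C[i, i] = depth[id(leaves[labels[i]])]
        for j in range(i + 1, n):
            cj = anc[labels[j]]
            mrca_depth = max(d for k, d in ci.items() if k in cj)
            C[i, j] = C[j, i] = mrca_depth
    return C


def blomberg_k(traits: Sequence[float], tree: PhyloTree) -> float:
    """Blomberg's K: observed vs Brownian-expected signal strength.

    K = (MSE0/MSE) / E[MSE0/MSE | BM], where MSE0 is the trait mean squared
    error about the phylogenetically corrected mean and MSE the GLS mean
    squared error under the BM covariance C. K = 1 is the BM expectation;
    K > 1 means more signal than BM predicts, K -> 0 none.
    """
    y = np.asarray(traits, dtype=float)
    _centered(y)
    C = bm_covariance(tree)
    n = y.size
    if C.shape != (n, n):
        raise ValidationError("traits not aligned to tree tips")
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    ahat = (ones @ Cinv @ y) / (ones @ Cinv @ ones)
    resid = y - ahat
    mse0 = (resid @ resid) / (n - 1)
    mse = (resid @ Cinv @ resid) / (n - 1)
    expected = (np.trace(C) - n / (ones @ Cinv @ ones)) / (n - 1)
    return float((mse0 / mse) / expected)


def _lambda_covariance(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def _gls_loglik(y: np.ndarray, C: np.ndarray) -> float:
    n = y.size
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            f"singular covariance (condition number {np.linalg.cond(C):.3g})"
        ) from exc
    logdet = 2.0 * np.log(np.diag(L)).sum()
    Cinv_y = np.linalg.solve(C, y)
    Cinv_1 = np.linalg.solve(C, np.ones(n))
    mu = (np.ones(n) @ Cinv_y) / (np.ones(n) @ Cinv_1)
    r = y - mu
    sigma2 = (r @ np.linalg.solve(C, r)) / n
    return float(-0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n))


def _lambda_upper_bound(C: np.ndarray) -> float:
    # largest lambda keeping the scaled covariance positive-definite
    lo, hi = 1.0, 1.0
    def ok(lam: float) -> bool:
        try:
            np.linalg.cholesky(_lambda_covariance(C, lam))
            return True
        except np.linalg.LinAlgError:
            return False
    if not ok(1.0):
        return 1.0
    while ok(hi * 2) and hi < 16:
        hi *= 2
    hi *= 2
    for _ in range(40):
        mid = (lo + hi) / 2
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return lo


def pagel_lambda(
    traits: Sequence[float], tree: PhyloTree, lambda_max: float | None = None
) -> tuple[float, float, float]:
    """Maximum-likelihood Pagel's lambda with a boundary-aware LRT.

    Lambda scales the off-diagonal entries of the BM covariance: lambda = 0
    is an iid (star) model, lambda = 1 pure BM. The MLE is found by bounded
    scalar search on [0, lambda_max], where lambda_max (found numerically,
    and slightly above 1 for most ultrametric trees) keeps the covariance
    positive-definite. The likelihood-ratio test against lambda = 0 uses the
    50:50 mixture chi2_0/chi2_1 null appropriate at a boundary.

    Returns (lambda_hat, log-likelihood at the MLE, LRT p-value).
    """
    y = np.asarray(traits, dtype=float)
    _centered(y)
    C = bm_covariance(tree)
    if C.shape[0] != y.size:
        raise ValidationError("traits not aligned to tree tips")
    if lambda_max is None:
        lambda_max = _lambda_upper_bound(C)

    def nll(lam: float) -> float:
        return -_gls_loglik(y, _lambda_covariance(C, lam))

    res = optimize.minimize_scalar(
        nll, bounds=(0.0, lambda_max), method="bounded",
        options={"xatol": 1e-8},
    )
    # polish the boundaries (the bounded search never lands exactly on them)
    # and break likelihood ties toward the smaller, simpler lambda — on a
    # star tree the profile is exactly flat and lambda = 0 is the answer
    candidates = [(float(res.x), -float(res.fun))]
    for lam_edge in (0.0, lambda_max):
        candidates.append((lam_edge, _gls_loglik(y, _lambda_covariance(C, lam_edge))))
    ll_best = max(ll for _, ll in candidates)
    lam_hat, ll_hat = min(
        (c for c in candidates if c[1] >= ll_best - 1e-9), key=lambda c: c[0]
    )
    ll0 = _gls_loglik(y, _lambda_covariance(C, 0.0))
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = 0.5 * stats.chi2.sf(lr, df=1) + (0.5 if lr <= 1e-12 else 0.0)
    return lam_hat, ll_hat, float(p)


# --- Correlogram ------------------------------------------------------------

@dataclass
class CorrelogramResult:
    """Moran's I per phylogenetic-distance class with permutation envelopes.

    ``class_flag`` follows the usual correlogram coloring: 'positive' when
    the class I exceeds the upper envelope bound, 'negative' below the lower
    bound, 'none' inside, and 'empty' for classes with fewer than 2 pairs.
    """

    class_bounds: np.ndarray  # (n_classes + 1,) increasing breakpoints
    class_I: np.ndarray
    envelope: np.ndarray  # (n_classes, 2) lower/upper permutation bounds
    class_flag: list[str]
    n_pairs: np.ndarray
    level: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "d_lo": self.class_bounds[:-1],
                "d_hi": self.class_bounds[1:],
                "n_pairs": self.n_pairs,
                "moran_i": self.class_I,
                "env_lo": self.envelope[:, 0],
                "env_hi": self.envelope[:, 1],
                "flag": self.class_flag,
            }
        )


def correlogram(
    traits: Sequence[float],
    D: DistanceMatrix,
    *,
    n_classes: int = 4,
    n_perm: int = 999,
    seed: int = 0,
    level: float = 0.95,
) -> CorrelogramResult:
    """Moran's I within successive patristic-distance classes.

    Classes are equal-frequency (quantile) bins of the off-diagonal
    distances, which avoids empty classes on taxonomy trees with few
    distinct depths. Within a class the weights stay 1/d, masked to pairs
    whose distance falls in the class; the permutation envelope per class is
    the central ``level`` interval of the permuted class I values.
    """
    if n_classes < 2:
        raise ValidationError("need at least 2 distance classes")
    z = _centered(traits)
    n = z.size
    if D.n != n:
        raise ValidationError("traits not aligned to distance matrix")
    off = ~np.eye(n, dtype=bool)
    dvals = D.d[off]
    qs = np.quantile(dvals, np.linspace(0, 1, n_classes + 1))
    qs[0] = 0.0  # classes partition (0, max d]
    qs[-1] = dvals.max()
    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    Z = z[perm].T
    class_I = np.full(n_classes, np.nan)
    envelope = np.full((n_classes, 2), np.nan)
    flags: list[str] = []
    n_pairs = np.zeros(n_classes, dtype=int)
    alpha = 1.0 - level
    for k in range(n_classes):
        lo, hi = qs[k], qs[k + 1]
        in_class = off & (D.d > lo) & (D.d <= hi)
        n_pairs[k] = int(in_class.sum() // 2)
        if n_pairs[k] < 2:
            flags.append("empty")
            continue
        w = np.where(in_class, 1.0 / np.where(D.d == 0, np.inf, D.d), 0.0)
        obs = n / w.sum() * (z @ w @ z) / (z @ z)
        null = _moran_batch(Z, w)
        lo_q, hi_q = np.quantile(null, [alpha / 2, 1 - alpha / 2])
        class_I[k] = obs
        envelope[k] = (lo_q, hi_q)
        if obs > hi_q:
            flags.append("positive")
        elif obs < lo_q:
            flags.append("negative")
        else:
            flags.append("none")
    return CorrelogramResult(qs, class_I, envelope, flags, n_pairs, level)
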