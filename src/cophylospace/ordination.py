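"""Ordination machinery: PCoA, spatial eigenvectors, db-RDA, variance partitioning.

This is the core of the spatially explicit congruence analysis.  A
response distance matrix (one partner's genetic distances) is embedded
by principal coordinates analysis, then regressed on (i) predictor axes
derived from the other partner's genetic distance matrix and (ii) a
subset of Moran's eigenvector maps (MEMs) — orthogonal spatial variables
at decreasing scales built from truncated geographic distances — chosen
by permutation-based forward selection.  Adjusted R² (Ezekiel) values
from the three db-RDA fits are combined into the classic variance
partition: partner-alone [a], spatially structured partner [b],
space-alone [c] and unexplained [d].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import minimum_spanning_tree
from skbio import DistanceMatrix
from sklearn.base import BaseEstimator

__all__ = [
    "PCoA",
    "pcoa",
    "MoranEigenvectorMaps",
    "mem_basis",
    "explanatory_axes",
    "DistanceBasedRDA",
    "dbrda",
    "adjusted_r2",
    "forward_select_mems",
    "VariancePartition",
    "variance_partition",
]

#: relative tolerance (times the leading eigenvalue) below which an
#: eigenvalue is treated as zero
EIG_RTOL = 1e-10


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d * d
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _as_dm(d) -> DistanceMatrix:
    if isinstance(d, DistanceMatrix):
        return d
    raise TypeError(f"expected a skbio.DistanceMatrix, got {type(d).__name__}")


class PCoA(BaseEstimator):
    """Principal coordinates analysis of a distance matrix.

    Gower double-centering of -0.5 * D∘D followed by a symmetric
    eigendecomposition.  Coordinates are the eigenvectors scaled by the
    square roots of their (positive) eigenvalues, so Euclidean distances
    between coordinate rows reproduce a Euclidean-embeddable input
    exactly.

    Parameters
    ----------
    correction : {'none', 'lingoes', 'cailliez'}
        How to handle negative eigenvalues from non-Euclidean inputs.
        With ``'none'`` (default) negative-eigenvalue axes are reported
        in ``eigenvalues_`` but excluded from ``coordinates_``; the two
        corrections add a constant to the (squared) off-diagonal
        distances to make all eigenvalues non-negative.

    Attributes
    ----------
    eigenvalues_ : ndarray, descending (of the analysed, possibly
        corrected, matrix)
    coordinates_ : ndarray (n, k), positive-eigenvalue axes only
    n_negative_ : int, count of negative eigenvalues
    ids_ : tuple of specimen ids
    """

    def __init__(self, correction: str = "none"):
        self.correction = correction

    def fit(self, distance_matrix: DistanceMatrix) -> "PCoA":
        dm = _as_dm(distance_matrix)
        if self.correction not in ("none", "lingoes", "cailliez"):
            raise ValueError(f"unknown correction {self.correction!r}")
        d = dm.data.astype(float)
        n = d.shape[0]
        if n < 2:
            raise ValueError("PCoA needs at least 2 specimens")

        if self.correction != "none":
            c = self._correction_constant(d)
            if c > 0:
                off = ~np.eye(n, dtype=bool)
                d = d.copy()
                if self.correction == "lingoes":
                    d[off] = np.sqrt(d[off] ** 2 + 2.0 * c)
                else:
                    d[off] = d[off] + c

        g = _gower_center(d)
        vals, vecs = eigh(g)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        lead = max(vals[0], 0.0)
        tol = EIG_RTOL * lead if lead > 0 else 0.0
        pos = vals > tol
        if not pos.any():
            raise ValueError("no positive eigenvalues: degenerate distance matrix")
        self.eigenvalues_ = vals
        self.n_negative_ = int((vals < -tol).sum())
        self.coordinates_ = vecs[:, pos] * np.sqrt(vals[pos])
        self.ids_ = tuple(dm.ids)
        return self

    def _correction_constant(self, d: np.ndarray) -> float:
        g = _gower_center(d)
        vals = eigh(g, eigvals_only=True)
        if vals.min() >= 0:
            return 0.0
        if self.correction == "lingoes":
            return float(-vals.min())
        # Cailliez: largest real eigenvalue of the 2n x 2n companion problem
        n = d.shape[0]
        delta2 = -0.5 * d  # centered below
        a = -0.5 * d * d
        j = np.eye(n) - np.ones((n, n)) / n
        d1 = j @ a @ j
        d2 = j @ delta2 @ j
        block = np.block(
            [[np.zeros((n, n)), 2.0 * d1], [-np.eye(n), -4.0 * d2]]
        )
        ev = np.linalg.eigvals(block)
        return float(np.max(ev.real))


def pcoa(distance_matrix: DistanceMatrix, correction: str = "none") -> PCoA:
    """Fit :class:`PCoA` and return the fitted estimator."""
    return PCoA(correction=correction).fit(distance_matrix)


# ---------------------------------------------------------------------------
# Moran's eigenvector maps


class MoranEigenvectorMaps(BaseEstimator):
    """Spatial eigenvector basis (MEM / PCNM) from geographic distances.

    Distances above the truncation threshold ``t`` are replaced by
    ``4 t``; the truncated matrix is analysed by PCoA and the
    positive-eigenvalue eigenvectors (unit norm, centered) are retained
    as spatial predictors.  MEM 1 describes the broadest spatial scale;
    there are at most n - 1 MEMs.

    Parameters
    ----------
    truncation : float or None
        Threshold in the units of the input matrix (metres for
        geographic distances).  ``None`` (default) uses the longest edge
        of a minimum spanning tree over the points, the standard rule
        that keeps every site connected.

    Attributes
    ----------
    vectors_ : ndarray (n, m), orthonormal centered eigenvectors
    eigenvalues_ : ndarray (m,), descending positive eigenvalues
    truncation_ : float, the threshold actually used
    indices_ : ndarray of 1-based MEM numbers (1 = broadest scale)
    """

    def __init__(self, truncation: float | None = None):
        self.truncation = truncation

    def fit(self, geographic_distances: DistanceMatrix) -> "MoranEigenvectorMaps":
        dm = _as_dm(geographic_distances)
        d = dm.data.astype(float)
        n = d.shape[0]
        off = d[~np.eye(n, dtype=bool)]
        if off.size == 0 or np.all(off == 0):
            raise ValueError("all points coincident: no spatial structure representable")
        if self.truncation is None:
            mst = minimum_spanning_tree(d)
            t = float(mst.data.max())
        else:
            t = float(self.truncation)
            if t <= 0:
                raise ValueError("truncation must be positive")
        dstar = np.where(d <= t, d, 4.0 * t)
        np.fill_diagonal(dstar, 0.0)

        g = _gower_center(dstar)
        vals, vecs = eigh(g)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        tol = EIG_RTOL * max(vals[0], 0.0)
        pos = vals > tol
        if not pos.any():
            raise ValueError("no positive MEM eigenvalues")
        self.vectors_ = vecs[:, pos]
        self.eigenvalues_ = vals[pos]
        self.truncation_ = t
        self.indices_ = np.arange(1, int(pos.sum()) + 1)
        self.ids_ = tuple(dm.ids)
        return self


def mem_basis(
    geographic_distances: DistanceMatrix, truncation: float | None = None
) -> MoranEigenvectorMaps:
    """Fit :class:`MoranEigenvectorMaps` and return the fitted estimator."""
    return MoranEigenvectorMaps(truncation=truncation).fit(geographic_distances)


# ---------------------------------------------------------------------------
# predictors from a distance matrix


def explanatory_axes(
    distance_matrix: DistanceMatrix, rule: str | int = "positive"
) -> np.ndarray:
    """PCoA axes of a distance matrix for use as db-RDA predictors.

    ``rule`` is ``'positive'`` (all positive-eigenvalue axes, default),
    ``'cum95'`` (smallest axis set covering at least 95% of the positive
    inertia) or an integer k (first k axes).
    """
    ord_ = pcoa(distance_matrix)
    coords = ord_.coordinates_
    if isinstance(rule, (int, np.integer)) and not isinstance(rule, bool):
        k = int(rule)
        if k < 1:
            raise ValueError("axis retention k must be >= 1")
        k = min(k, coords.shape[1])
        return coords[:, :k]
    if rule == "positive":
        return coords
    if rule == "cum95":
        lam = ord_.eigenvalues_[: coords.shape[1]]
        shares = np.cumsum(lam) / lam.sum()
        k = int(np.searchsorted(shares, 0.95 - 1e-12) + 1)
        return coords[:, :k]
    raise ValueError(f"unknown axis retention rule {rule!r}")


# ---------------------------------------------------------------------------
# distance-based redundancy analysis


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel's adjusted R²: 1 - (1 - R²)(n - 1)/(n - m - 1)."""
    if m == 0:
        return float(r2)
    if n <= m + 1:
        raise ValueError(f"adjusted R² undefined for n={n}, m={m} (n must exceed m+1)")
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - m - 1))


def _orthonormal_basis(x: np.ndarray, warn: bool = True) -> np.ndarray:
    """Orthonormal basis of the column space of the centered predictors.

    Collinear columns are dropped (with a warning) via pivoted QR.
    """
    xc = x - x.mean(axis=0, keepdims=True)
    if xc.shape[1] == 0:
        return xc
    # SVD rather than QR: rank detection on an unpivoted QR diagonal is unsafe
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    tol = s[0] * max(xc.shape) * np.finfo(float).eps if s.size and s[0] > 0 else 0.0
    rank = int((s > tol).sum())
    if rank < xc.shape[1] and warn:
        warnings.warn(
            f"dropping {xc.shape[1] - rank} collinear predictor column(s)",
            stacklevel=3,
        )
    return u[:, :rank]


class DistanceBasedRDA(BaseEstimator):
    """Distance-based redundancy analysis with a permutation test.

    The response distance matrix is embedded by PCoA (positive axes);
    the coordinates are projected onto the column space of the centered
    predictors.  R² is the constrained fraction of total inertia,
    adjusted by the Ezekiel formula, and the pseudo-F statistic is
    tested by permuting response rows.

    Parameters
    ----------
    n_permutations : int
        Number of row permutations for the test (0 skips the test).
    random_state : int or numpy Generator or None

    Attributes
    ----------
    r2_, adj_r2_, f_statistic_, p_value_ : floats
    n_features_ : int, predictor rank actually used
    n_samples_ : int
    """

    def __init__(self, n_permutations: int = 999, random_state=None):
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, response_distances: DistanceMatrix, X: np.ndarray) -> "DistanceBasedRDA":
        dm = _as_dm(response_distances)
        x = np.asarray(X, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        n = dm.shape[0]
        if x.shape[0] != n:
            raise ValueError(f"predictor rows ({x.shape[0]}) != specimens ({n})")
        q = _orthonormal_basis(x)
        m = q.shape[1]
        if m == 0:
            raise ValueError("predictor matrix has rank 0")
        if m >= n - 1:
            raise ValueError(f"saturated model: {m} predictors for {n} specimens")

        y = pcoa(dm).coordinates_  # column-centered by construction
        total = float((y * y).sum())
        proj = q.T @ y
        r2 = float((proj * proj).sum() / total)
        self.r2_ = r2
        self.adj_r2_ = adjusted_r2(r2, n, m)
        resid = 1.0 - r2
        self.f_statistic_ = (r2 / m) / (resid / (n - m - 1)) if resid > 0 else np.inf
        self.n_features_ = m
        self.n_samples_ = n
        self.ids_ = tuple(dm.ids)

        if self.n_permutations and self.n_permutations > 0:
            rng = np.random.default_rng(self.random_state)
            count = 0
            for _ in range(int(self.n_permutations)):
                yp = y[rng.permutation(n)]
                pr = q.T @ yp
                r2p = float((pr * pr).sum() / total)
                if r2p >= r2 - 1e-12:
                    count += 1
            self.p_value_ = (count + 1) / (int(self.n_permutations) + 1)
        else:
            self.p_value_ = np.nan
        return self


def dbrda(
    response_distances: DistanceMatrix,
    X: np.ndarray,
    n_permutations: int = 999,
    seed=None,
) -> DistanceBasedRDA:
    """Fit :class:`DistanceBasedRDA` and return the fitted estimator."""
    return DistanceBasedRDA(n_permutations=n_permutations, random_state=seed).fit(
        response_distances, X
    )


# ---------------------------------------------------------------------------
# forward selection of MEMs


def forward_select_mems(
    response_distances: DistanceMatrix,
    basis: MoranEigenvectorMaps,
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed=None,
) -> list[int]:
    """Greedy forward selection of spatial eigenvectors.

    At each step every remaining MEM is tested by the permutation
    p-value of its partial pseudo-F given the MEMs already selected
    (response rows permuted, the same draws shared by all candidates of
    a step).  The candidate with the lowest p enters (ties broken by
    larger added R², then lower MEM index); selection stops when no
    candidate reaches ``p <= alpha``.  Returns 1-based MEM indices in
    selection order; an empty list is a legal result.
    """
    dm = _as_dm(response_distances)
    if tuple(dm.ids) != tuple(basis.ids_):
        raise KeyError("MEM basis labels do not match the response matrix")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    vectors = basis.vectors_
    n, n_mem = vectors.shape
    y = pcoa(dm).coordinates_
    total = float((y * y).sum())
    rng = np.random.default_rng(seed)

    selected: list[int] = []          # 0-based columns
    q_sel = np.empty((n, 0))          # orthonormal basis of selected block
    r2_cur = 0.0
    n_perm = int(n_permutations)

    while len(selected) < min(n_mem, n - 2):
        remaining = [j for j in range(n_mem) if j not in selected]
        if not remaining:
            break
        # orthogonal complements of each candidate w.r.t. selected block
        cand = vectors[:, remaining]
        cand = cand - cand.mean(axis=0, keepdims=True)
        if q_sel.shape[1]:
            cand = cand - q_sel @ (q_sel.T @ cand)
        norms = np.linalg.norm(cand, axis=0)
        ok = norms > 1e-10
        if not ok.any():
            break
        cand = cand[:, ok] / norms[ok]
        rem = [r for r, keep in zip(remaining, ok) if keep]
        m_new = q_sel.shape[1] + 1
        df_resid = n - m_new - 1
        if df_resid < 1:
            break

        base_obs = float(((q_sel.T @ y) ** 2).sum()) if q_sel.shape[1] else 0.0
        add_obs = ((cand.T @ y) ** 2).sum(axis=1)
        r2_new_obs = (base_obs + add_obs) / total
        f_obs = (r2_new_obs - r2_cur) / ((1.0 - r2_new_obs) / df_resid)

        exceed = np.zeros(len(rem), dtype=int)
        for _ in range(n_perm):
            yp = y[rng.permutation(n)]
            base_p = float(((q_sel.T @ yp) ** 2).sum()) if q_sel.shape[1] else 0.0
            tot_p = total  # permutation of rows preserves total inertia
            add_p = ((cand.T @ yp) ** 2).sum(axis=1)
            r2_new_p = (base_p + add_p) / tot_p
            f_p = (r2_new_p - base_p / tot_p) / ((1.0 - r2_new_p) / df_resid)
            exceed += f_p >= f_obs - 1e-12
        pvals = (exceed + 1) / (n_perm + 1)

        best_p = pvals.min()
        if best_p > alpha:
            break
        ties = np.flatnonzero(pvals == best_p)
        if ties.size > 1:
            gains = add_obs[ties]
            ties = ties[gains == gains.max()]
        # remaining is index-ordered, so the first tie has the lowest MEM index
        pick = int(ties[0])
        j = rem[pick]
        selected.append(j)
        q_sel = np.hstack([q_sel, cand[:, [pick]]])
        r2_cur = float(r2_new_obs[pick])

    return [int(j) + 1 for j in selected]


# ---------------------------------------------------------------------------
# variance partitioning


@dataclass(frozen=True)
class VariancePartition:
    """Adjusted-R² variance partition of a response distance matrix.

    ``a`` partner-alone, ``b`` spatially structured partner (shared),
    ``c`` space-alone, ``d`` unexplained.  Fractions sum to 1; a, b, c
    may be slightly negative (an adjusted-R² artifact) and are reported
    raw — :meth:`clamped` gives the display version with negatives set
    to zero.  ``has_space`` is False when no spatial block was supplied,
    in which case b = c = 0 and a is the partner-alone adjusted R².
    """

    a: float
    b: float
    c: float
    d: float
    has_space: bool = True

    def clamped(self) -> tuple[float, float, float, float]:
        a, b, c = (max(v, 0.0) for v in (self.a, self.b, self.c))
        return a, b, c, self.d


def variance_partition(
    response_distances: DistanceMatrix,
    partner_X: np.ndarray,
    space_X: np.ndarray | None = None,
) -> VariancePartition:
    """Partition response variation between partner and space predictor blocks.

    With A, B, AB the adjusted R² of the partner block, the space block
    and their union: a = AB - B, b = A + B - AB, c = AB - A,
    d = 1 - AB.  An empty spatial block reduces to a single adjusted R²
    (a = A, b = c = 0, d = 1 - A).
    """
    dm = _as_dm(response_distances)
    px = np.asarray(partner_X, dtype=float)
    if px.ndim == 1:
        px = px[:, None]
    if space_X is None or np.size(space_X) == 0:
        fit = dbrda(dm, px, n_permutations=0)
        a = fit.adj_r2_
        return VariancePartition(a=a, b=0.0, c=0.0, d=1.0 - a, has_space=False)
    sx = np.asarray(space_X, dtype=float)
    if sx.ndim == 1:
        sx = sx[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a_adj = dbrda(dm, px, n_permutations=0).adj_r2_
        b_adj = dbrda(dm, sx, n_permutations=0).adj_r2_
        ab_adj = dbrda(dm, np.hstack([px, sx]), n_permutations=0).adj_r2_
    return VariancePartition(
        a=ab_adj - b_adj,
        b=a_adj + b_adj - ab_adj,
        c=ab_adj - a_adj,
        d=1.0 - ab_adj,
        has_space=True,
    )
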