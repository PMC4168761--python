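"""Procrustes approach to co-phylogeny (PACo).

Both partner distance matrices are embedded by PCoA; the fungal
configuration is then translated, uniformly scaled and rotated
(reflections allowed) onto the algal configuration by least squares.
The residual sum of squares m² measures global incongruence: the
smaller m², the stronger the co-diversification signal.  Significance
comes from randomising which fungus is paired with which alga and
recomputing m²; the per-specimen squared residuals show which specimens
fit the co-diversification pattern worst.

Reflections are part of the admissible transformation family because
PCoA axis signs are arbitrary; excluding them would make the statistic
depend on eigenvector sign conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from sklearn.base import BaseEstimator

from .ordination import pcoa

__all__ = [
    "ProcrustesFit",
    "procrustes_superimpose",
    "PACo",
    "PACoResult",
    "paco_test",
    "residuals_by_trait",
]


@dataclass(frozen=True)
class ProcrustesFit:
    """Least-squares superimposition of configuration Y onto X.

    The fitted transform is ``T(y) = scale * (y - y_mean) @ rotation + x_mean``;
    ``residuals`` are per-row squared residuals ``||x_i - T(y_i)||²`` and
    ``m2`` is their sum.
    """

    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    residuals: np.ndarray
    m2: float


def _pad_columns(x: np.ndarray, k: int) -> np.ndarray:
    if x.shape[1] == k:
        return x
    return np.hstack([x, np.zeros((x.shape[0], k - x.shape[1]))])


def procrustes_superimpose(
    X: np.ndarray, Y: np.ndarray, scale: bool = True
) -> ProcrustesFit:
    """Superimpose Y onto X by translation, rotation and (optionally) scale.

    Rows are paired observations; the narrower configuration is padded
    with zero columns.  The rotation comes from the SVD of Yᵀ X over the
    full orthogonal group, so reflections are admissible.
    """
    x = np.asarray(X, dtype=float)
    y = np.asarray(Y, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"row counts differ: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 paired rows")
    k = max(x.shape[1], y.shape[1])
    x = _pad_columns(x, k)
    y = _pad_columns(y, k)

    x_mean = x.mean(axis=0)
    y_mean = y.mean(axis=0)
    xc = x - x_mean
    yc = y - y_mean
    ynorm2 = float((yc * yc).sum())
    if ynorm2 == 0.0:
        raise ValueError("Y configuration is degenerate (all rows identical)")

    u, sv, vt = np.linalg.svd(yc.T @ xc)
    rotation = u @ vt
    s = float(sv.sum()) / ynorm2 if scale else 1.0
    fitted = s * (yc @ rotation)
    resid = ((xc - fitted) ** 2).sum(axis=1)
    translation = x_mean - s * (y_mean @ rotation)
    return ProcrustesFit(
        rotation=rotation,
        scale=s,
        translation=translation,
        residuals=resid,
        m2=float(resid.sum()),
    )


@dataclass
class PACoResult:
    """Outcome of the association-randomisation congruence test."""

    m2: float
    p_value: float
    n_permutations: int
    residuals: pd.Series
    null_m2: np.ndarray = field(repr=False)
    fit: ProcrustesFit = field(repr=False)


class PACo(BaseEstimator):
    """Procrustean co-phylogeny test on paired distance matrices.

    ``fit(algal_distances, fungal_distances)`` embeds both matrices by
    PCoA (positive axes), superimposes the fungal configuration onto the
    algal one, and builds the null distribution of m² by permuting the
    row pairing of the fungal configuration ``n_permutations`` times.
    The test is one-sided with small m² as evidence of congruence:
    p = (#{m²_perm <= m²_obs} + 1) / (n_permutations + 1).

    Parameters
    ----------
    n_permutations : int, default 10000
        Association randomisations.
    direction : {'fungi-onto-algae', 'algae-onto-fungi'}
        Which configuration is transformed onto which.
    random_state : int or numpy Generator or None

    Attributes
    ----------
    m2_ : observed Procrustes sum of squared residuals
    p_value_ : permutation p-value
    residuals_ : per-specimen squared residuals (pandas Series)
    null_m2_ : the permuted statistics
    """

    def __init__(
        self,
        n_permutations: int = 10_000,
        direction: str = "fungi-onto-algae",
        random_state=None,
    ):
        self.n_permutations = n_permutations
        self.direction = direction
        self.random_state = random_state

    def fit(
        self, algal_distances: DistanceMatrix, fungal_distances: DistanceMatrix
    ) -> "PACo":
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.direction not in ("fungi-onto-algae", "algae-onto-fungi"):
            raise ValueError(f"unknown direction {self.direction!r}")
        ids = tuple(algal_distances.ids)
        if set(ids) != set(fungal_distances.ids):
            missing = sorted(set(ids) ^ set(fungal_distances.ids))
            raise KeyError(f"specimen labels do not match: {missing}")
        fungal_distances = fungal_distances.filter(ids)

        xa = pcoa(algal_distances).coordinates_
        xf = pcoa(fungal_distances).coordinates_
        if self.direction == "fungi-onto-algae":
            x, y = xa, xf
        else:
            x, y = xf, xa

        obs = procrustes_superimpose(x, y)
        n = x.shape[0]
        k = max(x.shape[1], y.shape[1])
        xc = _pad_columns(x, k) - _pad_columns(x, k).mean(axis=0)
        yc = _pad_columns(y, k) - _pad_columns(y, k).mean(axis=0)
        xnorm2 = float((xc * xc).sum())
        ynorm2 = float((yc * yc).sum())

        rng = np.random.default_rng(self.random_state)
        nperm = int(self.n_permutations)
        null = np.empty(nperm)
        for b in range(nperm):
            yp = yc[rng.permutation(n)]
            # permuting rows of a centered matrix keeps columns centered,
            # so m² has the closed form below (optimal scale folded in)
            sv = np.linalg.svd(yp.T @ xc, compute_uv=False)
            null[b] = xnorm2 - (sv.sum() ** 2) / ynorm2
        count = int((null <= obs.m2 + 1e-12).sum())

        self.m2_ = obs.m2
        self.p_value_ = (count + 1) / (nperm + 1)
        self.residuals_ = pd.Series(obs.residuals, index=list(ids), name="r2")
        self.null_m2_ = null
        self.fit_ = obs
        self.ids_ = ids
        return self

    @property
    def result_(self) -> PACoResult:
        return PACoResult(
            m2=self.m2_,
            p_value=self.p_value_,
            n_permutations=int(self.n_permutations),
            residuals=self.residuals_,
            null_m2=self.null_m2_,
            fit=self.fit_,
        )


def paco_test(
    algal_distances: DistanceMatrix,
    fungal_distances: DistanceMatrix,
    n_permutations: int = 10_000,
    seed=None,
    direction: str = "fungi-onto-algae",
) -> PACoResult:
    """Run the PACo congruence test and return a :class:`PACoResult`."""
    est = PACo(
        n_permutations=n_permutations, direction=direction, random_state=seed
    ).fit(algal_distances, fungal_distances)
    return est.result_


def residuals_by_trait(
    result: PACoResult, traits: dict[str, str] | pd.Series | None
) -> pd.DataFrame:
    """Group per-specimen squared residuals by a categorical trait.

    Returns one row per trait group with count, mean and median of the
    squared residuals, plus the share of the group's specimens whose
    residual exceeds the overall median (large residual = poor fit to
    the co-diversification pattern).  Specimens absent from ``traits``
    (or an empty/None map) fall in an ``'unlabelled'`` group; trait keys
    that are not specimens are an error.
    """
    r = result.residuals
    traits = dict(traits) if traits is not None else {}
    unknown = set(traits) - set(r.index)
    if unknown:
        raise KeyError(f"traits given for unknown specimens: {sorted(unknown)}")
    labels = pd.Series(
        [traits.get(s, "unlabelled") for s in r.index], index=r.index, name="trait"
    )
    overall_median = float(r.median())
    df = pd.DataFrame({"r2": r, "trait": labels})
    grouped = df.groupby("trait")["r2"].agg(n="count", mean="mean", median="median")
    grouped["frac_above_overall_median"] = df.groupby("trait")["r2"].apply(
        lambda v: float((v > overall_median).mean())
    )
    grouped.attrs["overall_median"] = overall_median
    return grouped
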