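"""Genetic and geographic distance estimation, and matrix summaries.

Genetic distances come in two flavours: the uncorrected p-distance (the
proportion of compared sites that differ) and the Tamura–Nei 1993 (TN93)
model distance, which distinguishes the two transition classes (A<->G,
C<->T) from transversions under unequal base frequencies.  Sites where
either sequence of a pair carries a gap, ``N`` or an IUPAC ambiguity code
are excluded for that pair (pairwise deletion); complete deletion is
available as an option.

Geographic distances are great-circle (haversine) distances in metres on
a sphere of radius 6,371,000 m — at sampling extents of order 10^6 m the
difference from an ellipsoid is immaterial to the spatial eigenvector
basis built from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .io import UNAMBIGUOUS, AlignedSequenceSet

__all__ = [
    "p_distance",
    "tn93_distance",
    "TN93Result",
    "geographic_distance",
    "haversine_m",
    "summarize_matrix",
    "MatrixSummary",
    "SaturationError",
    "EARTH_RADIUS_M",
]

EARTH_RADIUS_M = 6_371_000.0

# A=0 C=1 G=2 T=3; anything else (gap, N, IUPAC ambiguity) is missing (-1)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


class SaturationError(ValueError):
    """A TN93 logarithm argument was non-positive (saturated pair)."""


def _encode(aln: AlignedSequenceSet) -> np.ndarray:
    """Encode the alignment as an (n, L) int8 array; missing sites are -1."""
    raw = np.frombuffer(
        "".join(aln.sequences).encode("ascii"), dtype=np.uint8
    ).reshape(len(aln), aln.length)
    return _CODE[raw]


def _pair_iter(n: int):
    for i in range(n - 1):
        for j in range(i + 1, n):
            yield i, j


def _complete_mask(codes: np.ndarray) -> np.ndarray:
    return (codes >= 0).all(axis=0)


def p_distance(
    aln: AlignedSequenceSet, deletion: str = "pairwise"
) -> DistanceMatrix:
    """Uncorrected p-distance matrix from an alignment.

    ``d(i, j)`` is the number of differing compared sites divided by the
    number of compared sites.  With ``deletion='pairwise'`` (default) a
    site is compared for a pair when both sequences carry an unambiguous
    base there; ``'complete'`` restricts all pairs to columns where every
    sequence is unambiguous.

    Raises
    ------
    ValueError
        If some pair has no comparable site (the error names the pair).
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"deletion must be pairwise|complete, got {deletion!r}")
    codes = _encode(aln)
    n = len(aln)
    valid = codes >= 0
    if deletion == "complete":
        keep = _complete_mask(codes)
        codes = codes[:, keep]
        valid = valid[:, keep]
    d = np.zeros((n, n))
    for i, j in _pair_iter(n):
        both = valid[i] & valid[j]
        m = int(both.sum())
        if m == 0:
            raise ValueError(
                f"no comparable sites between {aln.specimen_ids[i]!r} "
                f"and {aln.specimen_ids[j]!r}"
            )
        diff = int(((codes[i] != codes[j]) & both).sum())
        d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(d, list(aln.specimen_ids))


@dataclass
class TN93Result:
    """TN93 distances with per-pair estimability flags.

    ``values`` holds NaN where the closed form is inestimable (a log
    argument <= 0, i.e. saturation); those pairs are listed in
    ``inestimable``.  :meth:`to_distance_matrix` refuses to build a
    distance matrix while any pair is flagged, so saturation can never
    silently propagate as NaN.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    inestimable: tuple[tuple[str, str], ...]

    @property
    def any_inestimable(self) -> bool:
        return len(self.inestimable) > 0

    def to_distance_matrix(self) -> DistanceMatrix:
        if self.any_inestimable:
            raise SaturationError(
                f"TN93 distance inestimable for pairs: {list(self.inestimable)}"
            )
        return DistanceMatrix(self.values, list(self.ids))


def _tn93_pair(xi: np.ndarray, xj: np.ndarray, freqs: np.ndarray | None) -> float:
    """Closed-form TN93 distance for one encoded pair (compared sites only)."""
    m = xi.size
    if freqs is None:
        counts = np.bincount(np.concatenate([xi, xj]), minlength=4)
        g = counts / counts.sum()
    else:
        g = freqs
    gA, gC, gG, gT = g
    gR, gY = gA + gG, gC + gT
    diff = xi != xj
    lo = np.minimum(xi, xj)[diff]
    hi = np.maximum(xi, xj)[diff]
    p1 = float(np.sum((lo == 0) & (hi == 2))) / m  # A<->G transitions
    p2 = float(np.sum((lo == 1) & (hi == 3))) / m  # C<->T transitions
    q = float(diff.sum()) / m - p1 - p2            # transversions
    if p1 + p2 + q == 0.0:
        return 0.0

    k1 = 2.0 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2.0 * gC * gT / gY if gY > 0 else 0.0
    k3 = 2.0 * (gR * gY - (gA * gG * gY / gR if gR > 0 else 0.0)
                - (gC * gT * gR / gY if gY > 0 else 0.0))

    d = 0.0
    if k1 > 0.0:
        a1 = 1.0 - p1 / k1 - q / (2.0 * gR)
        if a1 <= 0:
            return np.nan
        d -= k1 * np.log(a1)
    elif p1 > 0:
        return np.nan  # A<->G differences observed but purine product is zero
    if k2 > 0.0:
        a2 = 1.0 - p2 / k2 - q / (2.0 * gY)
        if a2 <= 0:
            return np.nan
        d -= k2 * np.log(a2)
    elif p2 > 0:
        return np.nan
    if gR * gY > 0:
        b = 1.0 - q / (2.0 * gR * gY)
        if b <= 0:
            return np.nan
        d -= k3 * np.log(b)
    elif q > 0:
        return np.nan
    return d


def tn93_distance(
    aln: AlignedSequenceSet,
    deletion: str = "pairwise",
    frequencies: str = "pair",
) -> TN93Result:
    """TN93 model distances from an alignment.

    Base frequencies are estimated per pair from that pair's compared
    sites (default) or globally from all unambiguous sites
    (``frequencies='global'``).  Saturated pairs (any logarithm argument
    <= 0) are flagged inestimable rather than returned as silent NaN.
    """
    if frequencies not in ("pair", "global"):
        raise ValueError(f"frequencies must be pair|global, got {frequencies!r}")
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"deletion must be pairwise|complete, got {deletion!r}")
    codes = _encode(aln)
    if deletion == "complete":
        codes = codes[:, _complete_mask(codes)]
    n = len(aln)
    gfreq = None
    if frequencies == "global":
        flat = codes[codes >= 0]
        gfreq = np.bincount(flat, minlength=4) / flat.size
    d = np.zeros((n, n))
    bad: list[tuple[str, str]] = []
    for i, j in _pair_iter(n):
        both = (codes[i] >= 0) & (codes[j] >= 0)
        if not both.any():
            raise ValueError(
                f"no comparable sites between {aln.specimen_ids[i]!r} "
                f"and {aln.specimen_ids[j]!r}"
            )
        dij = _tn93_pair(codes[i][both], codes[j][both], gfreq)
        if np.isnan(dij):
            bad.append((aln.specimen_ids[i], aln.specimen_ids[j]))
        d[i, j] = d[j, i] = dij
    return TN93Result(tuple(aln.specimen_ids), d, tuple(bad))


# ---------------------------------------------------------------------------
# geographic distance


def haversine_m(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in metres between decimal-degree points."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def geographic_distance(coords: pd.DataFrame) -> DistanceMatrix:
    """Pairwise haversine distance matrix (metres) from a lon/lat table."""
    lon = coords["lon"].to_numpy(dtype=float)
    lat = coords["lat"].to_numpy(dtype=float)
    d = haversine_m(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, [str(s) for s in coords.index])


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class MatrixSummary:
    """Mean/SD/range of the off-diagonal upper-triangle entries."""

    mean: float
    sd: float
    min: float
    max: float
    n_pairs: int


def summarize_matrix(dm: DistanceMatrix) -> MatrixSummary:
    """Summary statistics over unique pairs of a distance matrix.

    The SD is the sample standard deviation (ddof=1, or 0.0 for a single
    pair).  For a geographic matrix the spatial extent is ``max``.
    """
    vals = dm.condensed_form()
    if vals.size == 0:
        raise ValueError("matrix has fewer than 2 specimens")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return MatrixSummary(
        mean=float(np.mean(vals)),
        sd=sd,
        min=float(np.min(vals)),
        max=float(np.max(vals)),
        n_pairs=int(vals.size),
    )
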