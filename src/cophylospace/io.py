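"""Readers, writers and run configuration.

All tabular formats are plain text: FASTA alignments, labelled square
distance matrices (TSV or CSV, full square or triangle-only), and
``specimen_id,lon,lat`` coordinate tables.  The universal in-memory
currency for distances is :class:`skbio.DistanceMatrix`; label order in
the source file defines specimen order everywhere downstream, and joins
between matrices are always by label, never by position.
"""

from __future__ import annotations

import dataclasses
import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix

__all__ = [
    "SpecimenSet",
    "AlignedSequenceSet",
    "RunConfig",
    "read_alignment",
    "write_alignment",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_coordinates",
    "write_coordinates",
    "match_labels",
    "validate_distance_matrix",
]

#: Residues that carry an unambiguous base for distance computation.
UNAMBIGUOUS = set("ACGT")
#: Full legal alphabet in alignments (IUPAC nucleotide codes, gap, N).
ALPHABET = set("ACGTURYSWKMBDHVN-.?")


class AlignmentError(ValueError):
    """Malformed alignment input (ragged lengths, duplicate ids, bad residues)."""


class MatrixFormatError(ValueError):
    """Malformed distance-matrix input."""


@dataclass(frozen=True)
class SpecimenSet:
    """An ordered set of specimen identifiers with optional categorical traits.

    Traits are per-specimen labels such as growth form or the presence of
    apothecia, used for grouping Procrustes residuals.
    """

    specimen_ids: tuple[str, ...]
    traits: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.specimen_ids)
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if list(ids).count(s) > 1})
            raise ValueError(f"duplicate specimen ids: {dupes}")
        object.__setattr__(self, "specimen_ids", ids)
        unknown = set(self.traits) - set(ids)
        if unknown:
            raise ValueError(f"trait keys are not specimen ids: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.specimen_ids)


@dataclass(frozen=True)
class AlignedSequenceSet:
    """An aligned set of nucleotide sequences keyed by specimen id.

    Sequences are stored uppercased; all must have equal length and the
    set must contain at least two records.  Gaps, ``N`` and IUPAC
    ambiguity codes are legal here and are resolved by the distance
    module's comparison rules, not at parse time.
    """

    specimen_ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.specimen_ids)
        seqs = tuple(str(s).upper() for s in self.sequences)
        if len(ids) != len(seqs):
            raise AlignmentError("ids and sequences differ in count")
        if len(ids) < 2:
            raise AlignmentError("an alignment needs at least 2 sequences")
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if list(ids).count(s) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        length = len(seqs[0])
        for sid, seq in zip(ids, seqs):
            if len(seq) != length:
                raise AlignmentError(
                    f"record {sid!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - ALPHABET
            if bad:
                raise AlignmentError(f"record {sid!r} has illegal residues {sorted(bad)}")
        object.__setattr__(self, "specimen_ids", ids)
        object.__setattr__(self, "sequences", seqs)

    def __len__(self) -> int:
        return len(self.specimen_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def reorder(self, ids: Sequence[str]) -> "AlignedSequenceSet":
        index = {s: i for i, s in enumerate(self.specimen_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        return AlignedSequenceSet(
            tuple(ids), tuple(self.sequences[index[s]] for s in ids)
        )


@dataclass
class RunConfig:
    """Configuration for a full congruence analysis run.

    Parameters
    ----------
    dependent : {'algae', 'fungi', 'both'}
        Which partner's genetic distance matrix is treated as the
        response.  ``'both'`` runs the analysis in each direction.
    distance_model : {'p', 'tn93'}
        Genetic distance estimator applied to alignments.
    mem_truncation : float or None
        Truncation distance (metres) for the spatial eigenvector basis;
        ``None`` selects the largest minimum-spanning-tree edge.
    forward_alpha : float
        Entry threshold for forward selection of spatial eigenvectors.
    forward_permutations : int
        Permutations per candidate during forward selection.
    n_permutations : int
        Association randomisations for the Procrustes congruence test.
    seed : int
        Master seed; per-stage seeds are derived by fixed offsets.
    axis_retention : 'positive' | 'cum95' | int
        Rule converting an explanatory distance matrix into predictor
        axes (all positive-eigenvalue axes, axes covering >=95% of the
        positive inertia, or the first k axes).
    output_dir : str or None
        Where report files are written.
    """

    dependent: str = "both"
    distance_model: str = "p"
    mem_truncation: float | None = None
    forward_alpha: float = 0.05
    forward_permutations: int = 999
    n_permutations: int = 10_000
    seed: int = 0
    axis_retention: str | int = "positive"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.dependent not in ("algae", "fungi", "both"):
            raise ValueError(f"dependent must be algae|fungi|both, got {self.dependent!r}")
        if self.distance_model not in ("p", "tn93"):
            raise ValueError(f"distance_model must be p|tn93, got {self.distance_model!r}")
        if self.mem_truncation is not None and self.mem_truncation <= 0:
            raise ValueError("mem_truncation must be positive")
        if not 0 <= self.forward_alpha <= 1:
            raise ValueError("forward_alpha must be in [0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.forward_permutations < 1:
            raise ValueError("forward_permutations must be >= 1")

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name}={'' if v is None else v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs: dict = {}
        casts = {
            "mem_truncation": lambda v: float(v) if v else None,
            "forward_alpha": float,
            "forward_permutations": int,
            "n_permutations": int,
            "seed": int,
            "axis_retention": lambda v: int(v) if v.isdigit() else v,
            "output_dir": lambda v: v or None,
        }
        for raw in Path(path).read_text().splitlines():
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            key, _, value = raw.partition("=")
            key, value = key.strip(), value.strip()
            kwargs[key] = casts.get(key, str)(value)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# alignments


def read_alignment(path: str | Path) -> AlignedSequenceSet:
    """Read an aligned FASTA file.

    Raises :class:`AlignmentError` on ragged record lengths (the error
    names the offending record) or duplicate headers.
    """
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise AlignmentError(f"no FASTA records in {path}")
    return AlignedSequenceSet(tuple(ids), tuple(seqs))


def write_alignment(aln: AlignedSequenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.specimen_ids, aln.sequences)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# distance matrices


def validate_distance_matrix(
    values: np.ndarray, ids: Sequence[str], tol: float = 1e-9
) -> DistanceMatrix:
    """Validate and build a labelled distance matrix.

    Checks squareness, zero diagonal, non-negativity and symmetry within
    ``tol`` (reporting the worst-offending cell), then symmetrises
    exactly by averaging.
    """
    values = np.asarray(values, dtype=float)
    ids = [str(s) for s in ids]
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise MatrixFormatError(f"matrix is not square: shape {values.shape}")
    if len(ids) != values.shape[0]:
        raise MatrixFormatError("label count does not match matrix size")
    if np.isnan(values).any():
        raise MatrixFormatError("matrix contains missing values")
    diag = np.diag(values)
    if np.any(np.abs(diag) > tol):
        i = int(np.argmax(np.abs(diag)))
        raise MatrixFormatError(f"nonzero diagonal at {ids[i]!r}: {diag[i]!r}")
    asym = np.abs(values - values.T)
    worst = np.unravel_index(np.argmax(asym), asym.shape)
    if asym[worst] > tol:
        i, j = worst
        raise MatrixFormatError(
            f"asymmetric beyond tolerance {tol:g}: d({ids[i]},{ids[j]})={values[i, j]!r}"
            f" vs d({ids[j]},{ids[i]})={values[j, i]!r}"
        )
    if (values < -tol).any():
        i, j = np.unravel_index(np.argmin(values), values.shape)
        raise MatrixFormatError(f"negative entry d({ids[i]},{ids[j]})={values[i, j]!r}")
    sym = 0.5 * (values + values.T)
    np.fill_diagonal(sym, 0.0)
    sym = np.clip(sym, 0.0, None)
    return DistanceMatrix(sym, ids)


def _sniff_delimiter(header: str) -> str:
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_distance_matrix(
    path: str | Path, tol: float = 1e-6
) -> DistanceMatrix:
    """Read a labelled square distance matrix from TSV or CSV.

    The delimiter is detected from the header line.  Triangle-only files
    (empty or absent cells on one side of the diagonal) are mirrored to
    the full square.  Asymmetry beyond ``tol`` is an error naming the
    worst cell.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise MatrixFormatError(f"empty matrix file: {path}")
    sep = _sniff_delimiter(lines[0])
    df = pd.read_csv(_io.StringIO("\n".join(lines)), sep=sep, index_col=0)
    ids = [str(s) for s in df.index]
    if len(set(ids)) != len(ids):
        raise MatrixFormatError("duplicate row labels in matrix file")
    if list(map(str, df.columns)) != ids:
        # tolerate a column order differing from row order only if the
        # label sets agree; reorder columns to the row order
        if set(map(str, df.columns)) != set(ids):
            raise MatrixFormatError(
                "row and column labels disagree: "
                f"{sorted(set(ids) ^ set(map(str, df.columns)))}"
            )
        df.columns = list(map(str, df.columns))
        df = df[ids]
    values = df.to_numpy(dtype=float)
    # mirror triangle-only files
    nan = np.isnan(values)
    if nan.any():
        lower_empty = np.triu(~nan, 1).any() and not np.tril(~nan, -1).any()
        upper_empty = np.tril(~nan, -1).any() and not np.triu(~nan, 1).any()
        if lower_empty or upper_empty:
            filled = np.where(nan, 0.0, values)
            values = filled + filled.T - np.diag(np.diag(filled))
            np.fill_diagonal(values, np.where(np.isnan(np.diag(df)), 0.0, np.diag(df)))
        else:
            raise MatrixFormatError("matrix has scattered missing cells")
    return validate_distance_matrix(values, ids, tol=tol)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    df.to_csv(path, sep=sep, float_format="%.12g")


# ---------------------------------------------------------------------------
# coordinates


def read_coordinates(path: str | Path) -> pd.DataFrame:
    """Read a ``specimen_id,lon,lat`` CSV into a DataFrame indexed by id.

    Longitudes must lie in [-180, 180] and latitudes in [-90, 90];
    duplicate ids are an error.
    """
    df = pd.read_csv(path)
    required = {"specimen_id", "lon", "lat"}
    if not required <= set(df.columns):
        raise MatrixFormatError(
            f"coordinate file must have columns {sorted(required)}, got {list(df.columns)}"
        )
    df["specimen_id"] = df["specimen_id"].astype(str)
    if df["specimen_id"].duplicated().any():
        dupes = sorted(df.loc[df["specimen_id"].duplicated(), "specimen_id"])
        raise MatrixFormatError(f"duplicate specimen ids in coordinates: {dupes}")
    if ((df["lat"] < -90) | (df["lat"] > 90)).any():
        bad = df.loc[(df["lat"] < -90) | (df["lat"] > 90), "specimen_id"].tolist()
        raise MatrixFormatError(f"latitude outside [-90, 90] for {bad}")
    if ((df["lon"] < -180) | (df["lon"] > 180)).any():
        bad = df.loc[(df["lon"] < -180) | (df["lon"] > 180), "specimen_id"].tolist()
        raise MatrixFormatError(f"longitude outside [-180, 180] for {bad}")
    return df.set_index("specimen_id")[["lon", "lat"]]


def write_coordinates(coords: pd.DataFrame, path: str | Path) -> None:
    out = coords[["lon", "lat"]].copy()
    out.insert(0, "specimen_id", out.index)
    out.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# label alignment


def match_labels(*matrices: DistanceMatrix) -> tuple[DistanceMatrix, ...]:
    """Reorder matrices to the label order of the first one.

    Joins are by label with an explicit error on mismatch, never by
    position: pairing integrity between partner matrices is the core
    assumption of the congruence tests.
    """
    if not matrices:
        return ()
    ref = list(matrices[0].ids)
    out = [matrices[0]]
    for dm in matrices[1:]:
        if set(dm.ids) != set(ref):
            missing = sorted(set(ref) - set(dm.ids))
            extra = sorted(set(dm.ids) - set(ref))
            raise KeyError(
                f"specimen labels do not match: missing {missing}, unexpected {extra}"
            )
        out.append(dm.filter(ref))
    return tuple(out)
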