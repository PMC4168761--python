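"""Synthetic paired-symbiont datasets with known ground truth.

The generator emulates the mechanisms thought to shape lichen
co-diversification: vertical co-dispersal (co-speciation of the fungal
and algal lineages), horizontal photobiont acquisition (the fungus
re-associating with an algal lineage from the environmental pool), and
dispersal limitation (spatially autocorrelated specimen placement).

The fungal lineage diversifies by a pure-birth (Yule) process.  The
algal pool diversifies on the same timeline by background speciation
events occurring at the same total rate as the fungal process, so the
pool carries genetic diversity regardless of how often co-speciation
occurs.  At each fungal
speciation the partner algal lineage co-speciates with probability
``p_cospeciation`` (each fungal daughter keeps its own algal daughter);
otherwise one fungal daughter inherits the parent's partner and the
other attaches to an extant algal lineage chosen uniformly.  After each
speciation every other fungal lineage independently re-attaches to a
uniform algal lineage with probability ``switch_rate``.  Sequences
evolve along both trees under Jukes–Cantor; coordinates interpolate
between uniform placement and Brownian diffusion along the fungal tree
according to ``spatial_signal``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .io import AlignedSequenceSet, write_alignment, write_coordinates

__all__ = [
    "TreeNode",
    "SyntheticScenario",
    "SyntheticDataset",
    "simulate_cophylogeny",
    "evolve_sequences",
    "assign_locations",
    "generate_dataset",
]

#: reference point (lon, lat) around which synthetic coordinates are laid
#: out; mid-latitude Southern Hemisphere, comparable to the sampling region
#: the generator emulates
_ORIGIN = (172.0, -43.0)
_M_PER_DEG = 111_195.0  # meridian metres per degree on the R=6371 km sphere


class TreeNode:
    """Minimal rooted tree with branch lengths."""

    __slots__ = ("name", "length", "children")

    def __init__(self, name: str | None = None, length: float = 0.0, children=None):
        self.name = name
        self.length = float(length)
        self.children: list[TreeNode] = list(children) if children else []

    def is_tip(self) -> bool:
        return not self.children

    def tips(self) -> list["TreeNode"]:
        if self.is_tip():
            return [self]
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_tip():
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def tip_names(self) -> list[str]:
        return [t.name for t in self.tips()]

    def scale(self, factor: float) -> None:
        stack = [self]
        while stack:
            node = stack.pop()
            node.length *= factor
            stack.extend(node.children)

    def tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        stack = [(self, self.length)]
        while stack:
            node, depth = stack.pop()
            if node.is_tip():
                depths[node.name] = depth
            for ch in node.children:
                stack.append((ch, depth + ch.length))
        return depths

    def cophenetic_distances(self) -> DistanceMatrix:
        """Tip-to-tip path-length distance matrix."""
        names = self.tip_names()
        index = {s: i for i, s in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))

        def recurse(node: TreeNode, depth: float) -> list[tuple[int, float]]:
            if node.is_tip():
                return [(index[node.name], depth)]
            groups = [recurse(ch, depth + ch.length) for ch in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for i, di in groups[gi]:
                        for j, dj in groups[gj]:
                            dij = di + dj - 2.0 * depth
                            d[i, j] = d[j, i] = dij
            return [t for g in groups for t in g]

        recurse(self, 0.0)
        return DistanceMatrix(d, names)

    def prune_to(self, keep: set[str]) -> "TreeNode":
        """Induced subtree on ``keep`` tips, degree-2 nodes suppressed."""

        def recurse(node: TreeNode) -> TreeNode | None:
            if node.is_tip():
                return (
                    TreeNode(node.name, node.length) if node.name in keep else None
                )
            kept = [c for c in (recurse(ch) for ch in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                child.length += node.length
                return child
            return TreeNode(node.name, node.length, kept)

        pruned = recurse(self)
        if pruned is None:
            raise ValueError("no tips retained")
        return pruned

    def to_newick(self) -> str:
        def recurse(node: TreeNode) -> str:
            if node.is_tip():
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(recurse(ch) for ch in node.children)
            return f"({inner}):{node.length:.10g}"

        return recurse(self) + ";"


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for one synthetic dataset.

    Defaults describe a strongly co-dispersing, spatially structured
    community: 40 specimens, full co-speciation, no switching, 600-site
    ITS-like sequences at a substitution rate giving pairwise p-distances
    in the 0–0.2 range, and country-scale (600 km) Brownian placement.
    """

    n_specimens: int = 40
    p_cospeciation: float = 1.0
    switch_rate: float = 0.0
    seq_length: int = 600
    subst_rate: float = 0.05
    spatial_signal: float = 1.0
    bounding_box: float = 600_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 4:
            raise ValueError("n_specimens must be >= 4")
        if not 0.0 <= self.p_cospeciation <= 1.0:
            raise ValueError("p_cospeciation must be in [0, 1]")
        if self.switch_rate < 0.0 or self.switch_rate > 1.0:
            raise ValueError("switch_rate must be in [0, 1]")
        if not 0.0 <= self.spatial_signal <= 1.0:
            raise ValueError("spatial_signal must be in [0, 1]")
        if self.seq_length < 1 or self.subst_rate < 0 or self.bounding_box <= 0:
            raise ValueError("invalid sequence or box parameters")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground truth."""

    algal_alignment: AlignedSequenceSet
    fungal_alignment: AlignedSequenceSet
    coordinates: pd.DataFrame
    association: dict[str, str]
    scenario: SyntheticScenario
    fungal_tree: TreeNode = field(repr=False, default=None)
    algal_tree: TreeNode = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_alignment(self.algal_alignment, outdir / "algal.fasta")
        write_alignment(self.fungal_alignment, outdir / "fungal.fasta")
        write_coordinates(self.coordinates, outdir / "coordinates.csv")
        with open(outdir / "association.tsv", "w") as fh:
            fh.write("specimen_id\talgal_lineage\n")
            for sid in self.fungal_alignment.specimen_ids:
                fh.write(f"{sid}\t{self.association[sid]}\n")
        with open(outdir / "scenario.txt", "w") as fh:
            for key, value in vars(self.scenario).items():
                fh.write(f"{key}={value}\n")


# ---------------------------------------------------------------------------
# co-phylogeny simulation


class _Lineage:
    __slots__ = ("node", "birth")

    def __init__(self, node: TreeNode, birth: float):
        self.node = node
        self.birth = birth


def simulate_cophylogeny(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> tuple[TreeNode, TreeNode, dict[str, str]]:
    """Simulate paired fungal/algal trees and the specimen association.

    Returns the fungal tree (tips ``S001``…), the induced algal tree on
    partnered lineages (tips ``A001``…) and the map from fungal tip to
    algal tip.  Both trees share one timeline, rescaled so the fungal
    root-to-tip depth is 1.
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    n = scenario.n_specimens

    f_root = TreeNode()
    a_root = TreeNode()
    t = 0.0
    fungal = [_Lineage(f_root, 0.0)]
    algal = [_Lineage(a_root, 0.0)]
    partner: dict[int, int] = {id(fungal[0]): 0}  # fungal lineage -> algal idx

    def split(lineages: list[_Lineage], idx: int, time: float) -> tuple[_Lineage, _Lineage]:
        parent = lineages[idx]
        parent.node.length = time - parent.birth
        d1, d2 = TreeNode(), TreeNode()
        parent.node.children = [d1, d2]
        l1, l2 = _Lineage(d1, time), _Lineage(d2, time)
        lineages[idx] = l1
        lineages.append(l2)
        return l1, l2

    while len(fungal) < n:
        # fungal lineages speciate at per-lineage rate 1; the algal pool
        # speciates at the same TOTAL rate as the fungal process (rather
        # than per pool lineage), so pool diversity tracks the sampled
        # radiation and event counts stay bounded
        total_rate = 2.0 * len(fungal)
        t += rng.exponential(1.0 / total_rate)
        if rng.random() < 0.5:
            # fungal speciation
            fi = int(rng.integers(len(fungal)))
            old = fungal[fi]
            a_idx = partner.pop(id(old))
            f1, f2 = split(fungal, fi, t)
            if rng.random() < scenario.p_cospeciation:
                split(algal, a_idx, t)  # first daughter keeps slot a_idx
                partner[id(f1)] = a_idx
                partner[id(f2)] = len(algal) - 1
            else:
                partner[id(f1)] = a_idx
                partner[id(f2)] = int(rng.integers(len(algal)))
            if scenario.switch_rate > 0:
                for lin in fungal:
                    if lin is f1 or lin is f2:
                        continue
                    if rng.random() < scenario.switch_rate:
                        partner[id(lin)] = int(rng.integers(len(algal)))
        else:
            # background algal speciation: the partnered history follows
            # the first daughter, the second joins the free-living pool
            ai = int(rng.integers(len(algal)))
            split(algal, ai, t)

    for lin in fungal:
        lin.node.length = t - lin.birth
    for lin in algal:
        lin.node.length = t - lin.birth

    # stable specimen order: left-to-right tip order of the fungal tree
    f_tips = f_root.tips()
    for i, tip in enumerate(f_tips, 1):
        tip.name = f"S{i:03d}"
    partnered_idx = sorted({partner[id(lin)] for lin in fungal})
    a_names = {ai: f"A{j:03d}" for j, ai in enumerate(partnered_idx, 1)}
    for ai, lin in enumerate(algal):
        lin.node.name = a_names.get(ai, f"pool{ai}")

    association = {
        lin.node.name: a_names[partner[id(lin)]] for lin in fungal
    }

    if t > 0:
        f_root.scale(1.0 / t)
        a_root.scale(1.0 / t)
    a_induced = a_root.prune_to(set(a_names.values()))
    return f_root, a_induced, association


# ---------------------------------------------------------------------------
# sequence evolution (Jukes–Cantor)


def evolve_sequences(
    tree: TreeNode, subst_rate: float, seq_length: int, seed
) -> AlignedSequenceSet:
    """Evolve sequences along a tree under Jukes–Cantor.

    The root sequence is uniform random; on a branch of length ``b``
    (time units) each site differs from its parent with probability
    (3/4)(1 - exp(-4·subst_rate·b/3)), the exact JC transition
    probability, and changed sites pick uniformly among the other three
    bases.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    root_seq = rng.integers(0, 4, size=seq_length)

    ids: list[str] = []
    seqs: list[str] = []

    def mutate(parent: np.ndarray, blen: float) -> np.ndarray:
        p = 0.75 * (1.0 - np.exp(-4.0 * subst_rate * blen / 3.0))
        child = parent.copy()
        hit = rng.random(seq_length) < p
        if hit.any():
            child[hit] = (child[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        return child

    def recurse(node: TreeNode, seq: np.ndarray) -> None:
        seq = mutate(seq, node.length)
        if node.is_tip():
            ids.append(node.name)
            seqs.append("".join(bases[seq]))
            return
        for child in node.children:
            recurse(child, seq)

    recurse(tree, root_seq)
    return AlignedSequenceSet(tuple(ids), tuple(seqs))


# ---------------------------------------------------------------------------
# spatial placement


def assign_locations(
    tree: TreeNode, spatial_signal: float, bounding_box: float, seed
) -> pd.DataFrame:
    """Place tips in a square box, mixing Brownian and uniform positions.

    A 2-D Brownian motion diffuses along the tree (variance ∝ branch
    length), its tip positions are rescaled to span the box, and each
    coordinate is the convex mix ``σ·brownian + (1-σ)·uniform``.  The
    box (side ``bounding_box`` metres) is converted to lon/lat around a
    fixed mid-latitude origin.
    """
    if not 0.0 <= spatial_signal <= 1.0:
        raise ValueError("spatial_signal must be in [0, 1]")
    rng = np.random.default_rng(seed)

    names: list[str] = []
    positions: list[np.ndarray] = []

    def recurse(node: TreeNode, pos: np.ndarray) -> None:
        pos = pos + rng.normal(scale=np.sqrt(max(node.length, 0.0)), size=2)
        if node.is_tip():
            names.append(node.name)
            positions.append(pos)
            return
        for child in node.children:
            recurse(child, pos)

    recurse(tree, np.zeros(2))
    bm = np.vstack(positions)
    span = bm.max(axis=0) - bm.min(axis=0)
    scaled = np.empty_like(bm)
    for axis in range(2):
        if span[axis] > 0:
            scaled[:, axis] = (bm[:, axis] - bm[:, axis].min()) / span[axis]
        else:
            scaled[:, axis] = 0.5
    uniform = rng.uniform(0.0, 1.0, size=bm.shape)
    xy = (spatial_signal * scaled + (1.0 - spatial_signal) * uniform) * bounding_box

    lon0, lat0 = _ORIGIN
    lat = lat0 + (xy[:, 1] - bounding_box / 2.0) / _M_PER_DEG
    lon = lon0 + (xy[:, 0] - bounding_box / 2.0) / (
        _M_PER_DEG * np.cos(np.radians(lat0))
    )
    return pd.DataFrame({"lon": lon, "lat": lat}, index=pd.Index(names, name="specimen_id"))


# ---------------------------------------------------------------------------
# full dataset


def generate_dataset(scenario: SyntheticScenario) -> SyntheticDataset:
    """Generate a complete paired dataset for the given scenario.

    Deterministic in the scenario (including its seed): per-stage
    generators are spawned from one seed sequence.  Algal sequences are
    evolved on the induced algal tree; specimens sharing an algal
    lineage receive identical algal sequences, which is how zero
    genetic distances arise in real paired datasets.
    """
    ss = np.random.SeedSequence(scenario.seed)
    s_tree, s_fseq, s_aseq, s_loc = ss.spawn(4)

    f_tree, a_tree, association = simulate_cophylogeny(
        scenario, rng=np.random.default_rng(s_tree)
    )
    fungal_aln = evolve_sequences(
        f_tree, scenario.subst_rate, scenario.seq_length, s_fseq
    )
    algal_tip_aln = evolve_sequences(
        a_tree, scenario.subst_rate, scenario.seq_length, s_aseq
    )
    tip_seq = dict(zip(algal_tip_aln.specimen_ids, algal_tip_aln.sequences))

    specimen_ids = fungal_aln.specimen_ids
    algal_aln = AlignedSequenceSet(
        specimen_ids, tuple(tip_seq[association[sid]] for sid in specimen_ids)
    )
    coords = assign_locations(
        f_tree, scenario.spatial_signal, scenario.bounding_box, s_loc
    )
    coords = coords.loc[list(specimen_ids)]
    return SyntheticDataset(
        algal_alignment=algal_aln,
        fungal_alignment=fungal_aln,
        coordinates=coords,
        association=association,
        scenario=scenario,
        fungal_tree=f_tree,
        algal_tree=a_tree,
    )
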