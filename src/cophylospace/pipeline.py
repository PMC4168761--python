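"""End-to-end congruence analysis and report generation.

Runs the full workflow — genetic distances, spatial eigenvector basis,
forward selection, variance partitioning and the Procrustes congruence
test — in one or both dependent-matrix directions, and renders the
results both as machine-readable TSV (full precision) and as a compact
human table (2 d.p. fractions, ``–`` for skipped spatial fields,
``<0.001``-style small p-values).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from . import __version__
from .distances import (
    MatrixSummary,
    geographic_distance,
    p_distance,
    summarize_matrix,
    tn93_distance,
)
from .io import AlignedSequenceSet, RunConfig, match_labels
from .ordination import (
    MoranEigenvectorMaps,
    VariancePartition,
    explanatory_axes,
    forward_select_mems,
    mem_basis,
    variance_partition,
)
from .paco import PACoResult, paco_test

__all__ = ["DirectionResult", "CongruenceReport", "run_congruence_analysis", "write_report"]

# fixed per-stage seed offsets derived from the master seed, so each
# stochastic stage is independently reproducible
_SEED_OFFSETS = {
    ("forward", "algae"): 11,
    ("forward", "fungi"): 12,
    ("paco", "algae"): 21,
    ("paco", "fungi"): 22,
}
_SEED_MOD = 2**31 - 1


def _stage_seed(master: int, stage: str, direction: str) -> int:
    return (int(master) + _SEED_OFFSETS[(stage, direction)]) % _SEED_MOD


@dataclass
class DirectionResult:
    """One dependent-matrix direction of the analysis."""

    dependent: str                      # 'algae' or 'fungi'
    selected_mems: list[int]            # 1-based, in selection order
    partition: VariancePartition
    paco: PACoResult


@dataclass
class CongruenceReport:
    """Full analysis outcome: summaries plus per-direction results."""

    n_specimens: int
    algal_summary: MatrixSummary
    fungal_summary: MatrixSummary
    spatial_extent_m: float | None
    n_mems: int
    directions: dict[str, DirectionResult]
    config: RunConfig
    specimen_ids: tuple[str, ...] = field(default=())

    def human_table(self) -> str:
        """Render the per-direction results as a compact text table."""
        rows = ["Dependent\tSignificant MEMs\tPartner\tShared\tSpace\tUnexpl.\tP"]
        for name, res in self.directions.items():
            vp = res.partition
            if vp.has_space:
                mems = ", ".join(str(i) for i in res.selected_mems) or "none"
                shared = f"{vp.b:.2f}"
                space = f"{vp.c:.2f}"
            else:
                mems, shared, space = "–", "–", "–"
            floor = 10.0 / (res.paco.n_permutations + 1)
            p = f"<{floor:.3g}" if res.paco.p_value < floor else f"{res.paco.p_value:.3g}"
            rows.append(
                f"{name}\t{mems}\t{vp.a:.2f}\t{shared}\t{space}\t{vp.d:.2f}\t{p}"
            )
        return "\n".join(rows)


def _genetic_distances(
    data: AlignedSequenceSet | DistanceMatrix, model: str
) -> DistanceMatrix:
    if isinstance(data, DistanceMatrix):
        return data
    if isinstance(data, AlignedSequenceSet):
        if model == "p":
            return p_distance(data)
        return tn93_distance(data).to_distance_matrix()
    raise TypeError(
        f"expected an alignment or a distance matrix, got {type(data).__name__}"
    )


def run_congruence_analysis(
    config: RunConfig,
    algal: AlignedSequenceSet | DistanceMatrix,
    fungal: AlignedSequenceSet | DistanceMatrix,
    coordinates: pd.DataFrame | None = None,
    geographic_distances: DistanceMatrix | None = None,
) -> CongruenceReport:
    """Run the full congruence analysis described by ``config``.

    ``algal`` and ``fungal`` may be alignments (distances are computed
    with ``config.distance_model``) or precomputed distance matrices.
    Space enters either as a lon/lat table or a ready geographic
    distance matrix; with neither, the spatial stages are skipped and
    fractions reduce to partner/unexplained.

    Stages run in order: distances → MEM basis → forward selection →
    variance partitioning → PACo, for each requested direction.  Both
    directions share one MEM basis (space depends only on the
    locations), so differences in selected MEMs stem from the response
    matrix alone.
    """
    try:
        alg_d = _genetic_distances(algal, config.distance_model)
        fun_d = _genetic_distances(fungal, config.distance_model)
    except Exception as exc:
        raise RuntimeError(f"stage 'distances' failed: {exc}") from exc

    geo_d: DistanceMatrix | None = None
    if geographic_distances is not None:
        geo_d = geographic_distances
    elif coordinates is not None:
        geo_d = geographic_distance(coordinates)

    try:
        if geo_d is not None:
            alg_d, fun_d, geo_d = match_labels(alg_d, fun_d, geo_d)
        else:
            alg_d, fun_d = match_labels(alg_d, fun_d)
    except KeyError as exc:
        raise RuntimeError(f"stage 'label matching' failed: {exc}") from exc

    basis: MoranEigenvectorMaps | None = None
    if geo_d is not None:
        try:
            basis = mem_basis(geo_d, truncation=config.mem_truncation)
        except Exception as exc:
            raise RuntimeError(f"stage 'MEM basis' failed: {exc}") from exc

    responses = {"algae": (alg_d, fun_d), "fungi": (fun_d, alg_d)}
    wanted = ["algae", "fungi"] if config.dependent == "both" else [config.dependent]

    directions: dict[str, DirectionResult] = {}
    for name in wanted:
        response_d, partner_d = responses[name]
        try:
            partner_x = explanatory_axes(partner_d, rule=config.axis_retention)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'explanatory axes' ({name}-dependent) failed: {exc}"
            ) from exc

        selected: list[int] = []
        space_x = None
        if basis is not None:
            try:
                selected = forward_select_mems(
                    response_d,
                    basis,
                    alpha=config.forward_alpha,
                    n_permutations=config.forward_permutations,
                    seed=_stage_seed(config.seed, "forward", name),
                )
            except Exception as exc:
                raise RuntimeError(
                    f"stage 'forward selection' ({name}-dependent) failed: {exc}"
                ) from exc
            if selected:
                space_x = basis.vectors_[:, [i - 1 for i in selected]]

        try:
            partition = variance_partition(response_d, partner_x, space_x)
            if basis is not None and space_x is None:
                # spatial stage ran but nothing was selected: the spatial
                # fractions are genuinely (not structurally) zero
                partition = dataclasses.replace(partition, has_space=True)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'variance partitioning' ({name}-dependent) failed: {exc}"
            ) from exc

        try:
            direction = "fungi-onto-algae" if name == "algae" else "algae-onto-fungi"
            paco = paco_test(
                alg_d,
                fun_d,
                n_permutations=config.n_permutations,
                seed=_stage_seed(config.seed, "paco", name),
                direction=direction,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'PACo' ({name}-dependent) failed: {exc}") from exc

        directions[name] = DirectionResult(
            dependent=name, selected_mems=selected, partition=partition, paco=paco
        )

    return CongruenceReport(
        n_specimens=alg_d.shape[0],
        algal_summary=summarize_matrix(alg_d),
        fungal_summary=summarize_matrix(fun_d),
        spatial_extent_m=summarize_matrix(geo_d).max if geo_d is not None else None,
        n_mems=basis.vectors_.shape[1] if basis is not None else 0,
        directions=directions,
        config=config,
        specimen_ids=tuple(alg_d.ids),
    )


def write_report(report: CongruenceReport, outdir: str | Path) -> None:
    """Write report.tsv, residuals.tsv, mems.tsv and provenance.txt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = report.config

    header = [
        f"# cophylospace {__version__}",
        f"# seed={cfg.seed} distance_model={cfg.distance_model} "
        f"axis_retention={cfg.axis_retention} forward_alpha={cfg.forward_alpha} "
        f"forward_permutations={cfg.forward_permutations} "
        f"n_permutations={cfg.n_permutations} mem_truncation={cfg.mem_truncation}",
    ]

    rows = []
    for name, res in report.directions.items():
        vp = res.partition
        rows.append(
            {
                "dependent": name,
                "significant_mems": ",".join(map(str, res.selected_mems)),
                "partner": vp.a,
                "shared": vp.b if vp.has_space else np.nan,
                "space": vp.c if vp.has_space else np.nan,
                "unexplained": vp.d,
                "paco_m2": res.paco.m2,
                "paco_p": res.paco.p_value,
                "n_permutations": res.paco.n_permutations,
            }
        )
    with open(outdir / "report.tsv", "w") as fh:
        fh.write("\n".join(header) + "\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False, float_format="%.10g")

    resid = pd.DataFrame(
        {name: res.paco.residuals for name, res in report.directions.items()}
    )
    resid.index.name = "specimen_id"
    with open(outdir / "residuals.tsv", "w") as fh:
        fh.write("\n".join(header) + "\n")
        resid.to_csv(fh, sep="\t", float_format="%.10g")

    mems = pd.DataFrame(
        {
            name: ",".join(map(str, res.selected_mems))
            for name, res in report.directions.items()
        },
        index=["selected_mems"],
    ).T
    with open(outdir / "mems.tsv", "w") as fh:
        fh.write("\n".join(header) + "\n")
        mems.to_csv(fh, sep="\t")

    with open(outdir / "provenance.txt", "w") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write(f"n_specimens={report.n_specimens}\n")
        fh.write(f"n_mems={report.n_mems}\n")
        if report.spatial_extent_m is not None:
            fh.write(f"spatial_extent_m={report.spatial_extent_m:.10g}\n")
        alg, fun = report.algal_summary, report.fungal_summary
        fh.write(
            f"algal_distance mean={alg.mean:.10g} sd={alg.sd:.10g} "
            f"range={alg.min:.10g}-{alg.max:.10g}\n"
        )
        fh.write(
            f"fungal_distance mean={fun.mean:.10g} sd={fun.sd:.10g} "
            f"range={fun.min:.10g}-{fun.max:.10g}\n"
        )
        fh.write(report.human_table() + "\n")
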