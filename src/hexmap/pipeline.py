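"""End-to-end orchestration: filter -> linkage -> cluster -> order ->
IBD -> QTL, with per-stage bookkeeping.

Every stage is an ordinary library call; this module wires them
together, records marker/individual counts as the map funnels down, and
serializes artifacts as delimited text.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dosage as dm
from . import grouping, ibd, linkage, ordering, qtl

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline thresholds; defaults follow the mapping protocol."""

    ploidy: int = 6
    max_missing_markers: float = 0.05
    skew_alpha: float = 0.001
    max_missing_individuals: float = 0.10
    max_impossible: float = 0.02
    cluster_lod: float = 10.0
    cluster_min_size: int = 5
    assign_lod: float = 5.0
    min_links: int = 5
    min_joint_obs: int = 10
    r_grid_step: float = 0.005
    nn_fit_threshold: float = 4.0
    nn_k: int = 10
    ibd_grid_step: float = 1.0
    n_perm: int = 1000
    perm_percentile: float = 5.0
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    matrix: dm.DosageMatrix  # filtered, unique-representative matrix
    filter_report: dm.FilterReport
    bins: list[dm.MarkerBin]
    clusters: list[grouping.HomologueCluster]
    clgs: list[grouping.CLG]
    assignments: list[grouping.PhasedMarker]
    unassigned: list[str]
    phased_map: pd.DataFrame
    maps: dict[int, ordering.CLGMap]
    full_maps: dict[int, pd.DataFrame]  # duplicates re-attached
    ibd_marker: dict[int, ibd.IBDArray]
    ibd_grid: dict[int, ibd.IBDArray]
    gic: dict[int, pd.DataFrame]
    stage_counts: dict[str, int] = field(default_factory=dict)
    scans: dict[str, qtl.QTLScan] = field(default_factory=dict)

    def positions(self, clg: int) -> dict[str, float]:
        return self.maps[clg].position_of()


def run_pipeline(
    matrix: dm.DosageMatrix,
    config: RunConfig | None = None,
    phenotypes: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full mapping pipeline on a raw dosage matrix.

    ``phenotypes`` (optional) is a DataFrame indexed by individual with
    one column per trait; each trait triggers a genome scan with a
    permutation threshold.
    """
    cfg = config or RunConfig()
    counts: dict[str, int] = {
        "markers_input": matrix.n_markers,
        "individuals_input": matrix.n_individuals,
    }

    # -- stage 1: quality filtering ------------------------------------
    matrix, rep_m = dm.filter_markers(
        matrix, max_missing=cfg.max_missing_markers, skew_alpha=cfg.skew_alpha
    )
    matrix, rep_i = dm.filter_individuals(
        matrix,
        max_missing=cfg.max_missing_individuals,
        max_impossible=cfg.max_impossible,
    )
    report = dm.FilterReport(
        removed_markers=rep_m.removed_markers,
        removed_individuals=rep_i.removed_individuals,
    )
    counts["markers_filtered"] = matrix.n_markers
    counts["individuals_filtered"] = matrix.n_individuals

    # -- stage 2: duplicate binning ------------------------------------
    bins = dm.bin_duplicates(matrix)
    reps = [b.representative for b in bins]
    rep_idx = [matrix.marker_index(m) for m in reps]
    work = matrix.subset(marker_idx=rep_idx)
    counts["markers_unique"] = work.n_markers
    logger.info("%d markers in %d bins after filtering", matrix.n_markers, len(bins))

    # -- stage 3: backbone clustering ----------------------------------
    clusters: list[grouping.HomologueCluster] = []
    simplex_links = {}
    for parent in (1, 2):
        simplex = grouping.simplex_markers(work, parent)
        links = linkage.pairwise_linkage(
            work, simplex, min_n=cfg.min_joint_obs, grid_step=cfg.r_grid_step
        )
        simplex_links[parent] = links
        clusters += grouping.cluster_backbone(
            links,
            simplex,
            parent,
            lod_threshold=cfg.cluster_lod,
            min_size=cfg.cluster_min_size,
        )
    counts["backbone_clusters"] = sum(1 for c in clusters if not c.excluded)

    # -- stage 4: CLG identification through 1x1 bridges ---------------
    simplex_all = grouping.simplex_markers(work, 1) + grouping.simplex_markers(work, 2)
    bridges = [
        m
        for i, m in enumerate(work.marker_ids)
        if work.seg_type(i) == (1, 1)
    ]
    bridge_links = (
        linkage.pairwise_linkage(
            work, bridges, simplex_all, min_n=cfg.min_joint_obs, grid_step=cfg.r_grid_step
        )
        if bridges
        else linkage._empty_frame()
    )
    clgs, ambiguous = grouping.identify_clg(
        clusters, bridge_links, lod_threshold=cfg.assign_lod
    )
    counts["clgs"] = len(clgs)
    counts["ambiguous_bridges"] = len(ambiguous)

    # -- stage 5: assignment and phasing -------------------------------
    others = [m for m in work.marker_ids if m not in set(simplex_all) and m not in set(bridges)]
    other_links = (
        linkage.pairwise_linkage(
            work, others, simplex_all, min_n=cfg.min_joint_obs, grid_step=cfg.r_grid_step
        )
        if others
        else linkage._empty_frame()
    )
    all_links = pd.concat(
        [simplex_links[1], simplex_links[2], bridge_links, other_links],
        ignore_index=True,
    )
    assignments, unassigned = grouping.assign_and_phase(
        work,
        all_links,
        clusters,
        clgs,
        lod_threshold=cfg.assign_lod,
        min_links=cfg.min_links,
    )
    phased_map = grouping.phased_map_frame(assignments, clgs, clusters, ploidy=cfg.ploidy)
    counts["markers_assigned"] = len(assignments)
    counts["markers_phased"] = len(phased_map)

    # -- stage 6: per-CLG ordering -------------------------------------
    maps: dict[int, ordering.CLGMap] = {}
    full_maps: dict[int, pd.DataFrame] = {}
    bin_of = {b.representative: b for b in bins}
    for clg in clgs:
        members = sorted(
            pm.marker for pm in assignments if pm.clg == clg.clg_id
        )
        if len(members) < 2:
            continue
        clg_links = linkage.pairwise_linkage(
            work, members, min_n=cfg.min_joint_obs, grid_step=cfg.r_grid_step
        )
        di = ordering.DistanceInput.from_linkages(clg_links, members)
        cmap = ordering.iterate_ordering(
            di, fit_threshold=cfg.nn_fit_threshold, k=cfg.nn_k
        )
        maps[clg.clg_id] = cmap
        full_maps[clg.clg_id] = ordering.attach_duplicates(
            cmap, [bin_of[m] for m in cmap.markers if m in bin_of]
        )
    counts["markers_ordered"] = sum(len(m.markers) for m in maps.values())
    counts["markers_mapped_with_duplicates"] = sum(
        len(f) for f in full_maps.values()
    )

    # -- stage 7: IBD reconstruction -----------------------------------
    ibd_marker: dict[int, ibd.IBDArray] = {}
    ibd_grid: dict[int, ibd.IBDArray] = {}
    gic_tabs: dict[int, pd.DataFrame] = {}
    for clg_id, cmap in maps.items():
        pos = cmap.position_of()
        try:
            arr = ibd.interpolate_ibd(work, phased_map, pos, clg_id)
        except dm.HexmapError:
            continue
        grid = ibd.grid_ibd(arr, step=cfg.ibd_grid_step)
        ibd_marker[clg_id] = arr
        ibd_grid[clg_id] = grid
        gic_tabs[clg_id] = ibd.gic(grid)

    result = PipelineResult(
        config=cfg,
        matrix=matrix,
        filter_report=report,
        bins=bins,
        clusters=clusters,
        clgs=clgs,
        assignments=assignments,
        unassigned=unassigned,
        phased_map=phased_map,
        maps=maps,
        full_maps=full_maps,
        ibd_marker=ibd_marker,
        ibd_grid=ibd_grid,
        gic=gic_tabs,
        stage_counts=counts,
    )

    # -- stage 8: QTL scans --------------------------------------------
    if phenotypes is not None and ibd_grid:
        grids = [ibd_grid[c] for c in sorted(ibd_grid)]
        for trait in phenotypes.columns:
            result.scans[trait] = qtl.scan_with_threshold(
                grids,
                phenotypes[trait],
                n_perm=cfg.n_perm,
                percentile=cfg.perm_percentile,
                seed=np.random.default_rng(cfg.seed),
            )
    return result


# ---------------------------------------------------------------------------
# artifact serialization


def write_artifacts(result: PipelineResult, outdir: str | Path) -> None:
    """Write all pipeline artifacts as delimited text under ``outdir``.

    Every table carries the config hash and seed in a sidecar manifest.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_counts": result.stage_counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    result.filter_report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    result.phased_map.to_csv(out / "phased_map.tsv", sep="\t", index=False)
    rows = []
    for clg_id, cmap in result.maps.items():
        df = cmap.to_frame()
        df.insert(0, "CLG", clg_id)
        df["round_removed"] = ""
        rows.append(df)
        rem = pd.DataFrame(
            [(clg_id, m, r) for m, r in cmap.removed.items()],
            columns=["CLG", "marker_id", "round_removed"],
        )
        if len(rem):
            rows.append(rem)
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(
            out / "integrated_map.tsv", sep="\t", index=False
        )
    for clg_id, grid in result.ibd_grid.items():
        grid.to_frame().to_csv(out / f"ibd_clg{clg_id}.tsv", sep="\t", index=False)
    if result.gic:
        pd.concat(result.gic.values(), ignore_index=True).to_csv(
            out / "gic.tsv", sep="\t", index=False
        )
    for trait, sc in result.scans.items():
        tab = sc.table.copy()
        tab.to_csv(out / f"qtl_{trait}.tsv", sep="\t", index=False)
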