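"""Homologue backbone clusters, chromosomal linkage groups and phasing.

The mapping strategy works upward from the simplest marker type:

1. simplex x nulliplex (1x0 / 0x1) markers are clustered per parent at a
   high LOD threshold using coupling-phase linkages only; each connected
   component is a *homologue backbone cluster* representing one physical
   homologous chromosome of one parent (repulsion estimates are too
   uncertain in a hexaploid to contribute);
2. bi-parental simplex x simplex (1x1) markers bridge one cluster of each
   parent; clusters connected through shared 1x1 markers merge into
   *chromosomal linkage groups* (CLG), each holding up to ploidy
   homologue clusters per parent;
3. every remaining marker is assigned to the CLG with most qualifying
   coupling linkages to backbone markers, and each of its alleles is
   phased to the homologue whose backbone shows at least ``min_links``
   coupling linkages above the LOD threshold.  A marker whose number of
   phased homologues does not match its parental dosage is kept on the
   map but excluded from the phased set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dosage import DosageMatrix

logger = logging.getLogger(__name__)


@dataclass
class HomologueCluster:
    """Coupling-linked simplex markers representing one homologue."""

    cluster_id: str
    parent: int  # 1 or 2
    markers: list[str]
    excluded: bool = False  # too small to be mapped

    @property
    def size(self) -> int:
        return len(self.markers)


@dataclass
class CLG:
    """Chromosomal linkage group: homologue clusters of both parents
    connected through bi-parental bridge markers."""

    clg_id: int
    clusters: list[str]
    bridges: list[str] = field(default_factory=list)
    # consensus pairing: bridge support per (P1 cluster, P2 cluster)
    pairing_support: dict[tuple[str, str], int] = field(default_factory=dict)


def simplex_markers(matrix: DosageMatrix, parent: int) -> list[str]:
    """Marker ids with simplex dosage in ``parent`` and nulliplex in the
    other (1x0 for parent 1, 0x1 for parent 2)."""
    want = (1, 0) if parent == 1 else (0, 1)
    return [m for i, m in enumerate(matrix.marker_ids) if matrix.seg_type(i) == want]


def _coupling_edges(
    linkages: pd.DataFrame, parent: int, lod_threshold: float
) -> pd.DataFrame:
    shared = linkages["phase1"] if parent == 1 else linkages["phase2"]
    return linkages[(linkages["lod"] >= lod_threshold) & (shared > 0)]


def cluster_backbone(
    linkages: pd.DataFrame,
    markers: list[str],
    parent: int,
    lod_threshold: float = 10.0,
    min_size: int = 5,
) -> list[HomologueCluster]:
    """Single-linkage clustering of one parent's simplex markers.

    Edges are pairs with LOD >= ``lod_threshold`` whose best phase is
    coupling (shared-homologue count > 0 in that parent); connected
    components are homologue clusters.  Components smaller than
    ``min_size`` are flagged excluded and take no part in mapping.
    Clusters are numbered by descending size (ties: smallest member id).
    """
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(markers)
    edges = _coupling_edges(linkages, parent, lod_threshold)
    g.add_edges_from(zip(edges["marker_a"], edges["marker_b"]))
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    out = []
    for k, comp in enumerate(comps):
        out.append(
            HomologueCluster(
                cluster_id=f"P{parent}_{k + 1:02d}",
                parent=parent,
                markers=comp,
                excluded=len(comp) < min_size,
            )
        )
    return out


def _link_table(linkages: pd.DataFrame, cluster_of: dict[str, str]) -> pd.DataFrame:
    """Long table of (marker, backbone marker, cluster, lod, coupling)
    with one row per orientation in which the partner is a clustered
    backbone marker."""
    rows = []
    for mcol, scol, pcol in (
        ("marker_a", "marker_b", None),
        ("marker_b", "marker_a", None),
    ):
        sub = linkages[linkages[scol].isin(cluster_of)].copy()
        if not len(sub):
            continue
        clusters = sub[scol].map(cluster_of)
        parent = clusters.str.startswith("P1").map({True: 1, False: 2})
        shared = np.where(parent == 1, sub["phase1"], sub["phase2"])
        rows.append(
            pd.DataFrame(
                {
                    "marker": sub[mcol].to_numpy(),
                    "backbone": sub[scol].to_numpy(),
                    "cluster": clusters.to_numpy(),
                    "parent": parent.to_numpy(),
                    "lod": sub["lod"].to_numpy(),
                    "shared": shared,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["marker", "backbone", "cluster", "parent", "lod", "shared"]
        )
    return pd.concat(rows, ignore_index=True)


def identify_clg(
    clusters: list[HomologueCluster],
    bridge_linkages: pd.DataFrame,
    lod_threshold: float = 5.0,
) -> tuple[list[CLG], list[str]]:
    """Merge homologue clusters into CLGs through 1x1 bridge markers.

    Each bridge marker attaches to its best-LOD coupling-linked cluster
    per parent; clusters sharing a bridge merge transitively.  Bridges
    with a tied best cluster in either parent are logged ambiguous and
    skipped.  CLGs are numbered by descending total marker count.
    """
    cluster_of = {
        m: c.cluster_id for c in clusters if not c.excluded for m in c.markers
    }
    sizes = {c.cluster_id: c.size for c in clusters}
    table = _link_table(bridge_linkages, cluster_of)
    table = table[(table["lod"] > lod_threshold) & (table["shared"] > 0)]

    g: nx.Graph = nx.Graph()
    g.add_nodes_from(c.cluster_id for c in clusters if not c.excluded)
    ambiguous: list[str] = []
    attachments: dict[str, dict[int, str]] = {}
    for marker, sub in table.groupby("marker", sort=True):
        best: dict[int, str] = {}
        for parent in (1, 2):
            per_cluster = (
                sub[sub["parent"] == parent].groupby("cluster")["lod"].max()
            )
            if per_cluster.empty:
                continue
            top = per_cluster.max()
            winners = per_cluster[per_cluster >= top - 1e-9].index.tolist()
            if len(winners) > 1:
                best[parent] = None
            else:
                best[parent] = winners[0]
        if None in best.values():
            ambiguous.append(marker)
            logger.info("bridge marker %s ties between clusters; skipped", marker)
            continue
        if len(best) == 2:
            attachments[marker] = best
            g.add_edge(best[1], best[2], bridge=marker)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-sum(sizes.get(cid, 0) for cid in c), c[0]))
    out = []
    for k, comp in enumerate(comps):
        clg = CLG(clg_id=k + 1, clusters=comp)
        support: dict[tuple[str, str], int] = {}
        for marker, best in attachments.items():
            if best.get(1) in comp or best.get(2) in comp:
                clg.bridges.append(marker)
                key = (best[1], best[2])
                support[key] = support.get(key, 0) + 1
        clg.pairing_support = support
        out.append(clg)
    return out, ambiguous


@dataclass
class PhasedMarker:
    """Allele-to-homologue assignment of one marker within a CLG."""

    marker: str
    clg: int
    homologues: tuple[str, ...]  # cluster ids carrying the marker's alleles
    phased: bool  # assigned homologues match parental dosages
    link_counts: dict[str, int] = field(default_factory=dict)


def assign_and_phase(
    matrix: DosageMatrix,
    linkages: pd.DataFrame,
    clusters: list[HomologueCluster],
    clgs: list[CLG],
    lod_threshold: float = 5.0,
    min_links: int = 5,
) -> tuple[list[PhasedMarker], list[str]]:
    """Assign every marker to a CLG and phase its alleles to homologues.

    A qualifying linkage is a coupling linkage to a clustered backbone
    (1x0 / 0x1) marker with LOD > ``lod_threshold``.  The marker goes to
    the CLG with the most qualifying linkages (equal support between two
    CLGs leaves it unassigned, logged); each allele is phased to every
    homologue cluster with >= ``min_links`` qualifying linkages.  Markers
    whose phased-homologue count per parent does not equal the parental
    dosage are reported with ``phased=False``.  Backbone markers of
    retained clusters are phased to their own cluster by construction.

    Returns (assignments, unassigned marker ids).
    """
    cluster_of = {
        c_.cluster_id: c_ for c_ in clusters
    }
    marker_cluster = {
        m: c_.cluster_id for c_ in clusters if not c_.excluded for m in c_.markers
    }
    clg_of_cluster = {cid: clg.clg_id for clg in clgs for cid in clg.clusters}
    table = _link_table(linkages, marker_cluster)
    table = table[(table["lod"] > lod_threshold) & (table["shared"] > 0)]
    table = table[table["cluster"].map(clg_of_cluster).notna()]

    excluded_backbone = {
        m for c_ in clusters if c_.excluded for m in c_.markers
    }
    out: list[PhasedMarker] = []
    unassigned: list[str] = []
    grouped = {m: sub for m, sub in table.groupby("marker", sort=False)}
    for i, marker in enumerate(matrix.marker_ids):
        d1, d2 = matrix.seg_type(i)
        if marker in excluded_backbone:
            # simplex markers of undersized clusters take no part in mapping
            unassigned.append(marker)
            continue
        if marker in marker_cluster:
            cid = marker_cluster[marker]
            out.append(
                PhasedMarker(
                    marker=marker,
                    clg=clg_of_cluster.get(cid, -1),
                    homologues=(cid,),
                    phased=clg_of_cluster.get(cid) is not None,
                )
            )
            continue
        sub = grouped.get(marker)
        if sub is None or not len(sub):
            unassigned.append(marker)
            continue
        by_clg = sub["cluster"].map(clg_of_cluster).value_counts()
        if len(by_clg) > 1 and by_clg.iloc[0] == by_clg.iloc[1]:
            unassigned.append(marker)
            logger.info("marker %s has tied CLG support; unassigned", marker)
            continue
        clg_id = int(by_clg.index[0])
        sub = sub[sub["cluster"].map(clg_of_cluster) == clg_id]
        link_counts = sub.groupby("cluster")["backbone"].nunique().to_dict()
        homs = tuple(
            sorted(c for c, k in link_counts.items() if k >= min_links)
        )
        n1 = sum(1 for c in homs if cluster_of[c].parent == 1)
        n2 = len(homs) - n1
        out.append(
            PhasedMarker(
                marker=marker,
                clg=clg_id,
                homologues=homs,
                phased=(n1 == d1 and n2 == d2),
                link_counts=link_counts,
            )
        )
    return out, unassigned


def phased_map_frame(
    assignments: list[PhasedMarker],
    clgs: list[CLG],
    clusters: list[HomologueCluster],
    ploidy: int = 6,
) -> pd.DataFrame:
    """Wide phased-map table: marker_id, CLG, h1..h(2*ploidy) indicator
    columns (1 where the allele resides).  Within each CLG, that CLG's P1
    clusters occupy h1..h{ploidy} and P2 clusters h{ploidy+1}..h{2*ploidy},
    ordered by descending cluster size."""
    sizes = {c.cluster_id: c.size for c in clusters}
    parent_of = {c.cluster_id: c.parent for c in clusters}
    slot: dict[str, int] = {}
    for clg in clgs:
        for parent in (1, 2):
            cids = sorted(
                (c for c in clg.clusters if parent_of[c] == parent),
                key=lambda c: (-sizes[c], c),
            )
            base = 0 if parent == 1 else ploidy
            for k, cid in enumerate(cids):
                slot[cid] = base + k
    cols = [f"h{i + 1}" for i in range(2 * ploidy)]
    rows = []
    for pm in assignments:
        if not pm.phased or pm.clg < 0:
            continue
        ind = [0] * (2 * ploidy)
        ok = True
        for cid in pm.homologues:
            if cid not in slot:
                ok = False
                break
            ind[slot[cid]] = 1
        if ok:
            rows.append([pm.marker, pm.clg] + ind)
    return pd.DataFrame(rows, columns=["marker_id", "CLG"] + cols)
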