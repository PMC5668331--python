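"""Truth-comparison utilities for simulator-validated runs.

A simulated population carries its design (which homologue carries each
marker allele) and its inheritance truth (which founder homologues each
individual received).  These helpers score a pipeline run against that
truth: cluster purity, ordering concordance, phasing accuracy, and IBD
probability calibration.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .pipeline import PipelineResult
from .sim import InheritanceTruth, SimulatedDesign


def _true_chrom(design: SimulatedDesign) -> dict[str, int]:
    return dict(zip(design.marker_ids, design.chrom))


def _true_pos(design: SimulatedDesign) -> dict[str, float]:
    return dict(zip(design.marker_ids, design.position))


def _true_carriers(design: SimulatedDesign) -> dict[str, tuple[set, set]]:
    return {
        m: (set(c1), set(c2))
        for m, c1, c2 in zip(
            design.marker_ids, design.carriers_p1, design.carriers_p2
        )
    }


def cluster_truth_map(
    result: PipelineResult, design: SimulatedDesign
) -> dict[str, tuple[int, int]]:
    """Majority-vote mapping cluster id -> (true chromosome, true
    homologue index within the cluster's parent)."""
    chrom = _true_chrom(design)
    carriers = _true_carriers(design)
    out = {}
    for c in result.clusters:
        if c.excluded:
            continue
        votes: Counter = Counter()
        for m in c.markers:
            hs = carriers[m][0] if c.parent == 1 else carriers[m][1]
            for h in hs:
                votes[(chrom[m], h)] += 1
        out[c.cluster_id] = votes.most_common(1)[0][0]
    return out


def ordering_concordance(
    result: PipelineResult, design: SimulatedDesign
) -> pd.DataFrame:
    """Per CLG: marker purity (fraction from the dominant true
    chromosome), |Kendall tau| between estimated and true order, map
    length and true span."""
    chrom = _true_chrom(design)
    pos = _true_pos(design)
    rows = []
    for clg_id, cmap in result.maps.items():
        chroms = [chrom[m] for m in cmap.markers]
        dom = Counter(chroms).most_common(1)[0][0]
        purity = chroms.count(dom) / len(chroms)
        est = [p for m, p in zip(cmap.markers, cmap.positions) if chrom[m] == dom]
        tru = [pos[m] for m in cmap.markers if chrom[m] == dom]
        tau = abs(kendalltau(est, tru).statistic) if len(est) > 2 else np.nan
        rows.append(
            (clg_id, dom, purity, tau, cmap.length, max(tru) - min(tru))
        )
    return pd.DataFrame(
        rows,
        columns=["CLG", "true_chromosome", "purity", "kendall_tau", "map_length", "true_span"],
    )


def phasing_accuracy(result: PipelineResult, design: SimulatedDesign) -> float:
    """Fraction of phased markers whose allele->homologue assignment
    matches the simulated design exactly (both parents)."""
    chrom = _true_chrom(design)
    carriers = _true_carriers(design)
    ctruth = cluster_truth_map(result, design)
    parent_of = {c.cluster_id: c.parent for c in result.clusters}
    good = total = 0
    for pm in result.assignments:
        if not pm.phased:
            continue
        ch = chrom[pm.marker]
        est1 = {
            ctruth[c][1]
            for c in pm.homologues
            if parent_of[c] == 1 and ctruth[c][0] == ch
        }
        est2 = {
            ctruth[c][1]
            for c in pm.homologues
            if parent_of[c] == 2 and ctruth[c][0] == ch
        }
        t1, t2 = carriers[pm.marker]
        good += est1 == t1 and est2 == t2
        total += 1
    return good / total if total else np.nan


def _slot_clusters(result: PipelineResult) -> dict[tuple[int, int], str]:
    """(CLG id, homologue slot) -> cluster id, matching the layout of
    the phased map columns h1..h12."""
    sizes = {c.cluster_id: c.size for c in result.clusters}
    parent_of = {c.cluster_id: c.parent for c in result.clusters}
    ploidy = result.config.ploidy
    out = {}
    for clg in result.clgs:
        for parent in (1, 2):
            cids = sorted(
                (c for c in clg.clusters if parent_of[c] == parent),
                key=lambda c: (-sizes[c], c),
            )
            base = 0 if parent == 1 else ploidy
            for k, cid in enumerate(cids):
                out[(clg.clg_id, base + k)] = cid
    return out


def ibd_calibration(
    result: PipelineResult,
    truth: InheritanceTruth,
    design: SimulatedDesign,
    level: str = "grid",
    n_bins: int = 10,
    min_obs: int = 50,
) -> pd.DataFrame:
    """Bin gridded (or marker-level) IBD probabilities and compare the
    mean prediction with the observed truth frequency per bin.

    Truth at a grid locus is looked up at the nearest mapped marker of
    the dominant true chromosome.  Returns a table with bin, mean
    predicted probability, observed frequency and count for bins with at
    least ``min_obs`` observations.
    """
    chrom = _true_chrom(design)
    ctruth = cluster_truth_map(result, design)
    slot_of = _slot_clusters(result)
    ploidy = result.config.ploidy
    arrays = result.ibd_grid if level == "grid" else result.ibd_marker
    acc = defaultdict(lambda: [0.0, 0.0, 0])
    for clg_id, arr in arrays.items():
        cmap = result.maps[clg_id]
        doms = [chrom[m] for m in cmap.markers]
        dom = Counter(doms).most_common(1)[0][0]
        presence = truth.presence(dom)
        chrom_ids = [m for m in design.marker_ids if chrom[m] == dom]
        posmap = cmap.position_of()
        mapped = [(m, posmap[m]) for m in cmap.markers if chrom[m] == dom]
        mpos = np.array([p for _, p in mapped])
        mids = [m for m, _ in mapped]
        if level == "grid":
            loci = arr.positions
        else:
            # marker-level array rows follow the phased map sorted by position
            sub = result.phased_map[result.phased_map["CLG"] == clg_id]
            mk = [m for m in sub["marker_id"] if m in posmap]
            order = np.argsort([posmap[m] for m in mk], kind="stable")
            loci = np.array([posmap[mk[i]] for i in order])
        near = np.argmin(np.abs(loci[:, None] - mpos[None, :]), axis=1)
        truth_cols = np.array([chrom_ids.index(mids[j]) for j in near])
        # truth rows are in simulation order; recover each retained
        # individual's original index from the generator's id scheme
        truth_rows = np.array(
            [int(iid.rsplit("_", 1)[1]) - 1 for iid in arr.individual_ids]
        )
        for slot in range(2 * ploidy):
            cid = slot_of.get((clg_id, slot))
            if cid is None or ctruth[cid][0] != dom:
                continue
            hidx = ctruth[cid][1] + (0 if slot < ploidy else ploidy)
            p = arr.prob[:, :, slot]  # (loci, individuals)
            t = presence[np.ix_(truth_rows, [hidx], truth_cols)][:, 0, :].T.astype(float)
            b = np.clip((p * n_bins).astype(int), 0, n_bins - 1)
            for bb in range(n_bins):
                mask = b == bb
                n = int(mask.sum())
                if n:
                    acc[bb][0] += p[mask].sum()
                    acc[bb][1] += t[mask].sum()
                    acc[bb][2] += n
    rows = [
        (b, s[0] / s[2], s[1] / s[2], s[2])
        for b, s in sorted(acc.items())
        if s[2] >= min_obs
    ]
    return pd.DataFrame(
        rows, columns=["bin", "mean_predicted", "observed_frequency", "n"]
    )
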