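"""Marker ordering within a chromosomal linkage group.

Pairwise recombination fractions are Haldane-transformed to distances
and embedded by weighted multidimensional scaling (stress majorization,
LOD^2 weights) in two dimensions; a principal curve is threaded through
the embedding and markers are projected onto it.  Arc length along the
curve, rescaled so that local pairwise distances are reproduced in
weighted least squares, gives map positions in cM.  Problematic markers
are removed iteratively by their nearest-neighbour fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosage import HexmapError

D_CAP_CM = 100.0  # distance assigned to effectively-unlinked pairs


def haldane_r(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Map distance (cM) -> recombination fraction, r = (1 - e^(-2d))/2
    with d in Morgan.  Always < 0.5."""
    d = np.asarray(d_cM, dtype=float)
    if (d < 0).any():
        raise HexmapError("map distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cM) else r


def haldane_d(r: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction -> map distance (cM); defined for r < 0.5."""
    rr = np.asarray(r, dtype=float)
    if ((rr < 0) | (rr >= 0.5)).any():
        raise HexmapError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * rr)
    return float(d) if np.isscalar(r) else d


@dataclass
class DistanceInput:
    """Symmetric pairwise distance (cM) and weight (LOD^2) matrices for
    the markers of one CLG."""

    markers: list[str]
    d: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.markers)
        if self.d.shape != (n, n) or self.w.shape != (n, n):
            raise HexmapError("distance/weight shape mismatch")

    @classmethod
    def from_linkages(
        cls, linkages: pd.DataFrame, markers: list[str], d_cap: float = D_CAP_CM
    ) -> "DistanceInput":
        """Build from a pairwise-linkage table; pairs absent from the
        table get weight 0 and the cap distance."""
        n = len(markers)
        index = {m: i for i, m in enumerate(markers)}
        d = np.full((n, n), d_cap)
        w = np.zeros((n, n))
        np.fill_diagonal(d, 0.0)
        ia = linkages["marker_a"].map(index)
        ib = linkages["marker_b"].map(index)
        ok = ia.notna() & ib.notna()
        ia = ia[ok].astype(int).to_numpy()
        ib = ib[ok].astype(int).to_numpy()
        dist = np.minimum(haldane_d(np.minimum(linkages["r"][ok].to_numpy(), 0.49999)), d_cap)
        lod2 = linkages["lod"][ok].to_numpy() ** 2
        d[ia, ib] = d[ib, ia] = dist
        w[ia, ib] = w[ib, ia] = lod2
        return cls(markers=list(markers), d=d, w=w)


@dataclass
class CLGMap:
    """Ordered markers of one CLG with cM positions and diagnostics."""

    markers: list[str]
    positions: np.ndarray  # cM, nondecreasing in `order`
    order: np.ndarray  # marker indices sorted left-to-right
    nn_fit: np.ndarray | None = None
    removed: dict[str, int] = field(default_factory=dict)  # marker -> round

    @property
    def length(self) -> float:
        return float(self.positions.max() - self.positions.min()) if len(self.positions) else 0.0

    def position_of(self) -> dict[str, float]:
        return dict(zip(self.markers, self.positions))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "marker_id": np.asarray(self.markers, dtype=object)[self.order],
                "position_cM": self.positions[self.order],
            }
        )
        if self.nn_fit is not None:
            df["nn_fit"] = self.nn_fit[self.order]
        return df


def _classical_scaling(d: np.ndarray, ndim: int = 2) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:ndim]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)


def _smacof(
    d: np.ndarray,
    w: np.ndarray,
    ndim: int = 2,
    max_iter: int = 200,
    tol: float = 1e-7,
) -> np.ndarray:
    """Weighted stress majorization with deterministic classical-scaling
    initialization."""
    n = d.shape[0]
    x = _classical_scaling(d, ndim)
    if n <= ndim:
        return x
    v = -w.copy()
    np.fill_diagonal(v, 0.0)
    np.fill_diagonal(v, -v.sum(axis=1))
    vinv = np.linalg.pinv(v + np.ones((n, n)) / n) - np.ones((n, n)) / n
    prev_stress = np.inf
    for _ in range(max_iter):
        diff = x[:, None, :] - x[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        np.fill_diagonal(dist, 1.0)
        ratio = np.divide(d, dist, out=np.zeros_like(d), where=dist > 1e-12)
        b = -w * ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = vinv @ (b @ x)
        np.fill_diagonal(dist, 0.0)
        stress = (w * (dist - d) ** 2).sum() / 2.0
        if prev_stress - stress < tol * max(prev_stress, 1e-12):
            break
        prev_stress = stress
    return x


def _smooth_series(y: np.ndarray, span: int) -> np.ndarray:
    """Centred running mean with reflective ends (odd window)."""
    if span < 1:
        return y.copy()
    win = 2 * span + 1
    pad = np.concatenate([y[span:0:-1], y, y[-2 : -2 - span : -1]])
    kernel = np.ones(win) / win
    return np.convolve(pad, kernel, mode="valid")


def _project_to_polyline(points: np.ndarray, curve: np.ndarray) -> np.ndarray:
    """Arc-length parameter of each point's nearest location on the
    polyline ``curve``."""
    seg = np.diff(curve, axis=0)
    seg_len = np.sqrt((seg**2).sum(axis=1))
    seg_len = np.where(seg_len < 1e-12, 1e-12, seg_len)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    # (points, segments)
    rel = points[:, None, :] - curve[None, :-1, :]
    t = (rel * seg[None, :, :]).sum(axis=2) / (seg_len**2)[None, :]
    t = np.clip(t, 0.0, 1.0)
    proj = curve[None, :-1, :] + t[:, :, None] * seg[None, :, :]
    dist2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    best = np.argmin(dist2, axis=1)
    return cum[best] + t[np.arange(len(points)), best] * seg_len[best]


def _principal_curve(
    x: np.ndarray, span_frac: float = 0.12, n_iter: int = 8
) -> np.ndarray:
    """Arc-length parameterisation of a principal curve through the 2-D
    embedding (iterated local averaging along the current ordering)."""
    n = x.shape[0]
    # initial parameter: first principal axis
    xc = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    lam = xc @ vt[0]
    span = max(3, int(round(span_frac * n / 2)))
    for _ in range(n_iter):
        order = np.argsort(lam, kind="stable")
        curve = np.column_stack(
            [_smooth_series(x[order, k], span) for k in range(x.shape[1])]
        )
        lam_new = _project_to_polyline(x, curve)
        # re-anchor to avoid drift in degenerate cases
        if np.allclose(lam_new, lam_new[0]):
            break
        lam = lam_new
    return lam


def order_clg(di: DistanceInput, anchor: str | None = None) -> CLGMap:
    """Order one CLG by weighted MDS + principal-curve projection.

    Positions are arc length along the curve, rescaled by weighted least
    squares against locally-estimated pairwise distances; leftmost marker
    sits at 0 cM.  Orientation is deterministic: the ``anchor`` marker
    (default: lexicographically smallest id) lands in the left half.
    Raises if the weighted linkage graph is disconnected (re-cluster).
    """
    n = len(di.markers)
    if n == 0:
        raise HexmapError("empty CLG")
    if n == 1:
        return CLGMap(markers=list(di.markers), positions=np.zeros(1), order=np.array([0]))
    comp = _connected_components(di.w > 0)
    if comp.max() != 0:
        raise HexmapError(
            "CLG linkage graph is disconnected; re-cluster before ordering"
        )
    x = _smacof(di.d, di.w)
    lam = _principal_curve(x) if n > 3 else x[:, 0]
    # weighted LS scale against local pairwise distances
    iu, ju = np.triu_indices(n, k=1)
    t = np.abs(lam[iu] - lam[ju])
    dd = di.d[iu, ju]
    ww = di.w[iu, ju]
    local = (dd < 30.0) & (ww > 0)
    denom = (ww[local] * t[local] ** 2).sum()
    alpha = (ww[local] * t[local] * dd[local]).sum() / denom if denom > 0 else 1.0
    pos = lam * alpha
    if n > 3:
        pos = _refine_1d(pos, di.d, di.w)
        # final polish on short pairs only: Haldane distances of loose
        # linkages are upward-biased (convexity) and stretch the map
        # ends; short-pair distances are nearly unbiased.  The cap is
        # raised until the short-pair graph is connected and nearly all
        # markers keep enough informative short partners to be pinned
        # down; too sparse a cap wrinkles the map instead of fixing it.
        for cap in (15.0, 20.0, 30.0, 50.0):
            w_short = np.where(di.d <= cap, di.w, 0.0)
            informative = (di.d <= cap) & (di.w >= 25.0)
            np.fill_diagonal(informative, False)
            degree = informative.sum(axis=1)
            if (
                _connected_components(w_short > 0).max() == 0
                and np.percentile(degree, 5) >= 10
            ):
                pos = _refine_1d(pos, di.d, w_short)
                break
    pos -= pos.min()
    anchor_idx = di.markers.index(anchor) if anchor else int(np.argmin(np.asarray(di.markers, dtype=object)))
    if pos[anchor_idx] > pos.max() / 2.0:
        pos = pos.max() - pos
    return CLGMap(
        markers=list(di.markers),
        positions=pos,
        order=np.argsort(pos, kind="stable"),
    )


def _refine_1d(
    pos: np.ndarray, d: np.ndarray, w: np.ndarray, n_iter: int = 200
) -> np.ndarray:
    """Polish map positions by weighted stress majorization restricted to
    one dimension, starting from the principal-curve arc lengths.  The
    2-D embedding fixes the global order; this step tightens local
    distances against the informative pairwise estimates."""
    n = len(pos)
    v = -w.copy()
    np.fill_diagonal(v, 0.0)
    np.fill_diagonal(v, -v.sum(axis=1))
    vinv = np.linalg.pinv(v + np.ones((n, n)) / n) - np.ones((n, n)) / n
    x = pos.copy()
    for _ in range(n_iter):
        dist = np.maximum(np.abs(x[:, None] - x[None, :]), 1e-9)
        b = -w * d / dist
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = vinv @ (b @ x)
    return x


def _connected_components(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    comp = np.full(n, -1)
    c = 0
    for s in range(n):
        if comp[s] >= 0:
            continue
        stack = [s]
        comp[s] = c
        while stack:
            u = stack.pop()
            for v in np.where(adj[u] & (comp < 0))[0]:
                comp[v] = c
                stack.append(v)
        c += 1
    return comp


def nn_fit(
    cmap: CLGMap, di: DistanceInput, k: int = 10, min_lod: float = 5.0
) -> np.ndarray:
    """Per-marker nearest-neighbour fit: mean |map distance - pairwise
    distance| (cM) over the k nearest map neighbours whose pairwise
    estimate is informative (LOD >= ``min_lod``).

    Averaging keeps the statistic on the per-neighbour cM scale
    regardless of k, and the LOD floor keeps essentially-unlinked pairs
    (repulsion or cross-parent, whose Haldane distances are noise) from
    swamping the diagnostic; the total fit of the map is the sum over
    markers."""
    n = len(cmap.markers)
    fits = np.zeros(n)
    pos = cmap.positions
    w_min = min_lod**2
    for i in range(n):
        have = np.where((di.w[i] >= w_min) & (np.arange(n) != i))[0]
        if have.size == 0:
            continue
        gaps = np.abs(pos[have] - pos[i])
        nearest = have[np.argsort(gaps, kind="stable")[:k]]
        fits[i] = np.abs(np.abs(pos[nearest] - pos[i]) - di.d[i, nearest]).mean()
    return fits


def iterate_ordering(
    di: DistanceInput,
    fit_threshold: float = 4.0,
    k: int = 10,
    max_rounds: int = 10,
    anchor: str | None = None,
) -> CLGMap:
    """Order, prune markers whose nearest-neighbour fit exceeds
    ``fit_threshold``, and re-order while the fit keeps improving.

    A pruning round is accepted only if the mean per-marker fit of the
    re-ordered map drops: the raw total trivially shrinks with the
    marker count, so it cannot distinguish genuine improvement from
    attrition, whereas the mean compares map quality like for like
    across rounds.  Removed markers are recorded with the round that
    dropped them.
    """
    current = di
    removed: dict[str, int] = {}
    cmap = order_clg(current, anchor=anchor)
    cmap.nn_fit = nn_fit(cmap, current, k=k)
    mean_fit = cmap.nn_fit.mean()
    for rnd in range(1, max_rounds + 1):
        bad = np.where(cmap.nn_fit > fit_threshold)[0]
        if bad.size == 0 or bad.size >= len(current.markers) - 2:
            break
        keep = np.setdiff1d(np.arange(len(current.markers)), bad)
        trial = DistanceInput(
            markers=[current.markers[i] for i in keep],
            d=current.d[np.ix_(keep, keep)],
            w=current.w[np.ix_(keep, keep)],
        )
        try:
            tmap = order_clg(trial, anchor=anchor if anchor in trial.markers else None)
        except HexmapError:
            break  # pruning disconnected the graph; keep previous map
        tmap.nn_fit = nn_fit(tmap, trial, k=k)
        t_mean = tmap.nn_fit.mean()
        if t_mean >= mean_fit:
            break
        for i in bad:
            removed[current.markers[i]] = rnd
        current, cmap, mean_fit = trial, tmap, t_mean
    cmap.removed = removed
    return cmap


def attach_duplicates(cmap: CLGMap, bins) -> pd.DataFrame:
    """Re-attach binned duplicate markers at their representative's
    position.  ``bins`` is an iterable of MarkerBin."""
    pos = cmap.position_of()
    rows = [
        (m, pos[b.representative])
        for b in bins
        if b.representative in pos
        for m in b.members
    ]
    return pd.DataFrame(rows, columns=["marker_id", "position_cM"]).sort_values(
        ["position_cM", "marker_id"], ignore_index=True
    )


def same_contig_rmse(
    positions: dict[str, float],
    contig_of: dict[str, str],
    homologue_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """RMSE of map-position differences between same-contig simplex
    marker pairs, split by same- vs different-homologue phasing.

    Markers from one transcript contig should map ~0 cM apart; the
    same-homologue RMSE gauges local ordering quality, the
    different-homologue RMSE gauges homologue integration quality.
    """
    from collections import defaultdict

    by_contig: dict[str, list[str]] = defaultdict(list)
    for m, c in contig_of.items():
        if m in positions:
            by_contig[c].append(m)
    rows = []
    for c, ms in sorted(by_contig.items()):
        ms = sorted(ms)
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                a, b = ms[i], ms[j]
                same_h = None
                if homologue_of is not None:
                    ha, hb = homologue_of.get(a), homologue_of.get(b)
                    same_h = (ha == hb) if ha is not None and hb is not None else None
                rows.append((c, a, b, positions[a] - positions[b], same_h))
    pairs = pd.DataFrame(
        rows, columns=["contig", "marker_a", "marker_b", "delta_cM", "same_homologue"]
    )
    out = []
    if len(pairs):
        out.append(("all", float(np.sqrt((pairs["delta_cM"] ** 2).mean())), len(pairs)))
        for flag, label in ((True, "same_homologue"), (False, "different_homologue")):
            sub = pairs[pairs["same_homologue"] == flag]
            if len(sub):
                out.append((label, float(np.sqrt((sub["delta_cM"] ** 2).mean())), len(sub)))
    return pd.DataFrame(out, columns=["group", "rmse_cM", "n_pairs"])
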