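"""Pairwise recombination-frequency and phase likelihoods under polysomic
(random-bivalent-pairing) inheritance.

Rather than a catalogue of closed-form likelihood functions per marker
segregation-type combination, one generic engine builds the joint
offspring dosage distribution for any pair of markers numerically from
the pairing/transmission model:

* the ``2m`` homologues of a parent pair uniformly at random into ``m``
  bivalents (15 scenarios in a hexaploid, 3 in a tetraploid);
* each bivalent {i, j} transmits one product which carries homologue i
  at locus A and stays on i at locus B with probability (1-r)/2, or
  switches to the partner j with probability r/2 (and symmetrically
  starting from j).

A parental *phase class* is fully characterised by the number of
homologues carrying both markers' alleles ("shared count" s): all
placements with equal s are permutation-equivalent under random pairing.
Joint gamete-dosage probabilities are therefore polynomials in r of
degree <= m per parent; coefficients are enumerated once per
(ploidy, dosage_A, dosage_B, s) and cached.  Offspring distributions are
convolutions of the two parental gamete distributions.

The maximum-likelihood r (grid search with golden-section refinement)
and the best phase class give the pair's recombination estimate; the LOD
is the base-10 likelihood ratio against independence (r = 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .dosage import (
    MISSING,
    DosageMatrix,
    HexmapError,
    _check_ploidy,
    offspring_dosage_distribution,
)
from .sim import enumerate_bivalent_pairings

_TIE_TOL = 1e-9
_LOG_ZERO = -1e30  # stands in for log(0) so that 0 * _LOG_ZERO == 0


def shared_count_range(ploidy: int, da: int, db: int) -> range:
    """Admissible shared-homologue counts for one parent with dosages
    (da, db) at the two loci."""
    return range(max(0, da + db - ploidy), min(da, db) + 1)


def phase_classes(
    ploidy: int, dos_a: tuple[int, int], dos_b: tuple[int, int]
) -> list[tuple[int, int]]:
    """All joint phase classes (s1, s2), ordered by increasing coupling so
    that tie-breaking prefers the more-coupled (later) class."""
    out = [
        (s1, s2)
        for s1 in shared_count_range(ploidy, dos_a[0], dos_b[0])
        for s2 in shared_count_range(ploidy, dos_a[1], dos_b[1])
    ]
    out.sort(key=lambda s: (s[0] + s[1], s[0]))
    return out


@lru_cache(maxsize=None)
def _gamete_coeffs(ploidy: int, da: int, db: int, shared: int) -> np.ndarray:
    """Polynomial coefficients (in r) of the joint gamete-dosage
    distribution of one parent.

    Returns C with shape (m+1, m+1, m+1): P(a, b | r) = sum_k C[a,b,k] r^k
    where a, b are transmitted dosages at the two loci and m = ploidy/2.
    """
    _check_ploidy(ploidy)
    if shared not in shared_count_range(ploidy, da, db):
        raise HexmapError(
            f"shared count {shared} impossible for dosages ({da}, {db})"
        )
    m = ploidy // 2
    # canonical allele placement for this phase class
    a_set = set(range(da))
    b_set = set(range(shared)) | set(range(da, da + db - shared))
    pairings = enumerate_bivalent_pairings(ploidy)
    total = np.zeros((m + 1, m + 1, m + 1))
    for pairing in pairings:
        # per-bivalent joint (a, b, degree) polynomial distribution
        acc = np.zeros((1, 1, 1))
        acc[0, 0, 0] = 1.0
        for i, j in pairing:
            biv = np.zeros((2, 2, 2))
            for start, other in ((i, j), (j, i)):
                a_c = 1 if start in a_set else 0
                # no switch: (1-r)/2 ; switch to partner: r/2
                biv[a_c, 1 if start in b_set else 0, 0] += 0.5
                biv[a_c, 1 if start in b_set else 0, 1] -= 0.5
                biv[a_c, 1 if other in b_set else 0, 1] += 0.5
            acc = _conv3(acc, biv)
        total[: acc.shape[0], : acc.shape[1], : acc.shape[2]] += acc
    return total / len(pairings)


def _conv3(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """3-D polynomial-tensor convolution (dosage axes + degree axis)."""
    out = np.zeros(
        (
            x.shape[0] + y.shape[0] - 1,
            x.shape[1] + y.shape[1] - 1,
            x.shape[2] + y.shape[2] - 1,
        )
    )
    for a in range(y.shape[0]):
        for b in range(y.shape[1]):
            for k in range(y.shape[2]):
                if y[a, b, k]:
                    out[a:, b:, k:][
                        : x.shape[0], : x.shape[1], : x.shape[2]
                    ] += y[a, b, k] * x
    return out


def _eval_poly(coeffs: np.ndarray, r: float | np.ndarray) -> np.ndarray:
    """Evaluate a coefficient tensor (..., deg) at scalar or vector r."""
    deg = coeffs.shape[-1]
    r = np.asarray(r, dtype=float)
    powers = r[..., None] ** np.arange(deg) if r.ndim else r ** np.arange(deg)
    out = coeffs @ powers.T if r.ndim else coeffs @ powers
    return np.clip(out, 0.0, None)


def two_locus_gamete_distribution(
    ploidy: int, da: int, db: int, shared: int, r: float
) -> np.ndarray:
    """Joint distribution of transmitted dosages (a, b) of one parent with
    dosages (da, db), phase class ``shared``, at recombination fraction r.

    Shape (m+1, m+1) with m = ploidy/2; sums to 1; marginals equal the
    single-locus gamete dosage distributions for every r.
    """
    if not 0.0 <= r <= 0.5:
        raise HexmapError(f"recombination fraction {r} outside [0, 0.5]")
    return _eval_poly(_gamete_coeffs(ploidy, da, db, shared), r)


@lru_cache(maxsize=None)
def _offspring_coeffs(
    ploidy: int,
    dos_a: tuple[int, int],
    dos_b: tuple[int, int],
    s1: int,
    s2: int,
) -> np.ndarray:
    """Polynomial coefficients of the joint offspring dosage distribution
    P(dosage at A, dosage at B | r); shape (ploidy+1, ploidy+1, deg)."""
    c1 = _gamete_coeffs(ploidy, dos_a[0], dos_b[0], s1)
    c2 = _gamete_coeffs(ploidy, dos_a[1], dos_b[1], s2)
    return _conv3(c1, c2)


def offspring_joint_distribution(
    ploidy: int,
    dos_a: tuple[int, int],
    dos_b: tuple[int, int],
    phase: tuple[int, int],
    r: float,
) -> np.ndarray:
    """Joint F1 dosage distribution for a marker pair at phase (s1, s2)."""
    if not 0.0 <= r <= 0.5:
        raise HexmapError(f"recombination fraction {r} outside [0, 0.5]")
    return _eval_poly(_offspring_coeffs(ploidy, dos_a, dos_b, *phase), r)


def joint_counts(
    matrix: DosageMatrix, a: int | str, b: int | str
) -> np.ndarray:
    """(ploidy+1)x(ploidy+1) cross-tabulation of jointly non-missing
    progeny dosages for two markers (by id or index)."""
    ia = a if isinstance(a, int) else matrix.marker_index(a)
    ib = b if isinstance(b, int) else matrix.marker_index(b)
    xa, xb = matrix.progeny[ia], matrix.progeny[ib]
    ok = (xa != MISSING) & (xb != MISSING)
    p = matrix.ploidy
    counts = np.zeros((p + 1, p + 1))
    np.add.at(counts, (xa[ok], xb[ok]), 1.0)
    return counts


def pair_likelihood(
    counts: np.ndarray,
    ploidy: int,
    dos_a: tuple[int, int],
    dos_b: tuple[int, int],
    phase: tuple[int, int],
    r: float,
) -> float:
    """Multinomial log-likelihood of a joint dosage cross-tab under the
    offspring joint distribution.  An observed cell with zero probability
    yields -inf (impossible phase or data error)."""
    probs = offspring_joint_distribution(ploidy, dos_a, dos_b, phase, r)
    obs = counts > 0
    if (probs[obs] <= 0).any():
        return -np.inf
    return float((counts[obs] * np.log(probs[obs])).sum())


@dataclass
class PairLinkage:
    """Recombination estimate for one marker pair."""

    marker_a: str
    marker_b: str
    r_hat: float
    lod: float
    phase: tuple[int, int]  # shared-homologue count per parent
    loglik: float
    n: int


_R_MAX = 0.49999  # open upper bound of the admissible r range


def _golden_refine(f, lo: float, hi: float, iters: int = 24) -> tuple[float, float]:
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    x = c if fc >= fd else d
    return x, max(fc, fd)


def estimate_pair(
    matrix: DosageMatrix,
    a: int | str,
    b: int | str,
    min_n: int = 10,
    grid_step: float = 0.005,
) -> PairLinkage:
    """Maximum-likelihood r, LOD and phase class for one marker pair.

    The likelihood is maximized over all joint phase classes and over r
    on a grid with golden-section refinement around the best grid point.
    LOD compares against independence at r = 1/2 (phase-free).  Ties
    between phase classes (within 1e-9) resolve to the more-coupled one.
    """
    ia = a if isinstance(a, int) else matrix.marker_index(a)
    ib = b if isinstance(b, int) else matrix.marker_index(b)
    counts = joint_counts(matrix, ia, ib)
    n = int(counts.sum())
    if n < min_n:
        raise HexmapError(
            f"only {n} jointly non-missing progeny (< {min_n}): linkage undefined"
        )
    p = matrix.ploidy
    dos_a, dos_b = matrix.seg_type(ia), matrix.seg_type(ib)
    grid = np.arange(0.0, 0.5, grid_step)
    best = None  # (loglik, phase, r)
    for phase in phase_classes(p, dos_a, dos_b):
        coeffs = _offspring_coeffs(p, dos_a, dos_b, *phase)
        probs = _eval_poly(coeffs, grid)  # (p+1, p+1, n_grid)
        with np.errstate(divide="ignore"):
            logp = np.where(probs > 0, np.log(np.where(probs > 0, probs, 1.0)), _LOG_ZERO)
        ll = np.einsum("ab,abr->r", counts, logp)
        k = int(np.argmax(ll))
        lo = max(0.0, grid[k] - grid_step)
        hi = min(_R_MAX, grid[k] + grid_step)

        def f(r, _ph=phase):
            return pair_likelihood(counts, p, dos_a, dos_b, _ph, r)

        r_hat, ll_hat = _golden_refine(f, lo, hi)
        for cand_r, cand_ll in ((grid[k], ll[k]), (r_hat, ll_hat)):
            if best is None or cand_ll > best[0] + _TIE_TOL or (
                cand_ll > best[0] - _TIE_TOL and phase != best[1]
            ):
                best = (cand_ll, phase, cand_r)
    ll_best, phase, r_hat = best
    ll_half = pair_likelihood(counts, p, dos_a, dos_b, phase, 0.5)
    lod = max(0.0, (ll_best - ll_half) / np.log(10.0))
    return PairLinkage(
        marker_a=matrix.marker_ids[ia],
        marker_b=matrix.marker_ids[ib],
        r_hat=float(min(r_hat, _R_MAX)),
        lod=float(lod),
        phase=phase,
        loglik=float(ll_best),
        n=n,
    )


# ---------------------------------------------------------------------------
# vectorized all-pairs stage


def pairwise_linkage(
    matrix: DosageMatrix,
    markers_a: list | None = None,
    markers_b: list | None = None,
    min_n: int = 10,
    grid_step: float = 0.005,
) -> pd.DataFrame:
    """Recombination/LOD/phase estimates for many marker pairs at once.

    With only ``markers_a`` given, all unordered pairs within that set are
    estimated; with both sets, all cross pairs.  Pairs are grouped by
    segregation-type combination and the likelihood grid is evaluated for
    a whole group in one array operation; the refinement around the best
    grid point runs as a vectorized golden-section search.

    Returns a DataFrame with columns marker_a, marker_b, r, lod,
    phase1, phase2, n (pairs with fewer than ``min_n`` joint observations
    are dropped).
    """
    if markers_a is None:
        markers_a = list(range(matrix.n_markers))
    idx_a = np.array(
        [m if isinstance(m, (int, np.integer)) else matrix.marker_index(m) for m in markers_a]
    )
    within = markers_b is None
    if within:
        idx_b = idx_a
    else:
        idx_b = np.array(
            [m if isinstance(m, (int, np.integer)) else matrix.marker_index(m) for m in markers_b]
        )
    p = matrix.ploidy
    types_a = [matrix.seg_type(i) for i in idx_a]
    types_b = [matrix.seg_type(i) for i in idx_b]
    groups_a: dict[tuple[int, int], list[int]] = {}
    for k, t in enumerate(types_a):
        groups_a.setdefault(t, []).append(k)
    groups_b: dict[tuple[int, int], list[int]] = {}
    for k, t in enumerate(types_b):
        groups_b.setdefault(t, []).append(k)

    frames = []
    for ta, ka in sorted(groups_a.items()):
        for tb, kb in sorted(groups_b.items()):
            if within and tb < ta:
                continue
            sub_a = idx_a[ka]
            sub_b = idx_b[kb]
            frames.append(
                _pairwise_group(
                    matrix, sub_a, sub_b, ta, tb,
                    upper_only=within and ta == tb,
                    min_n=min_n, grid_step=grid_step,
                )
            )
    out = pd.concat([f for f in frames if len(f)], ignore_index=True) if frames else _empty_frame()
    return out


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["marker_a", "marker_b", "r", "lod", "phase1", "phase2", "n"]
    )


def _support(ploidy: int, dos: tuple[int, int]) -> np.ndarray:
    return np.array(sorted(offspring_dosage_distribution(ploidy, *dos)))


def _pairwise_group(
    matrix: DosageMatrix,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    dos_a: tuple[int, int],
    dos_b: tuple[int, int],
    upper_only: bool,
    min_n: int,
    grid_step: float,
) -> pd.DataFrame:
    p = matrix.ploidy
    sup_a = _support(p, dos_a)
    sup_b = _support(p, dos_b)
    xa = matrix.progeny[idx_a]
    xb = matrix.progeny[idx_b]
    # indicator stacks: (n_support, n_markers, n_individuals)
    ind_a = np.stack([(xa == d) for d in sup_a]).astype(np.float32)
    ind_b = np.stack([(xb == d) for d in sup_b]).astype(np.float32)
    na, nb = len(idx_a), len(idx_b)
    counts = np.empty((len(sup_a), len(sup_b), na, nb), dtype=np.float32)
    for ia_ in range(len(sup_a)):
        for ib_ in range(len(sup_b)):
            counts[ia_, ib_] = ind_a[ia_] @ ind_b[ib_].T
    # observations outside the offspring support (possible only with data
    # errors) are ignored, matching the pairwise-complete contract
    cells = counts.reshape(len(sup_a) * len(sup_b), na * nb).T  # (pairs, cells)
    n_joint = cells.sum(axis=1)

    if upper_only:
        ii, jj = np.triu_indices(na, k=1)
        keep = np.ravel_multi_index((ii, jj), (na, nb))
    else:
        keep = np.arange(na * nb)
    keep = keep[n_joint[keep] >= min_n]
    if keep.size == 0:
        return _empty_frame()
    cells = np.ascontiguousarray(cells[keep])
    n_joint = n_joint[keep]

    phases = phase_classes(p, dos_a, dos_b)
    grid = np.arange(0.0, 0.5, grid_step)
    best_ll = np.full(keep.size, -np.inf)
    best_r = np.zeros(keep.size)
    best_phase = np.zeros(keep.size, dtype=int)
    coeff_list = []
    for pi, phase in enumerate(phases):
        coeffs = _offspring_coeffs(p, dos_a, dos_b, *phase)
        sub = coeffs[np.ix_(sup_a, sup_b)].reshape(len(sup_a) * len(sup_b), -1)
        coeff_list.append(sub)
        probs = _eval_poly(sub, grid)  # (cells, n_grid)
        logp = np.where(probs > 0, np.log(np.where(probs > 0, probs, 1.0)), _LOG_ZERO)
        ll = cells @ logp  # (pairs, n_grid)
        k = np.argmax(ll, axis=1)
        ll_k = ll[np.arange(keep.size), k]
        # >= with tolerance: later (more coupled) phases win ties
        upd = ll_k > best_ll - _TIE_TOL
        best_ll = np.where(upd, ll_k, best_ll)
        best_r = np.where(upd, grid[k], best_r)
        best_phase = np.where(upd, pi, best_phase)

    # vectorized golden-section refinement around the best grid point,
    # each pair within its own phase class
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    lo = np.maximum(0.0, best_r - grid_step)
    hi = np.minimum(_R_MAX, best_r + grid_step)

    def ll_at(r_vec: np.ndarray) -> np.ndarray:
        out = np.empty_like(r_vec)
        for pi in range(len(phases)):
            sel = best_phase == pi
            if not sel.any():
                continue
            probs = _eval_poly(coeff_list[pi], r_vec[sel])  # (cells, nsel)
            logp = np.where(probs > 0, np.log(np.where(probs > 0, probs, 1.0)), _LOG_ZERO)
            out[sel] = np.einsum("pc,cp->p", cells[sel], logp)
        return out

    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc, fd = ll_at(c), ll_at(d)
    for _ in range(22):
        left = fc >= fd
        hi = np.where(left, d, hi)
        lo = np.where(left, lo, c)
        c = hi - invphi * (hi - lo)
        d = lo + invphi * (hi - lo)
        fc, fd = ll_at(c), ll_at(d)
    r_ref = np.where(fc >= fd, c, d)
    ll_ref = np.maximum(fc, fd)
    better = ll_ref > best_ll
    best_r = np.where(better, r_ref, best_r)
    best_ll = np.where(better, ll_ref, best_ll)

    ll_half = ll_at(np.full(keep.size, 0.5))
    lod = np.maximum(0.0, (best_ll - ll_half) / np.log(10.0))

    ai, bi = np.unravel_index(keep, (na, nb))
    ids = matrix.marker_ids
    phase_arr = np.array(phases)
    return pd.DataFrame(
        {
            "marker_a": [ids[i] for i in idx_a[ai]],
            "marker_b": [ids[j] for j in idx_b[bi]],
            "r": np.minimum(best_r, _R_MAX),
            "lod": lod,
            "phase1": phase_arr[best_phase, 0],
            "phase2": phase_arr[best_phase, 1],
            "n": n_joint.astype(int),
        }
    )
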