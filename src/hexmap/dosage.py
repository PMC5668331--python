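"""Marker dosage matrices for a bi-parental F1 population at even ploidy.

A dosage is the integer count (0..ploidy) of the alternative allele at a
bi-allelic SNP in a polyploid genotype.  A hexaploid has seven dosage
classes (0..6).  Under polysomic inheritance a parent of dosage ``d``
transmits ``k`` allele copies in a gamete of ``ploidy/2`` chromosomes with
hypergeometric probability (random bivalent pairing, no double reduction).

This module ingests, validates, filters and canonicalizes dosage matrices:
segregation chi-square tests, marker/individual filtering, duplicate
binning, and the fundamental-form canonicalization of parental dosage
pairs under joint allele-label swap.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

MISSING = -1  # in-memory sentinel for a missing dosage call
NA_TOKEN = "NA"  # on-disk representation


class HexmapError(ValueError):
    """Invalid argument or data inconsistency."""


# ---------------------------------------------------------------------------
# segregation model


@lru_cache(maxsize=None)
def gamete_dosage_distribution(ploidy: int, parent_dosage: int) -> dict[int, float]:
    """Distribution of the allele dosage transmitted in a single gamete.

    A parent of dosage ``d`` at even ploidy ``2m`` transmits ``k`` copies
    with probability C(d,k)*C(2m-d, m-k)/C(2m, m): the gamete receives a
    uniform random half of the homologues (polysomic inheritance, no
    double reduction).

    Returns a dict mapping gamete dosage -> probability over the support
    max(0, d-m)..min(d, m).
    """
    _check_ploidy(ploidy)
    if not 0 <= parent_dosage <= ploidy:
        raise HexmapError(f"parent dosage {parent_dosage} outside 0..{ploidy}")
    m = ploidy // 2
    denom = comb(ploidy, m, exact=True)
    out = {}
    for k in range(max(0, parent_dosage - m), min(parent_dosage, m) + 1):
        out[k] = (
            comb(parent_dosage, k, exact=True)
            * comb(ploidy - parent_dosage, m - k, exact=True)
            / denom
        )
    return out


@lru_cache(maxsize=None)
def offspring_dosage_distribution(ploidy: int, d1: int, d2: int) -> dict[int, float]:
    """F1 offspring dosage distribution: convolution of the two parental
    gamete distributions."""
    g1 = gamete_dosage_distribution(ploidy, d1)
    g2 = gamete_dosage_distribution(ploidy, d2)
    out: dict[int, float] = {}
    for k1, p1 in g1.items():
        for k2, p2 in g2.items():
            out[k1 + k2] = out.get(k1 + k2, 0.0) + p1 * p2
    return dict(sorted(out.items()))


def is_segregating(ploidy: int, d1: int, d2: int) -> bool:
    """A marker segregates iff its expected offspring distribution has at
    least two support points, i.e. some parent is heterozygous."""
    return len(offspring_dosage_distribution(ploidy, d1, d2)) >= 2


def fundamental_form(ploidy: int, d1: int, d2: int) -> tuple[int, int]:
    """Canonical parental dosage pair under joint allele-label swap.

    Swapping reference and alternative allele maps (d1, d2) to
    (ploidy-d1, ploidy-d2) and leaves segregation untouched.  The
    representative with d1+d2 <= ploidy (ties: smaller d1) is chosen.
    Idempotent by construction.
    """
    _check_ploidy(ploidy)
    for d in (d1, d2):
        if not 0 <= d <= ploidy:
            raise HexmapError(f"dosage {d} outside 0..{ploidy}")
    a, b = (ploidy - d1, ploidy - d2)
    if d1 + d2 < ploidy or (d1 + d2 == ploidy and d1 <= a):
        return (d1, d2)
    return (a, b)


def _check_ploidy(ploidy: int) -> None:
    if ploidy < 2 or ploidy % 2:
        raise HexmapError(f"ploidy must be a positive even integer, got {ploidy}")


# ---------------------------------------------------------------------------
# container


@dataclass
class DosageMatrix:
    """Integer dosage calls for parents and F1 progeny.

    ``progeny`` is an int8 array of shape (n_markers, n_individuals) with
    values 0..ploidy or MISSING; ``parental`` is (n_markers, 2).
    """

    ploidy: int
    marker_ids: list[str]
    individual_ids: list[str]
    parental: np.ndarray
    progeny: np.ndarray

    def __post_init__(self) -> None:
        _check_ploidy(self.ploidy)
        self.parental = np.asarray(self.parental, dtype=np.int16)
        self.progeny = np.asarray(self.progeny, dtype=np.int16)
        n_mark, n_ind = self.progeny.shape
        if len(self.marker_ids) != n_mark or len(self.individual_ids) != n_ind:
            raise HexmapError("id lists do not match matrix shape")
        if len(set(self.marker_ids)) != n_mark:
            raise HexmapError("marker ids are not unique")
        if self.parental.shape != (n_mark, 2):
            raise HexmapError("parental dosages must be (n_markers, 2)")
        bad = (self.parental < 0) | (self.parental > self.ploidy)
        if bad.any():
            raise HexmapError("parental dosages outside 0..ploidy or missing")
        ok = (self.progeny == MISSING) | (
            (self.progeny >= 0) & (self.progeny <= self.ploidy)
        )
        if not ok.all():
            raise HexmapError("progeny dosages outside 0..ploidy")

    @property
    def n_markers(self) -> int:
        return self.progeny.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.progeny.shape[1]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise HexmapError(f"unknown marker {marker_id!r}") from None

    def missing_fraction_markers(self) -> np.ndarray:
        return (self.progeny == MISSING).mean(axis=1)

    def missing_fraction_individuals(self) -> np.ndarray:
        return (self.progeny == MISSING).mean(axis=0)

    def seg_type(self, i: int) -> tuple[int, int]:
        return (int(self.parental[i, 0]), int(self.parental[i, 1]))

    def subset(self, marker_idx=None, individual_idx=None) -> "DosageMatrix":
        mi = (
            np.arange(self.n_markers)
            if marker_idx is None
            else np.asarray(marker_idx, dtype=int)
        )
        ii = (
            np.arange(self.n_individuals)
            if individual_idx is None
            else np.asarray(individual_idx, dtype=int)
        )
        return DosageMatrix(
            ploidy=self.ploidy,
            marker_ids=[self.marker_ids[i] for i in mi],
            individual_ids=[self.individual_ids[j] for j in ii],
            parental=self.parental[mi],
            progeny=self.progeny[np.ix_(mi, ii)],
        )

    # -- delimited text round trip -------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.progeny, index=self.marker_ids, columns=self.individual_ids
        )
        df.insert(0, "P2", self.parental[:, 1])
        df.insert(0, "P1", self.parental[:, 0])
        df.index.name = "marker_id"
        return df

    def write(self, path, sep: str = "\t") -> None:
        df = self.to_frame().astype(object)
        prog = df.iloc[:, 2:]
        df.iloc[:, 2:] = prog.where(prog != MISSING, NA_TOKEN)
        df.to_csv(path, sep=sep)


def read_dosage_file(path, ploidy: int, sep: str | None = None) -> DosageMatrix:
    """Read a dosage matrix from delimited text.

    One marker per row; columns marker_id, P1, P2, then one column per
    individual; missing = "NA"; header row required.  ``sep=None``
    sniffs comma vs tab from the header line.
    """
    if sep is None:
        if hasattr(path, "read"):
            head = path.readline()
            path.seek(0)
        else:
            with open(path) as fh:
                head = fh.readline()
        sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=sep, na_values=[NA_TOKEN], dtype={0: str})
    df = df.set_index(df.columns[0])
    if list(df.columns[:2]) != ["P1", "P2"]:
        raise HexmapError("dosage file must have columns marker_id, P1, P2, ...")
    if df[["P1", "P2"]].isna().any().any():
        raise HexmapError("parental dosages may not be missing")
    prog = df.iloc[:, 2:].to_numpy(dtype=float)
    prog = np.where(np.isnan(prog), MISSING, prog).astype(np.int16)
    return DosageMatrix(
        ploidy=ploidy,
        marker_ids=[str(m) for m in df.index],
        individual_ids=[str(c) for c in df.columns[2:]],
        parental=df[["P1", "P2"]].to_numpy(dtype=np.int16),
        progeny=prog,
    )


# ---------------------------------------------------------------------------
# quality filtering


def segregation_test(
    ploidy: int, d1: int, d2: int, observed: np.ndarray
) -> tuple[float, float]:
    """Chi-square goodness-of-fit of progeny dosages against the polysomic
    expectation for parental dosages (d1, d2).

    ``observed`` is a 1-D array of non-missing progeny dosages.  Degrees of
    freedom = (#classes with nonzero expectation) - 1.  Observations in
    zero-expectation classes contribute an infinite statistic (p = 0).
    """
    observed = np.asarray(observed)
    observed = observed[observed != MISSING]
    n = observed.size
    if n == 0:
        raise HexmapError("segregation test undefined: all progeny missing")
    expected = offspring_dosage_distribution(ploidy, d1, d2)
    df = len(expected) - 1
    if df == 0:
        # non-segregating: either all observations match (chi2=0) or the
        # data are impossible under the cross
        only = next(iter(expected))
        return (0.0, 1.0) if (observed == only).all() else (np.inf, 0.0)
    counts = np.bincount(observed, minlength=ploidy + 1)
    impossible = sum(
        counts[d] for d in range(ploidy + 1) if d not in expected and counts[d]
    )
    if impossible:
        return (np.inf, 0.0)
    chi2 = sum(
        (counts[d] - n * p) ** 2 / (n * p) for d, p in expected.items()
    )
    return (float(chi2), float(stats.chi2.sf(chi2, df)))


@dataclass
class FilterReport:
    """Removal bookkeeping from marker / individual filtering."""

    removed_markers: dict[str, str] = field(default_factory=dict)
    removed_individuals: dict[str, str] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for reason in list(self.removed_markers.values()) + list(
            self.removed_individuals.values()
        ):
            out[reason] = out.get(reason, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [("marker", k, v) for k, v in self.removed_markers.items()]
        rows += [("individual", k, v) for k, v in self.removed_individuals.items()]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])


def filter_markers(
    matrix: DosageMatrix, max_missing: float = 0.05, skew_alpha: float = 0.001
) -> tuple[DosageMatrix, FilterReport]:
    """Drop non-segregating, high-missingness and skewed markers.

    Retained markers segregate under the polysomic model, have a progeny
    missing fraction <= ``max_missing`` and a segregation-test p-value
    >= ``skew_alpha``.
    """
    report = FilterReport()
    keep = []
    miss = matrix.missing_fraction_markers()
    for i, mid in enumerate(matrix.marker_ids):
        d1, d2 = matrix.seg_type(i)
        if not is_segregating(matrix.ploidy, d1, d2):
            report.removed_markers[mid] = "non_segregating"
            continue
        if miss[i] > max_missing:
            report.removed_markers[mid] = "missing"
            continue
        row = matrix.progeny[i]
        if not (row != MISSING).any():
            report.removed_markers[mid] = "missing"
            continue
        _, p = segregation_test(matrix.ploidy, d1, d2, row)
        if p < skew_alpha:
            report.removed_markers[mid] = "skewed"
            continue
        keep.append(i)
    if not keep:
        import warnings

        warnings.warn("marker filtering removed every marker", stacklevel=2)
    return matrix.subset(marker_idx=keep), report


def impossible_dosage_rate(matrix: DosageMatrix) -> np.ndarray:
    """Per individual: fraction of non-missing calls with zero probability
    under the cross's offspring distribution.  Selfings of one parent show
    systematically impossible dosages at markers where the other parent
    contributes (e.g. dosage 2 at a 1x0 marker)."""
    possible = np.zeros((matrix.n_markers, matrix.ploidy + 2), dtype=bool)
    for i in range(matrix.n_markers):
        d1, d2 = matrix.seg_type(i)
        for d in offspring_dosage_distribution(matrix.ploidy, d1, d2):
            possible[i, d] = True
    possible[:, MISSING] = True  # missing never counts as impossible
    ok = possible[np.arange(matrix.n_markers)[:, None], matrix.progeny]
    nonmiss = (matrix.progeny != MISSING).sum(axis=0).astype(float)
    nonmiss[nonmiss == 0] = 1.0
    return (~ok).sum(axis=0) / nonmiss


def filter_individuals(
    matrix: DosageMatrix,
    max_missing: float = 0.10,
    max_impossible: float = 0.02,
) -> tuple[DosageMatrix, FilterReport]:
    """Drop individuals with too much missing data and flag likely
    selfings / outliers whose dosages are incompatible with the cross at
    more than ``max_impossible`` of their non-missing markers."""
    report = FilterReport()
    miss = matrix.missing_fraction_individuals()
    bad_rate = impossible_dosage_rate(matrix)
    keep = []
    for j, iid in enumerate(matrix.individual_ids):
        if miss[j] > max_missing:
            report.removed_individuals[iid] = "missing"
        elif bad_rate[j] > max_impossible:
            report.removed_individuals[iid] = "cross_incompatible"
        else:
            keep.append(j)
    return matrix.subset(individual_idx=keep), report


# ---------------------------------------------------------------------------
# duplicate binning


@dataclass
class MarkerBin:
    representative: str
    members: list[str]


def bin_duplicates(matrix: DosageMatrix) -> list[MarkerBin]:
    """Group markers with identical non-missing dosage vectors.

    Identity is judged on shared non-missing entries; bins are formed
    greedily in marker-input order against existing representatives
    (deterministic; avoids intransitivity ambiguity).  The member with the
    fewest missing values becomes the representative.
    """
    prog = matrix.progeny
    miss_count = (prog == MISSING).sum(axis=1)
    bins: list[list[int]] = []
    sig_map: dict[bytes, int] = {}  # exact-signature fast path
    gappy_bins: list[int] = []  # bins whose founding representative has missing data
    for i in range(matrix.n_markers):
        sig = prog[i].tobytes()
        if sig in sig_map:
            bins[sig_map[sig]].append(i)
            continue
        # complete rows can only extend a complete bin via exact identity
        # (handled above) or a bin founded on a gappy representative
        candidates = gappy_bins if miss_count[i] == 0 else range(len(bins))
        placed = False
        for bi in candidates:
            rep = bins[bi][0]
            both = (prog[i] != MISSING) & (prog[rep] != MISSING)
            if (prog[i][both] == prog[rep][both]).all():
                bins[bi].append(i)
                placed = True
                break
        if not placed:
            sig_map[sig] = len(bins)
            if miss_count[i]:
                gappy_bins.append(len(bins))
            bins.append([i])
    out = []
    for b in bins:
        rep = min(b, key=lambda i: (miss_count[i], i))
        out.append(
            MarkerBin(
                representative=matrix.marker_ids[rep],
                members=[matrix.marker_ids[i] for i in b],
            )
        )
    return out
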