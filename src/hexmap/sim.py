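"""Random-bivalent-pairing meiosis simulator for even-ploidy F1 populations.

Serves as fixture generator and brute-force oracle for the linkage,
phasing and IBD machinery: every simulated population carries its truth
(parental phases and per-locus founder-homologue inheritance).

Model: at meiosis the ``2m`` homologues of a chromosome form ``m``
bivalents, the pairing (a perfect matching) drawn uniformly from the
(2m-1)!! possibilities — 15 for a hexaploid, 3 for a tetraploid.  Each
bivalent transmits one recombinant product whose founder-homologue
identity switches at the points of a Poisson process of rate 1 per
Morgan along the chromosome, which reproduces Haldane's mapping function
(no crossover interference, no double reduction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .dosage import MISSING, DosageMatrix, HexmapError, _check_ploidy


@lru_cache(maxsize=None)
def enumerate_bivalent_pairings(ploidy: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """All perfect matchings of homologues 0..ploidy-1 into bivalents.

    Returns (ploidy-1)!! distinct matchings, each a tuple of ploidy/2
    disjoint pairs covering every homologue.
    """
    _check_ploidy(ploidy)

    def rec(items: tuple[int, ...]):
        if not items:
            yield ()
            return
        first, rest = items[0], items[1:]
        for k, partner in enumerate(rest):
            remaining = rest[:k] + rest[k + 1 :]
            for tail in rec(remaining):
                yield ((first, partner),) + tail

    return tuple(rec(tuple(range(ploidy))))


@dataclass
class ParentalGenome:
    """Phased parental genome: per chromosome, a (ploidy x n_markers)
    binary allele matrix on a shared cM grid.

    ``positions[c]`` are nonnegative, nondecreasing marker positions (cM);
    ``homologues[c]`` rows are the ploidy homologous chromosomes.
    """

    ploidy: int
    positions: list[np.ndarray]
    homologues: list[np.ndarray]

    def __post_init__(self) -> None:
        _check_ploidy(self.ploidy)
        if len(self.positions) != len(self.homologues):
            raise HexmapError("positions/homologues chromosome count mismatch")
        self.positions = [np.asarray(p, dtype=float) for p in self.positions]
        self.homologues = [np.asarray(h, dtype=np.int8) for h in self.homologues]
        for pos, hom in zip(self.positions, self.homologues):
            if hom.shape != (self.ploidy, pos.size):
                raise HexmapError("homologue matrix shape mismatch")
            if (np.diff(pos) < 0).any() or (pos < 0).any():
                raise HexmapError("marker positions must be nonnegative nondecreasing")

    @property
    def n_chromosomes(self) -> int:
        return len(self.positions)

    def dosages(self, chrom: int) -> np.ndarray:
        return self.homologues[chrom].sum(axis=0)


def simulate_gamete(
    parent: ParentalGenome, chrom: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One meiotic product for one chromosome.

    Returns ``(alleles, labels)``: per transmitted homologue (ploidy/2
    rows) the allele states and the founder-homologue index at every
    marker locus.
    """
    pairings = enumerate_bivalent_pairings(parent.ploidy)
    pairing = pairings[rng.integers(len(pairings))]
    pos = parent.positions[chrom]
    length = float(pos[-1]) if pos.size else 0.0
    m = parent.ploidy // 2
    labels = np.empty((m, pos.size), dtype=np.int16)
    for b, (i, j) in enumerate(pairing):
        current = [i, j] if rng.random() < 0.5 else [j, i]
        # founder switch points: Poisson rate 1/Morgan = 0.01/cM (Haldane)
        n_x = rng.poisson(0.01 * length)
        cuts = np.sort(rng.uniform(0.0, length, size=n_x))
        seg = np.searchsorted(cuts, pos, side="right") % 2
        labels[b] = np.where(seg == 0, current[0], current[1])
    alleles = parent.homologues[chrom][labels, np.arange(pos.size)]
    return alleles, labels


@dataclass
class InheritanceTruth:
    """Founder-homologue labels per individual, chromosome and marker.

    ``labels[c]`` has shape (n_individuals, ploidy, n_markers): for each
    individual the ploidy/2 maternal then ploidy/2 paternal transmitted
    homologues, valued 0..ploidy-1 within the transmitting parent.
    """

    ploidy: int
    labels: list[np.ndarray] = field(default_factory=list)

    def presence(self, chrom: int) -> np.ndarray:
        """Indicator array (n_individuals, 2*ploidy, n_markers): does
        parental homologue h reach the individual at each locus?  Rows
        0..ploidy-1 are P1 homologues, ploidy..2*ploidy-1 are P2's."""
        lab = self.labels[chrom]
        n_ind, p, n_mark = lab.shape
        m = p // 2
        out = np.zeros((n_ind, 2 * self.ploidy, n_mark), dtype=bool)
        ind = np.arange(n_ind)[:, None]
        loc = np.arange(n_mark)[None, :]
        for g in range(m):
            out[ind, lab[:, g, :], loc] = True
        for g in range(m, p):
            out[ind, self.ploidy + lab[:, g, :], loc] = True
        return out

    def to_frame(self, chrom: int, individual_ids, marker_ids) -> pd.DataFrame:
        lab = self.labels[chrom]
        rows = []
        for i, iid in enumerate(individual_ids):
            for g in range(lab.shape[1]):
                rows.append([iid, g] + list(lab[i, g]))
        return pd.DataFrame(rows, columns=["individual", "gamete_slot"] + list(marker_ids))


def simulate_f1(
    p1: ParentalGenome,
    p2: ParentalGenome,
    n_individuals: int,
    seed: int | np.random.Generator,
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    marker_prefix: str = "M",
    marker_ids: list[str] | None = None,
) -> tuple[DosageMatrix, InheritanceTruth]:
    """Simulate an F1 population with known inheritance truth.

    Dosage = allele count over the six (2m) inherited homologue segments.
    Optional uniform missing-data injection and genotyping errors
    (+/-1 dosage, clipped) at the given per-call rates.
    """
    if p1.ploidy != p2.ploidy or p1.n_chromosomes != p2.n_chromosomes:
        raise HexmapError("parents must share ploidy and chromosome count")
    for c in range(p1.n_chromosomes):
        if not np.array_equal(p1.positions[c], p2.positions[c]):
            raise HexmapError("parents must share marker grids")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ploidy = p1.ploidy
    truth = InheritanceTruth(ploidy=ploidy)
    dosage_blocks = []
    auto_ids: list[str] = []
    for c in range(p1.n_chromosomes):
        n_mark = p1.positions[c].size
        lab = np.empty((n_individuals, ploidy, n_mark), dtype=np.int16)
        dos = np.empty((n_mark, n_individuals), dtype=np.int16)
        m = ploidy // 2
        for i in range(n_individuals):
            a1, l1 = simulate_gamete(p1, c, rng)
            a2, l2 = simulate_gamete(p2, c, rng)
            lab[i, :m] = l1
            lab[i, m:] = l2
            dos[:, i] = a1.sum(axis=0) + a2.sum(axis=0)
        truth.labels.append(lab)
        dosage_blocks.append(dos)
        auto_ids += [f"{marker_prefix}{c+1}_{k+1}" for k in range(n_mark)]
    if marker_ids is None:
        marker_ids = auto_ids
    progeny = np.vstack(dosage_blocks)
    if error_rate > 0:
        err = rng.random(progeny.shape) < error_rate
        shift = rng.choice([-1, 1], size=progeny.shape)
        progeny = np.where(err, np.clip(progeny + shift, 0, ploidy), progeny)
    if missing_rate > 0:
        progeny = np.where(
            rng.random(progeny.shape) < missing_rate, MISSING, progeny
        ).astype(np.int16)
    parental = np.vstack(
        [
            np.column_stack([p1.dosages(c), p2.dosages(c)])
            for c in range(p1.n_chromosomes)
        ]
    )
    matrix = DosageMatrix(
        ploidy=ploidy,
        marker_ids=marker_ids,
        individual_ids=[f"F1_{i+1:04d}" for i in range(n_individuals)],
        parental=parental,
        progeny=progeny,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# fixture factory


@dataclass
class SimulatedDesign:
    """Bookkeeping for a designed marker layout (which homologue carries
    which marker's alleles)."""

    marker_ids: list[str]
    chrom: np.ndarray  # chromosome index per marker
    position: np.ndarray  # cM per marker
    # allele placement: per marker, per parent, tuple of carrier homologues
    carriers_p1: list[tuple[int, ...]]
    carriers_p2: list[tuple[int, ...]]


def design_population(
    ploidy: int = 6,
    n_chromosomes: int = 2,
    chrom_length_cM: float = 90.0,
    n_simplex_per_homologue: int = 10,
    n_duplex: int = 0,
    n_simplex_simplex: int = 0,
    seed: int | np.random.Generator = 0,
) -> tuple[ParentalGenome, ParentalGenome, SimulatedDesign]:
    """Lay out a marker design mirroring a typical F1 mapping panel.

    Per chromosome and parent, every homologue carries
    ``n_simplex_per_homologue`` simplex (1x0 / 0x1) markers at uniform
    random positions; ``n_duplex`` 2x0 markers (two random homologues of
    P1) and ``n_simplex_simplex`` 1x1 markers (one random homologue of
    each parent) are added per chromosome.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ids: list[str] = []
    chroms: list[int] = []
    poss: list[float] = []
    car1: list[tuple[int, ...]] = []
    car2: list[tuple[int, ...]] = []
    for c in range(n_chromosomes):
        entries: list[tuple[float, str, tuple[int, ...], tuple[int, ...]]] = []
        for parent in (1, 2):
            for h in range(ploidy):
                for k in range(n_simplex_per_homologue):
                    pos = float(rng.uniform(0, chrom_length_cM))
                    name = f"S{parent}_c{c+1}_h{h+1}_{k+1}"
                    c1 = (h,) if parent == 1 else ()
                    c2 = (h,) if parent == 2 else ()
                    entries.append((pos, name, c1, c2))
        for k in range(n_duplex):
            pos = float(rng.uniform(0, chrom_length_cM))
            hh = tuple(sorted(rng.choice(ploidy, size=2, replace=False).tolist()))
            entries.append((pos, f"D_c{c+1}_{k+1}", hh, ()))
        for k in range(n_simplex_simplex):
            pos = float(rng.uniform(0, chrom_length_cM))
            h1 = int(rng.integers(ploidy))
            h2 = int(rng.integers(ploidy))
            entries.append((pos, f"B_c{c+1}_{k+1}", (h1,), (h2,)))
        entries.sort(key=lambda e: (e[0], e[1]))
        for pos, name, c1, c2 in entries:
            ids.append(name)
            chroms.append(c)
            poss.append(pos)
            car1.append(c1)
            car2.append(c2)
    chrom_arr = np.array(chroms)
    pos_arr = np.array(poss)
    genomes = []
    for parent, carriers in ((1, car1), (2, car2)):
        positions = []
        homologues = []
        for c in range(n_chromosomes):
            idx = np.where(chrom_arr == c)[0]
            positions.append(pos_arr[idx])
            hom = np.zeros((ploidy, idx.size), dtype=np.int8)
            for col, mi in enumerate(idx):
                for h in carriers[mi]:
                    hom[h, col] = 1
            homologues.append(hom)
        genomes.append(
            ParentalGenome(ploidy=ploidy, positions=positions, homologues=homologues)
        )
    design = SimulatedDesign(
        marker_ids=ids,
        chrom=chrom_arr,
        position=pos_arr,
        carriers_p1=car1,
        carriers_p2=car2,
    )
    return genomes[0], genomes[1], design
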