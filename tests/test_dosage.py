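import io

import numpy as np
import pytest

from hexmap import dosage as dm
from hexmap.dosage import (
    MISSING,
    DosageMatrix,
    HexmapError,
    bin_duplicates,
    filter_individuals,
    filter_markers,
    fundamental_form,
    gamete_dosage_distribution,
    is_segregating,
    offspring_dosage_distribution,
    read_dosage_file,
    segregation_test,
)

from oracles import gamete_dosage_bruteforce


class TestGameteDistribution:
    @pytest.mark.parametrize(
        "ploidy,d,expected",
        [
            (6, 0, {0: 1.0}),
            (6, 1, {0: 0.5, 1: 0.5}),
            (6, 3, {0: 0.05, 1: 0.45, 2: 0.45, 3: 0.05}),
            (6, 6, {3: 1.0}),
            (4, 2, {0: 1 / 6, 1: 4 / 6, 2: 1 / 6}),
        ],
    )
    def test_known_values(self, ploidy, d, expected):
        got = gamete_dosage_distribution(ploidy, d)
        assert set(got) == set(expected)
        for k in expected:
            assert got[k] == pytest.approx(expected[k])

    @pytest.mark.parametrize("ploidy", [2, 4, 6, 8])
    def test_matches_subset_enumeration(self, ploidy):
        for d in range(ploidy + 1):
            got = gamete_dosage_distribution(ploidy, d)
            want = gamete_dosage_bruteforce(ploidy, d)
            assert set(got) == set(want)
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-12)

    def test_support_and_normalisation(self):
        for d in range(7):
            dist = gamete_dosage_distribution(6, d)
            assert sum(dist.values()) == pytest.approx(1.0)
            assert min(dist) == max(0, d - 3)
            assert max(dist) == min(d, 3)

    @pytest.mark.parametrize("ploidy,d", [(5, 2), (6, -1), (6, 7)])
    def test_invalid_arguments(self, ploidy, d):
        with pytest.raises(HexmapError):
            gamete_dosage_distribution(ploidy, d)


class TestOffspringDistribution:
    @pytest.mark.parametrize(
        "d1,d2,expected",
        [
            (1, 0, {0: 0.5, 1: 0.5}),
            (1, 1, {0: 0.25, 1: 0.5, 2: 0.25}),
            (6, 6, {6: 1.0}),
        ],
    )
    def test_known_values(self, d1, d2, expected):
        got = offspring_dosage_distribution(6, d1, d2)
        assert got == pytest.approx(expected)

    def test_mean_is_midparent(self):
        for d1 in range(7):
            for d2 in range(7):
                dist = offspring_dosage_distribution(6, d1, d2)
                mean = sum(k * p for k, p in dist.items())
                assert mean == pytest.approx((d1 + d2) / 2)

    def test_segregation_support(self):
        # >= 2 classes iff some parent heterozygous, exactly 1 otherwise
        for d1 in range(7):
            for d2 in range(7):
                n_classes = len(offspring_dosage_distribution(6, d1, d2))
                het = d1 % 6 != 0 or d2 % 6 != 0
                assert (n_classes >= 2) == het == is_segregating(6, d1, d2)


class TestFundamentalForm:
    def test_idempotent_and_canonical(self):
        for d1 in range(7):
            for d2 in range(7):
                f = fundamental_form(6, d1, d2)
                assert fundamental_form(6, *f) == f
                assert f[0] + f[1] <= 6
                assert f in ((d1, d2), (6 - d1, 6 - d2))

    def test_allele_swap_preserves_segregation(self):
        # swapping allele labels mirrors the offspring distribution
        for d1 in range(7):
            for d2 in range(7):
                a = offspring_dosage_distribution(6, d1, d2)
                b = offspring_dosage_distribution(6, 6 - d1, 6 - d2)
                assert a == pytest.approx({6 - k: p for k, p in b.items()})


class TestSegregationTest:
    def test_one_zero_moderate_skew(self):
        observed = np.array([0] * 180 + [1] * 220)
        chi2, p = segregation_test(6, 1, 0, observed)
        assert chi2 == pytest.approx(4.0)
        assert p == pytest.approx(0.0455, abs=1e-3)
        assert p >= 0.001  # retained at the mapping filter threshold

    def test_exact_expectation(self):
        observed = np.array([0] * 200 + [1] * 200)
        chi2, p = segregation_test(6, 1, 0, observed)
        assert chi2 == 0.0 and p == 1.0

    def test_fully_skewed(self):
        chi2, p = segregation_test(6, 1, 0, np.zeros(400, dtype=int))
        assert chi2 == pytest.approx(400.0)
        assert p < 1e-10

    def test_all_missing_is_error(self):
        with pytest.raises(HexmapError):
            segregation_test(6, 1, 0, np.full(10, MISSING))

    def test_impossible_class_gives_zero_p(self):
        observed = np.array([0] * 199 + [1] * 200 + [5])
        _, p = segregation_test(6, 1, 0, observed)
        assert p == 0.0


def _matrix(parental, progeny, ploidy=6):
    n_mark = len(parental)
    n_ind = len(progeny[0])
    return DosageMatrix(
        ploidy=ploidy,
        marker_ids=[f"m{i}" for i in range(n_mark)],
        individual_ids=[f"i{j}" for j in range(n_ind)],
        parental=np.array(parental),
        progeny=np.array(progeny),
    )


class TestFilterMarkers:
    def test_removal_reasons(self):
        n = 100
        rng = np.random.default_rng(0)
        ok_row = rng.binomial(1, 0.5, size=n)
        missing_row = ok_row.copy()
        missing_row[:6] = MISSING  # 6% missing
        skewed_row = np.zeros(n, dtype=int)
        nonseg_row = np.full(n, 3)
        mat = _matrix(
            [(1, 0), (1, 0), (1, 0), (6, 0)],
            [ok_row, missing_row, skewed_row, nonseg_row],
        )
        out, report = filter_markers(mat)
        assert out.marker_ids == ["m0"]
        assert report.removed_markers == {
            "m1": "missing",
            "m2": "skewed",
            "m3": "non_segregating",
        }

    def test_idempotent(self, small_pop):
        matrix, _, _ = small_pop
        once, _ = filter_markers(matrix)
        twice, rep = filter_markers(once)
        assert twice.marker_ids == once.marker_ids
        assert not rep.removed_markers

    def test_empty_result_warns(self):
        mat = _matrix([(6, 0)], [np.full(50, 3)])
        with pytest.warns(UserWarning):
            out, _ = filter_markers(mat)
        assert out.n_markers == 0


class TestFilterIndividuals:
    def test_high_missingness_removed(self):
        rng = np.random.default_rng(1)
        prog = rng.binomial(1, 0.5, size=(50, 10))
        prog[:7, 0] = MISSING  # 14% missing for individual 0
        mat = _matrix([(1, 0)] * 50, prog)
        out, report = filter_individuals(mat)
        assert report.removed_individuals == {"i0": "missing"}
        assert out.n_individuals == 9

    def test_selfing_flagged_clean_f1_retained(self, small_pop):
        matrix, _, _ = small_pop
        rng = np.random.default_rng(5)
        # a selfing of parent 1 carries dosages drawn from the P1 x P1
        # cross: impossible at markers where P2 contributes
        progeny = matrix.progeny.copy()
        selfed = np.empty(matrix.n_markers, dtype=np.int16)
        for i in range(matrix.n_markers):
            d1 = matrix.parental[i, 0]
            dist = offspring_dosage_distribution(6, d1, d1)
            ks, ps = zip(*dist.items())
            selfed[i] = rng.choice(ks, p=ps)
        progeny[:, 0] = selfed
        mat = DosageMatrix(
            ploidy=6,
            marker_ids=matrix.marker_ids,
            individual_ids=matrix.individual_ids,
            parental=matrix.parental,
            progeny=progeny,
        )
        out, report = filter_individuals(mat)
        iid = matrix.individual_ids[0]
        assert report.removed_individuals.get(iid) == "cross_incompatible"
        # everything else is a clean simulated F1 and stays
        assert out.n_individuals == mat.n_individuals - 1


class TestBinDuplicates:
    def test_identical_markers_share_a_bin(self):
        row = np.array([0, 1, 1, 0, 1] * 20)
        mat = _matrix([(1, 0)] * 2, [row, row])
        bins = bin_duplicates(mat)
        assert len(bins) == 1 and sorted(bins[0].members) == ["m0", "m1"]

    def test_single_mismatch_separates(self):
        row = np.array([0, 1, 1, 0, 1] * 20)
        row2 = row.copy()
        row2[3] = 1
        bins = bin_duplicates(_matrix([(1, 0)] * 2, [row, row2]))
        assert len(bins) == 2

    def test_representative_has_fewest_missing(self):
        row = np.array([0, 1, 1, 0, 1] * 20)
        gappy = row.copy()
        gappy[:3] = MISSING
        bins = bin_duplicates(_matrix([(1, 0)] * 2, [gappy, row]))
        assert len(bins) == 1
        assert bins[0].representative == "m1"

    def test_partition_and_pairwise_compatibility(self):
        # three markers pairwise identical on shared non-missing entries;
        # greedy grouping must still yield a partition in which every
        # member is compatible with its representative
        base = np.array([0, 1, 1, 0, 1, 0, 1, 1] * 10)
        a = base.copy()
        a[:20] = MISSING
        b = base.copy()
        b[20:40] = MISSING
        c = base.copy()
        c[40:60] = MISSING
        mat = _matrix([(1, 0)] * 3, [a, b, c])
        bins = bin_duplicates(mat)
        members = sorted(m for bn in bins for m in bn.members)
        assert members == ["m0", "m1", "m2"]  # a partition
        for bn in bins:
            rep = mat.progeny[mat.marker_index(bn.representative)]
            for m in bn.members:
                row = mat.progeny[mat.marker_index(m)]
                both = (row != MISSING) & (rep != MISSING)
                assert (row[both] == rep[both]).all()


class TestIO:
    def test_round_trip(self, small_pop):
        matrix, _, _ = small_pop
        buf = io.StringIO()
        matrix.write(buf)
        buf.seek(0)
        back = read_dosage_file(buf, ploidy=6, sep="\t")
        assert back.marker_ids == matrix.marker_ids
        assert back.individual_ids == matrix.individual_ids
        assert np.array_equal(back.progeny, matrix.progeny)
        assert np.array_equal(back.parental, matrix.parental)

    def test_na_tokens_become_missing(self):
        text = "marker_id,P1,P2,a,b\nm1,1,0,NA,1\n"
        mat = read_dosage_file(io.StringIO(text), ploidy=6, sep=",")
        assert mat.progeny[0, 0] == MISSING and mat.progeny[0, 1] == 1

    def test_missing_parental_rejected(self):
        text = "marker_id,P1,P2,a\nm1,NA,0,1\n"
        with pytest.raises(HexmapError):
            read_dosage_file(io.StringIO(text), ploidy=6, sep=",")

    def test_validation_rejects_bad_dosage(self):
        with pytest.raises(HexmapError):
            _matrix([(1, 0)], [np.array([7, 0, 1])])
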