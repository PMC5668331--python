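import numpy as np
import pandas as pd
import pytest

from hexmap import evaluation, pipeline
from hexmap.dosage import MISSING, DosageMatrix, HexmapError
from hexmap.ibd import (
    IBDArray,
    _normalize_per_parent,
    gic,
    grid_ibd,
    informative_calls,
    interpolate_ibd,
)
from hexmap.ordering import haldane_r


class TestInformativeCalls:
    def test_biparental_simplex(self):
        dosages = np.array([0, 1, 2, MISSING])
        calls, bad = informative_calls(6, 1, 1, dosages)
        assert calls[0] == 0.0  # no allele: both carriers absent
        assert np.isnan(calls[1])  # single copy: origin ambiguous
        assert calls[2] == 1.0  # both copies: both carriers present
        assert np.isnan(calls[3])
        assert bad == 0

    def test_duplex_zero_dosage(self):
        calls, _ = informative_calls(6, 2, 0, np.array([0, 1, 2]))
        assert calls[0] == 0.0
        assert np.isnan(calls[1])
        assert calls[2] == 1.0

    def test_impossible_dosage_flagged(self):
        calls, bad = informative_calls(6, 1, 1, np.array([3, 2]))
        assert bad == 1
        assert np.isnan(calls[0])

    def test_no_allele_marker_rejected(self):
        with pytest.raises(HexmapError):
            informative_calls(6, 0, 0, np.array([0]))


def _six_simplex_fixture(second_locus_dosage):
    """One P1 simplex marker per homologue at 0 cM plus one extra marker
    on homologue 1 at 5 cM; a single individual carrying h1..h3."""
    marker_ids = [f"s{h}" for h in range(1, 7)] + ["x"]
    parental = np.array([[1, 0]] * 7)
    progeny = np.array([[1], [1], [1], [0], [0], [0], [second_locus_dosage]])
    matrix = DosageMatrix(
        ploidy=6,
        marker_ids=marker_ids,
        individual_ids=["ind1"],
        parental=parental,
        progeny=progeny,
    )
    cols = {f"h{i}": np.zeros(7, dtype=int) for i in range(1, 13)}
    for k in range(6):
        cols[f"h{k + 1}"][k] = 1
    cols["h1"][6] = 1  # marker x sits on homologue 1
    phased = pd.DataFrame({"marker_id": marker_ids, "CLG": 1, **cols})
    positions = {m: 0.0 for m in marker_ids[:6]}
    positions["x"] = 5.0
    return matrix, phased, positions


class TestInterpolateIBD:
    def test_informative_call_is_exact_at_zero_distance(self):
        matrix, phased, positions = _six_simplex_fixture(1)
        arr = interpolate_ibd(matrix, phased, positions, clg=1)
        row0 = list(phased["marker_id"]).index  # rows sorted by position
        # at the 0 cM locus block, h1..h3 present, h4..h6 absent
        locus0 = np.where(arr.positions == 0.0)[0]
        assert np.allclose(arr.prob[locus0[0], 0, :3], 1.0)
        assert np.allclose(arr.prob[locus0[0], 0, 3:6], 0.0)

    def test_haldane_fill_five_cm(self):
        # marker x missing: its h1 probability comes from the informative
        # call 5 cM away, P = 1 - r(5 cM) = 0.953; the six-homologue
        # layout is balanced so normalization leaves it untouched
        matrix, phased, positions = _six_simplex_fixture(MISSING)
        arr = interpolate_ibd(matrix, phased, positions, clg=1)
        locus_x = np.where(arr.positions == 5.0)[0][0]
        assert arr.prob[locus_x, 0, 0] == pytest.approx(1 - haldane_r(5.0), abs=1e-3)
        assert arr.prob[locus_x, 0, 3] == pytest.approx(haldane_r(5.0), abs=1e-3)

    def test_equidistant_conflicting_calls_average(self):
        # h1: present at 0 cM, absent at 10 cM (and h2 the mirror image);
        # h3/h4 present and h5/h6 absent at 5 cM keep the parental sum at
        # 3 so normalization is neutral.  At the 5 cM locus the h1 fill
        # averages (1 - r) from the left and r from the right to 0.5.
        marker_ids = ["a1", "b1", "a2", "b2", "c3", "c4", "c5", "c6"]
        carriers = [0, 0, 1, 1, 2, 3, 4, 5]
        pos = [0.0, 10.0, 0.0, 10.0, 5.0, 5.0, 5.0, 5.0]
        dosages = [1, 0, 0, 1, 1, 1, 0, 0]
        matrix = DosageMatrix(
            ploidy=6,
            marker_ids=marker_ids,
            individual_ids=["i"],
            parental=np.array([[1, 0]] * 8),
            progeny=np.array(dosages)[:, None],
        )
        cols = {f"h{i}": np.zeros(8, dtype=int) for i in range(1, 13)}
        for row, h in enumerate(carriers):
            cols[f"h{h + 1}"][row] = 1
        phased = pd.DataFrame({"marker_id": marker_ids, "CLG": 1, **cols})
        positions = dict(zip(marker_ids, pos))
        arr = interpolate_ibd(matrix, phased, positions, clg=1)
        locus_mid = np.where(arr.positions == 5.0)[0][0]
        assert arr.prob[locus_mid, 0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_empty_homologue_recovered_from_others(self, small_pop):
        matrix, truth, design = small_pop
        drop = {
            m
            for m, c1, c2, ch in zip(
                design.marker_ids,
                design.carriers_p1,
                design.carriers_p2,
                design.chrom,
            )
            if ch == 0 and c2 == (0,) and not c1
        }
        keep = [i for i, m in enumerate(matrix.marker_ids) if m not in drop]
        result = pipeline.run_pipeline(
            matrix.subset(marker_idx=keep), pipeline.RunConfig(seed=1)
        )
        # find the CLG of chromosome 0: it has only 11 clusters
        clg = next(c for c in result.clgs if len(c.clusters) == 11)
        arr = result.ibd_marker[clg.clg_id]
        # slot h12 (last P2 slot) has no cluster: probabilities there are
        # complemented purely through the other five homologues
        empty = arr.prob[:, :, 11]
        pres = truth.presence(0)
        truth_rows = [int(i.rsplit("_", 1)[1]) - 1 for i in arr.individual_ids]
        # compare against truth of the dropped homologue at the nearest
        # mapped marker
        posmap = result.maps[clg.clg_id].position_of()
        chrom = dict(zip(design.marker_ids, design.chrom))
        pos_t = dict(zip(design.marker_ids, design.position))
        sub = result.phased_map[result.phased_map["CLG"] == clg.clg_id]
        mk = [m for m in sub["marker_id"] if m in posmap]
        order = np.argsort([posmap[m] for m in mk], kind="stable")
        mk_sorted = [mk[i] for i in order]
        chrom_ids = [m for m in design.marker_ids if chrom[m] == 0]
        concord = []
        for row, mid in enumerate(mk_sorted):
            if chrom[mid] != 0:
                continue
            t = pres[truth_rows, 6 + 0, chrom_ids.index(mid)]
            concord.append(((empty[row] > 0.5) == t).mean())
        assert np.mean(concord) >= 0.8

    def test_per_parent_sums_are_three(self, small_run):
        result, _, _ = small_run
        for arr in result.ibd_marker.values():
            s1 = arr.prob[:, :, :6].sum(axis=2)
            s2 = arr.prob[:, :, 6:].sum(axis=2)
            assert np.allclose(s1, 3.0, atol=1e-6)
            assert np.allclose(s2, 3.0, atol=1e-6)
            assert arr.prob.min() >= 0.0 and arr.prob.max() <= 1.0


class TestNormalization:
    def test_conservation_on_random_tensors(self):
        rng = np.random.default_rng(0)
        prob = rng.uniform(0, 1, size=(5, 9, 12))
        out = _normalize_per_parent(prob, 6)
        assert np.allclose(out[..., :6].sum(axis=-1), 3.0, atol=1e-6)
        assert np.allclose(out[..., 6:].sum(axis=-1), 3.0, atol=1e-6)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_certain_calls_left_in_place(self):
        # parent sum 2.9: the missing 0.1 of presence mass must land on
        # the uncertain homologues, not the certain 0/1 calls
        prob = np.array([[[1.0, 1.0, 0.8, 0.1, 0.0, 0.0] + [0.5] * 6]])
        out = _normalize_per_parent(prob, 6)
        assert out[0, 0, 0] == pytest.approx(1.0, abs=1e-6)
        assert out[0, 0, 4] == pytest.approx(0.0, abs=0.02)
        assert out[0, 0, 2] > 0.8
        assert out[0, 0, 3] > 0.1
        assert out[0, 0, :6].sum() == pytest.approx(3.0, abs=1e-6)


class TestGridIBD:
    def _arr(self, positions, prob):
        return IBDArray(
            clg=1,
            ploidy=6,
            positions=np.asarray(positions, dtype=float),
            individual_ids=[f"F1_{i + 1:04d}" for i in range(prob.shape[1])],
            prob=prob,
            homologue_names=[f"h{i}" for i in range(1, 13)],
        )

    def test_constant_trace_stays_constant(self):
        pos = np.array([0.0, 3.0, 7.0, 12.0, 20.0])
        prob = np.zeros((5, 2, 12))
        prob[:, :, :3] = 1.0
        prob[:, :, 6:9] = 1.0
        grid = grid_ibd(self._arr(pos, prob))
        assert np.allclose(grid.prob[:, :, :3], 1.0)
        assert np.allclose(grid.prob[:, :, 3:6], 0.0)

    def test_grid_positions_contract(self):
        pos = np.array([0.0, 4.0, 9.0, 13.7])
        prob = np.full((4, 1, 12), 0.5)
        grid = grid_ibd(self._arr(pos, prob))
        assert np.array_equal(grid.positions, np.arange(0.0, 15.0))

    def test_values_clamped_and_renormalized(self, small_run):
        result, _, _ = small_run
        for grid in result.ibd_grid.values():
            assert grid.prob.min() >= 0.0 and grid.prob.max() <= 1.0
            assert np.allclose(grid.prob[:, :, :6].sum(axis=2), 3.0, atol=1e-6)

    def test_gridded_probabilities_track_truth(self, small_run):
        result, truth, design = small_run
        cal = evaluation.ibd_calibration(result, truth, design, level="grid")
        high = cal[(cal["bin"] <= 1) | (cal["bin"] >= 8)]
        err = (high["mean_predicted"] - high["observed_frequency"]).abs()
        assert (err <= 0.1).all()


class TestGIC:
    def _profile(self, values):
        prob = np.zeros((1, len(values), 12))
        prob[0, :, 0] = values
        arr = IBDArray(
            clg=1,
            ploidy=6,
            positions=np.array([0.0]),
            individual_ids=[f"i{k}" for k in range(len(values))],
            prob=prob,
            homologue_names=[f"h{i}" for i in range(1, 13)],
        )
        return gic(arr)["h1"].iloc[0]

    def test_fully_informative(self):
        assert self._profile([0.0, 1.0, 1.0, 0.0]) == pytest.approx(1.0)

    def test_uninformative(self):
        assert self._profile([0.5, 0.5]) == pytest.approx(0.0)

    def test_mixed(self):
        assert self._profile([0.75, 0.75, 1.0, 1.0]) == pytest.approx(0.75)

    def test_half_rounds_down(self):
        # P = 0.5 rounds to 0, so |P - [P]| = 0.5
        assert self._profile([0.5]) == pytest.approx(0.0)
        assert self._profile([0.51]) == pytest.approx(1 - 2 * 0.49)

    def test_lower_at_chromosome_ends(self, dense_run):
        result, _, _ = dense_run
        for tab in result.gic.values():
            cols = [c for c in tab.columns if c.startswith("h")]
            prof = tab[cols].mean(axis=1).to_numpy()
            pos = tab["position_cM"].to_numpy()
            ends = prof[(pos <= 3) | (pos >= pos.max() - 3)].mean()
            mid = prof[(pos > 20) & (pos < pos.max() - 20)].mean()
            assert ends < mid
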