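"""Co-localization: AND gate, per-object counting vs oracle, classification,
nuclear accumulation, Pearson r."""

import numpy as np
import pandas as pd
import pytest

from mircoloc import (and_gate, classify_mves, max_intensity_projection,
                      nuclear_accumulation, object_coloc_counts,
                      pearson_coefficient, simulate_field)
from mircoloc.coloc import classification_table
from mircoloc.core import CellMap, Spot, SpotSet
from mircoloc.puncta import assign_spots_to_cells, detect_puncta, spot_mask
from mircoloc.segment import segment_field

from conftest import small_params


class TestAndGate:
    def test_idempotent_commutative_bounded(self, rng):
        a = rng.uniform(size=(16, 16)) < 0.4
        b = rng.uniform(size=(16, 16)) < 0.4
        np.testing.assert_array_equal(and_gate(a, a), a)
        np.testing.assert_array_equal(and_gate(a, b), and_gate(b, a))
        assert and_gate(a, b).sum() <= min(a.sum(), b.sum())

    def test_disjoint_masks_give_empty(self):
        a = np.zeros((4, 4), bool); a[0] = True
        b = np.zeros((4, 4), bool); b[2] = True
        assert not and_gate(a, b).any()

    def test_hand_enumerated_overlap(self):
        # 4x4 grid, overlap enumerated by hand: exactly 3 shared pixels
        a = np.array([[1, 1, 0, 0],
                      [1, 1, 0, 0],
                      [0, 0, 0, 0],
                      [0, 0, 0, 0]], bool)
        b = np.array([[0, 1, 1, 0],
                      [1, 1, 0, 0],
                      [0, 0, 0, 0],
                      [0, 0, 0, 0]], bool)
        assert and_gate(a, b).sum() == 3

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            and_gate(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


def _random_scene(rng, size=128, n_cells=3, n_spots=25):
    """Random label scenes for oracle comparisons (no imaging involved)."""
    cells = np.zeros((size, size), dtype=np.int32)
    w = size // n_cells
    for c in range(n_cells):
        cells[:, c * w:(c + 1) * w] = c + 1
    nuclei = np.zeros_like(cells)
    cm = CellMap(nucleus_labels=nuclei, cell_labels=cells, pixel_size_nm=80.0)
    labels = np.zeros((size, size), dtype=np.int32)
    spots = []
    for lbl in range(1, n_spots + 1):
        r = int(rng.integers(2, size - 3))
        c = int(rng.integers(2, size - 3))
        h = int(rng.integers(1, 4))
        wd = int(rng.integers(1, 4))
        region = labels[r:r + h, c:c + wd]
        if (region != 0).any():
            continue
        labels[r:r + h, c:c + wd] = lbl
        area = h * wd
        spots.append(Spot(lbl, (r + (h - 1) / 2, c + (wd - 1) / 2), area,
                          1.0, float(area), 2 * np.sqrt(area / np.pi),
                          cell_id=int(cells[r, c])))
    other = rng.uniform(size=(size, size)) < 0.15
    return SpotSet("mve", spots, labels), other, cm


def _oracle_counts(spot_set, other_mask, cell_map, min_overlap):
    """Brute force: explicit per-object pixel-set intersection."""
    rows = {}
    other = {tuple(p) for p in np.argwhere(other_mask)}
    for cid in cell_map.retained_cell_ids:
        rows[cid] = [0, 0]
    for s in spot_set.spots:
        if s.cell_id not in rows:
            continue
        pix = {tuple(p) for p in np.argwhere(spot_set.label_image == s.label)}
        rows[s.cell_id][0] += 1
        if len(pix & other) >= min_overlap:
            rows[s.cell_id][1] += 1
    return rows


class TestObjectColoc:
    def test_matches_bruteforce_oracle_on_random_fields(self, rng):
        for _ in range(5):
            ss, other, cm = _random_scene(rng)
            got = object_coloc_counts(ss, other, cm, min_overlap_px=2)
            want = _oracle_counts(ss, other, cm, 2)
            for _, row in got.iterrows():
                assert (row.n_obj, row.n_coloc) == tuple(want[row.cell_id])

    def test_empty_mirna_mask_gives_zero_coloc(self, rng):
        ss, _, cm = _random_scene(rng)
        got = object_coloc_counts(ss, np.zeros(cm.shape, bool), cm)
        assert (got.n_coloc == 0).all()

    def test_superset_mask_gives_rate_one(self, rng):
        ss, _, cm = _random_scene(rng)
        got = object_coloc_counts(ss, np.ones(cm.shape, bool), cm)
        with_objs = got[got.n_obj > 0]
        assert (with_objs.coloc_rate == 1.0).all()

    def test_cells_without_objects_report_missing_rate(self, rng):
        ss, other, cm = _random_scene(rng, n_spots=1)
        got = object_coloc_counts(ss, other, cm)
        empty = got[got.n_obj == 0]
        assert empty.coloc_rate.isna().all()


@pytest.fixture(scope="module")
def scene():
    return _random_scene(np.random.default_rng(5))


class TestClassifyMves:
    def test_empty_masks_give_all_single(self, scene):
        ss, _, cm = scene
        res = classify_mves(ss, np.zeros(cm.shape, bool), np.zeros(cm.shape, bool),
                            cm, rng=np.random.default_rng(0))
        assert all(r.n_single == r.n_evaluated for r in res)

    def test_guide_covering_mask_gives_all_guide_only(self, scene):
        ss, _, cm = scene
        res = classify_mves(ss, np.ones(cm.shape, bool), np.zeros(cm.shape, bool),
                            cm, rng=np.random.default_rng(0))
        assert all(r.n_guide_only == r.n_evaluated for r in res)

    def test_classes_exclusive_and_exhaustive(self, scene, rng):
        ss, other, cm = scene
        res = classify_mves(ss, other, rng.uniform(size=cm.shape) < 0.2, cm,
                            rng=np.random.default_rng(1))
        for r in res:
            assert (r.n_single + r.n_guide_only + r.n_passenger_only
                    + r.n_both == r.n_evaluated)
            assert r.n_evaluated <= min(20, r.n_mve)
            # 3-way projection counts "both" in each positive class
            assert r.n_guide_pos == r.n_guide_only + r.n_both
            assert r.n_passenger_pos == r.n_passenger_only + r.n_both

    def test_sampling_is_seed_deterministic(self, scene):
        ss, other, cm = scene
        r1 = classify_mves(ss, other, other, cm, rng=np.random.default_rng(9))
        r2 = classify_mves(ss, other, other, cm, rng=np.random.default_rng(9))
        t1, t2 = classification_table(r1), classification_table(r2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_category_rates_recover_independent_placement(self):
        """Guide at 0.6 and passenger at 0.2 placed independently: the
        measured per-MVE positive rates and the both-class rate follow the
        product law within +/-0.07 over >= 50 cells."""
        p = small_params(field_size_px=(1024, 1024), n_cells=8,
                         coloc_fraction_guide=0.6, coloc_fraction_passenger=0.2,
                         guide_spots_per_cell_mean=12.0,
                         passenger_spots_per_cell_mean=12.0)
        tot = {"g": 0, "p": 0, "both": 0, "n": 0}
        seeds = [101, 102, 103, 104, 105, 106, 107]
        for fs in seeds:
            stack, truth = simulate_field(p, seed=fs)
            proj = max_intensity_projection(stack)
            cm = segment_field(proj)
            mve = assign_spots_to_cells(
                detect_puncta(proj.channel("mve"), 500.0, 80.0, min_area_px=2), cm)
            gmask = spot_mask(detect_puncta(proj.channel("mirna_guide"), 200.0,
                                            80.0, min_area_px=2))
            pmask = spot_mask(detect_puncta(proj.channel("mirna_passenger"),
                                            200.0, 80.0, min_area_px=2))
            res = classify_mves(mve, gmask, pmask, cm, sample_n=1000,
                                rng=np.random.default_rng(fs))
            for r in res:
                tot["g"] += r.n_guide_pos
                tot["p"] += r.n_passenger_pos
                tot["both"] += r.n_both
                tot["n"] += r.n_evaluated
        assert tot["n"] >= 50 * 8  # >= 50 cells with ~12 MVEs each
        pg, pp = tot["g"] / tot["n"], tot["p"] / tot["n"]
        pboth = tot["both"] / tot["n"]
        # expected per-MVE hit rates from the truth model: an MVE with m MVEs
        # per cell and k colocalized spots is hit w.p. 1-(1-1/m)^k; rather
        # than integrate that analytically we check the independence product
        # law, which holds regardless of the marginals.
        assert abs(pboth - pg * pp) <= 0.07


class TestNuclearAccumulation:
    def test_uniform_image_accumulates_nothing(self, clean_field):
        stack, _ = clean_field
        cm = segment_field(max_intensity_projection(stack))
        res = nuclear_accumulation(np.full(cm.shape, 3.0), cm, ratio_threshold=1.5)
        np.testing.assert_allclose(res.per_cell.ratio, 1.0)
        assert res.fraction_accumulated == 0.0

    def test_nucleus_only_signal_accumulates_everything(self, clean_field):
        stack, _ = clean_field
        cm = segment_field(max_intensity_projection(stack))
        img = np.where(cm.nucleus_labels > 0, 100.0, 1.0)
        res = nuclear_accumulation(img, cm)
        assert res.fraction_accumulated == 1.0

    def test_simulated_nuclear_fraction_raises_score(self):
        """Fields with 90% nuclear guide placement score strictly above
        matched fields with none, across seeds."""
        for fs in (21, 22):
            hi = simulate_field(small_params(nuclear_fraction_guide=0.9), seed=fs)
            lo = simulate_field(small_params(nuclear_fraction_guide=0.0), seed=fs)
            scores = []
            for stack, _ in (hi, lo):
                proj = max_intensity_projection(stack)
                cm = segment_field(proj)
                res = nuclear_accumulation(proj.channel("mirna_guide"), cm,
                                           ratio_threshold=1.02)
                scores.append(res.per_cell.ratio.mean())
            assert scores[0] > scores[1]


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        x = rng.uniform(size=(20, 20))
        assert pearson_coefficient(x, x) == pytest.approx(1.0)

    def test_affine_invariance_and_sign(self, rng):
        x = rng.uniform(size=(20, 20))
        assert pearson_coefficient(x, 2.0 * x + 1.0) == pytest.approx(1.0)
        assert pearson_coefficient(x, -0.5 * x + 3.0) == pytest.approx(-1.0)

    def test_null_distribution_of_independent_noise(self):
        """|r| < 0.05 for >= 95% of 100 independent 100x100 noise pairs."""
        ok = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            a = rng.normal(size=(100, 100))
            b = rng.normal(size=(100, 100))
            ok += abs(pearson_coefficient(a, b)) < 0.05
        assert ok >= 95

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson_coefficient(np.ones((5, 5)), np.random.default_rng(0).uniform(size=(5, 5)))
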