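"""Censored normalization, paired testing, FDR machinery, annotation mapping."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirtox import diffexp, synthdata
from mirtox.containers import CtMatrix

from conftest import make_ct, paired_sheet


# -- detection-limit capping -------------------------------------------------

def _one_plate_ct(values_row: list[float]) -> CtMatrix:
    sheet = paired_sheet("t", len(values_row) // 2)
    return make_ct(np.array([values_row]), sheet)


class TestCapDetectionLimit:
    def test_above_limit_capped_and_flagged(self):
        ct = _one_plate_ct([36.2, 20.0])
        capped = diffexp.cap_detection_limit(ct)
        assert capped.values.iloc[0, 0] == 35.0
        assert bool(capped.censored.iloc[0, 0])

    def test_just_below_limit_untouched(self):
        ct = _one_plate_ct([34.999, 20.0])
        capped = diffexp.cap_detection_limit(ct)
        assert capped.values.iloc[0, 0] == 34.999
        assert not bool(capped.censored.iloc[0, 0])

    def test_at_limit_flagged(self):
        ct = _one_plate_ct([35.0, 20.0])
        capped = diffexp.cap_detection_limit(ct)
        assert bool(capped.censored.iloc[0, 0])

    def test_all_censored_column(self):
        sheet = paired_sheet("t", 1)
        ct = make_ct(np.array([[40.0, 20.0], [37.0, 21.0]]), sheet)
        capped = diffexp.cap_detection_limit(ct)
        assert (capped.values.iloc[:, 0] == 35.0).all()
        assert capped.censored.iloc[:, 0].all()


# -- mean-centered normalization ---------------------------------------------

class TestMeanCenterNormalize:
    def test_worked_example(self):
        # one plate holding raw Ct 20, 30 and a censored 35: mean of the
        # non-censored values is 25, so normalized = (5, -5, -10)
        rows = [
            ("s1", "plate0", "t", 1, "treated"),
            ("s2", "plate0", "t", 2, "treated"),
            ("s3", "plate0", "t", 3, "treated"),
            ("c1", "plate0", "t", 1, "control"),
            ("c2", "plate0", "t", 2, "control"),
            ("c3", "plate0", "t", 3, "control"),
        ]
        sheet = pd.DataFrame(
            rows, columns=["sample", "plate", "treatment", "replicate", "role"]
        ).set_index("sample")
        ct = make_ct(np.array([[20.0, 30.0, 36.0, 25.0, 25.0, 25.0]]), sheet)
        capped = diffexp.cap_detection_limit(ct)
        norm = diffexp.mean_center_normalize(capped)
        mean = (20 + 30 + 25 * 3) / 5
        assert norm.values.loc["miR-0000", "s1"] == pytest.approx(mean - 20)
        assert norm.values.loc["miR-0000", "s2"] == pytest.approx(mean - 30)
        # the censored entry still receives plate_mean - 35
        assert norm.values.loc["miR-0000", "s3"] == pytest.approx(mean - 35)

    def test_single_noncensored_value_normalizes_to_zero(self):
        sheet = paired_sheet("t", 1)
        ct = make_ct(np.array([[27.0, 40.0]]), sheet)
        norm = diffexp.mean_center_normalize(diffexp.cap_detection_limit(ct))
        assert norm.values.iloc[0, 0] == pytest.approx(0.0)

    def test_fully_censored_plate_errors(self):
        sheet = paired_sheet("t", 1)
        ct = make_ct(np.array([[40.0, 41.0]]), sheet)
        with pytest.raises(ValueError, match="plate0.*censored|censored.*plate0"):
            diffexp.mean_center_normalize(diffexp.cap_detection_limit(ct))

    def test_noncensored_mean_is_zero(self):
        rng = np.random.default_rng(7)
        sheet = paired_sheet("t", 3)
        ct = make_ct(rng.uniform(20, 38, size=(25, 6)), sheet)
        capped = diffexp.cap_detection_limit(ct)
        norm = diffexp.mean_center_normalize(capped)
        mask = ~norm.censored.to_numpy()
        assert abs(norm.values.to_numpy()[mask].mean()) < 1e-9

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n_mirnas = int(rng.integers(2, 15))
        sheet = pd.concat(
            [paired_sheet("a", 2, "plate0"), paired_sheet("b", 2, "plate1")]
        )
        values = rng.uniform(15, 40, size=(n_mirnas, len(sheet)))
        if not (values < 35).any(axis=0).all():  # keep each plate analyzable
            values[0] = 20.0
        norm = diffexp.mean_center_normalize(
            diffexp.cap_detection_limit(make_ct(values, sheet))
        )
        for plate, block in norm.samples.groupby("plate"):
            vals = norm.values[block.index].to_numpy()
            mask = ~norm.censored[block.index].to_numpy()
            assert abs(vals[mask].mean()) < 1e-9


# -- fold change and paired t ------------------------------------------------

def _noise_free_result(log2_effect: float):
    cfg = synthdata.CtSimConfig(
        n_mirnas=3,
        treatments=(("t", 3),),
        baseline_sd_between_mirnas=0.0,
        replicate_sd=0.0,
        plate_shift_sd=0.0,
        spikes=(synthdata.Spike(0, "t", log2_effect),),
        seed=0,
    )
    res = synthdata.gen_ct_matrix(cfg)
    capped = diffexp.cap_detection_limit(res.ct)
    norm = diffexp.mean_center_normalize(capped)
    return diffexp.fold_change(norm, capped, "t")


class TestFoldChange:
    def test_spike_round_trip_up(self):
        fc = _noise_free_result(1.0)
        assert fc.iloc[0] == pytest.approx(2.0)
        assert fc.iloc[1] == pytest.approx(1.0)

    def test_spike_round_trip_down(self):
        fc = _noise_free_result(-2.0)
        assert fc.iloc[0] == pytest.approx(0.25)

    def test_no_effect_gives_unity(self):
        fc = _noise_free_result(0.0)
        assert np.allclose(fc.to_numpy(), 1.0)


def _ct_with_differences(diffs: list[float]) -> tuple:
    """One-miRNA matrix whose treated-control normalized differences are diffs."""
    n = len(diffs)
    sheet = paired_sheet("t", n)
    base = 25.0
    # treated Ct lower by diff => normalized (mean - ct) difference = diff
    treated = [base - d for d in diffs]
    control = [base] * n
    values = np.array([treated + control])
    ct = make_ct(values, sheet)
    capped = diffexp.cap_detection_limit(ct)
    return diffexp.mean_center_normalize(capped), capped


class TestPairedT:
    def test_worked_example(self):
        norm, ct = _ct_with_differences([1.0, 2.0, 3.0])
        res = diffexp.paired_t(norm, ct, "t")
        assert res["t_stat"].iloc[0] == pytest.approx(3.4641, abs=1e-4)
        assert res["df"].iloc[0] == 2
        assert res["p"].iloc[0] == pytest.approx(0.0742, abs=1e-4)

    def test_zero_mean_differences(self):
        norm, ct = _ct_with_differences([-1.0, 0.0, 1.0])
        res = diffexp.paired_t(norm, ct, "t")
        assert res["t_stat"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_single_pair_errors(self):
        norm, ct = _ct_with_differences([1.0])
        with pytest.raises(ValueError, match="pair"):
            diffexp.paired_t(norm, ct, "t")

    def test_degenerate_constant_nonzero(self):
        norm, ct = _ct_with_differences([2.0, 2.0, 2.0])
        res = diffexp.paired_t(norm, ct, "t")
        assert bool(res["degenerate"].iloc[0])
        assert res["p"].iloc[0] == np.finfo(float).tiny

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        diffs = list(rng.normal(0.4, 1.0, 5))
        norm, ct = _ct_with_differences(diffs)
        res = diffexp.paired_t(norm, ct, "t")
        t_ref, p_ref = stats.ttest_rel(
            norm.values[ct.pairs("t")["treated"]].iloc[0],
            norm.values[ct.pairs("t")["control"]].iloc[0],
        )
        assert res["t_stat"].iloc[0] == pytest.approx(float(t_ref), abs=1e-10)
        assert res["p"].iloc[0] == pytest.approx(float(p_ref), abs=1e-12)


# -- multiple testing ---------------------------------------------------------

class TestBhAdjust:
    def test_worked_example(self):
        adj = diffexp.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert diffexp.bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            diffexp.bh_adjust(np.array([0.0, 0.5]))

    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(max_examples=60, deadline=None)
    def test_output_at_least_input(self, ps):
        arr = np.asarray(ps)
        adj = diffexp.bh_adjust(arr)
        assert np.all(adj >= arr - 1e-15)
        assert np.all(adj <= 1.0)


class TestStoreyQ:
    def test_pi0_one_equals_bh(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(1e-6, 1.0, 50)
        assert np.allclose(diffexp.storey_q(p, pi0=1.0), diffexp.bh_adjust(p))

    def test_small_m_equals_bh(self):
        p = np.array([0.01, 0.2, 0.9])
        assert np.allclose(diffexp.storey_q(p), diffexp.bh_adjust(p))

    def test_all_ones(self):
        assert np.allclose(diffexp.storey_q(np.ones(20)), 1.0)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.001, 1.0, 200)
        q = diffexp.storey_q(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_pi0_estimate_near_one_under_uniform(self):
        rng = np.random.default_rng(0)
        ests = []
        for _ in range(100):
            p = rng.uniform(1e-9, 1.0, 1000)
            ests.append(min(1.0, np.sum(p > 0.5) / (0.5 * 1000)))
        assert abs(np.mean(ests) - 1.0) < 0.05


# -- significance filter -----------------------------------------------------

class TestSelectSignificant:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (1.5, 0.009, True),
            (1.49, 0.0001, False),
            (0.5, 0.02, False),
            (0.5, 0.009, True),
            (1.0 / 1.5, 0.009, True),
            (1.5, 0.01, False),
        ],
    )
    def test_boundaries(self, fc, p, expected):
        rec = pd.DataFrame({"fold_change": [fc], "p": [p]})
        out = diffexp.select_significant(rec)
        assert bool(out["significant"].iloc[0]) is expected


# -- annotation mapping -------------------------------------------------------

def _annotation(names, non_human=(), discontinued=()):
    return synthdata.gen_mirna_annotation(names, non_human, discontinued)


class TestMapAnnotations:
    def test_absent_name_unmapped(self):
        amap, kept = diffexp.map_annotations(["miR-x"], _annotation(["miR-a"]))
        assert amap["status"].iloc[0] == "unmapped"
        assert kept == []

    def test_all_mapped_unchanged(self):
        names = [f"miR-{i}" for i in range(5)]
        amap, kept = diffexp.map_annotations(names, _annotation(names))
        assert kept == names
        assert (amap["status"] == "mapped").all()

    def test_41_to_39_structural(self):
        # 41 significant names of which one is non-human and one discontinued
        names = [f"miR-{i:02d}" for i in range(41)]
        table = _annotation(names, non_human=[names[3]], discontinued=[names[17]])
        amap, kept = diffexp.map_annotations(names, table)
        assert len(names) == 41
        assert len(kept) == 39
        assert set(names) - set(kept) == {names[3], names[17]}
        reasons = amap.set_index("assay_name")["reason"]
        assert "human" in reasons[names[3]]
        assert "discontinued" in reasons[names[17]]

    def test_duplicate_assay_errors(self):
        table = pd.concat([_annotation(["miR-a"]), _annotation(["miR-a"])])
        with pytest.raises(ValueError, match="duplicate"):
            diffexp.map_annotations(["miR-a"], table)


# -- full differential table --------------------------------------------------

class TestDifferentialTable:
    def test_columns_and_invariants(self):
        cfg = synthdata.CtSimConfig(
            n_mirnas=30,
            treatments=(("t", 3),),
            replicate_sd=0.3,
            spikes=(synthdata.Spike(0, "t", 3.0),),
            seed=4,
        )
        res = synthdata.gen_ct_matrix(cfg)
        capped = diffexp.cap_detection_limit(res.ct)
        norm = diffexp.mean_center_normalize(capped)
        table = diffexp.differential_table(norm, capped)
        assert {"mirna", "exposure", "fold_change", "p", "q_storey", "p_bh",
                "significant", "censored_fraction"} <= set(table.columns)
        assert ((table["p"] > 0) & (table["p"] <= 1)).all()
        assert (table["p_bh"] >= table["p"] - 1e-15).all()
        assert ((table["fold_change"] > 0)).all()
        # the strong spike must be recovered
        spiked = table[table["mirna"] == "miR-0000"]
        assert bool(spiked["significant"].iloc[0])
        assert spiked["fold_change"].iloc[0] > 4
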