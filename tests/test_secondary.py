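"""RT model, position bias, median split, brightness contrasts, similarity."""

import numpy as np
import pandas as pd
import pytest

import pareidoscope as ps
from pareidoscope.classification import ChoiceDataset


def _rt_log(mu_by_type, n_per_type=400, participants=("S1", "S2", "S3"),
            rt_sd=0.25, seed=11, n_corrections=0):
    rng = np.random.default_rng(seed)
    rows = []
    types = list(mu_by_type)
    for p in participants:
        poff = rng.normal(0, 0.1)
        for i in range(n_per_type * len(types)):
            tt = types[i % len(types)]
            rt = float(np.exp(mu_by_type[tt] + poff + rng.normal(0, rt_sd)))
            rows.append(dict(
                participant=p, session=0, trial=i, trial_type=tt,
                category="human_face", stim_id_1="n0", stim_id_2="n1",
                stim_id_3="n2", cell_1=0, cell_2=1, cell_3=2, chosen_cell=0,
                chosen_stim="n0", rt_ms=rt, rewarded=True, correct=True,
                is_correction=False,
            ))
    log = pd.DataFrame(rows)
    for _ in range(n_corrections):
        extra = log.iloc[[0]].assign(is_correction=True, trial_type="correction")
        log = pd.concat([log, extra], ignore_index=True)
    return log


class TestLogRtModel:
    def test_recovers_injected_multiplicative_effect(self):
        # test trials exp(0.5) slower than easy baseline
        mus = {"baseline_easy": np.log(700), "baseline_difficult": np.log(900),
               "test": np.log(700) + 0.5}
        res = ps.log_rt_mixed_model(_rt_log(mus))
        row = res.contrasts.set_index("contrast").loc["easy_vs_test"]
        assert abs(row["estimate"] - 0.5) < 0.05
        assert row["ci_low"] < row["estimate"] < row["ci_high"]

    def test_constant_rts_give_zero_contrasts(self):
        mus = {"baseline_easy": np.log(800), "baseline_difficult": np.log(800),
               "test": np.log(800)}
        res = ps.log_rt_mixed_model(_rt_log(mus, n_per_type=50, rt_sd=0.0))
        assert np.allclose(res.contrasts["estimate"], 0.0, atol=1e-10)

    def test_corrections_excluded_and_counted(self):
        mus = {"baseline_easy": np.log(700), "test": np.log(900)}
        res = ps.log_rt_mixed_model(_rt_log(mus, n_per_type=30, n_corrections=7))
        assert res.n_corrections_excluded == 7

    def test_contrasts_reported_per_category(self, fx_tiny):
        res = ps.log_rt_mixed_model(fx_tiny.log)
        assert set(res.contrasts["contrast"]) == {
            "easy_vs_difficult", "easy_vs_test", "difficult_vs_test",
        }
        # evidence-dependent RTs: test trials slower than easy baseline
        row = res.contrasts.set_index("contrast").loc["easy_vs_test"]
        assert row["estimate"] > 0


class TestPositionBias:
    def _log_with_cells(self, cells):
        return pd.DataFrame(dict(
            participant="S1", session=0, trial=np.arange(len(cells)),
            trial_type="test", category="letter", stim_id_1="a", stim_id_2="b",
            stim_id_3="c", cell_1=0, cell_2=1, cell_3=2, chosen_cell=cells,
            chosen_stim="a", rt_ms=500.0, rewarded=True, correct=None,
            is_correction=False,
        ))

    def test_extreme_bias_value(self):
        # 300 choices of one cell: (300-50)^2/50 + 5*50 = 1500
        table = ps.position_bias_chisq(self._log_with_cells([2] * 300))
        assert table["chi_square"].iloc[0] == pytest.approx(1500.0)

    def test_uniform_choices_give_zero(self):
        table = ps.position_bias_chisq(self._log_with_cells(list(range(6)) * 50))
        assert table["chi_square"].iloc[0] == pytest.approx(0.0)

    def test_matches_bruteforce_formula(self):
        rng = np.random.default_rng(4)
        cells = rng.integers(0, 6, size=240)
        table = ps.position_bias_chisq(self._log_with_cells(cells))
        expected = sum(
            (np.sum(cells == c) - 40) ** 2 / 40 for c in range(6)
        )
        assert table["chi_square"].iloc[0] == pytest.approx(expected)

    def test_no_test_trials_rejected(self):
        log = self._log_with_cells([0]).assign(trial_type="baseline_easy")
        with pytest.raises(ValueError):
            ps.position_bias_chisq(log)

    def test_bias_strength_uncorrelated_with_null_clarity(self, fx_tiny_random):
        # random observers with injected position bias: chi-square varies but
        # mean raw p stays near 0.5, so the correlation is weak
        rows = []
        for participant in fx_tiny_random.ds.participants:
            one = fx_tiny_random.ds.restrict(participant)
            smap = ps.pixelwise_mixed_model(one, fx_tiny_random.aoi, "individual")
            rows.append({"participant": participant,
                         "mean_p": ps.mean_raw_p(smap)})
        summary = pd.DataFrame(rows)
        assert np.all(np.abs(summary["mean_p"] - 0.5) < 0.1)


class TestSpearman:
    def test_perfect_monotone_association(self):
        rho, _ = ps.spearman_corr([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        rho, _ = ps.spearman_corr([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_ties_match_midrank_bruteforce(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
        y = np.array([2.0, 1.0, 3.0, 5.0, 4.0, 6.0])

        def midrank(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i : j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        rx, ry = midrank(x), midrank(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, _ = ps.spearman_corr(x, y)
        assert rho == pytest.approx(expected)

    def test_one_tailed_option(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [6, 4, 5, 3, 1, 2]
        _, p_two = ps.spearman_corr(x, y)
        _, p_less = ps.spearman_corr(x, y, alternative="less")
        assert p_less == pytest.approx(p_two / 2)

    def test_constant_input_signalled(self):
        with pytest.raises(ValueError):
            ps.spearman_corr([1, 1, 1], [1, 2, 3])


class TestMedianSplit:
    def _ds_with_rts(self, rts):
        n = len(rts)
        stim = np.random.default_rng(0).integers(0, 255, (n, 3, 4, 3)).astype(np.uint8)
        return ChoiceDataset(
            stimuli=stim, chosen_idx=np.zeros(n, dtype=int),
            participant=np.array(["S1"] * n, dtype=object), trial=np.arange(n),
            rt_ms=np.asarray(rts, dtype=float), category="letter",
        )

    def test_distinct_rts_split_at_median(self):
        split = ps.rt_median_split(self._ds_with_rts(np.arange(1.0, 11.0)))
        assert len(split.faster) == 5 and len(split.slower) == 5
        assert split.faster.rt_ms.max() < split.slower.rt_ms.min()

    def test_constant_rts_flagged_degenerate(self):
        split = ps.rt_median_split(self._ds_with_rts([300.0] * 8))
        assert len(split.faster) == 8 and len(split.slower) == 0
        assert split.empty_groups == ["S1"]

    def test_halves_partition_dataset(self, fx_tiny):
        split = ps.rt_median_split(fx_tiny.ds)
        assert len(split.faster) + len(split.slower) == len(fx_tiny.ds)
        # per-participant medians: each faster half has >= half the trials
        for participant in fx_tiny.ds.participants:
            n_all = (fx_tiny.ds.participant == participant).sum()
            n_fast = (split.faster.participant == participant).sum()
            assert n_fast >= n_all // 2


class TestBrightnessModel:
    def test_identical_planes_zero_contrast(self):
        plane = np.random.default_rng(1).normal(0, 2, (10, 8))
        aoi = ps.AOISpec(0, 0, 8, 10)
        res = ps.brightness_difference_model({"a": plane, "b": plane.copy()}, aoi)
        assert res.contrasts["estimate"].iloc[0] == pytest.approx(0.0)

    def test_constant_offset_recovered_exactly(self):
        rng = np.random.default_rng(2)
        plane = rng.normal(-2, 1, (12, 10))
        aoi = ps.AOISpec(0, 0, 10, 12)
        res = ps.brightness_difference_model({"a": plane, "b": plane + 1.5}, aoi)
        row = res.contrasts.iloc[0]
        assert row["contrast"] == "a_vs_b"
        assert row["estimate"] == pytest.approx(1.5)
        assert row["ci_low"] < 1.5 < row["ci_high"] or row["se"] == pytest.approx(0.0)

    def test_category_means_match_closed_form(self):
        rng = np.random.default_rng(3)
        planes = {c: rng.normal(m, 1, (6, 5)) for c, m in
                  [("x", -1.0), ("y", -2.0), ("z", -3.0)]}
        aoi = ps.AOISpec(0, 0, 5, 6)
        res = ps.brightness_difference_model(planes, aoi)
        for _, row in res.category_stats.iterrows():
            v = planes[row["category"]].ravel()
            assert row["mean"] == pytest.approx(v.mean())
            assert row["se"] == pytest.approx(v.std(ddof=1) / np.sqrt(v.size))
        # contrast equals difference of category means (paired by coordinate)
        xy = res.contrasts.set_index("contrast").loc["x_vs_y", "estimate"]
        assert xy == pytest.approx(planes["y"].mean() - planes["x"].mean())

    def test_plane_too_small_for_aoi_rejected(self):
        aoi = ps.AOISpec(0, 0, 5, 6)
        with pytest.raises(ValueError):
            ps.brightness_difference_model(
                {"a": np.zeros((6, 5)), "b": np.zeros((5, 5))}, aoi)


class TestImageSimilarity:
    def test_self_spectrum_correlation_is_one(self):
        img = np.random.default_rng(5).normal(128, 30, (44, 40))
        assert ps.spectrum_correlation(img, img) == pytest.approx(1.0)

    def test_pure_sinusoid_peaks_at_its_frequency(self):
        n = 100
        img = np.tile(np.sin(2 * np.pi * 10 * np.arange(n) / n), (n, 1))
        profile = ps.radial_amplitude_spectrum(img)
        assert len(profile) == n // 2
        assert profile.argmax() == 10

    def test_profile_length_is_half_min_dimension(self):
        img = np.random.default_rng(6).normal(size=(35, 30))
        assert len(ps.radial_amplitude_spectrum(img)) == 15

    def test_euclidean_distance_examples(self):
        a = np.zeros((220, 200))
        assert ps.euclidean_image_distance(a, a) == 0.0
        # unit offset over the full-scale AOI: sqrt(44000) ~ 209.76
        d = ps.euclidean_image_distance(a, a + 1)
        assert d == pytest.approx(np.sqrt(44_000), rel=1e-12)
        b = np.random.default_rng(7).normal(size=(220, 200))
        assert ps.euclidean_image_distance(a, b) == pytest.approx(
            ps.euclidean_image_distance(b, a))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ps.euclidean_image_distance(np.zeros((2, 2)), np.zeros((3, 2)))
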