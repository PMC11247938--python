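"""Segment/sucker measurements and the two-way ANOVA + Tukey stage."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from ancmorph import (
    ParameterError,
    SegmentRecord,
    cell_density,
    cross_sectional_area,
    records_to_frame,
    segments_per_sucker,
    summarize_widths,
    two_way_anova_tukey,
)
from ancmorph.synthetic import TableSpec, gen_segment_table


class TestSegmentsPerSucker:
    @pytest.mark.parametrize("ant,post,n,expected", [
        (45, 45, 6, 7.5),
        (44, 47, 6, (44 + 47) / 2 / 6),
        (0, 0, 6, 0.0),
    ])
    def test_examples(self, ant, post, n, expected):
        assert segments_per_sucker(ant, post, n) == pytest.approx(expected)

    def test_exhaustive_small_grid_matches_closed_form(self):
        for a, p, n in itertools.product(range(0, 12), range(0, 12),
                                         range(1, 5)):
            assert segments_per_sucker(a, p, n) == ((a + p) / 2) / n

    def test_side_exchange_invariance(self):
        for a, p in itertools.product(range(0, 10), repeat=2):
            assert segments_per_sucker(a, p) == segments_per_sucker(p, a)

    def test_zero_suckers_rejected(self):
        with pytest.raises(ParameterError):
            segments_per_sucker(10, 10, 0)


class TestClosedFormMeasures:
    def test_density_grid(self):
        for count, area in itertools.product(range(0, 20), range(1, 20)):
            assert cell_density(count, float(area)) == count / area

    def test_density_homogeneity(self):
        assert cell_density(50, 1000.0) == cell_density(100, 2000.0) == 0.05

    def test_density_zero_area_rejected(self):
        with pytest.raises(ParameterError):
            cell_density(5, 0.0)

    def test_area_grid_and_symmetry(self):
        for w, h in itertools.product(range(1, 15), repeat=2):
            assert cross_sectional_area(w, h) == w * h
            assert cross_sectional_area(w, h) == cross_sectional_area(h, w)

    def test_area_rejects_nonpositive(self):
        with pytest.raises(ParameterError):
            cross_sectional_area(0, 5)


def _records(pos, terr, widths):
    return [
        SegmentRecord("a1", pos, ("anterior", "posterior")[i % 2], terr, w)
        for i, w in enumerate(widths)
    ]


class TestSummarizeWidths:
    def test_two_step_averaging_simple(self):
        recs = _records("proximal", "ExA", [10, 12]) + \
            _records("proximal", "InA", [6, 8])
        tab = summarize_widths(records_to_frame(recs))
        by = {(r.position, r.territory): r for r in tab.itertuples()}
        assert by[("proximal", "ExA")].mean == pytest.approx(11.0)
        assert by[("proximal", "InA")].mean == pytest.approx(7.0)
        assert by[("proximal", "total")].mean == pytest.approx(9.0)

    def test_total_is_mean_of_cell_means_not_pooled(self):
        # ExA {10,12,14} (mean 12), InA {6} (mean 6): total 9, pooled 10.5
        recs = _records("distal", "ExA", [10, 12, 14]) + \
            _records("distal", "InA", [6])
        tab = summarize_widths(records_to_frame(recs))
        total = tab[(tab.position == "distal")
                    & (tab.territory == "total")]["mean"].item()
        assert total == pytest.approx(9.0)
        assert total != pytest.approx(10.5)

    def test_identical_values_zero_sem(self):
        recs = _records("proximal", "ExA", [5.0] * 6) + \
            _records("proximal", "InA", [5.0] * 6)
        tab = summarize_widths(records_to_frame(recs))
        cells = tab[tab.territory != "total"]
        assert (cells["mean"] == 5.0).all()
        assert (cells["sem"] == 0.0).all()

    def test_empty_cell_warns_and_is_omitted(self):
        recs = _records("proximal", "ExA", [10, 12])
        with pytest.warns(UserWarning, match="InA"):
            tab = summarize_widths(records_to_frame(recs))
        assert "InA" not in set(tab.territory)

    def test_recovers_generating_offsets_within_two_sem(self):
        spec = TableSpec(territory_offset=5.0, taper_rate=8.0, noise_sd=3.0,
                         replicates=24, seed=11)
        tabs = gen_segment_table(spec)
        tab = summarize_widths(tabs.segments)
        for pos in ("proximal", "intermediate", "distal"):
            cells = {r.territory: r for r in
                     tab[tab.position == pos].itertuples()}
            diff = cells["ExA"].mean - cells["InA"].mean
            pooled_sem = np.hypot(cells["ExA"].sem, cells["InA"].sem)
            assert abs(diff - spec.territory_offset) <= 2 * pooled_sem


class TestRecordValidation:
    def test_negative_width_rejected(self):
        with pytest.raises(ParameterError):
            SegmentRecord("a", "proximal", "anterior", "ExA", -1.0)

    def test_nuclei_without_area_rejected(self):
        with pytest.raises(ParameterError):
            SegmentRecord("a", "proximal", "anterior", "ExA", 10.0,
                          nuclei_count=5)


class TestTwoWayAnova:
    def test_strong_territory_effect_detected(self):
        tabs = gen_segment_table(TableSpec(territory_offset=3.0,
                                           taper_rate=0.0, noise_sd=1.0,
                                           seed=0))
        res = two_way_anova_tukey(tabs.segments, "width", "position",
                                  "territory")
        assert res.significant["territory"]
        assert res.p_values["territory"] < 0.001
        tuk = res.tukey["territory"]
        assert bool(tuk.reject.iloc[0])
        # Tukey table covers all level pairs of each tested factor
        assert len(res.tukey["position"]) == 3

    def test_taper_detected_as_position_effect(self):
        tabs = gen_segment_table(TableSpec(territory_offset=0.0,
                                           taper_rate=8.0, noise_sd=3.0,
                                           seed=1))
        res = two_way_anova_tukey(tabs.segments, "width", "position",
                                  "territory")
        assert res.significant["position"]

    def test_single_replicate_refuses_interaction(self):
        tabs = gen_segment_table(TableSpec(replicates=1, seed=2))
        with pytest.warns(UserWarning, match="interaction"):
            res = two_way_anova_tukey(tabs.segments, "width", "position",
                                      "territory")
        assert not res.interaction_included
        assert "interaction" not in res.p_values

    def test_single_level_factor_rejected(self):
        tabs = gen_segment_table(TableSpec(seed=3))
        df = tabs.segments[tabs.segments.territory == "ExA"]
        with pytest.raises(ParameterError):
            two_way_anova_tukey(df, "width", "position", "territory")

    def test_null_rejection_rate_roughly_alpha(self):
        # quick calibration at 150 tables; the full 1,000-table check runs
        # in the acceptance suite
        rej = {"territory": 0, "position": 0}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(150):
                tabs = gen_segment_table(TableSpec(
                    territory_offset=0.0, taper_rate=0.0, noise_sd=1.0,
                    seed=seed))
                res = two_way_anova_tukey(tabs.segments, "width", "position",
                                          "territory")
                for f in rej:
                    rej[f] += res.significant[f]
        for f, k in rej.items():
            assert 0.01 <= k / 150 <= 0.12, f

    def test_tukey_pooled_error_matches_statsmodels_oneway(self):
        # with a single two-level factor the pooled-error Tukey reduces to
        # the classic one-way case; cross-check p against statsmodels
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "y": np.r_[rng.normal(0, 1, 20), rng.normal(1, 1, 20)],
            "g": ["a"] * 20 + ["b"] * 20,
            "h": (["u", "v"] * 20),
        })
        res = two_way_anova_tukey(df, "y", "g", "h")
        sm_res = pairwise_tukeyhsd(df.y, df.g)
        # residual df differ slightly (two-way model), so compare loosely
        assert res.tukey["g"].meandiff.iloc[0] == pytest.approx(
            sm_res.meandiffs[0])
        assert res.tukey["g"].p_adj.iloc[0] == pytest.approx(
            float(sm_res.pvalues[0]), abs=0.02)
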