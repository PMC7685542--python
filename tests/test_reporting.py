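import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import anaemap as am
from anaemap.reporting import (
    observed_annual_totals,
    observed_quarter_totals,
    severity_class_fractions,
)
from conftest import identity_chains


class TestClassifyPrevalence:
    @pytest.mark.parametrize(
        "p,label",
        [
            (0.0, "Normal"),
            (0.049, "Normal"),
            (0.05, "Mild"),
            (0.199, "Mild"),
            (0.20, "Moderate"),
            (0.399, "Moderate"),
            (0.40, "Severe"),
            (1.0, "Severe"),
        ],
    )
    def test_who_boundaries(self, p, label):
        assert am.classify_prevalence(p).label == label

    @pytest.mark.parametrize("p", [-0.01, 1.01])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            am.classify_prevalence(p)

    @given(
        p1=st.floats(0, 1, allow_nan=False),
        p2=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_prevalence(self, p1, p2):
        if p1 > p2:
            p1, p2 = p2, p1
        assert am.classify_prevalence(p1) <= am.classify_prevalence(p2)

    def test_class_ordering(self):
        s = am.SeverityClass
        assert s.NORMAL < s.MILD < s.MODERATE < s.SEVERE


class TestObservedArithmetic:
    def test_percent_change_examples(self):
        assert am.percent_change(155_539, 171_682) == 10.4
        assert am.percent_change(155_539, 263_305) == 69.3
        assert am.percent_change(155_539, 295_642) == 90.1
        assert am.percent_change(123.0, 123.0) == 0.0

    def test_percent_change_rejects_nonpositive_base(self):
        with pytest.raises(ValueError):
            am.percent_change(0, 10)

    def test_quarterly_shares_reported_counts(self):
        shares = am.quarterly_shares([213_350, 222_250, 215_273, 235_295])
        np.testing.assert_allclose(shares, [24.1, 25.1, 24.3, 26.6])
        assert shares.sum() == pytest.approx(100.0, abs=0.2)

    def test_quarterly_shares_degenerate_inputs(self):
        np.testing.assert_allclose(
            am.quarterly_shares([1, 1, 1, 1]), [25.0, 25.0, 25.0, 25.0]
        )
        np.testing.assert_allclose(
            am.quarterly_shares([100, 0, 0, 0]), [100.0, 0.0, 0.0, 0.0]
        )
        with pytest.raises(ValueError):
            am.quarterly_shares([0, 0, 0, 0])

    def test_observed_totals(self):
        panel = am.generate_severity_fixture(
            [0.1, 0.2], denominator=100, n_times=8
        )
        totals = observed_annual_totals(panel)
        # two years of four quarters each, constant cases per cell
        assert totals == {2016: 4 * (10 + 20), 2017: 4 * (10 + 20)}
        np.testing.assert_allclose(
            observed_quarter_totals(panel), [60.0, 60.0, 60.0, 60.0]
        )


class TestSeverityProportions:
    def fixture_with_identity_chains(self, targets, **kw):
        panel = am.generate_severity_fixture(list(targets), **kw)
        chains = identity_chains(panel)
        # pi == 1 so prevalence equals cases/N only when E carries the
        # engineered rates rather than the pooled standardised offset
        E = am.ExpectedCounts(E=panel.cases.copy())
        return panel, chains, E

    def test_all_severe_degenerate(self):
        panel, chains, E = self.fixture_with_identity_chains([0.5] * 6)
        df = am.severity_proportions(chains, panel, E)
        assert df.loc["Severe", "median"] == 100.0
        assert df.loc["Normal", "median"] == 0.0

    def test_fractions_partition_every_draw(self):
        panel, chains, E = self.fixture_with_identity_chains(
            [0.01, 0.07, 0.22, 0.41, 0.33]
        )
        fracs = severity_class_fractions(chains, panel, E)
        np.testing.assert_allclose(fracs.sum(axis=1), 1.0)

    def test_engineered_three_in_ten_severe(self):
        targets = [0.45, 0.55, 0.62] + [0.1] * 7
        panel, chains, E = self.fixture_with_identity_chains(targets)
        df = am.severity_proportions(chains, panel, E)
        assert df.loc["Severe", "median"] == 30.0
        assert df.loc["Mild", "median"] == 70.0

    def test_ui_width_shrinks_with_more_draws(self):
        """Monte-Carlo consistency: interval width decreases in draw count."""
        panel = am.generate_severity_fixture([0.1] * 8)
        E = am.compute_expected(panel)

        def noisy_chains(n_draws, seed):
            ch = identity_chains(panel, n_chains=2, n_draws=n_draws)
            rng = np.random.default_rng(seed)
            ch.draws["alpha"] = rng.normal(0.0, 0.6, (2, n_draws))
            return ch

        def severe_width(ch):
            df = am.severity_proportions(ch, panel, E)
            return (df["q97.5"] - df["q2.5"]).sum()

        w_small = np.mean([severe_width(noisy_chains(40, s)) for s in range(5)])
        w_large = np.mean(
            [severe_width(noisy_chains(4000, s)) for s in range(5)]
        )
        assert w_large <= w_small

    def test_yearly_selection(self):
        panel, chains, E = self.fixture_with_identity_chains(
            [0.1, 0.3], n_times=8
        )
        df16 = am.severity_proportions(chains, panel, E, year=2016)
        df17 = am.severity_proportions(chains, panel, E, year=2017)
        pd.testing.assert_frame_equal(df16, df17)  # constant panel
        with pytest.raises(ValueError):
            panel.time_indices_for_year(1999)


class TestZoneStratification:
    def test_two_zones_with_disjoint_severities(self):
        targets = [0.45, 0.5, 0.1, 0.12]
        panel = am.generate_severity_fixture(
            targets, zone=("Coast", "Coast", "Highland", "Highland")
        )
        chains = identity_chains(panel)
        E = am.ExpectedCounts(E=panel.cases.copy())
        df = am.stratify_by_zone(chains, panel, E)
        assert df.loc[("Coast", "Severe"), "median"] == 100.0
        assert df.loc[("Highland", "Mild"), "median"] == 100.0
        assert df.loc[("Coast", "Mild"), "median"] == 0.0

    def test_single_zone_matches_unstratified(self):
        panel = am.generate_severity_fixture(
            [0.1, 0.25, 0.45], zone=("Lake",) * 3
        )
        chains = identity_chains(panel)
        E = am.ExpectedCounts(E=panel.cases.copy())
        strat = am.stratify_by_zone(chains, panel, E).loc["Lake"]
        flat = am.severity_proportions(chains, panel, E)
        pd.testing.assert_frame_equal(strat, flat)

    def test_zone_fractions_partition_per_draw(self):
        panel = am.generate_severity_fixture(
            [0.1, 0.25, 0.45, 0.02], zone=("Lake", "Lake", "Coast", "Coast")
        )
        chains = identity_chains(panel)
        E = am.ExpectedCounts(E=panel.cases.copy())
        for zone in ("Lake", "Coast"):
            subset = np.array([z == zone for z in panel.zone])
            fracs = severity_class_fractions(
                chains, panel, E, area_subset=subset
            )
            np.testing.assert_allclose(fracs.sum(axis=1), 1.0)

    def test_missing_zone_labels_rejected_with_ids(self):
        panel = am.generate_severity_fixture([0.1, 0.2])
        chains = identity_chains(panel)
        E = am.compute_expected(panel)
        with pytest.raises(ValueError, match="no zone labels"):
            am.stratify_by_zone(chains, panel, E)


class TestAnnualTotals:
    def test_identity_risk_reproduces_expected_counts(self):
        panel = am.generate_severity_fixture([0.1, 0.3], n_times=8)
        chains = identity_chains(panel)
        E = am.compute_expected(panel)
        df = am.annual_case_totals(chains, panel, E)
        for year in (2016, 2017):
            ts = panel.time_indices_for_year(year)
            assert df.loc[year, "estimated_median"] == pytest.approx(
                E.E[:, ts].sum()
            )
            assert df.loc[year, "observed"] == panel.cases[:, ts].sum()

    def test_single_cell_panel(self):
        panel = am.CountPanel(
            ("a0",), np.array([[17.0]]), np.array([[100.0]]), ((2018, 2),)
        )
        chains = identity_chains(panel)
        E = am.compute_expected(panel)
        df = am.annual_case_totals(chains, panel, E)
        assert df.loc[2018, "observed"] == 17.0
        assert df.loc[2018, "estimated_median"] == pytest.approx(17.0)


class TestPrevalenceSummary:
    def test_round_trip_csv(self, small_fit, tmp_path):
        panel, model = small_fit
        summary = am.prevalence_summary(model.chains_, panel, model.E_)
        cell_p, ay_p = tmp_path / "cells.csv", tmp_path / "ay.csv"
        summary.write_csv(cell_p, ay_p)
        back = am.PrevalenceSummary.read_csv(cell_p, ay_p)
        for col in ("median", "q2.5", "q97.5"):
            np.testing.assert_allclose(
                back.cell_table[col], summary.cell_table[col], atol=1e-6
            )
        assert list(back.area_year_table["severity"]) == list(
            summary.area_year_table["severity"]
        )

    def test_quantile_ordering_and_class_consistency(self, small_fit):
        panel, model = small_fit
        summary = am.prevalence_summary(model.chains_, panel, model.E_)
        ay = summary.area_year_table
        assert (ay["q2.5"] <= ay["median"]).all()
        assert (ay["median"] <= ay["q97.5"]).all()
        for _, row in ay.iterrows():
            expected = am.classify_prevalence(
                min(max(row["median"], 0.0), 1.0)
            ).label
            assert row["severity"] == expected
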