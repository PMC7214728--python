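import numpy as np
import pytest

from ctlforge.stacking import (
    Bc1Counts,
    CrossDesign,
    DistanceEstimate,
    estimate_distance,
    estimate_table,
    read_counts_table,
    recomb_fraction,
    required_population,
    simulate_bc1,
    stack_plan,
)


class TestRecombFraction:
    def test_zero_distance_both_functions(self):
        for mf in ("direct", "haldane"):
            assert recomb_fraction(CrossDesign(5.0, 5.0, map_function=mf)) == 0.0

    def test_direct_one_percent_rule(self):
        assert recomb_fraction(CrossDesign(0.0, 1.0)) == pytest.approx(0.01)

    def test_direct_caps_at_half(self):
        assert recomb_fraction(CrossDesign(0.0, 80.0)) == 0.5

    def test_haldane_closed_form(self):
        r = recomb_fraction(CrossDesign(0.0, 3.06, map_function="haldane"))
        assert r == pytest.approx((1 - np.exp(-2 * 0.0306)) / 2)
        assert r == pytest.approx(0.0296825, abs=5e-6)

    def test_haldane_close_to_direct_below_3cm(self):
        for d in np.linspace(0.05, 3.0, 25):
            direct = recomb_fraction(CrossDesign(0.0, d))
            haldane = recomb_fraction(CrossDesign(0.0, d, map_function="haldane"))
            assert abs(direct - haldane) * 100 < 0.1  # <0.1 cM equivalent


class TestSimulate:
    def test_counts_conserved(self):
        counts = simulate_bc1(CrossDesign(0.0, 1.5), 1_000, seed=1)
        assert counts.n_total == 1_000

    def test_zero_distance_no_recombinants(self):
        counts = simulate_bc1(CrossDesign(0.0, 0.0), 2_000, seed=2)
        assert counts.n_both == 0 and counts.n_neither == 0

    def test_deterministic_given_seed(self):
        a = simulate_bc1(CrossDesign(0.0, 1.0), 500, seed=7)
        b = simulate_bc1(CrossDesign(0.0, 1.0), 500, seed=7)
        assert a == b

    def test_class_frequencies_near_binomial_expectation(self):
        n = 100_000
        counts = simulate_bc1(CrossDesign(0.0, 2.0), n, seed=3)  # r = 0.02
        expected = np.array([0.49, 0.49, 0.01, 0.01])
        observed = np.array(
            [counts.n_a_only, counts.n_b_only, counts.n_both, counts.n_neither]
        )
        sd = np.sqrt(n * expected * (1 - expected))
        assert (np.abs(observed - n * expected) < 3 * sd).all()

    def test_coupling_swaps_classes(self):
        rep = simulate_bc1(CrossDesign(0.0, 50.0, phase="repulsion"), 50_000, seed=4)
        coup = simulate_bc1(CrossDesign(0.0, 0.2, phase="coupling"), 50_000, seed=4)
        # in coupling the parental classes are both/neither
        assert coup.n_both + coup.n_neither > coup.n_a_only + coup.n_b_only
        # at capped r=0.5 all four classes are near-equal in repulsion too
        counts = np.array([rep.n_a_only, rep.n_b_only, rep.n_both, rep.n_neither])
        assert counts.std() < 0.02 * 50_000

    def test_invalid_population_size(self):
        with pytest.raises(ValueError):
            simulate_bc1(CrossDesign(0.0, 1.0), 0, seed=1)


class TestEstimate:
    @pytest.mark.parametrize(
        "n,k,expected",
        [
            (2688, 15, 0.56),
            (3578, 36, 1.01),
            (1913, 55, 2.88),
            (1481, 0, 0.00),
        ],
    )
    def test_published_crosses(self, n, k, expected):
        counts = Bc1Counts(n - k, 0, k, 0)
        est = estimate_distance(counts)
        assert est.cm_estimate == expected

    def test_ci_brackets_estimate(self):
        est = estimate_distance(Bc1Counts(1000, 1000, 10, 12))
        assert est.ci_low <= est.cm_estimate <= est.ci_high
        zero = estimate_distance(Bc1Counts(100, 100, 0, 0))
        assert zero.ci_low == 0.0 and zero.cm_estimate == 0.0

    def test_scale_consistency(self):
        a = estimate_distance(Bc1Counts(980, 990, 15, 15))
        b = estimate_distance(Bc1Counts(1960, 1980, 30, 30))
        assert a.cm_estimate == b.cm_estimate

    def test_parameter_recovery_over_replicates(self):
        """Mean estimate over 1,000 populations is within 2 SE of truth."""
        rng = np.random.default_rng(2024)
        n = 2_000
        for d in (0.25, 0.5, 1.0, 2.0, 3.0):
            design = CrossDesign(0.0, d)
            r = recomb_fraction(design)
            estimates = [
                estimate_distance(simulate_bc1(design, n, rng)).cm_estimate
                for _ in range(1_000)
            ]
            se_mean = 100 * np.sqrt(r * (1 - r) / n) / np.sqrt(1_000)
            assert abs(np.mean(estimates) - d) < 2 * se_mean + 0.005  # rounding grain


class TestRequiredPopulation:
    def test_limit_small_confidence(self):
        assert required_population(5.0, 1, 1e-9) == 1

    def test_one_cm_95(self):
        # smallest n with 1 - 0.99^n >= 0.95
        assert required_population(1.0, 1, 0.95) == 299

    def test_matches_closed_form_for_k1(self):
        for d in (0.2, 0.5, 2.0):
            r = d / 100
            n = required_population(d, 1, 0.9)
            assert 1 - (1 - r) ** n >= 0.9
            assert 1 - (1 - r) ** (n - 1) < 0.9

    def test_monotone_in_distance(self):
        ns = [required_population(d, 1, 0.95) for d in (0.25, 0.5, 1.0, 2.0, 3.0)]
        assert ns == sorted(ns, reverse=True)

    def test_zero_distance_error(self):
        with pytest.raises(ValueError):
            required_population(0.0)


class TestStackPlan:
    positions = {
        "M14": ("chr1", 51.54),
        "TS50": ("chr1", 50.95),
        "TS72": ("chr1", 51.33),
        "TSX": ("chr5", 10.0),
    }

    def test_predicted_distance_and_expected_recombinants(self):
        df = stack_plan(self.positions, {"pmi": "M14", "nptii": "TS50"}, n_seeds=2688)
        row = df.iloc[0]
        assert row["d_cm"] == pytest.approx(0.59, abs=1e-9)
        assert row["expected_recombinants"] == pytest.approx(2688 * 0.0059)

    def test_same_site_twice_flagged(self):
        df = stack_plan(self.positions, {"a": "TS50", "b": "TS50"}, n_seeds=100)
        assert df.iloc[0]["flag"] == "zero_distance"
        assert df.iloc[0]["d_cm"] == 0.0

    def test_unlinked_pair_excluded_from_cm_arithmetic(self):
        df = stack_plan(self.positions, {"a": "M14", "b": "TSX"}, n_seeds=100)
        assert not df.iloc[0]["linked"]
        assert np.isnan(df.iloc[0]["d_cm"])

    def test_expected_recombinants_at_tabled_cross(self):
        df = stack_plan(
            {"M14": ("chr1", 0.0), "TS50": ("chr1", 0.55)},
            {"pmi": "M14", "nptii": "TS50"},
            n_seeds=2688,
        )
        assert df.iloc[0]["expected_recombinants"] == pytest.approx(14.8, abs=0.05)


class TestIO:
    def test_counts_round_trip_and_estimates(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            [
                {"cross_id": "c1", "n_total": 2688, "n_a_only": 1336, "n_b_only": 1337,
                 "n_both": 8, "n_neither": 7},
            ]
        )
        p = tmp_path / "counts.csv"
        df.to_csv(p, index=False)
        est = estimate_table(read_counts_table(p))
        assert est.iloc[0]["cm_estimate"] == 0.56
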