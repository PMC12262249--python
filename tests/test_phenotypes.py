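"""Phenotype extraction, rescaling, bootstrap aggregation and volcano calls."""

import math

import numpy as np
import pandas as pd
import pytest

from mmscreen import lineage
from mmscreen.phenotypes import (
    aggregate_sgrna,
    baseline_rescale,
    extract_phenotypes,
    spherocylinder_volume,
    volcano,
    window_lineage_means,
)


class TestExtract:
    def test_growth_rate_exact_on_noiseless_exponential(self, noiseless_cells):
        cells, _ = noiseless_cells
        ex = extract_phenotypes(cells)
        lam = ex["growth_rate"].dropna()
        assert len(lam) > 50
        assert np.allclose(lam, 2.0, atol=1e-9)

    def test_septum_error_zero_at_perfect_midpoint(self, noiseless_cells):
        cells, _ = noiseless_cells
        ex = extract_phenotypes(cells)
        ls = ex["septum_error"].dropna()
        assert len(ls) > 10 and np.allclose(ls, 0.0, atol=1e-12)

    def test_tau_consistent_with_growth_rate(self, noiseless_cells):
        """Exact doubling: interdivision time equals 1/mean(growth rate)."""
        cells, _ = noiseless_cells
        ex = extract_phenotypes(cells)
        tau = ex["interdivision_time"].dropna().mean()
        lam = ex["growth_rate"].dropna().mean()
        assert tau == pytest.approx(1.0 / lam, rel=1e-9)

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError, match="lacks columns"):
            extract_phenotypes(pd.DataFrame({"trench_id": [0]}))

    def test_recovers_planted_growth_targets(self):
        """Window means land within bootstrap uncertainty of the simulated truth."""
        cfg = lineage.SimConfig(n_trenches_per_sgrna=15, seed=60)
        strains = lineage.make_strain_effects(
            {"g1": {"growth_rate": 0.4}, "g2": {"growth_rate": 0.8}}, [0, 4]
        )
        cells, truth = lineage.simulate_experiment(cfg, strains)
        ex = extract_phenotypes(cells)
        means = window_lineage_means(ex, (420.0, 600.0))
        agg = aggregate_sgrna(means, n_boot=300, seed=61)
        merged = agg.merge(truth, on="sgrna_id")
        n_ok = 0
        for _, row in merged.iterrows():
            err = abs(row["growth_rate_estimate"] - row["target_growth_rate"])
            n_ok += err < max(2 * row["growth_rate_sem"], 0.05)
        assert n_ok >= 0.95 * len(merged)


def _simulated_lineages(seed=62, n_trenches=12, n_controls=2):
    cfg = lineage.SimConfig(n_trenches_per_sgrna=n_trenches, seed=seed)
    strains = lineage.make_control_strains(n_controls)
    cells, _ = lineage.simulate_experiment(cfg, strains)
    return extract_phenotypes(cells)


class TestRescale:
    def test_control_post_over_pre_near_one(self):
        ex = _simulated_lineages()
        res = baseline_rescale(ex, induction_time_min=120.0)
        post = res.lineages[res.lineages["time_min"] >= 120]["length"]
        sem = post.std() / math.sqrt(len(post))
        assert abs(post.mean() - 1.0) < 2 * sem + 0.01

    def test_static_bias_removed(self):
        """A trench with a 2x static length bias rescales onto its unbiased twin."""
        ex = _simulated_lineages()
        one = ex[ex["trench_id"] == ex["trench_id"].iloc[0]].copy()
        biased = one.copy()
        biased["trench_id"] = one["trench_id"] + 10_000
        for c in ("length", "div_mother_length", "div_daughter_length"):
            biased[c] = biased[c] * 2.0
        biased = extract_phenotypes(biased.drop(columns=["growth_rate", "interdivision_time", "septum_error"]))
        pair = pd.concat([one, biased], ignore_index=True)
        res = baseline_rescale(pair, induction_time_min=120.0)
        a = res.lineages[res.lineages["trench_id"] < 10_000]["length"].to_numpy()
        b = res.lineages[res.lineages["trench_id"] >= 10_000]["length"].to_numpy()
        assert np.allclose(a, b, rtol=1e-9)

    def test_non_growing_trench_dropped(self):
        ex = _simulated_lineages()
        frozen = ex[ex["trench_id"] == ex["trench_id"].iloc[0]].copy()
        frozen["trench_id"] = 20_000
        frozen["length"] = 2.0
        frozen["division_flag"] = 0
        frozen = extract_phenotypes(
            frozen.drop(columns=["growth_rate", "interdivision_time", "septum_error"])
        )
        res = baseline_rescale(pd.concat([ex, frozen], ignore_index=True), 120.0)
        assert 20_000 in set(res.dropped["trench_id"])
        assert 20_000 not in set(res.lineages["trench_id"])

    def test_rescaling_idempotent(self):
        ex = _simulated_lineages()
        once = baseline_rescale(ex, 120.0).lineages
        twice = baseline_rescale(once, 120.0).lineages
        assert np.allclose(
            once["length"].to_numpy() / once.groupby("trench_id")["length"].transform(
                lambda s: 1.0
            ),
            twice["length"].to_numpy() * twice.groupby("trench_id")["length"].transform(
                lambda s: 1.0
            ),
            rtol=0.05,
        )
        # second pass divides by a baseline that is already ~1
        assert abs(twice["length"].mean() - once["length"].mean()) < 0.02


class TestAggregate:
    def test_quality_rule_strictly_more_than_seven_lineages(self):
        rng = np.random.default_rng(63)
        rows = []
        for sg, n in (("seven", 7), ("eight", 8)):
            for t in range(n):
                rows.append({"trench_id": f"{sg}_{t}", "sgrna_id": sg,
                             "length": 4.0 + 0.05 * rng.standard_normal()})
        agg = aggregate_sgrna(pd.DataFrame(rows), n_boot=200, seed=64)
        flags = agg.set_index("sgrna_id")["quality_pass"]
        assert not flags["seven"] and flags["eight"]

    def test_single_lineage_degenerate(self):
        agg = aggregate_sgrna(
            pd.DataFrame([{"trench_id": 0, "sgrna_id": "solo", "length": 3.0}]),
            n_boot=100, seed=65,
        )
        row = agg.iloc[0]
        assert row["length_estimate"] == 3.0
        assert row["length_sem"] == 0.0
        assert not row["quality_pass"]

    def test_bootstrap_sem_matches_analytic_median_sem(self):
        """SEM of the median on Normal data: ~1.2533 sigma/sqrt(n)."""
        rng = np.random.default_rng(66)
        n, sigma = 100, 2.0
        vals = rng.normal(10.0, sigma, size=n)
        rows = [{"trench_id": i, "sgrna_id": "x", "length": v} for i, v in enumerate(vals)]
        agg = aggregate_sgrna(pd.DataFrame(rows), n_boot=4000, seed=67)
        analytic = 1.2533 * sigma / math.sqrt(n)
        assert agg.iloc[0]["length_sem"] == pytest.approx(analytic, rel=0.2)

    def test_empty_window_errors(self):
        ex = _simulated_lineages()
        with pytest.raises(ValueError):
            window_lineage_means(ex, (1e6, 2e6))
        with pytest.raises(ValueError):
            window_lineage_means(ex, (100.0, 100.0))


def _volcano_inputs(rng, n_controls=12, n_lineages=20, effect=0.0):
    rows = []
    for c in range(n_controls):
        for t in range(n_lineages):
            rows.append({"trench_id": f"c{c}_{t}", "sgrna_id": f"ctrl{c}",
                         "length": rng.normal(4.0, 0.2)})
    for t in range(50):
        rows.append({"trench_id": f"x_{t}", "sgrna_id": "test",
                     "length": rng.normal(4.0 + effect, 0.2)})
    return pd.DataFrame(rows)


class TestVolcano:
    def test_null_controls_rarely_called(self):
        rng = np.random.default_rng(68)
        lm = _volcano_inputs(rng)
        agg = aggregate_sgrna(lm, n_boot=100, seed=69)
        controls = [s for s in lm["sgrna_id"].unique() if s.startswith("ctrl")]
        v = volcano(lm, agg, controls)
        null_calls = v[v["sgrna_id"].str.startswith("ctrl")]["called"]
        assert null_calls.mean() <= 0.05 + 1e-9

    def test_planted_four_sd_effect_called(self):
        rng = np.random.default_rng(70)
        lm = _volcano_inputs(rng, effect=0.0)
        agg0 = aggregate_sgrna(lm, n_boot=100, seed=71)
        controls = [s for s in lm["sgrna_id"].unique() if s.startswith("ctrl")]
        ctrl_sd = agg0[agg0["sgrna_id"].isin(controls)]["length_estimate"].std(ddof=1)
        lm = _volcano_inputs(rng, effect=4.0 * ctrl_sd)
        agg = aggregate_sgrna(lm, n_boot=100, seed=72)
        v = volcano(lm, agg, controls)
        assert bool(v[v["sgrna_id"] == "test"]["called"].iloc[0])

    def test_effect_threshold_is_inclusive(self):
        """An effect of exactly 2 control SDs with q < FDR is called."""
        rng = np.random.default_rng(73)
        rows = []
        for c in range(12):
            val = 4.0 + (0.1 if c % 2 else -0.1)
            for t in range(10):
                rows.append({"trench_id": f"c{c}_{t}", "sgrna_id": f"ctrl{c}", "length": val})
        lm0 = pd.DataFrame(rows)
        controls = [f"ctrl{c}" for c in range(12)]
        agg0 = aggregate_sgrna(lm0, n_boot=50, seed=74)
        ests = agg0[agg0["sgrna_id"].isin(controls)]["length_estimate"]
        target = float(ests.mean() + 2.0 * ests.std(ddof=1))
        test_rows = [{"trench_id": f"x_{t}", "sgrna_id": "test", "length": target}
                     for t in range(40)]
        lm = pd.concat([lm0, pd.DataFrame(test_rows)], ignore_index=True)
        agg = aggregate_sgrna(lm, n_boot=50, seed=75)
        v = volcano(lm, agg, controls)
        row = v[v["sgrna_id"] == "test"].iloc[0]
        assert row["effect_sd"] == pytest.approx(2.0, abs=1e-9)
        assert row["called"]

    def test_requires_ten_controls(self):
        rng = np.random.default_rng(76)
        lm = _volcano_inputs(rng, n_controls=5)
        agg = aggregate_sgrna(lm, n_boot=50, seed=77)
        with pytest.raises(ValueError, match="control"):
            volcano(lm, agg, [f"ctrl{c}" for c in range(5)])

    def test_fdr_controlled_under_global_null(self):
        """False-call rate across replicate null screens stays near the nominal FDR."""
        rng = np.random.default_rng(78)
        n_false = n_tests = 0
        for _ in range(20):
            lm = _volcano_inputs(rng, n_controls=12, n_lineages=10)
            agg = aggregate_sgrna(lm, n_boot=50, seed=int(rng.integers(2**31)))
            controls = [s for s in lm["sgrna_id"].unique() if s.startswith("ctrl")]
            v = volcano(lm, agg, controls)
            n_false += int(v["called"].sum())
            n_tests += len(v)
        assert n_false / max(n_tests, 1) <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_tests)


class TestSpherocylinder:
    def test_degenerate_sphere(self):
        V, peri, cross = spherocylinder_volume(1.0, 1.0)
        assert V == pytest.approx(math.pi / 6)
        assert peri == pytest.approx(math.pi)
        assert cross == pytest.approx(math.pi / 4)

    def test_rod_two_by_one(self):
        V, _, _ = spherocylinder_volume(2.0, 1.0)
        assert V == pytest.approx(math.pi / 4 + math.pi / 6)

    def test_monotone_in_length(self):
        L = np.linspace(1.0, 5.0, 50)
        V, _, _ = spherocylinder_volume(L, np.ones_like(L))
        assert (np.diff(V) > 0).all()

    def test_requires_length_at_least_width(self):
        with pytest.raises(ValueError):
            spherocylinder_volume(0.5, 1.0)
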