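"""Kinetic (p)ppGpp model, sector size model and hyperbolic scaling fits."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mmscreen.growthlaws import (
    KineticParams,
    SectorParams,
    beta_kappa,
    classify_scaling,
    fit_exponential,
    fit_hyperbolic,
    joint_fit,
    kinetic_steady_state,
    perimeter_correction,
    perturbation_scan,
    ribosome_law_fit,
    volume_from_sectors,
)


class TestSteadyState:
    def test_closed_form_in_basal_free_limit(self):
        """sigma -> 0, q = 0: g* = (alpha/beta)(tau_d/tau_t), independent of k_i."""
        for k_i in (0.2, 1.0, 5.0):
            p = KineticParams(k_i=k_i, sigma=1e-14)
            st = kinetic_steady_state(p)
            assert st.g == pytest.approx((p.alpha / p.beta) * (p.tau_d / p.tau_t), rel=1e-6)

    def test_double_knockout_pins_allocation(self):
        for tau_d in (0.1, 0.5):
            p = KineticParams(tau_d=tau_d, genotype="relA_spoT")
            st = kinetic_steady_state(p)
            assert st.g == 0.0 and st.phi_R == p.phi_max

    def test_matches_ode_integration_oracle(self):
        """Fixed point equals long-time integration of the rate equations."""
        rng = np.random.default_rng(110)
        for _ in range(20):
            p = KineticParams(
                k_i=rng.uniform(0.3, 3.0),
                tau_d=rng.uniform(0.1, 0.6),
                tau_t=rng.uniform(0.3, 1.2),
                alpha=rng.uniform(0.5, 2.0),
                beta=rng.uniform(1.0, 4.0),
                sigma=rng.uniform(0.0, 0.01),
                q=rng.uniform(0.0, 0.4),
                genotype=("WT", "relA")[int(rng.integers(2))],
            )
            st = kinetic_steady_state(p)

            from mmscreen.growthlaws import _phi_of_g, _pools, _q_eff

            def rhs(t, y):
                g, phi = y
                qe = _q_eff(p, g)
                R_D, R_T = _pools(p, phi, qe)
                dg = p.effective_alpha * R_D + p.sigma - p.beta * R_T * g
                dphi = (_phi_of_g(p, g) - phi) / 0.2
                return [dg, dphi]

            sol = solve_ivp(
                rhs, (0.0, 2000.0), [st.g * 1.5 + 0.01, p.phi_max / 2],
                rtol=1e-10, atol=1e-12,
            )
            g_inf, phi_inf = sol.y[:, -1]
            assert g_inf == pytest.approx(st.g, rel=1e-6, abs=1e-9)
            assert phi_inf == pytest.approx(st.phi_R, rel=1e-6)

    def test_invalid_genotype(self):
        with pytest.raises(ValueError):
            KineticParams(genotype="spoT")


class TestPerturbationSigns:
    """The three growth-law variants the perturbation scans must reproduce."""

    def test_capture_scan_is_smk(self):
        df = perturbation_scan(KineticParams(), "capture")
        assert df.attrs["slope"] > 0
        assert df["g"].iloc[-1] > df["g"].iloc[0]  # alarmone rises as growth falls

    def test_translocation_scan_inverts(self):
        df = perturbation_scan(KineticParams(), "translocation")
        assert df.attrs["slope"] < 0
        assert df["g"].iloc[-1] < df["g"].iloc[0]

    def test_initiation_scan_is_flat(self):
        p = KineticParams()
        cap = perturbation_scan(p, "capture").attrs["slope"]
        df = perturbation_scan(p, "initiation")
        assert abs(df.attrs["slope"]) < 0.02 * abs(cap)
        assert np.all(np.abs(df["g"] / df["g"].iloc[0] - 1.0) < 0.01)

    def test_single_aa_inverts_without_rela(self):
        df = perturbation_scan(KineticParams(genotype="relA"), "single_AA")
        assert df.attrs["slope"] < 0

    def test_single_aa_masked_in_wild_type(self):
        df = perturbation_scan(KineticParams(), "single_AA")
        assert df.attrs["slope"] > 0

    def test_multi_aa_not_inverse_without_rela(self):
        df = perturbation_scan(KineticParams(genotype="relA"), "multi_AA")
        assert df.attrs["slope"] >= 0

    def test_stalk_scan_is_flat(self):
        p = KineticParams()
        cap = perturbation_scan(p, "capture").attrs["slope"]
        df = perturbation_scan(p, "stalk")
        assert abs(df.attrs["slope"]) < 0.02 * abs(cap)

    def test_double_knockout_collapses_all_scans_to_flat(self):
        p = KineticParams(genotype="relA_spoT")
        for axis in ("capture", "translocation", "initiation", "single_AA"):
            df = perturbation_scan(p, axis)
            lam = df["growth_rate"].to_numpy()
            L = 2.0 ** df["phi_R"].to_numpy()  # any monotone proxy of phi_R
            label, slope = classify_scaling(lam, L, eligibility_growth=np.inf)
            assert label == "flat", axis


class TestRibosomeLawFit:
    def test_exact_line_recovery(self):
        lam = np.linspace(0.3, 1.5, 7)
        a2, b2, r2 = ribosome_law_fit(lam, 0.2 * lam + 0.1)
        assert (a2, b2) == (pytest.approx(0.2), pytest.approx(0.1))
        assert r2 == pytest.approx(1.0)

    def test_model_capture_scan_is_linear(self):
        df = perturbation_scan(KineticParams(), "capture", grid=np.linspace(1, 3, 15))
        _, _, r2 = ribosome_law_fit(df["growth_rate"], df["phi_R"])
        assert r2 >= 0.98

    def test_constant_curve_zero_slope(self):
        lam = np.linspace(0.3, 1.5, 5)
        a2, _, _ = ribosome_law_fit(lam, np.full_like(lam, 0.3))
        assert a2 == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_range_errors(self):
        with pytest.raises(ValueError):
            ribosome_law_fit([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])


class TestSectorModel:
    def test_no_coupling_limit(self):
        sp = SectorParams(a1=0.0, b1=0.2)
        phis = np.linspace(0.1, 0.5, 5)
        V = volume_from_sectors(phis, sp)
        assert np.allclose(V, V[0])

    def test_composition_yields_hyperbola_exactly(self):
        """V(phi_R(lambda)) == A/(1 - k lambda) with k = a1 a2/(1 - b1 - a1 b2)."""
        sp = SectorParams(a1=1.2, b1=0.08, V0=1.5)
        a2, b2 = 0.22, 0.05
        lam = np.linspace(0.2, 1.6, 9)
        V = volume_from_sectors(a2 * lam + b2, sp)
        k = sp.a1 * a2 / (1.0 - sp.b1 - sp.a1 * b2)
        A = sp.V0 / (1.0 - sp.b1 - sp.a1 * b2)
        assert np.allclose(V, A / (1.0 - k * lam), rtol=1e-12)

    def test_monotone_in_phi(self):
        sp = SectorParams(a1=1.0, b1=0.05)
        V = volume_from_sectors(np.linspace(0.1, 0.5, 20), sp)
        assert (np.diff(V) > 0).all()

    def test_divergence_raises(self):
        with pytest.raises(ValueError, match="vanishes"):
            volume_from_sectors(0.9, SectorParams(a1=1.2, b1=0.05))


class TestClassifyScaling:
    def test_positive_slope_is_smk(self):
        lam = np.linspace(0.3, 1.4, 6)
        label, slope = classify_scaling(lam, 2.0 ** (0.5 * lam))
        assert label == "SMK" and slope == pytest.approx(0.5)

    def test_negative_slope_is_inverse(self):
        lam = np.linspace(0.3, 1.4, 6)
        label, _ = classify_scaling(lam, 2.0 ** (-0.5 * lam))
        assert label == "inverse"

    def test_small_slope_is_flat(self):
        lam = np.linspace(0.3, 1.4, 6)
        label, _ = classify_scaling(lam, 2.0 ** (0.1 * lam))
        assert label == "flat"

    def test_fast_growers_ineligible(self):
        lam = np.linspace(0.95, 1.4, 6)
        label, slope = classify_scaling(lam, 2.0 ** (0.5 * lam))
        assert (label, slope) == ("ineligible", None)

    def test_too_few_points_ineligible(self):
        assert classify_scaling([0.5, 0.6], [2.0, 2.1])[0] == "ineligible"


class TestHyperbolicFits:
    def test_exact_inversion(self):
        lam = np.linspace(0.2, 1.5, 8)
        V = 2.0 / (1.0 - 0.5 * lam)
        A, k, rss = fit_hyperbolic(lam, V)
        assert A == pytest.approx(2.0, rel=1e-12)
        assert k == pytest.approx(0.5, rel=1e-12)
        assert rss < 1e-20

    def test_hyperbolic_beats_exponential_on_hyperbolic_data(self):
        """At 2% noise the correct model wins the RSS comparison in >= 90% of replicates."""
        rng = np.random.default_rng(111)
        lam = np.linspace(0.2, 1.6, 12)
        truth = 1.8 / (1.0 - 0.45 * lam)
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            V = truth * (1.0 + 0.02 * rng.standard_normal(lam.size))
            _, _, rss_h = fit_hyperbolic(lam, V)
            _, _, rss_e = fit_exponential(lam, V)
            wins += rss_h <= rss_e
        assert wins >= 0.90 * n_rep

    def test_flat_data_agrees_between_models(self):
        rng = np.random.default_rng(112)
        lam = np.linspace(0.2, 1.5, 10)
        V = 2.0 * (1.0 + 0.01 * rng.standard_normal(lam.size))
        A, k, _ = fit_hyperbolic(lam, V)
        V0, k_e, _ = fit_exponential(lam, V)
        assert abs(k) < 0.05 and abs(k_e) < 0.05
        assert A == pytest.approx(V0, rel=0.05)

    def test_nonpositive_volume_errors(self):
        with pytest.raises(ValueError):
            fit_hyperbolic([0.2, 0.4, 0.6], [1.0, -1.0, 2.0])


def _two_class_data(rng=None, noise=0.0, u=0.5, w1=0.2, w2=0.35):
    lam = np.linspace(0.2, 1.3, 9)
    out = {}
    for name, w in (("charging", w1), ("translocation", w2)):
        inv = u - w * lam
        if noise and rng is not None:
            inv = inv * (1.0 + noise * rng.standard_normal(lam.size))
        out[name] = (lam, 1.0 / inv)
    return out


class TestJointFit:
    def test_three_free_parameters(self):
        fit = joint_fit(_two_class_data(), n_boot=10, seed=113)
        assert fit.n_parameters == 3

    def test_exact_recovery_of_shared_intercept_and_slopes(self):
        fit = joint_fit(_two_class_data(), n_boot=10, seed=114)
        assert fit.u == pytest.approx(0.5, rel=1e-10)
        assert fit.slopes["charging"] == pytest.approx(0.2, rel=1e-10)
        assert fit.slopes["translocation"] == pytest.approx(0.35, rel=1e-10)
        assert fit.flat_level == pytest.approx(2.0, rel=1e-10)
        assert fit.k["charging"] == pytest.approx(0.4, rel=1e-10)

    def test_bootstrap_ci_coverage_at_two_percent_noise(self):
        """95% residual-bootstrap CI covers the true k in 90-99% of replicates."""
        rng = np.random.default_rng(115)
        n_rep, covered = 100, 0
        for _ in range(n_rep):
            data = _two_class_data(rng, noise=0.02)
            fit = joint_fit(data, n_boot=300, seed=int(rng.integers(2**31)))
            covered += fit.contains("k_charging", 0.2 / 0.5)
        assert 0.90 * n_rep <= covered <= 0.99 * n_rep

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(116)
        fit = joint_fit(_two_class_data(rng, noise=0.02), n_boot=400, seed=117)
        assert fit.ci["u"][0] <= fit.u <= fit.ci["u"][1]
        for c, w in fit.slopes.items():
            lo, hi = fit.ci[c]
            assert lo <= w <= hi


class TestBetaKappa:
    def test_ratio_constant_across_model_classes(self):
        """Classes generated from one sector model share kappa/beta to 1e-6."""
        sp = SectorParams(a1=1.2, b1=0.08)
        b2 = 0.05
        lam = np.linspace(0.2, 1.4, 9)
        laws, ks = {}, {}
        for name, a2 in (("charging", 0.18), ("translocation", 0.30)):
            V = volume_from_sectors(a2 * lam + b2, sp)
            _, k, _ = fit_hyperbolic(lam, V)
            laws[name] = (a2, b2)
            ks[name] = k
        table = beta_kappa(laws, ks)
        assert table.attrs["ratio_spread"] < 1e-6
        expected = sp.a1 / (1.0 - sp.b1 - sp.a1 * b2)
        assert np.allclose(table["ratio"], expected, rtol=1e-9)

    def test_zero_beta_zero_kappa(self):
        lam = np.linspace(0.2, 1.4, 5)
        V = volume_from_sectors(np.full_like(lam, 0.3), SectorParams(a1=1.0, b1=0.05))
        _, k, _ = fit_hyperbolic(lam, V)
        table = beta_kappa({"flat": (0.0, 0.3), "x": (0.2, 0.3)}, {"flat": k, "x": 0.3})
        assert table.set_index("class").loc["flat", "kappa"] == pytest.approx(0.0, abs=1e-12)

    def test_requires_two_classes(self):
        with pytest.raises(ValueError):
            beta_kappa({"only": (0.2, 0.1)}, {"only": 0.3})


class TestPerimeterCorrection:
    def test_constant_width_identical_relative_fit(self):
        lam, V = _two_class_data()["charging"]
        data = {"charging": (lam, V, np.ones_like(V)),
                "translocation": (*_two_class_data()["translocation"], np.ones_like(V))}
        data["translocation"] = (
            data["translocation"][0], data["translocation"][1], np.ones_like(V)
        )
        out = perimeter_correction(data, n_boot=10, seed=118).set_index("normalization")
        assert out.loc["perimeter", "relative_rss"] == pytest.approx(
            out.loc["raw", "relative_rss"], abs=1e-12
        )

    def test_perimeter_generated_data_improves(self):
        """When V carries a width-proportional factor, normalising it out helps."""
        rng = np.random.default_rng(119)
        lam = np.linspace(0.2, 1.1, 12)
        W = 1.0 + 0.3 * rng.random(lam.size)
        base = 1.0 / (0.5 - 0.25 * lam)
        data = {
            "a": (lam, base * np.pi * W, W),
            "b": (lam, 1.0 / (0.5 - 0.4 * lam) * np.pi * W, W),
        }
        out = perimeter_correction(data, n_boot=10, seed=120).set_index("normalization")
        assert out.loc["perimeter", "relative_rss"] < out.loc["raw", "relative_rss"]

    def test_reports_all_three_normalizations(self):
        lam, V = _two_class_data()["charging"]
        data = {"charging": (lam, V, np.ones_like(V)),
                "translocation": (lam, V * 1.1, np.ones_like(V))}
        out = perimeter_correction(data, n_boot=5, seed=121)
        assert set(out["normalization"]) == {"raw", "perimeter", "cross_section"}
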