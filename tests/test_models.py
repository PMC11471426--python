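"""Modelling layer: pseudo-absences, splits, SRE, TSS, ensembling,
variable importance, and ensemble recovery behaviour."""

import numpy as np
import pytest

from climniche import (
    ClimateNicheModel,
    GridConfig,
    NotEnsembleableError,
    SurfaceRangeEnvelope,
    build_ensemble,
    count_model_runs,
    evaluate_tss,
    generate_climate_grids,
    generate_pseudo_absences,
    make_eval_splits,
    make_virtual_species,
    sample_occurrences,
    variable_importance,
)
from climniche.models import SingleFit, fit_single_model


class TestPseudoAbsences:
    def test_contract(self, recent):
        presences = np.arange(50)
        sets = generate_pseudo_absences(recent, presences, n=500, replicates=2, seed=0)
        assert len(sets) == 2
        for s in sets:
            assert len(s) == 500
            assert len(np.unique(s)) == 500  # no duplicate cells
            assert not np.intersect1d(s, presences).size
        assert not np.array_equal(np.sort(sets[0]), np.sort(sets[1]))

    def test_too_many_requested(self, recent):
        with pytest.raises(ValueError):
            generate_pseudo_absences(recent, np.arange(10), n=recent.n_cells, seed=0)

    def test_sampling_uniform_over_repeats(self):
        """Monte-Carlo: per-cell selection frequency matches the uniform
        expectation within binomial tolerance."""
        grids = generate_climate_grids(GridConfig(n_rows=10, n_cols=10), seed=0)
        g = grids["recent"]
        presences = np.array([0])
        n, reps = 20, 400
        counts = np.zeros(g.n_cells)
        for i in range(reps):
            (s,) = generate_pseudo_absences(g, presences, n=n, replicates=1, seed=i)
            counts[s] += 1
        p = n / (g.n_cells - 1)
        sd = np.sqrt(reps * p * (1 - p))
        expected = reps * p
        assert np.all(np.abs(counts[1:] - expected) < 5 * sd)


class TestEvalSplits:
    def test_holdout_fraction(self):
        splits = make_eval_splits(100, 200, holdout=0.30, repeats=2, seed=0)
        assert len(splits) == 2
        for s in splits:
            assert len(s["test_p"]) == 30 and len(s["train_p"]) == 70
            assert len(s["test_a"]) == 60 and len(s["train_a"]) == 140

    def test_run_counting(self):
        # 8 techniques x (2 pseudo-absence replicates x 2 splits) = 32
        # single models, + 1 ensemble = 33 fits per species
        assert 8 * 2 * 2 == 32
        assert count_model_runs(1, n_techniques=8) == 33

    def test_too_few_presences(self):
        with pytest.raises(ValueError):
            make_eval_splits(5, 100)


class TestSurfaceRangeEnvelope:
    toy = np.array([[1, 1], [2, 2], [3, 3], [4, 4], [5, 5]], dtype=float)

    def test_hand_computed_envelope(self):
        """Bounds by hand (linear-interpolated quantiles of 1..5 at
        q=0.2): position 0.2*4 = 0.8 -> 1.8; upper 4.2."""
        sre = SurfaceRangeEnvelope(0.2).fit(self.toy)
        np.testing.assert_allclose(sre.lower_, [1.8, 1.8])
        np.testing.assert_allclose(sre.upper_, [4.2, 4.2])
        # spec cells from the envelope definition
        assert sre.predict_suitability([[3, 5]]) == 0  # one variable outside
        assert sre.predict_suitability([[3, 3]]) == 1

    def test_q0_training_presences_inside(self):
        sre = SurfaceRangeEnvelope(0.0).fit(self.toy)
        assert (sre.predict_suitability(self.toy) == 1).all()

    def test_conjunction_rule(self):
        sre = SurfaceRangeEnvelope(0.0).fit(self.toy)
        assert sre.predict_suitability([[3, 99]]) == 0

    def test_errors(self):
        with pytest.raises(ValueError):
            SurfaceRangeEnvelope(0.6)
        with pytest.raises(ValueError):
            SurfaceRangeEnvelope(0.1).fit(self.toy[:1])


class TestEvaluateTSS:
    def test_arithmetic_identity(self):
        """Optimal operating point sens 0.8 / spec 0.9 gives TSS 0.7
        (hand check: threshold 0.9 scores 1.7, every other candidate
        scores at most 1.6)."""
        scores = np.r_[[0.9] * 4, [0.05], [0.95], [0.5], [0.1] * 8]
        labels = np.r_[[1] * 5, [0] * 10]
        ev = evaluate_tss(scores, labels)
        assert ev["sensitivity"] == pytest.approx(0.8)
        assert ev["specificity"] == pytest.approx(0.9)
        assert ev["tss"] == pytest.approx(0.7)

    def test_perfect_separation(self):
        ev = evaluate_tss(np.r_[[0.9] * 5, [0.1] * 5], np.r_[[1] * 5, [0] * 5])
        assert ev["tss"] == pytest.approx(1.0)

    def test_toy_against_exhaustive_sweep(self):
        scores = np.array([0.9, 0.8, 0.4, 0.3, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0, 0, 0])
        ev = evaluate_tss(scores, labels)
        # independent brute force over a dense threshold lattice
        best = max(
            (labels[scores >= t].size and (scores[labels == 1] >= t).mean())
            + (scores[labels == 0] < t).mean()
            for t in np.linspace(0, 1, 1001)
        )
        assert ev["sensitivity"] + ev["specificity"] == pytest.approx(best)
        # presences and absences are separable at any cut in (0.3, 0.4]
        assert 0.3 < ev["threshold"] <= 0.4
        assert ev["tss"] == pytest.approx(1.0)

    def test_degenerate_constant_predictions(self):
        ev = evaluate_tss(np.full(10, 0.5), np.r_[[1] * 5, [0] * 5])
        assert ev["tss"] == 0.0 and ev["degenerate"]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_tss(np.r_[0.1, 0.9], np.r_[1, 1])


class TestSingleModels:
    def test_separable_toy_perfect_rf(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 3)), rng.normal(8, 1, (50, 3))])
        y = np.r_[np.ones(50), np.zeros(50)]
        est = fit_single_model("RF", X, y, seed=0)
        ev = evaluate_tss(est.predict_suitability(X), y)
        assert ev["tss"] == pytest.approx(1.0)

    def test_shuffled_labels_have_no_skill(self):
        """Permutation null: mean |TSS| on held-out data stays near 0."""
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (240, 4))
        vals = []
        for _ in range(30):
            y = rng.permutation(np.r_[np.ones(120), np.zeros(120)])
            est = fit_single_model("GLM", X[:160], y[:160], seed=0)
            vals.append(evaluate_tss(est.predict_suitability(X[160:]), y[160:])["tss"])
        assert abs(np.mean(vals)) < 0.15

    def test_single_class_and_unknown_technique_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError):
            fit_single_model("GLM", X, np.ones(20))
        with pytest.raises(KeyError):
            fit_single_model("SVM", X, np.r_[np.ones(10), np.zeros(10)])


def _fit(tss, pred=0.5):
    class _Const:
        def __init__(self, v):
            self.v = v

        def predict_suitability(self, X):
            return np.full(len(X), self.v)

    return SingleFit("GLM", 1, 1, _Const(pred), tss, 1.0, tss, 0.5)


class TestBuildEnsemble:
    def test_equal_weights_mean(self):
        members, w = build_ensemble(
            [_fit(0.8, 0.6), _fit(0.8, 0.8), _fit(0.8, 0.7)], cutoff=0.7
        )
        np.testing.assert_allclose(w, [1 / 3] * 3)
        pred = sum(wi * m.predict_suitability(np.zeros((1, 1))) for m, wi in zip(members, w))
        assert pred[0] == pytest.approx(0.7)

    def test_cutoff_excludes_weak_member(self):
        members, w = build_ensemble(
            [_fit(0.9), _fit(0.45), _fit(0.8), _fit(0.75)], cutoff=0.7
        )
        assert len(members) == 3
        assert all(m.tss > 0.7 for m in members)

    def test_weights_proportional_to_tss(self):
        # 0.8/2.27, 0.75/2.27, 0.72/2.27
        _, w = build_ensemble([_fit(0.8), _fit(0.75), _fit(0.72)], cutoff=0.7)
        np.testing.assert_allclose(w, [0.352423, 0.330396, 0.317181], atol=1e-6)
        assert w.sum() == pytest.approx(1.0)

    def test_too_few_members(self):
        with pytest.raises(NotEnsembleableError):
            build_ensemble([_fit(0.9), _fit(0.2), _fit(0.1)], cutoff=0.7)


class TestVariableImportance:
    def test_unused_variables_score_low_primary_ranks_first(self):
        """Recovery on a patchy grid with decorrelated months (short
        autocorrelation, so incidental spatial confounding between the
        suitable region and unused fields averages out): the niche's two
        variables dominate, the other 22 score near zero."""
        cfg = GridConfig(
            n_rows=100, n_cols=100, autocorr_length=4.0,
            temp_noise_sd=0.3, temp_month_noise_sd=2.5,
            prec_noise_sd=0.1, prec_month_noise_sd=0.5, lat_gradient=0.0,
            elev_relief=0.0, elev_north_slope=0.0,
        )
        g = generate_climate_grids(cfg, seed=8)["recent"]
        sp = make_virtual_species(
            g, variables=("tmean_01", "prec_06"), breadth_fraction=0.15, seed=0
        )
        occ = sample_occurrences(sp, g, 500, seed=1)
        res = ClimateNicheModel.from_dataframe(occ, g, n_pseudo_absences=1500).fit(
            seed=2, n_perm=5
        )
        imp = res.variable_importance
        ranked = imp.sort_values(ascending=False)
        assert set(ranked.index[:2]) == {"tmean_01", "prec_06"}
        assert imp.drop(["tmean_01", "prec_06"]).max() < 0.05

    def test_deterministic_and_degenerate(self, rng):
        X = rng.normal(size=(50, 4))

        def predict(M):
            return M[:, 0] ** 2 + 0.1 * M[:, 1]

        a = variable_importance(predict, X, n_perm=3, seed=7)
        b = variable_importance(predict, X, n_perm=3, seed=7)
        np.testing.assert_array_equal(a, b)
        assert a[0] > a[2]
        zeros = variable_importance(lambda M: np.ones(len(M)), X, n_perm=2, seed=0)
        assert (zeros == 0).all()

    def test_nperm_validated(self, rng):
        with pytest.raises(ValueError):
            variable_importance(lambda M: M[:, 0], rng.normal(size=(5, 2)), n_perm=0)


class TestEnsembleModel:
    def test_tss_identity_for_every_fit(self, fitted):
        f = fitted.fits_frame()
        np.testing.assert_allclose(f["tss"], f["sensitivity"] + f["specificity"] - 1)
        assert f["sensitivity"].between(0, 1).all()
        assert f["specificity"].between(0, 1).all()
        assert f["tss"].between(-1, 1).all()

    def test_weights_and_membership(self, fitted):
        assert fitted.weights.sum() == pytest.approx(1.0)
        assert (fitted.weights >= 0).all()
        assert all(m.tss > fitted.model.tss_cutoff for m in fitted.members)
        assert len(fitted.variable_importance) == 24

    def test_run_design(self, fitted):
        f = fitted.fits_frame()
        # 3 techniques x 2 pseudo-absence replicates x 2 splits
        assert len(f) == 12
        assert set(f["pa_replicate"]) == {1, 2} and set(f["split_replicate"]) == {1, 2}

    def test_refit_same_seed_reproduces(self, occurrences, recent, fitted):
        model = ClimateNicheModel.from_dataframe(
            occurrences, recent, n_pseudo_absences=800
        )
        again = model.fit(seed=5)
        assert again.tss == pytest.approx(fitted.tss)
        np.testing.assert_allclose(again.weights, fitted.weights)

    def test_summary_mentions_key_quantities(self, fitted):
        s = fitted.summary()
        assert "ensemble TSS" in s and "threshold" in s

    def test_ensemble_dominates_median_member(self, recent):
        """Median ensemble TSS at least matches the median member TSS
        across several virtual species (variance reduction)."""
        ens, mem = [], []
        for i in range(10):
            sp = make_virtual_species(
                recent,
                species_id=f"v{i}",
                optimum_quantiles=(0.3 + 0.04 * i, 0.6 - 0.03 * i),
                seed=i,
            )
            occ = sample_occurrences(sp, recent, 200, seed=50 + i)
            model = ClimateNicheModel.from_dataframe(
                occ, recent, n_pseudo_absences=600, tss_cutoff=-1.0
            )
            res = model.fit(seed=60 + i)
            ens.append(res.tss)
            mem.extend(f.tss for f in res.fits)
        assert np.median(ens) >= np.median(mem)
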