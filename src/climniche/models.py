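"""Ensemble climate-niche modelling.

The central objects follow the statsmodels convention: a
:class:`ClimateNicheModel` is constructed from data (presence points on
a :class:`~climniche.grid.ClimateGrid`, plus modelling options) and its
:meth:`~ClimateNicheModel.fit` returns a :class:`NicheEnsembleResults`
carrying the fitted single models, their true-skill-statistic (TSS)
scores, the TSS-proportional ensemble weights, held-out ensemble
performance, permutation variable importance, and projection methods.

Design: two replicates of uniformly sampled pseudo-absences stand in
for true absences; each technique is trained on four runs (2
pseudo-absence replicates x 2 random 70/30 presence splits) and scored
by TSS = sensitivity + specificity - 1 at the threshold maximizing
sensitivity + specificity.  Single models with TSS above the cutoff
(default 0.7) enter a weighted-mean ensemble with weights proportional
to TSS.  The bespoke surface range envelope (SRE) classifier scores a
cell 1 iff every climate variable falls within the [q, 1-q] quantile
interval of the training presences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .grid import CLIMATE_VARIABLES, ClimateGrid

__all__ = [
    "SurfaceRangeEnvelope",
    "TECHNIQUES",
    "DEFAULT_TECHNIQUES",
    "generate_pseudo_absences",
    "make_eval_splits",
    "fit_single_model",
    "fit_sre",
    "evaluate_tss",
    "build_ensemble",
    "variable_importance",
    "count_model_runs",
    "ClimateNicheModel",
    "NicheEnsembleResults",
    "NotEnsembleableError",
]


class NotEnsembleableError(RuntimeError):
    """Fewer than the minimum number of single models cleared the TSS cutoff."""


# ---------------------------------------------------------------------------
# surface range envelope


class SurfaceRangeEnvelope:
    """Rectilinear climate envelope fitted on presences only.

    A cell is suitable (score 1) iff, for every variable, its value lies
    within the [q, 1-q] quantile interval of the training presences.
    """

    def __init__(self, quantile: float = 0.025):
        if not 0 <= quantile < 0.5:
            raise ValueError("SRE quantile must lie in [0, 0.5)")
        self.quantile = quantile
        self.lower_: np.ndarray | None = None
        self.upper_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        if y is not None:
            X = X[np.asarray(y) == 1]
        if len(X) < 2:
            raise ValueError("SRE needs at least 2 presences")
        self.lower_ = np.quantile(X, self.quantile, axis=0)
        self.upper_ = np.quantile(X, 1.0 - self.quantile, axis=0)
        return self

    def predict_suitability(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        inside = (X >= self.lower_) & (X <= self.upper_)
        return inside.all(axis=1).astype(float)


class _SklearnSuitability:
    """Adapter giving any sklearn probabilistic classifier the
    ``predict_suitability`` surface."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.estimator.fit(X, y)
        return self

    def predict_suitability(self, X) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        cls = list(self.estimator.classes_)
        return proba[:, cls.index(1)]


class _HingeFeatures:
    """Piecewise-linear (hinge) basis expansion at fixed quantile knots,
    an adaptive-spline-style feature map for a linear learner."""

    def __init__(self, n_knots: int = 3):
        self.n_knots = n_knots
        self.knots_: np.ndarray | None = None

    def fit(self, X, y=None):
        qs = np.linspace(0.2, 0.8, self.n_knots)
        self.knots_ = np.quantile(np.asarray(X, dtype=float), qs, axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        feats = [X]
        for k in range(self.n_knots):
            feats.append(np.maximum(X - self.knots_[k], 0.0))
            feats.append(np.maximum(self.knots_[k] - X, 0.0))
        return np.hstack(feats)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_params(self, deep=True):
        return {"n_knots": self.n_knots}

    def set_params(self, **p):
        self.n_knots = p.get("n_knots", self.n_knots)
        return self


class _QuadraticFeatures:
    """Augment each variable with its square (the customary
    second-order polynomial terms of a niche-model GLM, letting a
    logistic fit unimodal responses)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.hstack([X, X**2])

    def fit_transform(self, X, y=None):
        return self.transform(X)

    def get_params(self, deep=True):
        return {}

    def set_params(self, **p):
        return self


def _make_glm(seed):
    return _SklearnSuitability(
        Pipeline(
            [
                ("quad", _QuadraticFeatures()),
                ("scale", StandardScaler()),
                ("glm", LogisticRegression(max_iter=1000, random_state=seed)),
            ]
        )
    )


def _make_rf(seed):
    return _SklearnSuitability(
        RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    )


def _make_ann(seed):
    return _SklearnSuitability(
        Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "ann",
                    MLPClassifier(
                        hidden_layer_sizes=(16,), max_iter=300, random_state=seed
                    ),
                ),
            ]
        )
    )


def _make_cta(seed):
    return _SklearnSuitability(
        DecisionTreeClassifier(max_depth=8, min_samples_leaf=5, random_state=seed)
    )


def _make_fda(seed):
    return _SklearnSuitability(LinearDiscriminantAnalysis())


def _make_gam(seed):
    return _SklearnSuitability(
        Pipeline(
            [
                ("spline", SplineTransformer(n_knots=5, degree=3)),
                ("glm", LogisticRegression(max_iter=1000, random_state=seed)),
            ]
        )
    )


def _make_mars(seed):
    return _SklearnSuitability(
        Pipeline(
            [
                ("hinge", _HingeFeatures(n_knots=3)),
                ("scale", StandardScaler()),
                ("glm", LogisticRegression(max_iter=1000, random_state=seed)),
            ]
        )
    )


TECHNIQUES = {
    "GLM": _make_glm,
    "RF": _make_rf,
    "SRE": lambda seed, q=0.025: SurfaceRangeEnvelope(q),
    "ANN": _make_ann,
    "CTA": _make_cta,
    "FDA": _make_fda,
    "GAM": _make_gam,
    "MARS": _make_mars,
}

DEFAULT_TECHNIQUES = ("GLM", "RF", "SRE")
FULL_TECHNIQUES = ("ANN", "CTA", "FDA", "GAM", "GLM", "MARS", "RF", "SRE")


# ---------------------------------------------------------------------------
# sampling and evaluation primitives


def generate_pseudo_absences(
    grid: ClimateGrid,
    presence_cells: np.ndarray,
    n: int = 50_000,
    replicates: int = 2,
    seed: int = 0,
) -> list[np.ndarray]:
    """Sample ``replicates`` independent sets of ``n`` background cells,
    uniformly without replacement, excluding presence cells."""
    presence_cells = np.unique(np.asarray(presence_cells))
    pool = np.setdiff1d(np.arange(grid.n_cells), presence_cells)
    if n > pool.size:
        raise ValueError(
            f"requested {n} pseudo-absences but only {pool.size} non-presence cells exist"
        )
    streams = np.random.SeedSequence(seed).spawn(replicates)
    return [
        np.random.default_rng(s).choice(pool, size=n, replace=False) for s in streams
    ]


def make_eval_splits(
    n_presences: int,
    n_absences: int,
    holdout: float = 0.30,
    repeats: int = 2,
    seed: int = 0,
) -> list[dict[str, np.ndarray]]:
    """Random 70/30 train/test splits of presence and absence indices.

    Returns ``repeats`` dicts with keys ``train_p, test_p, train_a,
    test_a`` (indices into the respective arrays).
    """
    if n_presences < 10:
        raise ValueError("need at least 10 presences to split")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repeats):
        p = rng.permutation(n_presences)
        a = rng.permutation(n_absences)
        kp = max(1, int(round(holdout * n_presences)))
        ka = max(1, int(round(holdout * n_absences)))
        out.append(
            {
                "test_p": p[:kp],
                "train_p": p[kp:],
                "test_a": a[:ka],
                "train_a": a[ka:],
            }
        )
    return out


def evaluate_tss(scores: np.ndarray, labels: np.ndarray) -> dict:
    """Threshold-optimized true skill statistic.

    Sweeps the sorted unique predicted values as candidate thresholds
    (prediction rule: suitable iff score >= threshold), maximizes
    sensitivity + specificity, breaking ties toward the smaller
    threshold, and returns ``{tss, sensitivity, specificity, threshold,
    degenerate}``.  Degenerate constant predictions score TSS 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("evaluation data must contain both classes")
    uniq = np.unique(scores)
    if uniq.size == 1:
        return {
            "tss": 0.0,
            "sensitivity": 1.0,
            "specificity": 0.0,
            "threshold": float(uniq[0]),
            "degenerate": True,
        }
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best = None
    for thr in uniq:  # ascending, so first max wins the tie toward smaller thr
        sens = float((pos >= thr).mean())
        spec = float((neg < thr).mean())
        if best is None or sens + spec > best[0] + 1e-12:
            best = (sens + spec, sens, spec, float(thr))
    _, sens, spec, thr = best
    return {
        "tss": sens + spec - 1.0,
        "sensitivity": sens,
        "specificity": spec,
        "threshold": thr,
        "degenerate": False,
    }


def fit_single_model(technique: str, X: np.ndarray, y: np.ndarray, seed: int = 0, **kw):
    """Fit one registered technique on labelled training data."""
    if technique not in TECHNIQUES:
        raise KeyError(f"unknown technique {technique!r}; registered: {sorted(TECHNIQUES)}")
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    est = TECHNIQUES[technique](seed, **kw) if technique == "SRE" else TECHNIQUES[technique](seed)
    est.fit(X, y)
    return est


def fit_sre(X_presence: np.ndarray, quantile: float = 0.025) -> SurfaceRangeEnvelope:
    """Fit the surface range envelope directly on presence climate values."""
    return SurfaceRangeEnvelope(quantile).fit(X_presence)


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class SingleFit:
    """One fitted technique run with its held-out evaluation."""

    technique: str
    pa_replicate: int
    split_replicate: int
    estimator: object
    tss: float
    sensitivity: float
    specificity: float
    threshold: float
    degenerate: bool = False

    def predict_suitability(self, X):
        return self.estimator.predict_suitability(X)


def build_ensemble(
    fits: list[SingleFit], cutoff: float = 0.7, min_members: int = 3
) -> tuple[list[SingleFit], np.ndarray]:
    """Select members with TSS strictly above ``cutoff`` and return
    (members, TSS-proportional weights summing to 1)."""
    members = [f for f in fits if f.tss > cutoff]
    if len(members) < min_members:
        raise NotEnsembleableError(
            f"only {len(members)} single models with TSS > {cutoff}; "
            f"need at least {min_members}"
        )
    t = np.array([f.tss for f in members], dtype=float)
    return members, t / t.sum()


def variable_importance(
    predict, X: np.ndarray, n_perm: int = 5, seed: int = 0
) -> np.ndarray:
    """Permutation importance: 1 - Pearson correlation between
    predictions on the original matrix and on the matrix with one
    column permuted, averaged over ``n_perm`` permutations and clipped
    to [0, 1].  Constant predictions score 0 everywhere."""
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    X = np.asarray(X, dtype=float)
    base = np.asarray(predict(X), dtype=float)
    if np.std(base) == 0:
        return np.zeros(X.shape[1])
    rng = np.random.default_rng(seed)
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        acc = 0.0
        for _ in range(n_perm):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            pred = np.asarray(predict(Xp), dtype=float)
            if np.std(pred) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(base, pred)[0, 1])
            acc += 1.0 - r
        scores[j] = acc / n_perm
    return np.clip(scores, 0.0, 1.0)


def count_model_runs(
    n_species: int, n_techniques: int = 8, pa_replicates: int = 2, split_repeats: int = 2
) -> int:
    """Total model runs for a study: per species, one run per
    (technique x pseudo-absence replicate x split) plus one ensemble."""
    return n_species * (n_techniques * pa_replicates * split_repeats + 1)


# ---------------------------------------------------------------------------
# statsmodels-style model / results


class ClimateNicheModel:
    """Ensemble niche model for one species on a climate grid.

    Parameters
    ----------
    presence_cells
        Flat indices of grid cells holding occurrence records (after QC).
    grid
        The training-scenario (recent) :class:`ClimateGrid`.
    techniques
        Names from the technique registry; default ``("GLM", "RF", "SRE")``.
    n_pseudo_absences, pa_replicates
        Background-sample size and number of replicates.
    holdout, split_repeats
        Evaluation-split fraction and number of splits per replicate.
    tss_cutoff
        Minimum single-model TSS for ensemble membership (strict).
    sre_quantile
        Envelope quantile for the SRE technique.
    """

    def __init__(
        self,
        presence_cells: np.ndarray,
        grid: ClimateGrid,
        species_id: str = "species",
        techniques: tuple[str, ...] = DEFAULT_TECHNIQUES,
        n_pseudo_absences: int = 2000,
        pa_replicates: int = 2,
        holdout: float = 0.30,
        split_repeats: int = 2,
        tss_cutoff: float = 0.7,
        min_members: int = 3,
        sre_quantile: float = 0.025,
    ):
        self.presence_cells = np.unique(np.asarray(presence_cells))
        if self.presence_cells.size < 10:
            raise ValueError("need at least 10 unique presence cells")
        unknown = set(techniques) - set(TECHNIQUES)
        if unknown:
            raise KeyError(f"unknown techniques: {sorted(unknown)}")
        self.grid = grid
        self.species_id = species_id
        self.techniques = tuple(techniques)
        self.n_pseudo_absences = n_pseudo_absences
        self.pa_replicates = pa_replicates
        self.holdout = holdout
        self.split_repeats = split_repeats
        self.tss_cutoff = tss_cutoff
        self.min_members = min_members
        self.sre_quantile = sre_quantile

    @classmethod
    def from_dataframe(
        cls, occurrences: pd.DataFrame, grid: ClimateGrid, species: str | None = None, **kw
    ) -> "ClimateNicheModel":
        """Build from a QC'd occurrence DataFrame (columns species, x, y)."""
        df = occurrences
        if species is not None:
            df = df[df["species"] == species]
        elif df["species"].nunique() == 1:
            species = df["species"].iloc[0]
        else:
            raise ValueError("occurrence table holds several species; pass species=")
        inside = grid.in_extent(df["x"].to_numpy(), df["y"].to_numpy())
        df = df[inside]
        cells = grid.cell_index(df["x"].to_numpy(), df["y"].to_numpy())
        return cls(cells, grid, species_id=species, **kw)

    def fit(self, seed: int = 0, n_perm: int = 3) -> "NicheEnsembleResults":
        """Fit all single-model runs, build the ensemble, evaluate it on
        pooled held-out data, and compute variable importance."""
        ss = np.random.SeedSequence(seed)
        pa_seed, split_seed, fit_seed, perm_seed = [
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
        ]

        pa_sets = generate_pseudo_absences(
            self.grid,
            self.presence_cells,
            n=self.n_pseudo_absences,
            replicates=self.pa_replicates,
            seed=pa_seed,
        )
        Xp = self.grid.feature_matrix(self.presence_cells)

        fits: list[SingleFit] = []
        pooled_scores: dict[tuple[str, int, int], tuple[np.ndarray, np.ndarray]] = {}
        for pa_id, pa_cells in enumerate(pa_sets, start=1):
            Xa = self.grid.feature_matrix(pa_cells)
            splits = make_eval_splits(
                len(self.presence_cells),
                len(pa_cells),
                holdout=self.holdout,
                repeats=self.split_repeats,
                seed=split_seed + pa_id,
            )
            for split_id, sp in enumerate(splits, start=1):
                X_train = np.vstack([Xp[sp["train_p"]], Xa[sp["train_a"]]])
                y_train = np.concatenate(
                    [np.ones(len(sp["train_p"])), np.zeros(len(sp["train_a"]))]
                )
                X_test = np.vstack([Xp[sp["test_p"]], Xa[sp["test_a"]]])
                y_test = np.concatenate(
                    [np.ones(len(sp["test_p"])), np.zeros(len(sp["test_a"]))]
                )
                for tech in self.techniques:
                    if tech == "SRE":
                        est = fit_single_model(
                            tech, X_train, y_train, seed=fit_seed, q=self.sre_quantile
                        )
                    else:
                        est = fit_single_model(tech, X_train, y_train, seed=fit_seed)
                    ev = evaluate_tss(est.predict_suitability(X_test), y_test)
                    fits.append(
                        SingleFit(
                            technique=tech,
                            pa_replicate=pa_id,
                            split_replicate=split_id,
                            estimator=est,
                            tss=ev["tss"],
                            sensitivity=ev["sensitivity"],
                            specificity=ev["specificity"],
                            threshold=ev["threshold"],
                            degenerate=ev["degenerate"],
                        )
                    )
                pooled_scores[(pa_id, split_id)] = (X_test, y_test)

        members, weights = build_ensemble(
            fits, cutoff=self.tss_cutoff, min_members=self.min_members
        )

        def ensemble_predict(X):
            return np.sum(
                [w * m.predict_suitability(X) for m, w in zip(members, weights)],
                axis=0,
            )

        # pooled held-out evaluation across all runs
        X_all = np.vstack([v[0] for v in pooled_scores.values()])
        y_all = np.concatenate([v[1] for v in pooled_scores.values()])
        ens_eval = evaluate_tss(ensemble_predict(X_all), y_all)

        X_imp = np.vstack([Xp, self.grid.feature_matrix(pa_sets[0])])
        importance = variable_importance(
            ensemble_predict, X_imp, n_perm=n_perm, seed=perm_seed
        )

        return NicheEnsembleResults(
            model=self,
            fits=fits,
            members=members,
            weights=weights,
            ensemble_eval=ens_eval,
            variable_importance=pd.Series(importance, index=list(CLIMATE_VARIABLES)),
            seed=seed,
        )


@dataclass
class NicheEnsembleResults:
    """Fitted ensemble: members, weights, evaluation, importance."""

    model: ClimateNicheModel
    fits: list[SingleFit]
    members: list[SingleFit]
    weights: np.ndarray
    ensemble_eval: dict
    variable_importance: pd.Series
    seed: int = 0

    @property
    def species_id(self) -> str:
        return self.model.species_id

    @property
    def threshold(self) -> float:
        """Binarization threshold from the recent-scenario evaluation."""
        return self.ensemble_eval["threshold"]

    @property
    def tss(self) -> float:
        return self.ensemble_eval["tss"]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Weighted-mean ensemble suitability for a feature matrix."""
        return np.sum(
            [w * m.predict_suitability(X) for m, w in zip(self.members, self.weights)],
            axis=0,
        )

    def fits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "technique": [f.technique for f in self.fits],
                "pa_replicate": [f.pa_replicate for f in self.fits],
                "split_replicate": [f.split_replicate for f in self.fits],
                "tss": [f.tss for f in self.fits],
                "sensitivity": [f.sensitivity for f in self.fits],
                "specificity": [f.specificity for f in self.fits],
                "threshold": [f.threshold for f in self.fits],
                "included": [f.tss > self.model.tss_cutoff for f in self.fits],
            }
        )

    def project(self, grid: ClimateGrid):
        """Project the ensemble onto a scenario grid (continuous map)."""
        from .projection import project

        return project(self, grid)

    def binary_map(self, grid: ClimateGrid, threshold: float | None = None):
        """Project and binarize at the recent-scenario threshold."""
        from .projection import binarize, project

        return binarize(project(self, grid), threshold or self.threshold)

    def summary(self) -> str:
        df = self.fits_frame()
        lines = [
            f"Climate-niche ensemble: {self.species_id}",
            f"  presences: {len(self.model.presence_cells)}  "
            f"pseudo-absences: {self.model.n_pseudo_absences} x {self.model.pa_replicates}",
            f"  single models: {len(self.fits)} "
            f"({len(self.members)} in ensemble, TSS > {self.model.tss_cutoff})",
            f"  ensemble TSS {self.tss:.3f}  "
            f"sens {self.ensemble_eval['sensitivity']:.3f}  "
            f"spec {self.ensemble_eval['specificity']:.3f}  "
            f"threshold {self.threshold:.3f}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            "  top variables: "
            + ", ".join(
                f"{v} ({s:.2f})"
                for v, s in self.variable_importance.nlargest(3).items()
            ),
        ]
        return "\n".join(lines)
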