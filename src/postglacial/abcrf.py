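"""ABC with random forests: reference tables, model choice, estimation.

Model choice follows the ABC-RF algorithm: a classification forest is
trained on the simulated summary statistics (augmented with linear
discriminant axes), the scenario with the majority of tree votes at the
observed point is selected, and its posterior probability is obtained by
regressing the out-of-bag correct-classification indicator on the same
features and evaluating that regression forest at the observed point.  The
global (prior) error is the out-of-bag misclassification rate.

Parameter estimation uses quantile regression forests: out-of-bag leaf
co-occurrence weights at the observed point define a weighted empirical
posterior from which the median and 95% credible interval are read off.

Event-time estimates are converted from generations to calendar years with
a fixed generation time (default 7 years).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .coalsim import simulate_dataset, summarize, summary_names
from .scenarios import DemographicScenario, check_valid, sample_parameters

DEFAULT_N_TREES = 500


# --------------------------------------------------------------------------
# reference table
# --------------------------------------------------------------------------


@dataclass
class ReferenceTable:
    """Per-simulation rows of (scenario id, parameter draw, summary vector)."""

    scenario_ids: np.ndarray  # str, length n_rows
    params: pd.DataFrame  # n_rows x parameters (NaN where not in scenario)
    features: np.ndarray  # n_rows x n_features (stats + mask columns)
    feature_names: list[str]
    pop_order: list[str]
    seed: int | None = None
    L: int | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def scenarios(self) -> list[str]:
        return list(dict.fromkeys(self.scenario_ids))

    def counts(self) -> pd.Series:
        return pd.Series(self.scenario_ids).value_counts()

    def restrict(self, scenario_id: str) -> "ReferenceTable":
        idx = np.where(self.scenario_ids == scenario_id)[0]
        return ReferenceTable(
            scenario_ids=self.scenario_ids[idx],
            params=self.params.iloc[idx].reset_index(drop=True),
            features=self.features[idx],
            feature_names=self.feature_names,
            pop_order=self.pop_order,
            seed=self.seed,
            L=self.L,
            provenance=dict(self.provenance),
        )

    def save(self, path_prefix: str) -> None:
        """Persist as TSV (rows) + JSON sidecar (provenance)."""
        df = pd.DataFrame(self.features, columns=self.feature_names)
        for col in self.params.columns[::-1]:
            df.insert(0, f"param:{col}", self.params[col].to_numpy())
        df.insert(0, "scenario", self.scenario_ids)
        df.to_csv(f"{path_prefix}.tsv", sep="\t", index=False)
        sidecar = {
            "feature_names": self.feature_names,
            "pop_order": self.pop_order,
            "seed": self.seed,
            "L": self.L,
            "provenance": self.provenance,
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @staticmethod
    def load(path_prefix: str) -> "ReferenceTable":
        df = pd.read_csv(f"{path_prefix}.tsv", sep="\t", dtype={"scenario": str})
        with open(f"{path_prefix}.json") as fh:
            sidecar = json.load(fh)
        param_cols = [c for c in df.columns if c.startswith("param:")]
        return ReferenceTable(
            scenario_ids=df["scenario"].to_numpy(),
            params=df[param_cols].rename(columns=lambda c: c[len("param:"):]),
            features=df[sidecar["feature_names"]].to_numpy(dtype=float),
            feature_names=sidecar["feature_names"],
            pop_order=sidecar["pop_order"],
            seed=sidecar["seed"],
            L=sidecar["L"],
            provenance=sidecar.get("provenance", {}),
        )


def _row_rng(seed: int, scenario_index: int, row_index: int) -> np.random.Generator:
    """Per-row generator so tables are worker-count independent."""
    return np.random.default_rng(np.random.SeedSequence([seed, scenario_index, row_index]))


def _simulate_row(scenario: DemographicScenario, L: int, pop_order, seed, si, ri):
    rng = _row_rng(seed, si, ri)
    draw = sample_parameters(scenario, rng)
    aln = simulate_dataset(scenario, draw, L, rng)
    sv = summarize(aln, pop_order)
    return draw, sv


def build_reference_table(
    model_set: list[DemographicScenario],
    n_per_scenario: int,
    L: int,
    seed: int = 0,
    workers: int = 1,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` datasets per scenario and summarise them.

    Rows are seeded individually from (seed, scenario index, row index), so
    the table is identical for any worker count.
    """
    if not model_set:
        raise ValueError("empty model set")
    for sc in model_set:
        check_valid(sc)
    pop_order = model_set[0].pop_labels
    for sc in model_set[1:]:
        if sc.pop_labels != pop_order:
            raise ValueError(
                "scenarios in a model set must share the same population groups"
            )
    names = None
    tasks = [
        (si, ri) for si in range(len(model_set)) for ri in range(n_per_scenario)
    ]
    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers)(
            delayed(_simulate_row)(model_set[si], L, pop_order, seed, si, ri)
            for si, ri in tasks
        )
    else:
        results = [
            _simulate_row(model_set[si], L, pop_order, seed, si, ri) for si, ri in tasks
        ]

    scen_ids = []
    param_rows = []
    feats = []
    for (si, ri), (draw, sv) in zip(tasks, results):
        scen_ids.append(model_set[si].id)
        param_rows.append(draw.values)
        if names is None:
            names = sv.feature_names()
        feats.append(sv.to_features())
    return ReferenceTable(
        scenario_ids=np.array(scen_ids),
        params=pd.DataFrame(param_rows),
        features=np.array(feats),
        feature_names=names,
        pop_order=pop_order,
        seed=seed,
        L=L,
        provenance={"n_per_scenario": n_per_scenario,
                    "scenarios": [sc.id for sc in model_set]},
    )


# --------------------------------------------------------------------------
# prior predictive check
# --------------------------------------------------------------------------


def prior_predictive_pca(
    table: ReferenceTable,
    observed,
    n_per_scenario_display: int = 1000,
    seed: int = 0,
) -> dict:
    """Project simulations and the observed vector on the first two PCA axes
    and report, per scenario, whether the observed point lies inside the
    scenario cloud (convex hull and 1st-99th percentile box)."""
    obs = observed.to_features() if hasattr(observed, "to_features") else np.asarray(observed)
    X = table.features
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [n for n, k in zip(table.feature_names, keep) if not k]
        # constant columns carry no information for the projection
    X = X[:, keep]
    obs_k = obs[keep]
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xs = (X - mu) / sd
    pca = PCA(n_components=2, random_state=seed)
    sim2 = pca.fit_transform(Xs)
    obs2 = pca.transform(((obs_k - mu) / sd).reshape(1, -1))[0]

    rng = np.random.default_rng(seed)
    report = {"observed": obs2.tolist(), "scenarios": {},
              "dropped_constant": [n for n, k in zip(table.feature_names, keep) if not k]}
    for sc in table.scenarios:
        idx = np.where(table.scenario_ids == sc)[0]
        if idx.size > n_per_scenario_display:
            idx = rng.choice(idx, size=n_per_scenario_display, replace=False)
        cloud = sim2[idx]
        lo, hi = np.percentile(cloud, [1, 99], axis=0)
        in_box = bool(np.all(obs2 >= lo) and np.all(obs2 <= hi))
        try:
            tri = Delaunay(cloud)
            in_hull = bool(tri.find_simplex(obs2) >= 0)
        except QhullError:
            in_hull = False
        report["scenarios"][sc] = {
            "inside_hull": in_hull,
            "inside_percentile_box": in_box,
            "n_displayed": int(idx.size),
            "cloud": cloud,
        }
    report["explained_variance_pct"] = (100 * pca.explained_variance_ratio_).tolist()
    return report


# --------------------------------------------------------------------------
# model choice
# --------------------------------------------------------------------------


@dataclass
class ModelChoiceResult:
    selected: str
    votes: pd.Series  # vote fraction per scenario (sums to 1)
    posterior_probability: float
    global_error: float
    local_error: float
    lda_observed: np.ndarray | None = None
    lda_simulated: np.ndarray | None = None
    lda_labels: np.ndarray | None = None
    n_trees: int = DEFAULT_N_TREES
    seed: int | None = None


class ScenarioClassifier:
    """ABC-RF scenario classifier, fitted once and applied to many points.

    A classification forest is trained on the simulated summary statistics
    (optionally augmented with LDA axes); the posterior-probability
    regressor is trained on the out-of-bag correct-classification
    indicator.  ``classify`` then evaluates any observed summary vector.
    """

    def __init__(self, n_trees: int = DEFAULT_N_TREES, seed: int = 0,
                 lda_axes: bool = True):
        self.n_trees = n_trees
        self.seed = seed
        self.lda_axes = lda_axes
        self._fitted = False

    def fit(self, table: ReferenceTable) -> "ScenarioClassifier":
        scenarios = table.scenarios
        if len(scenarios) < 2:
            raise ValueError("model choice requires >= 2 scenarios")
        counts = table.counts()
        empty = [s for s in scenarios if counts.get(s, 0) == 0]
        if empty:
            raise ValueError(f"scenarios without rows: {empty}")

        X = table.features
        y = table.scenario_ids
        self.scenarios_ = scenarios
        self.lda_ = None
        if self.lda_axes and len(scenarios) >= 2:
            self.lda_ = LinearDiscriminantAnalysis(
                n_components=min(len(scenarios) - 1, X.shape[1])
            )
            sim_proj = self.lda_.fit_transform(X, y)
            X = np.hstack([X, sim_proj])
            self.lda_simulated_ = sim_proj
        else:
            self.lda_simulated_ = None
        self.lda_labels_ = y

        self.clf_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.seed, oob_score=True, n_jobs=1
        )
        self.clf_.fit(X, y)

        oob_pred = self.clf_.classes_[np.argmax(self.clf_.oob_decision_function_, axis=1)]
        ok = np.all(np.isfinite(self.clf_.oob_decision_function_), axis=1)
        correct = (oob_pred == y).astype(float)
        self.global_error_ = float(1.0 - correct[ok].mean())

        self.reg_ = RandomForestRegressor(
            n_estimators=self.n_trees, random_state=self.seed + 1, n_jobs=1
        )
        self.reg_.fit(X[ok], correct[ok])
        self._fitted = True
        return self

    def _rows(self, observed_list) -> np.ndarray:
        rows = np.vstack([
            o.to_features() if hasattr(o, "to_features") else np.asarray(o)
            for o in observed_list
        ])
        if self.lda_ is not None:
            rows = np.hstack([rows, self.lda_.transform(rows)])
        return rows

    def vote_fractions(self, observed_list) -> pd.DataFrame:
        """Per-tree majority-vote fractions for each observed vector."""
        rows = self._rows(observed_list)
        votes = np.zeros((rows.shape[0], len(self.scenarios_)))
        index = {s: i for i, s in enumerate(self.clf_.classes_)}
        col = [index[s] for s in self.scenarios_]
        for t in self.clf_.estimators_:
            pred = t.predict(rows).astype(int)
            for r, p in enumerate(pred):
                votes[r, p] += 1
        votes /= len(self.clf_.estimators_)
        return pd.DataFrame(votes[:, col], columns=self.scenarios_)

    def classify(self, observed) -> ModelChoiceResult:
        if not self._fitted:
            raise RuntimeError("call fit() first")
        votes = self.vote_fractions([observed]).iloc[0]
        selected = votes.idxmax()
        rows = self._rows([observed])
        posterior = float(np.clip(self.reg_.predict(rows)[0], 0.0, 1.0))
        lda_obs = self.lda_.transform(
            (observed.to_features() if hasattr(observed, "to_features")
             else np.asarray(observed)).reshape(1, -1)
        )[0] if self.lda_ is not None else None
        return ModelChoiceResult(
            selected=selected,
            votes=votes,
            posterior_probability=posterior,
            global_error=self.global_error_,
            local_error=1.0 - posterior,
            lda_observed=lda_obs,
            lda_simulated=self.lda_simulated_,
            lda_labels=self.lda_labels_,
            n_trees=self.n_trees,
            seed=self.seed,
        )

    def select_many(self, observed_list) -> list[str]:
        """Majority-vote selections for a batch of observed vectors."""
        vf = self.vote_fractions(observed_list)
        return vf.idxmax(axis=1).tolist()


def rf_model_choice(
    table: ReferenceTable,
    observed,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    lda_axes: bool = True,
) -> ModelChoiceResult:
    """Random-forest scenario choice with posterior probability.

    Selected scenario = majority of tree votes at the observed point.
    Posterior probability = out-of-bag regression of the correct-
    classification indicator, evaluated at the observed point.  Global
    error = out-of-bag misclassification rate; local error = 1 - posterior.
    """
    return ScenarioClassifier(n_trees=n_trees, seed=seed, lda_axes=lda_axes).fit(
        table
    ).classify(observed)


# --------------------------------------------------------------------------
# parameter estimation (quantile regression forest)
# --------------------------------------------------------------------------


@dataclass
class ParameterPosterior:
    parameter: str
    median: float
    ci_low: float
    ci_high: float
    global_nmae: float
    local_error: float
    weights: np.ndarray | None = None
    n_trees: int = DEFAULT_N_TREES
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.median <= self.ci_high):
            raise ValueError("credible interval must bracket the median")


def weighted_quantile(values: np.ndarray, weights: np.ndarray, qs) -> np.ndarray:
    """Quantiles of a weighted empirical distribution."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return np.interp(np.atleast_1d(qs), cw, v)


class ParameterEstimator:
    """Quantile-regression-forest posterior for one parameter.

    Fit once on a single-scenario reference table; ``estimate`` then gives
    the posterior for any observed summary vector.  Leaf co-occurrence with
    the observed point defines weights over the training draws; the
    weighted 2.5/50/97.5% quantiles give the point estimate and 95%
    credible interval.  Global accuracy is the out-of-bag normalised mean
    absolute error; local accuracy reweights the out-of-bag absolute errors
    by the posterior weights.
    """

    def __init__(self, parameter: str, n_trees: int = DEFAULT_N_TREES, seed: int = 0,
                 min_samples_leaf: int = 5):
        self.parameter = parameter
        self.n_trees = n_trees
        self.seed = seed
        self.min_samples_leaf = min_samples_leaf
        self._fitted = False

    def fit(self, table: ReferenceTable) -> "ParameterEstimator":
        if len(table.scenarios) != 1:
            raise ValueError("parameter estimation expects a single-scenario table")
        if self.parameter not in table.params.columns:
            raise KeyError(f"parameter {self.parameter!r} not in table")
        y = table.params[self.parameter].to_numpy(dtype=float)
        X = table.features
        self.y_ = y
        self.constant_ = bool(np.allclose(y, y[0]))
        if self.constant_:
            self._fitted = True
            return self
        self.reg_ = RandomForestRegressor(
            n_estimators=self.n_trees, random_state=self.seed,
            min_samples_leaf=self.min_samples_leaf, oob_score=True, n_jobs=1,
        )
        self.reg_.fit(X, y)
        self.train_leaves_ = self.reg_.apply(X)  # (n, n_trees)
        self.abs_err_ = np.abs(self.reg_.oob_prediction_ - y)
        mean_abs = float(np.mean(np.abs(y)))
        self.scale_ = mean_abs if mean_abs > 0 else float(y.max() - y.min())
        self._fitted = True
        return self

    def estimate(self, observed) -> ParameterPosterior:
        if not self._fitted:
            raise RuntimeError("call fit() first")
        if self.constant_:
            v = float(self.y_[0])
            return ParameterPosterior(self.parameter, v, v, v, 0.0, 0.0, None,
                                      self.n_trees, self.seed)
        obs = observed.to_features() if hasattr(observed, "to_features") else np.asarray(observed)
        obs_leaves = self.reg_.apply(obs.reshape(1, -1))[0]  # (n_trees,)
        same = self.train_leaves_ == obs_leaves[None, :]
        leaf_sizes = same.sum(axis=0).astype(float)
        leaf_sizes[leaf_sizes == 0] = np.inf
        weights = (same / leaf_sizes[None, :]).mean(axis=1)
        weights /= weights.sum()

        lo, med, hi = weighted_quantile(self.y_, weights, [0.025, 0.5, 0.975])
        global_nmae = float(self.abs_err_.mean() / self.scale_)
        local_error = float(np.sum(weights * self.abs_err_) / self.scale_)
        med = float(np.clip(med, lo, hi))
        return ParameterPosterior(self.parameter, med, float(lo), float(hi),
                                  global_nmae, local_error, weights,
                                  self.n_trees, self.seed)


def rf_estimate_parameter(
    table: ReferenceTable,
    observed,
    parameter: str,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    min_samples_leaf: int = 5,
) -> ParameterPosterior:
    """One-shot quantile-regression-forest posterior (see ParameterEstimator)."""
    return ParameterEstimator(
        parameter, n_trees=n_trees, seed=seed, min_samples_leaf=min_samples_leaf
    ).fit(table).estimate(observed)


# --------------------------------------------------------------------------
# diagnostic plots
# --------------------------------------------------------------------------


def plot_predictive_pca(report: dict, ax=None):
    """Scatter the per-scenario PCA clouds with the observed point marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for sid, rep in report["scenarios"].items():
        cloud = rep["cloud"]
        ax.scatter(cloud[:, 0], cloud[:, 1], s=6, alpha=0.4, label=sid)
    obs = report["observed"]
    ax.scatter([obs[0]], [obs[1]], marker="*", s=160, c="k", label="observed")
    ev = report["explained_variance_pct"]
    ax.set_xlabel(f"PC1 ({ev[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({ev[1]:.1f}%)")
    ax.legend(fontsize=8)
    return ax


def plot_model_choice(result: ModelChoiceResult, axes=None):
    """Vote-fraction bars plus the LDA projection of simulations + observed."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 4))
    ax_votes, ax_lda = axes
    result.votes.plot.bar(ax=ax_votes, color="steelblue")
    ax_votes.set_ylabel("vote fraction")
    ax_votes.set_ylim(0, 1)
    ax_votes.axhline(result.posterior_probability, ls="--", c="k", lw=0.8)
    if result.lda_simulated is not None:
        proj = result.lda_simulated
        if proj.shape[1] == 1:
            proj = np.hstack([proj, np.zeros_like(proj)])
        for sid in pd.unique(result.lda_labels):
            sel = result.lda_labels == sid
            ax_lda.scatter(proj[sel, 0], proj[sel, 1], s=6, alpha=0.4, label=sid)
        obs = result.lda_observed
        ox, oy = (obs[0], obs[1] if obs.size > 1 else 0.0)
        ax_lda.scatter([ox], [oy], marker="*", s=160, c="k", label="observed")
        ax_lda.set_xlabel("LD1")
        ax_lda.set_ylabel("LD2")
        ax_lda.legend(fontsize=8)
    return axes


# --------------------------------------------------------------------------
# time conversion
# --------------------------------------------------------------------------


@dataclass
class TimeEstimate:
    """An event-time estimate in generations and calendar years."""

    generations: float
    ci_low_gen: float
    ci_high_gen: float
    generation_time: float = 7.0

    @property
    def years(self) -> float:
        return self.generations * self.generation_time

    @property
    def ci_years(self) -> tuple[float, float]:
        return (self.ci_low_gen * self.generation_time,
                self.ci_high_gen * self.generation_time)

    @property
    def ka(self) -> float:
        return self.years / 1000.0

    @property
    def ci_ka(self) -> tuple[float, float]:
        lo, hi = self.ci_years
        return lo / 1000.0, hi / 1000.0

    def rounded_ka(self, decimals: int = 1) -> tuple[float, float, float]:
        lo, hi = self.ci_ka
        return (round(self.ka, decimals), round(lo, decimals), round(hi, decimals))


def generations_to_years(
    estimate: ParameterPosterior | float,
    generation_time: float = 7.0,
    ci: tuple[float, float] | None = None,
) -> TimeEstimate:
    """Convert a time estimate from generations to calendar years (x 7 by
    default)."""
    if generation_time <= 0:
        raise ValueError("generation_time must be > 0")
    if isinstance(estimate, ParameterPosterior):
        return TimeEstimate(estimate.median, estimate.ci_low, estimate.ci_high,
                            generation_time)
    lo, hi = ci if ci is not None else (float(estimate), float(estimate))
    return TimeEstimate(float(estimate), lo, hi, generation_time)
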