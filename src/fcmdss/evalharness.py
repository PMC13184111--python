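"""Repeated stratified evaluation protocol, tuning, and robustness suites.

The protocol mirrors standard clinical-benchmark practice: each repeat draws
a stratified 60:20:20 train/validation/test split, fits all preprocessing on
the training partition only, tunes hyperparameters on validation, selects
the FCM classification threshold on validation, and reports test metrics;
results aggregate as mean +/- sd over repeats.  Baseline classifiers enter
through the thin :class:`ClassifierContract` adapter so FCM variants and
scikit-learn models share one pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from fcmdss.fcm_core import (
    ConceptGraph,
    ReasoningConfig,
    classify,
    inner_step_cost,
)
from fcmdss.fuzzify import (
    FeatureSpec,
    build_initial_graph,
    fuzzify_apply,
    fuzzify_fit,
)
from fcmdss.learning import (
    ExpertFeedback,
    LearningConfig,
    TrainResult,
    predict_batch,
    train,
)
from fcmdss.metrics import (
    DEFAULT_TAU_GRID,
    MetricsReport,
    adaptation_speed,
    auroc,
    confusion_metrics,
    i_struct,
    select_threshold,
    stability_indicator,
)
from fcmdss.synthdata import impose_imbalance, inject_missing


@dataclass
class SplitPlan:
    """Stratified train/validation/test ratios and the repeat schedule.

    Repeat ``i`` derives its random stream from ``base_seed + i``.
    """

    ratios: tuple[float, float, float] = (0.60, 0.20, 0.20)
    repeats: int = 20
    base_seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {self.ratios}")
        if self.repeats < 1:
            raise ValueError(f"repeats must be >= 1, got {self.repeats}")


@dataclass
class GridSpec:
    """Named hyperparameter grid: a list of parameter dictionaries."""

    points: list[dict]
    selection_metric: str = "f1"

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("hyperparameter grid must be non-empty")


#: Benchmark tuning grid for the FCM model (step size, penalty, expert share).
HCFDSS_GRID = GridSpec(
    points=[
        {"eta": eta, "beta": beta, "alpha": alpha}
        for eta in (0.001, 0.005, 0.01)
        for beta in (1e-4, 1e-3, 1e-2)
        for alpha in (0.1, 0.3, 0.5)
    ]
)

#: Expert-share values exercised by the sensitivity analysis.
ALPHA_GRID = (0.0, 0.1, 0.3, 0.5, 0.7, 0.9)


def stratified_split(
    y: Sequence[int], plan: SplitPlan, repeat_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/val/test index sets preserving class
    proportions (largest-remainder allocation per class); deterministic in
    ``(base_seed, repeat_index)``."""
    y = np.asarray(list(y), dtype=int)
    rng = np.random.default_rng(plan.base_seed + repeat_index)
    parts: list[list[int]] = [[], [], []]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 3:
            raise ValueError(
                f"class {cls} has only {len(idx)} members; cannot stratify 3 ways"
            )
        idx = rng.permutation(idx)
        n = len(idx)
        ideal = np.array(plan.ratios) * n
        counts = np.floor(ideal).astype(int)
        rem = ideal - counts
        for _ in range(n - counts.sum()):
            j = int(np.argmax(rem))
            counts[j] += 1
            rem[j] = -1.0
        start = 0
        for part, c in zip(parts, counts):
            part.extend(idx[start : start + c].tolist())
            start += c
    return tuple(np.sort(np.array(p, dtype=int)) for p in parts)


# --------------------------------------------------------------------------
# Classifier contracts


class ClassifierContract:
    """Minimal shared surface: fit on raw training rows, score in [0, 1].

    ``select_tau`` marks models whose operating threshold is chosen on the
    validation grid (the FCM variants); others classify at 0.5.
    """

    name: str = "contract"
    select_tau: bool = False

    def with_params(self, params: Mapping) -> "ClassifierContract":
        raise NotImplementedError

    def fit(self, X: pd.DataFrame, y: Sequence[int], seed: int = 0) -> "ClassifierContract":
        raise NotImplementedError

    def score(self, X: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError


class SklearnContract(ClassifierContract):
    """Thin adapter around a scikit-learn estimator factory.

    Preprocessing (training-median imputation and standardization) is fitted
    inside ``fit`` so nothing leaks across partitions.
    """

    def __init__(self, name: str, factory: Callable[..., object], params: dict | None = None):
        self.name = name
        self.factory = factory
        self.params = dict(params or {})
        self._pipe = None

    def with_params(self, params: Mapping) -> "SklearnContract":
        merged = {**self.params, **params}
        return SklearnContract(self.name, self.factory, merged)

    def fit(self, X: pd.DataFrame, y: Sequence[int], seed: int = 0) -> "SklearnContract":
        from sklearn.impute import SimpleImputer
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler

        est = self.factory(**self.params)
        if "random_state" in est.get_params():
            est.set_params(random_state=seed)
        self._pipe = Pipeline(
            [
                ("impute", SimpleImputer(strategy="median")),
                ("scale", StandardScaler()),
                ("model", est),
            ]
        )
        self._pipe.fit(X.to_numpy(dtype=float), np.asarray(list(y), dtype=int))
        return self

    def score(self, X: pd.DataFrame) -> np.ndarray:
        if self._pipe is None:
            raise RuntimeError("fit must be called before score")
        return self._pipe.predict_proba(X.to_numpy(dtype=float))[:, 1]


class FCMContract(ClassifierContract):
    """FCM classifier behind the shared contract.

    ``variant`` selects between the three graph-based models:

    * ``"fixed"`` — expert prior used as-is, no learning;
    * ``"hcfdss"`` — projected-gradient learning with expert blending toward
      the initial prior (``alpha = 0`` reduces to the purely data-driven
      learned FCM).
    """

    select_tau = True

    def __init__(
        self,
        specs: Sequence[FeatureSpec],
        variant: str = "hcfdss",
        eta: float = 0.01,
        beta: float = 1e-3,
        alpha: float = 0.3,
        steepness: float = 1.0,
        max_outer: int = 150,
        cost_weights: tuple[float, float] = (1.0, 1.0),
        cost_sensitive: bool = False,
        name: str | None = None,
    ):
        if variant not in ("fixed", "hcfdss"):
            raise ValueError(f"unknown FCM variant {variant!r}")
        self.specs = list(specs)
        self.variant = variant
        self.eta = eta
        self.beta = beta
        self.alpha = alpha
        self.steepness = steepness
        self.max_outer = max_outer
        self.cost_weights = tuple(cost_weights)
        self.cost_sensitive = cost_sensitive
        self.name = name or (
            "fcm_fixed" if variant == "fixed" else f"hcfdss(alpha={alpha})"
        )
        self.model = None
        self.prior: ConceptGraph | None = None
        self.result: TrainResult | None = None
        self.graph: ConceptGraph | None = None

    def with_params(self, params: Mapping) -> "FCMContract":
        kwargs = dict(
            specs=self.specs,
            variant=self.variant,
            eta=self.eta,
            beta=self.beta,
            alpha=self.alpha,
            steepness=self.steepness,
            max_outer=self.max_outer,
            cost_weights=self.cost_weights,
            cost_sensitive=self.cost_sensitive,
            name=self.name,
        )
        kwargs.update(params)
        return FCMContract(**kwargs)

    def _rconfig(self) -> ReasoningConfig:
        return ReasoningConfig(steepness=self.steepness, mode="clamped")

    def fit(self, X: pd.DataFrame, y: Sequence[int], seed: int = 0) -> "FCMContract":
        self.model = fuzzify_fit(X, y, self.specs)
        fuzzed = fuzzify_apply(self.model, X, y, provenance="train")
        self.prior = build_initial_graph(fuzzed)
        if self.variant == "fixed":
            self.graph = self.prior.copy()
            self.result = None
            return self
        lconfig = LearningConfig(
            step_size=self.eta,
            reg=self.beta,
            cost_weights=self.cost_weights,
            max_outer=self.max_outer,
            seed=seed,
        )
        feedback = None
        if self.alpha > 0:
            feedback = ExpertFeedback(
                alpha=self.alpha,
                mode="reference_matrix",
                reference=self.prior.weights.copy(),
            )
        self.result = train(
            fuzzed,
            self.prior,
            lconfig,
            self._rconfig(),
            feedback=feedback,
            cost_sensitive=self.cost_sensitive,
        )
        self.graph = self.result.graph
        return self

    def score(self, X: pd.DataFrame) -> np.ndarray:
        if self.graph is None:
            raise RuntimeError("fit must be called before score")
        fuzzed = fuzzify_apply(self.model, X, provenance="score")
        return predict_batch(self.graph, fuzzed.activations, self._rconfig())


def build_default_contracts(random_state_unused: int = 0) -> dict[str, tuple[ClassifierContract, GridSpec]]:
    """Baseline classifiers with their validation grids."""
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    return {
        "logistic_regression": (
            SklearnContract("logistic_regression", LogisticRegression, {"max_iter": 2000}),
            GridSpec([
                {"C": c, "class_weight": cw}
                for c in (0.01, 0.1, 1, 10)
                for cw in (None, "balanced")
            ]),
        ),
        "svm": (
            SklearnContract("svm", SVC, {"probability": True}),
            GridSpec(
                [{"kernel": "linear", "C": c} for c in (0.1, 1, 10)]
                + [
                    {"kernel": "rbf", "C": c, "gamma": g}
                    for c in (0.1, 1, 10)
                    for g in ("scale", 0.01, 0.1, 1)
                ]
            ),
        ),
        "random_forest": (
            SklearnContract("random_forest", RandomForestClassifier),
            GridSpec([
                {"n_estimators": t, "max_depth": d}
                for t in (100, 300, 500)
                for d in (None, 3, 5, 10)
            ]),
        ),
        "gradient_boosting": (
            SklearnContract("gradient_boosting", GradientBoostingClassifier),
            GridSpec([
                {"n_estimators": t, "learning_rate": lr, "max_depth": d}
                for t in (50, 100, 200)
                for lr in (0.01, 0.05, 0.1)
                for d in (2, 3, 5)
            ]),
        ),
        "knn": (
            SklearnContract("knn", KNeighborsClassifier),
            GridSpec([
                {"n_neighbors": k, "weights": w}
                for k in (3, 5, 7, 9, 11)
                for w in ("uniform", "distance")
            ]),
        ),
        "mlp": (
            SklearnContract("mlp", MLPClassifier, {"max_iter": 800}),
            GridSpec([
                {"hidden_layer_sizes": h, "alpha": a}
                for h in ((16,), (32,), (16, 8))
                for a in (1e-4, 1e-3, 1e-2)
            ]),
        ),
    }


# --------------------------------------------------------------------------
# Tuning and the main protocol


def _evaluate(
    contract: ClassifierContract,
    y: np.ndarray,
    scores: np.ndarray,
    tau: float,
) -> MetricsReport:
    yhat = np.array([classify(min(max(v, 0.0), 1.0), tau) for v in scores])
    cm = confusion_metrics(y, yhat)
    rep = MetricsReport(**cm)
    rep.auroc = auroc(y, scores)
    return rep


def tune(
    contract: ClassifierContract,
    grid: GridSpec,
    train_data: tuple[pd.DataFrame, np.ndarray],
    val_data: tuple[pd.DataFrame, np.ndarray],
    metric: str = "f1",
    seed: int = 0,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
) -> dict:
    """Fit each grid configuration on train, score validation, return the
    argmax configuration (ties -> first in declared grid order).

    The test partition is never passed in, so tuning cannot touch it.
    """
    best_cfg, best_val = None, -math.inf
    failures: list[str] = []
    Xtr, ytr = train_data
    Xval, yval = val_data
    for cfg in grid.points:
        try:
            c = contract.with_params(cfg).fit(Xtr, ytr, seed=seed)
            scores = c.score(Xval)
            tau = select_threshold(yval, scores, tau_grid) if c.select_tau else 0.5
            yhat = np.array([classify(min(max(v, 0.0), 1.0), tau) for v in scores])
            val = confusion_metrics(yval, yhat)[metric]
        except Exception as exc:  # aggregate causes; one bad point is not fatal
            failures.append(f"{cfg}: {exc}")
            continue
        if val > best_val:
            best_cfg, best_val = cfg, val
    if best_cfg is None:
        raise RuntimeError(
            "every grid configuration failed:\n" + "\n".join(failures)
        )
    return best_cfg


def run_protocol(
    table: pd.DataFrame,
    target: str,
    contracts: Sequence[ClassifierContract],
    plan: SplitPlan,
    grids: Mapping[str, GridSpec] | None = None,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
) -> dict:
    """Repeated stratified evaluation of all contracts on one dataset.

    Per repeat: split, (optionally) tune on validation, refit on train,
    select the FCM threshold on validation, evaluate on test.  Returns, per
    contract, the per-repeat reports, their mean/sd aggregate, a per-repeat
    failure count, and — for FCM contracts — the stability indicator over
    the repeats' final weight-change norms.
    """
    y_all = table[target].to_numpy(dtype=int)
    X_all = table.drop(columns=[target])
    grids = grids or {}
    out: dict[str, dict] = {}
    for contract in contracts:
        rows: list[MetricsReport] = []
        final_deltas: list[float] = []
        failures = 0
        for r in range(plan.repeats):
            tr, va, te = stratified_split(y_all, plan, r)
            Xtr, ytr = X_all.iloc[tr], y_all[tr]
            Xva, yva = X_all.iloc[va], y_all[va]
            Xte, yte = X_all.iloc[te], y_all[te]
            try:
                if contract.name in grids:
                    best = tune(
                        contract,
                        grids[contract.name],
                        (Xtr, ytr),
                        (Xva, yva),
                        seed=plan.base_seed + r,
                        tau_grid=tau_grid,
                    )
                    c = contract.with_params(best)
                else:
                    c = contract.with_params({})  # fresh clone per repeat
                c.fit(Xtr, ytr, seed=plan.base_seed + r)
                val_scores = c.score(Xva)
                tau = (
                    select_threshold(yva, val_scores, tau_grid)
                    if c.select_tau
                    else 0.5
                )
                rep = _evaluate(c, yte, c.score(Xte), tau)
                if isinstance(c, FCMContract):
                    rep.i_struct = i_struct(c.graph, c.prior)
                    if c.result is not None:
                        rep.adaptation_speed = adaptation_speed(
                            c.result.change_norms, LearningConfig().tol
                        )
                        if c.result.change_norms:
                            final_deltas.append(c.result.change_norms[-1])
                rows.append(rep)
            except Exception:
                failures += 1
        agg = MetricsReport.aggregate(rows)
        entry = {"per_repeat": rows, "aggregate": agg, "failures": failures}
        if final_deltas:
            entry["stability_indicator"] = stability_indicator(final_deltas)
        out[contract.name] = entry
    return out


def alpha_sensitivity(
    table: pd.DataFrame,
    target: str,
    specs: Sequence[FeatureSpec],
    plan: SplitPlan,
    alphas: Sequence[float] = ALPHA_GRID,
    **fcm_kwargs,
) -> dict[float, dict]:
    """Protocol rerun per expert-share value with all else (seeds included)
    fixed.  ``alpha = 0`` is the purely data-driven learned FCM."""
    for a in alphas:
        if not (0.0 <= a < 1.0):
            raise ValueError(f"alpha must lie in [0, 1), got {a}")
    results = {}
    for a in alphas:
        contract = FCMContract(specs, variant="hcfdss", alpha=a, **fcm_kwargs)
        res = run_protocol(table, target, [contract], plan)
        results[a] = res[contract.name]
    return results


def robustness_suite(
    table: pd.DataFrame,
    target: str,
    specs: Sequence[FeatureSpec],
    plan: SplitPlan,
    missing_rates: Sequence[float] = (0.0, 0.1, 0.2, 0.3),
    imbalance_ratios: Sequence[tuple[int, int]] = ((1, 1), (1, 2), (1, 3)),
    cost_weight_pairs: Sequence[tuple[float, float]] = ((1, 1), (1, 2), (1, 3)),
    **fcm_kwargs,
) -> list[dict]:
    """Cross missingness x imbalance x cost-weight conditions.

    Missingness is injected into the feature cells before any imputation;
    imbalance downsamples positives in the training partition only; the
    cost-sensitive objective replaces the plain one whenever the weight pair
    is not (1, 1).  Balanced accuracy is reported alongside the standard
    metrics in every row.
    """
    y_all = table[target].to_numpy(dtype=int)
    rows = []
    for rate in missing_rates:
        for ratio in imbalance_ratios:
            for weights in cost_weight_pairs:
                reports = []
                for r in range(plan.repeats):
                    seed = plan.base_seed + r
                    masked = inject_missing(table, rate, seed=seed, target=target)
                    tr, va, te = stratified_split(y_all, plan, r)
                    train_rows = masked.iloc[tr]
                    try:
                        train_rows = impose_imbalance(
                            train_rows, ratio, seed=seed, target=target
                        )
                    except ValueError:
                        continue  # unreachable ratio for this split
                    contract = FCMContract(
                        specs,
                        variant="hcfdss",
                        cost_weights=tuple(float(w) for w in weights),
                        cost_sensitive=tuple(weights) != (1, 1),
                        **fcm_kwargs,
                    )
                    Xtr = train_rows.drop(columns=[target])
                    ytr = train_rows[target].to_numpy(dtype=int)
                    Xva = masked.iloc[va].drop(columns=[target])
                    yva = y_all[va]
                    Xte = masked.iloc[te].drop(columns=[target])
                    yte = y_all[te]
                    contract.fit(Xtr, ytr, seed=seed)
                    tau = select_threshold(yva, contract.score(Xva))
                    reports.append(_evaluate(contract, yte, contract.score(Xte), tau))
                rows.append(
                    {
                        "missing_rate": rate,
                        "imbalance": ratio,
                        "cost_weights": tuple(weights),
                        "aggregate": MetricsReport.aggregate(reports),
                        "n_repeats": len(reports),
                    }
                )
    return rows


def complexity_counts(
    n_values: Sequence[int] = (12, 20, 30),
    density: float = 0.20,
    seed: int = 0,
) -> dict[int, int]:
    """Per-step multiply-accumulate counts for random masked graphs of
    increasing size at fixed edge density (free mode).

    At fixed density the count scales with the number of permitted edges,
    i.e. ~quadratically in the concept count.
    """
    rng = np.random.default_rng(seed)
    counts = {}
    for n in n_values:
        mask = (rng.random((n, n)) < density).astype(float)
        mask[0, n - 1] = 1.0  # keep at least one edge
        weights = mask * rng.uniform(-0.5, 0.5, (n, n))
        graph = ConceptGraph(
            names=[f"c{i}" for i in range(n)], mask=mask, weights=weights
        )
        counts[n] = inner_step_cost(graph)
    return counts
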