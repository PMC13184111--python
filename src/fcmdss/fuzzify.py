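"""Train-only normalization, Gaussian fuzzification, and initial-graph construction.

All statistics (min/max, medians, modes, category risk rates, initial edge
weights) are functions of the **training partition only** and are then reused
unchanged on validation and test data — the pipeline never sees held-out
rows.  Numeric features are min-max normalized, imputed with the training
median, and mapped to a scalar risk activation through a Gaussian membership
bump; categorical features are encoded as rescaled smoothed positive-class
rates.  Every activation lands in ``[0, 1]`` and is oriented so that larger
values support the positive diagnostic class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from fcmdss.fcm_core import ConceptGraph

#: Default Gaussian state parameters for benchmark numeric features:
#: Low / Medium / High centers and the shared spread.
DEFAULT_CENTERS = (0.15, 0.50, 0.85)
DEFAULT_SPREAD = 0.18

#: Smoothing constant in the categorical risk-activation rescaling.
EPS0 = 1e-8

#: Floor/cap for point-biserial initial weights and the output self-memory value.
WEIGHT_FLOOR = 0.05
WEIGHT_CAP = 0.90
SELF_MEMORY_WEIGHT = 0.20


@dataclass
class MembershipFunction:
    """Gaussian linguistic state ``mu(z) = exp(-(z - c)^2 / (2 sigma^2))``."""

    center: float
    spread: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError(f"spread must be > 0, got {self.spread}")


@dataclass
class FeatureSpec:
    """Declared kind and risk orientation of one predictive feature.

    ``orientation`` must be given for numeric features: ``higher_is_risk``
    maps the normalized value through the High membership state,
    ``lower_is_risk`` through the Low state.  The orientation encodes
    clinical knowledge and cannot be inferred from the data.  Categorical
    features carry a fitted category -> activation table instead.
    """

    name: str
    kind: str = "numeric"
    orientation: str | None = "higher_is_risk"
    memberships: tuple[MembershipFunction, ...] | None = None
    category_table: dict | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"kind must be numeric or categorical, got {self.kind!r}")
        if self.kind == "numeric":
            if self.orientation not in ("higher_is_risk", "lower_is_risk"):
                raise ValueError(
                    f"numeric feature {self.name!r} needs orientation "
                    "higher_is_risk or lower_is_risk"
                )
            if self.memberships is None:
                self.memberships = default_memberships()
        else:
            self.orientation = None
        if self.category_table is not None:
            bad = {c: a for c, a in self.category_table.items() if not 0 <= a <= 1}
            if bad:
                raise ValueError(f"category activations outside [0, 1]: {bad}")


def default_memberships() -> tuple[MembershipFunction, ...]:
    return tuple(
        MembershipFunction(c, DEFAULT_SPREAD, lab)
        for c, lab in zip(DEFAULT_CENTERS, ("Low", "Medium", "High"))
    )


@dataclass
class Normalizer:
    """Per-feature min/max and imputation statistics fitted on training rows."""

    mins: dict = field(default_factory=dict)
    maxs: dict = field(default_factory=dict)
    impute: dict = field(default_factory=dict)
    kinds: dict = field(default_factory=dict)
    fitted: bool = False
    unseen_category_count: int = 0


@dataclass
class FuzzifiedDataset:
    """Concept-activation matrix with aligned binary labels."""

    activations: np.ndarray  # (n_samples, d), entries in [0, 1]
    y: np.ndarray  # (n_samples,), {0, 1}
    specs: list[FeatureSpec]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.activations = np.asarray(self.activations, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.activations.ndim != 2:
            raise ValueError("activations must be a 2-D matrix")
        if self.activations.shape[0] != self.y.shape[0]:
            raise ValueError("activation rows and labels must align")
        if self.activations.shape[1] != len(self.specs):
            raise ValueError("one activation column per feature spec required")
        if np.any((self.activations < 0) | (self.activations > 1)):
            raise ValueError("activations must lie in [0, 1]")
        if not np.all(np.isin(self.y, (0, 1))):
            raise ValueError("labels must be binary")

    @property
    def n_samples(self) -> int:
        return self.activations.shape[0]

    @property
    def d(self) -> int:
        return self.activations.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.activations, columns=[s.name for s in self.specs]
        )
        df["y"] = self.y
        return df


def fit_normalizer(
    train_table: pd.DataFrame, specs: Sequence[FeatureSpec]
) -> Normalizer:
    """Derive per-feature min/max and imputation values from training rows only.

    Numeric features use median imputation; categorical features use the mode.
    A constant numeric feature (max == min) is recorded; application maps it
    to the uninformative middle value 0.5.
    """
    if len(train_table) == 0:
        raise ValueError("cannot fit a normalizer on an empty table")
    norm = Normalizer()
    for spec in specs:
        col = train_table[spec.name]
        norm.kinds[spec.name] = spec.kind
        if spec.kind == "numeric":
            vals = pd.to_numeric(col, errors="coerce")
            norm.impute[spec.name] = float(vals.median())
            norm.mins[spec.name] = float(vals.min())
            norm.maxs[spec.name] = float(vals.max())
        else:
            mode = col.mode(dropna=True)
            norm.impute[spec.name] = mode.iloc[0]
    norm.fitted = True
    return norm


def apply_normalizer(
    table: pd.DataFrame, normalizer: Normalizer
) -> pd.DataFrame:
    """Impute with training statistics, then min-max normalize numeric columns.

    Out-of-range test values are clamped to ``[0, 1]`` so downstream
    membership functions always see the fitted domain.  Unseen categorical
    levels fall back to the training mode (counted with a warning).
    """
    if not normalizer.fitted:
        raise ValueError("normalizer must be fitted before application")
    out = {}
    for name, kind in normalizer.kinds.items():
        col = table[name]
        if kind == "numeric":
            vals = pd.to_numeric(col, errors="coerce")
            vals = vals.fillna(normalizer.impute[name])
            lo, hi = normalizer.mins[name], normalizer.maxs[name]
            if hi > lo:
                z = (vals - lo) / (hi - lo)
                z = z.clip(0.0, 1.0)
            else:  # constant training feature: uninformative middle
                z = pd.Series(0.5, index=vals.index)
            out[name] = z.to_numpy(dtype=float)
        else:
            filled = col.where(col.notna(), normalizer.impute[name])
            out[name] = filled.to_numpy()
    return pd.DataFrame(out, index=table.index)


def gaussian_membership(z: float | np.ndarray, mf: MembershipFunction) -> float | np.ndarray:
    """Gaussian bump ``exp(-(z - c)^2 / (2 sigma^2))``; equals 1 iff ``z == c``."""
    z = np.asarray(z, dtype=float)
    val = np.exp(-((z - mf.center) ** 2) / (2.0 * mf.spread**2))
    return float(val) if val.ndim == 0 else val


def feature_to_concept(z: float | np.ndarray, spec: FeatureSpec) -> float | np.ndarray:
    """Scalar risk activation of a normalized numeric value.

    ``higher_is_risk`` features read off the High membership state,
    ``lower_is_risk`` the Low state, so that larger activations always mean
    stronger support for the positive class.
    """
    if spec.kind != "numeric":
        raise ValueError(
            f"feature {spec.name!r} is categorical; use encode_categorical"
        )
    low, _, high = spec.memberships
    mf = high if spec.orientation == "higher_is_risk" else low
    return gaussian_membership(z, mf)


def encode_categorical(
    train_column: pd.Series | Sequence, y: Sequence[int]
) -> dict:
    """Category -> risk-activation table from smoothed positive-class rates.

    Each category's positive rate is Laplace-smoothed, ``(k + 1) / (m + 2)``,
    then rescaled to ``[0, 1]`` across the observed categories with the
    smoothing constant ``EPS0`` in the denominator.  A single category (or
    all-equal rates) degenerates to activation 0.
    """
    col = pd.Series(list(train_column))
    yv = np.asarray(list(y), dtype=int)
    if len(col) != len(yv):
        raise ValueError("column and labels must align")
    cats = col.dropna().unique()
    if len(cats) == 0:
        raise ValueError("no categories observed in the training column")
    rates = {}
    for c in cats:
        sel = (col == c).to_numpy()
        m = int(sel.sum())
        k = int(yv[sel].sum())
        rates[c] = (k + 1.0) / (m + 2.0)
    p_min = min(rates.values())
    p_max = max(rates.values())
    return {c: (p - p_min) / (p_max - p_min + EPS0) for c, p in rates.items()}


def load_table2_memberships() -> dict[str, tuple[MembershipFunction, ...]]:
    """Packaged Gaussian membership parameters for the six continuous /
    ordinal cardiovascular benchmark features (Low, Medium, High)."""
    table = {
        "Age": ((0.20, 0.18), (0.50, 0.18), (0.80, 0.18)),
        "Resting blood pressure": ((0.20, 0.15), (0.50, 0.15), (0.80, 0.15)),
        "Serum cholesterol": ((0.20, 0.18), (0.50, 0.18), (0.80, 0.18)),
        "Maximum heart rate": ((0.20, 0.15), (0.50, 0.15), (0.80, 0.15)),
        "ST depression (oldpeak)": ((0.15, 0.12), (0.45, 0.15), (0.80, 0.18)),
        "Number of major vessels": ((0.10, 0.10), (0.45, 0.15), (0.85, 0.15)),
    }
    labels = ("Low", "Medium", "High")
    return {
        feat: tuple(
            MembershipFunction(c, s, lab) for (c, s), lab in zip(params, labels)
        )
        for feat, params in table.items()
    }


# --------------------------------------------------------------------------
# Full train/apply pipeline


@dataclass
class FuzzifyModel:
    """Fitted fuzzification pipeline: normalizer plus per-feature encoders."""

    normalizer: Normalizer
    specs: list[FeatureSpec]

    def to_dict(self) -> dict:
        """JSON-ready representation (category keys become strings)."""
        return {
            "normalizer": {
                "mins": self.normalizer.mins,
                "maxs": self.normalizer.maxs,
                "impute": {k: v for k, v in self.normalizer.impute.items()},
                "kinds": self.normalizer.kinds,
            },
            "specs": [
                {
                    "name": s.name,
                    "kind": s.kind,
                    "orientation": s.orientation,
                    "memberships": None
                    if s.memberships is None
                    else [[m.center, m.spread, m.label] for m in s.memberships],
                    "category_table": None
                    if s.category_table is None
                    else {str(c): a for c, a in s.category_table.items()},
                }
                for s in self.specs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzifyModel":
        norm = Normalizer(
            mins=dict(d["normalizer"]["mins"]),
            maxs=dict(d["normalizer"]["maxs"]),
            impute=dict(d["normalizer"]["impute"]),
            kinds=dict(d["normalizer"]["kinds"]),
            fitted=True,
        )
        specs = []
        for s in d["specs"]:
            mems = s.get("memberships")
            specs.append(
                FeatureSpec(
                    name=s["name"],
                    kind=s["kind"],
                    orientation=s.get("orientation"),
                    memberships=None
                    if mems is None
                    else tuple(MembershipFunction(c, sp, lab) for c, sp, lab in mems),
                    category_table=s.get("category_table"),
                )
            )
        return cls(normalizer=norm, specs=specs)


def fuzzify_fit(
    train_table: pd.DataFrame, y: Sequence[int], specs: Sequence[FeatureSpec]
) -> FuzzifyModel:
    """Fit normalization and categorical encoders on the training partition."""
    norm = fit_normalizer(train_table, specs)
    fitted_specs = []
    normed = apply_normalizer(train_table, norm)
    for spec in specs:
        if spec.kind == "categorical" and spec.category_table is None:
            table = encode_categorical(normed[spec.name], y)
            spec = replace(spec, category_table=table)
        fitted_specs.append(spec)
    return FuzzifyModel(normalizer=norm, specs=fitted_specs)


def fuzzify_apply(
    model: FuzzifyModel,
    table: pd.DataFrame,
    y: Sequence[int] | None = None,
    provenance: str = "",
) -> FuzzifiedDataset:
    """Map raw rows to concept activations with the fitted pipeline."""
    normed = apply_normalizer(table, model.normalizer)
    cols = []
    for spec in model.specs:
        if spec.kind == "numeric":
            cols.append(feature_to_concept(normed[spec.name].to_numpy(), spec))
        else:
            tab = spec.category_table
            mode = model.normalizer.impute[spec.name]
            vals = []
            for c in normed[spec.name]:
                if c in tab:
                    vals.append(tab[c])
                elif str(c) in tab:  # tables round-tripped through JSON
                    vals.append(tab[str(c)])
                else:
                    model.normalizer.unseen_category_count += 1
                    warnings.warn(
                        f"unseen category {c!r} in feature {spec.name!r}; "
                        "falling back to the training mode",
                        stacklevel=2,
                    )
                    vals.append(tab.get(mode, 0.0))
            cols.append(np.asarray(vals, dtype=float))
    acts = np.column_stack(cols) if cols else np.empty((len(table), 0))
    yv = np.zeros(len(table), dtype=int) if y is None else np.asarray(list(y), dtype=int)
    return FuzzifiedDataset(
        activations=acts, y=yv, specs=list(model.specs), provenance=provenance
    )


def build_initial_graph(fuzzified: FuzzifiedDataset) -> ConceptGraph:
    """Star-topology expert prior seeded by point-biserial associations.

    The graph has ``n = d + 1`` concepts: every feature concept feeds the
    diagnostic output node, which also carries a self-memory edge
    (``w = 0.20``); no feature-to-feature edges.  Each feature edge is
    initialized to ``clamp(|rho(phi_i, y)|, 0.05, 0.90)`` where ``rho`` is
    the point-biserial (Pearson) correlation between the concept activation
    and the binary label; the floor keeps every permitted edge alive, the cap
    keeps the prior inside the contraction-friendly range.  Bias starts at 0.
    """
    d = fuzzified.d
    if d < 1:
        raise ValueError("need at least one feature concept")
    n = d + 1
    mask = np.zeros((n, n))
    mask[:d, n - 1] = 1.0
    mask[n - 1, n - 1] = 1.0
    weights = np.zeros((n, n))
    y = fuzzified.y
    if len(np.unique(y)) < 2:
        warnings.warn(
            "single-class labels: point-biserial association undefined; "
            "initial feature weights fall to the 0.05 floor",
            stacklevel=2,
        )
        rho = np.zeros(d)
    else:
        yc = y - y.mean()
        rho = np.empty(d)
        for i in range(d):
            phi = fuzzified.activations[:, i]
            sp = phi.std()
            if sp == 0 or yc.std() == 0:
                rho[i] = 0.0
            else:
                rho[i] = np.corrcoef(phi, y)[0, 1]
    weights[:d, n - 1] = np.clip(np.abs(rho), WEIGHT_FLOOR, WEIGHT_CAP)
    weights[n - 1, n - 1] = SELF_MEMORY_WEIGHT
    names = [s.name for s in fuzzified.specs] + ["diagnosis"]
    return ConceptGraph(
        names=names, mask=mask, weights=weights, bias=0.0, output_index=n - 1
    )
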