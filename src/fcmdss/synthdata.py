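"""Synthetic patient-data generators and the three-concept worked example.

Two scenarios are provided.  The *cardiovascular* scenario draws eight
normalized risk features (systolic pressure, chest discomfort, cholesterol,
heart-rate irregularity, age-related risk, smoking, family history, body
mass) from stated Normal/Beta marginals and samples the binary label from

    p_cv(x) = sigma(1.40 x1 + 1.15 x2 + 0.90 x1 x3 + 0.55 log(1 + x4)
              + 0.40 x6 - 1.25).

The *metabolic* scenario uses seven features (glucose, insulin resistance,
BMI, triglycerides, activity, age-related vulnerability, diet risk) with

    p_met(x) = sigma(1.30 x1 + 0.95 x2 + 0.85 x3 x4 + 0.50 log(1 + x5)
               - 0.45 x6 + 0.35 x7 - 1.10).

Both default to 2000 samples.  Labels are drawn from the *pre-noise*
features; observation noise (Gaussian, sd 0.03) is added afterwards and the
features re-clamped to [0, 1].  One seed spawns three independent substreams
(features, labels, noise) so that toggling noise never changes the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from fcmdss.fcm_core import ConceptGraph

#: Marginal distributions of the cardiovascular features, in order.
CARDIO_DISTRIBUTIONS: tuple[tuple[str, tuple[float, float]], ...] = (
    ("normal", (0.68, 0.12)),
    ("beta", (3.0, 2.0)),
    ("normal", (0.62, 0.10)),
    ("beta", (2.0, 3.0)),
    ("normal", (0.55, 0.15)),
    ("beta", (2.0, 2.0)),
    ("beta", (3.0, 3.0)),
    ("normal", (0.50, 0.12)),
)

#: Metabolic marginals are not pinned down by the scenario description;
#: these defaults mirror the cardiovascular Normal/Beta alternation and are
#: overridable through :class:`ScenarioSpec`.
METABOLIC_DISTRIBUTIONS: tuple[tuple[str, tuple[float, float]], ...] = (
    ("normal", (0.60, 0.14)),
    ("beta", (2.0, 2.0)),
    ("normal", (0.55, 0.12)),
    ("beta", (2.0, 3.0)),
    ("normal", (0.50, 0.15)),
    ("beta", (3.0, 3.0)),
    ("beta", (3.0, 2.0)),
)


@dataclass
class ScenarioSpec:
    """Distributions, coefficients, and noise level of one synthetic scenario."""

    name: str
    distributions: tuple = CARDIO_DISTRIBUTIONS
    linear: dict = field(default_factory=dict)  # {feature index: coefficient}
    interactions: dict = field(default_factory=dict)  # {(i, j): coefficient}
    log_terms: dict = field(default_factory=dict)  # {i: coeff on log(1 + x_i)}
    intercept: float = 0.0
    n_samples: int = 2000
    noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    @property
    def n_features(self) -> int:
        return len(self.distributions)

    def probability(self, x: np.ndarray) -> np.ndarray:
        """Ground-truth disease probability for feature rows ``x``."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = np.full(x.shape[0], self.intercept)
        for i, c in self.linear.items():
            z += c * x[:, i]
        for (i, j), c in self.interactions.items():
            z += c * x[:, i] * x[:, j]
        for i, c in self.log_terms.items():
            z += c * np.log1p(x[:, i])
        return 1.0 / (1.0 + np.exp(-z))


def cardio_spec(n_samples: int = 2000, noise_sd: float = 0.03) -> ScenarioSpec:
    return ScenarioSpec(
        name="cardiovascular",
        distributions=CARDIO_DISTRIBUTIONS,
        linear={0: 1.40, 1: 1.15, 5: 0.40},
        interactions={(0, 2): 0.90},
        log_terms={3: 0.55},
        intercept=-1.25,
        n_samples=n_samples,
        noise_sd=noise_sd,
    )


def metabolic_spec(n_samples: int = 2000, noise_sd: float = 0.03) -> ScenarioSpec:
    return ScenarioSpec(
        name="metabolic",
        distributions=METABOLIC_DISTRIBUTIONS,
        linear={0: 1.30, 1: 0.95, 5: -0.45, 6: 0.35},
        interactions={(2, 3): 0.85},
        log_terms={4: 0.50},
        intercept=-1.10,
        n_samples=n_samples,
        noise_sd=noise_sd,
    )


def _draw_features(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    cols = []
    for family, params in spec.distributions:
        if family == "normal":
            mu, sd = params
            # Normal draws are clamped (not resampled) into [0, 1]
            cols.append(np.clip(rng.normal(mu, sd, spec.n_samples), 0.0, 1.0))
        elif family == "beta":
            a, b = params
            cols.append(rng.beta(a, b, spec.n_samples))
        else:
            raise ValueError(f"unknown distribution family {family!r}")
    return np.column_stack(cols)


def generate_scenario(spec: ScenarioSpec, seed: int) -> pd.DataFrame:
    """Sample one synthetic table: features ``x1..xd`` plus label column ``y``.

    The seed spawns three independent substreams — features, labels, noise —
    so labels are a deterministic function of the pre-noise features and the
    label stream alone.
    """
    feat_rng, label_rng, noise_rng = [
        np.random.Generator(np.random.PCG64(s))
        for s in np.random.SeedSequence(seed).spawn(3)
    ]
    x = _draw_features(spec, feat_rng)
    p = spec.probability(x)
    y = (label_rng.random(spec.n_samples) < p).astype(int)
    if spec.noise_sd > 0:
        x = np.clip(
            x + noise_rng.normal(0.0, spec.noise_sd, x.shape), 0.0, 1.0
        )
    df = pd.DataFrame(x, columns=[f"x{i + 1}" for i in range(spec.n_features)])
    df["y"] = y
    return df


def generate_cardio(n: int = 2000, seed: int = 0, noise_sd: float = 0.03) -> pd.DataFrame:
    """Cardiovascular scenario table (eight features + label)."""
    return generate_scenario(cardio_spec(n, noise_sd), seed)


def generate_metabolic(n: int = 2000, seed: int = 0, noise_sd: float = 0.03) -> pd.DataFrame:
    """Metabolic scenario table (seven features + label)."""
    return generate_scenario(metabolic_spec(n, noise_sd), seed)


def inject_missing(
    table: pd.DataFrame, rate: float, seed: int, target: str = "y"
) -> pd.DataFrame:
    """Mask each feature cell independently with the given probability
    (missing completely at random); the target column is never masked."""
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"missingness rate must lie in [0, 1), got {rate}")
    out = table.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    feat_cols = [c for c in table.columns if c != target]
    mask = rng.random((len(table), len(feat_cols))) < rate
    for j, c in enumerate(feat_cols):
        col = out[c].astype(float) if out[c].dtype.kind in "biu" else out[c]
        out[c] = col.mask(mask[:, j])
    return out


def impose_imbalance(
    train_rows: pd.DataFrame, ratio: tuple[int, int], seed: int, target: str = "y"
) -> pd.DataFrame:
    """Downsample positives in the training rows to a positives:negatives
    ratio; negatives are untouched.  Applies to the training partition only —
    callers must not pass validation/test rows."""
    pos_share, neg_share = ratio
    pos = train_rows[train_rows[target] == 1]
    neg = train_rows[train_rows[target] == 0]
    wanted_pos = int(round(len(neg) * pos_share / neg_share))
    if wanted_pos > len(pos):
        raise ValueError(
            f"cannot reach ratio {pos_share}:{neg_share}: need {wanted_pos} "
            f"positives but only {len(pos)} available"
        )
    rng = np.random.default_rng(seed)
    keep = rng.choice(pos.index.to_numpy(), size=wanted_pos, replace=False)
    kept = pd.concat([pos.loc[np.sort(keep)], neg])
    return kept.sort_index()


# --------------------------------------------------------------------------
# Worked example


@dataclass
class WorkedExample:
    """Three-concept illustration: blood pressure -> chest pain -> disease.

    Carries the initial graph, the patient's initial activation, the
    edgewise expert feedback on the chest-pain -> disease edge, the blended
    matrix, and the printed intermediate vectors used as test anchors.
    """

    graph: ConceptGraph
    initial_state: np.ndarray
    reviewed_edge: tuple[int, int]
    recommended_value: float
    alpha: float
    blended_weights: np.ndarray
    step1_pre_activation: np.ndarray
    step1_state: np.ndarray  # 2-dp rounded
    step2_pre_activation: np.ndarray
    step2_state: np.ndarray  # 2-dp rounded


def worked_example() -> WorkedExample:
    """The packaged three-concept cardiovascular illustration."""
    w0 = np.array(
        [
            [0.0, 0.30, 0.40],
            [0.0, 0.00, 0.60],
            [0.0, 0.00, 0.00],
        ]
    )
    mask = (w0 != 0).astype(float)
    graph = ConceptGraph(
        names=["High Blood Pressure", "Chest Pain", "Heart Disease"],
        mask=mask,
        weights=w0,
        bias=0.0,
        output_index=2,
    )
    w1 = w0.copy()
    w1[1, 2] = 0.66  # (1 - 0.3) * 0.60 + 0.3 * 0.80
    return WorkedExample(
        graph=graph,
        initial_state=np.array([0.80, 0.60, 0.00]),
        reviewed_edge=(1, 2),
        recommended_value=0.80,
        alpha=0.30,
        blended_weights=w1,
        step1_pre_activation=np.array([0.0, 0.24, 0.68]),
        step1_state=np.array([0.50, 0.56, 0.66]),
        step2_pre_activation=np.array([0.0, 0.15, 0.79]),
        step2_state=np.array([0.50, 0.54, 0.69]),
    )
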