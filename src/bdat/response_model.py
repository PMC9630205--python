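"""Explanatory item-response model with modified asymptotes.

Response accuracy on a BDAT trial is modelled by mixed-effects logistic
regression whose success probability is squeezed between a lower
asymptote ``g`` (guessing: the test is a one-alternative forced choice,
so blind responding is correct a fixed fraction of the time) and an
upper asymptote ``u`` (1 - inattention rate):

    P(correct) = g + (u - g) * logistic(eta)
    eta        = beta . x(item) + person_effect + track_effect

Separate models are used for ON items (covariate: metrical strength of
the target beat) and OFF items (strength, probe direction, displacement
level, and the direction x strength interaction).

Because g, u and the person random-intercept SD are shared across the
bank, the model is equivalent to a four-parameter logistic (4PL) IRT
model with constant guessing, inattention and discrimination:

    a = sigma_person          (discrimination)
    b = -(beta . x) / sigma_person   (difficulty)
    P(theta) = g + (u - g) * logistic(a * (theta - b))

with person abilities theta on a standard-normal z-score scale.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.special import expit

from .item_bank import Condition, Direction, ItemSpec

__all__ = [
    "ExplanatoryParams",
    "ItemParams",
    "ON_COEF_NAMES",
    "OFF_COEF_NAMES",
    "default_params",
    "load_params",
    "feature_vector",
    "linear_predictor",
    "response_probability",
    "irt_probability",
    "glmm_to_irt",
    "item_information",
    "log_likelihood",
]

ON_COEF_NAMES = ("intercept", "strength")
OFF_COEF_NAMES = ("intercept", "displacement", "direction", "strength",
                  "interaction")


@dataclass(frozen=True)
class ExplanatoryParams:
    """Condition-level model: fixed effects, random-effect SDs, asymptotes."""

    condition: Condition
    beta: Mapping[str, float]
    sigma_person: float
    sigma_track: float
    g: float  # lower asymptote (guessing)
    u: float  # upper asymptote (1 - inattention rate)

    def __post_init__(self) -> None:
        if not (0.0 <= self.g < self.u <= 1.0):
            raise ValueError("require 0 <= g < u <= 1")
        if self.sigma_person < 0 or self.sigma_track < 0:
            raise ValueError("random-effect SDs must be non-negative")
        names = ON_COEF_NAMES if self.condition is Condition.ON else OFF_COEF_NAMES
        missing = set(names) - set(self.beta)
        if missing:
            raise ValueError(f"missing coefficients: {sorted(missing)}")

    @property
    def coef_names(self) -> tuple[str, ...]:
        return ON_COEF_NAMES if self.condition is Condition.ON else OFF_COEF_NAMES

    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta[n] for n in self.coef_names], dtype=float)


@dataclass(frozen=True)
class ItemParams:
    """4PL parameters for a single item on the z-score ability scale."""

    a: float  # discrimination
    b: float  # difficulty
    g: float
    u: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("discrimination must be positive")
        if not (0.0 <= self.g < self.u <= 1.0):
            raise ValueError("require 0 <= g < u <= 1")
        if not np.isfinite(self.b):
            raise ValueError("difficulty must be finite")


def _coerce_condition(value) -> Condition:
    # YAML 1.1 parses bare ON/OFF as booleans; accept that spelling too
    if isinstance(value, bool):
        return Condition.ON if value else Condition.OFF
    return Condition(value)


def _load_yaml_params(name: str) -> ExplanatoryParams:
    ref = importlib.resources.files("bdat.params").joinpath(name)
    raw = yaml.safe_load(ref.read_text())
    return ExplanatoryParams(
        condition=_coerce_condition(raw["condition"]),
        beta=dict(raw["beta"]),
        sigma_person=float(raw["sigma_person"]),
        sigma_track=float(raw["sigma_track"]),
        g=float(raw["g"]),
        u=float(raw["u"]),
    )


def load_params(path) -> ExplanatoryParams:
    """Load ExplanatoryParams from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ExplanatoryParams(
        condition=_coerce_condition(raw["condition"]),
        beta=dict(raw["beta"]),
        sigma_person=float(raw["sigma_person"]),
        sigma_track=float(raw["sigma_track"]),
        g=float(raw["g"]),
        u=float(raw["u"]),
    )


def save_params(params: ExplanatoryParams, path) -> None:
    """Write ExplanatoryParams to a YAML file (round-trips with load_params)."""
    payload = {
        "condition": params.condition.value,
        "beta": {k: float(v) for k, v in params.beta.items()},
        "sigma_person": float(params.sigma_person),
        "sigma_track": float(params.sigma_track),
        "g": float(params.g),
        "u": float(params.u),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def default_params() -> dict[Condition, ExplanatoryParams]:
    """The bundled published calibration for the ON and OFF models."""
    return {
        Condition.ON: _load_yaml_params("on_condition.yaml"),
        Condition.OFF: _load_yaml_params("off_condition.yaml"),
    }


def feature_vector(item: ItemSpec) -> dict[str, float]:
    """Covariate coding for one item.

    strength: 1 for the strong beat (beat 3), 0 for the weak beat (beat 4);
    direction: 0 for early (reference), 1 for late;
    displacement: the level index 1..7 (not raw percent);
    interaction: direction * strength.  ON items use {intercept, strength}.
    """
    strength = 1.0 if item.target_beat == 3 else 0.0
    if item.condition is Condition.ON:
        return {"intercept": 1.0, "strength": strength}
    direction = 1.0 if item.direction is Direction.LATE else 0.0
    return {
        "intercept": 1.0,
        "displacement": float(item.displacement_level),
        "direction": direction,
        "strength": strength,
        "interaction": direction * strength,
    }


def linear_predictor(features: Mapping[str, float], params: ExplanatoryParams,
                     person_effect: float = 0.0, track_effect: float = 0.0) -> float:
    """beta . x plus the person and track random effects, in logits."""
    expected = set(params.coef_names)
    if set(features) != expected:
        raise ValueError(
            f"feature keys {sorted(features)} do not match "
            f"{params.condition.value} coefficients {sorted(expected)}")
    eta = sum(params.beta[k] * v for k, v in features.items())
    return float(eta + person_effect + track_effect)


def response_probability(eta, g: float, u: float):
    """Asymptote-modified logistic: P = g + (u - g) * logistic(eta)."""
    if not (0.0 <= g < u <= 1.0):
        raise ValueError("require 0 <= g < u <= 1")
    return g + (u - g) * expit(np.asarray(eta, dtype=float))


def irt_probability(theta, item: ItemParams):
    """4PL response probability at ability theta."""
    eta = item.a * (np.asarray(theta, dtype=float) - item.b)
    return response_probability(eta, item.g, item.u)


def glmm_to_irt(item: ItemSpec, params: ExplanatoryParams) -> ItemParams:
    """Map the explanatory model to constant-discrimination 4PL parameters.

    The person random-intercept SD becomes the (constant) discrimination,
    each item's fixed-effect predictor becomes its difficulty
    b = -(beta . x)/sigma_person, and the asymptotes carry over.  The track
    random effect is excluded here: at administration time each track is
    presented at most once per session and its calibrated SD is small.
    """
    if params.sigma_person <= 0:
        raise ValueError("sigma_person must be positive (degenerate model)")
    x = feature_vector(item)
    eta = sum(params.beta[k] * v for k, v in x.items())
    return ItemParams(a=params.sigma_person, b=-eta / params.sigma_person,
                      g=params.g, u=params.u)


def item_information(theta, item: ItemParams):
    """Fisher information of one Bernoulli response at ability theta.

    I(theta) = a^2 (P-g)^2 (u-P)^2 / ((u-g)^2 P (1-P)); reduces to the
    familiar a^2 P (1-P) when g=0, u=1.
    """
    p = irt_probability(theta, item)
    num = item.a**2 * (p - item.g) ** 2 * (item.u - p) ** 2
    den = (item.u - item.g) ** 2 * p * (1.0 - p)
    return num / den


def log_likelihood(responses: Sequence[tuple[ItemParams, int]], theta) -> np.ndarray:
    """Bernoulli log-likelihood of a response pattern at ability theta.

    Finite for every pattern because g > 0 and u < 1 keep the per-item
    probabilities away from 0 and 1.  ``theta`` may be a scalar or grid.
    """
    if len(responses) == 0:
        raise ValueError("responses must be non-empty")
    theta = np.asarray(theta, dtype=float)
    ll = np.zeros_like(theta, dtype=float)
    for item, y in responses:
        if y not in (0, 1):
            raise ValueError("responses must be 0 or 1")
        p = irt_probability(theta, item)
        ll = ll + (np.log(p) if y == 1 else np.log1p(-p))
    return ll
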