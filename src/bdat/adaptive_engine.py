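"""Adaptive administration of the BDAT.

The adaptive test presents a fixed number of trials (default 25).  After
every response the participant's ability is re-estimated, and the next
item is the unused-track item whose difficulty is closest to the running
estimate (or, optionally, the item with maximum Fisher information).
The first item is always the one with difficulty closest to 0, the mean
ability of the calibration population.  Abilities live on the z-score
scale shared with item difficulties; the final score is also reported as
a pseudo-IQ (mean 100, SD 15).

Ability is estimated by EAP (expected a posteriori) under a standard
normal prior on a fixed grid over [-4, 4]: unlike maximum likelihood it
is defined for all-correct and all-incorrect patterns.  ML is available
as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .item_bank import Condition, ItemBank, ItemSpec
from .response_model import (ExplanatoryParams, ItemParams, glmm_to_irt,
                             item_information, log_likelihood)

__all__ = [
    "THETA_GRID",
    "AbilityEstimate",
    "SessionState",
    "SessionResult",
    "estimate_ability",
    "select_next_item",
    "run_session",
    "pseudo_iq",
]

#: Ability grid: z-score scale from -4 to 4, step 0.01.
THETA_GRID = np.round(np.arange(-400, 401) * 0.01, 10)


@dataclass(frozen=True)
class AbilityEstimate:
    theta: float
    se: float
    method: str = "EAP"
    n_responses: int = 0


@dataclass
class SessionState:
    """Mutable state of one adaptive session."""

    bank: ItemBank
    params: dict[Condition, ExplanatoryParams]
    rng: np.random.Generator
    length: int = 25
    selection: str = "difficulty"  # or "information"
    condition_p_on: float = 0.5
    administered: list[tuple[ItemSpec, int, AbilityEstimate]] = field(
        default_factory=list)
    used_tracks: set = field(default_factory=set)

    def __post_init__(self) -> None:
        # cache per-item 4PL parameters once: selection scans the whole
        # bank every trial
        self._items = list(self.bank)
        self._iparams = [glmm_to_irt(it, self.params[it.condition])
                         for it in self._items]
        self._b = np.array([ip.b for ip in self._iparams])
        self._tracks = np.array([it.track_id for it in self._items])
        self._is_on = np.array([it.condition is Condition.ON
                                for it in self._items])

    @property
    def estimate(self) -> AbilityEstimate:
        if not self.administered:
            return estimate_ability([])
        return self.administered[-1][2]

    def item_params(self, item: ItemSpec) -> ItemParams:
        return glmm_to_irt(item, self.params[item.condition])

    def remaining(self) -> list[ItemSpec]:
        return [it for it in self._items if it.track_id not in self.used_tracks]


@dataclass
class SessionResult:
    final: AbilityEstimate
    pseudo_iq: float
    trials: pd.DataFrame  # per-trial log

    def to_json_dict(self) -> dict:
        return {
            "theta": self.final.theta, "se": self.final.se,
            "method": self.final.method, "n_responses": self.final.n_responses,
            "pseudo_iq": self.pseudo_iq,
        }


def estimate_ability(responses: Sequence[tuple[ItemParams, int]],
                     method: str = "EAP") -> AbilityEstimate:
    """Ability estimate from a scored response pattern.

    EAP: posterior mean and SD over THETA_GRID under a standard-normal
    prior.  With no responses the prior mean 0 is returned.  ML: grid
    argmax of the likelihood, SE from the Fisher information at the
    maximum (undefined se for empty or degenerate patterns).
    """
    grid = THETA_GRID
    log_prior = -0.5 * grid**2
    if len(responses) == 0:
        if method == "EAP":
            w = np.exp(log_prior - log_prior.max())
            w /= w.sum()
            mean = float(grid @ w)
            sd = float(np.sqrt(grid**2 @ w - mean**2))
            return AbilityEstimate(theta=0.0, se=sd, method="EAP", n_responses=0)
        raise ValueError("ML estimate undefined with no responses")
    ll = log_likelihood(responses, grid)
    if method == "EAP":
        logw = ll + log_prior
        w = np.exp(logw - logw.max())
        w /= w.sum()
        mean = float(grid @ w)
        sd = float(np.sqrt(max(grid**2 @ w - mean**2, 1e-12)))
        return AbilityEstimate(theta=mean, se=sd, method="EAP",
                               n_responses=len(responses))
    if method == "ML":
        i = int(np.argmax(ll))
        theta = float(grid[i])
        info = sum(item_information(theta, it) for it, _ in responses)
        se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
        return AbilityEstimate(theta=theta, se=se, method="ML",
                               n_responses=len(responses))
    raise ValueError(f"unknown method {method!r}")


def select_next_item(state: SessionState) -> ItemSpec:
    """Pick the next item for the session.

    The first trial takes the item with difficulty closest to 0 from the
    whole bank.  Later trials first draw the condition (ON with
    probability ``condition_p_on``), then pick, among items of that
    condition on unused tracks, the one with difficulty closest to the
    current ability estimate (``selection='difficulty'``) or with maximum
    information at it (``selection='information'``).  Ties are broken by
    a seeded uniform choice.  Raises ``LookupError`` when no track remains.
    """
    avail = ~np.isin(state._tracks, list(state.used_tracks)) \
        if state.used_tracks else np.ones(len(state._items), dtype=bool)
    if not avail.any():
        raise LookupError("item bank exhausted: session complete")
    theta = state.estimate.theta if state.administered else 0.0

    mask = avail
    if state.administered:
        want_on = state.rng.random() < state.condition_p_on
        cond_mask = avail & (state._is_on == want_on)
        if cond_mask.any():
            mask = cond_mask

    idx = np.flatnonzero(mask)
    if state.selection == "information":
        score = np.array([-item_information(theta, state._iparams[i])
                          for i in idx])
    else:
        score = np.abs(state._b[idx] - theta)
    best = score.min()
    ties = np.flatnonzero(score <= best + 1e-12)
    pick = ties[0] if len(ties) == 1 else ties[state.rng.integers(len(ties))]
    item = state._items[int(idx[pick])]
    state.used_tracks.add(item.track_id)
    return item


def run_session(respond: Callable[[ItemSpec], int], bank: ItemBank,
                params: dict[Condition, ExplanatoryParams], length: int = 25,
                seed: int = 0, selection: str = "difficulty",
                method: str = "EAP", condition_p_on: float = 0.5
                ) -> SessionResult:
    """Administer one adaptive session of ``length`` trials.

    ``respond`` maps an ItemSpec to a scored response (1 = correct).  Each
    track is used at most once.  Deterministic given the responder, bank
    and seed.
    """
    n_tracks = len({it.track_id for it in bank})
    if n_tracks < length:
        raise ValueError(f"bank has {n_tracks} tracks < session length {length}")
    state = SessionState(bank=bank, params=params,
                         rng=np.random.default_rng(seed), length=length,
                         selection=selection, condition_p_on=condition_p_on)
    scored: list[tuple[ItemParams, int]] = []
    rows = []
    for trial in range(length):
        item = select_next_item(state)
        y = respond(item)
        if y not in (0, 1):
            raise ValueError(f"responder returned non-binary value {y!r}")
        scored.append((state.item_params(item), int(y)))
        est = estimate_ability(scored, method=method)
        state.administered.append((item, int(y), est))
        rows.append({
            "trial": trial + 1, "item_id": item.item_id,
            "track_id": item.track_id, "condition": item.condition.value,
            "target_beat": item.target_beat, "direction": item.direction.value,
            "displacement_level": item.displacement_level,
            "b": state.item_params(item).b, "response": int(y),
            "theta": est.theta, "se": est.se,
        })
    final = state.administered[-1][2] if state.administered \
        else estimate_ability([], method="EAP")
    return SessionResult(final=final, pseudo_iq=pseudo_iq(final.theta),
                         trials=pd.DataFrame(rows))


def pseudo_iq(theta: float) -> float:
    """Affine rescaling of ability to an IQ-like scale: 100 + 15*theta."""
    return 100.0 + 15.0 * float(theta)
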