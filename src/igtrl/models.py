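"""Reinforcement-learning models of IGT choice.

Three candidate models are implemented as utility + learning + choice-rule
components:

* ``evl`` — Expectancy Valence Learning: linear valence
  u = (1 - w)·win - w·|loss| with loss-attention weight w, delta-rule
  updating with recency phi, and a trial-dependent softmax sensitivity
  theta(t) = (t/10)^c.
* ``pvl_delta`` — Prospect Valence Learning with the delta rule: prospect
  utility u(x) = x^alpha for x >= 0, -lambda·|x|^alpha for x < 0 applied to
  the net outcome, delta-rule updating with learning rate A, and
  trial-independent sensitivity theta = 3^c - 1.
* ``pvl_decay`` — PVL with the decay-reinforcement rule: every deck's
  expectancy decays by recency factor A each trial and the chosen deck
  adds the current utility.

All models choose by softmax over deck expectancies; expectancies start at
zero so the first trial is uniform over the four decks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .task import CARDS_PER_DECK, DECK_INDEX, DECKS, Outcome, PayoffSchedule, Session, Trial

MODELS = ("evl", "pvl_delta", "pvl_decay")
_MODEL_ID = {"evl": 0, "pvl_delta": 1, "pvl_decay": 2}

# Natural-scale parameter bounds, in the order used by the packed arrays.
PVL_BOUNDS = {"alpha": (0.0, 1.0), "lam": (0.0, 5.0), "A": (0.0, 1.0), "c": (0.0, 5.0)}
EVL_BOUNDS = {"w": (0.0, 1.0), "phi": (0.0, 1.0), "c_evl": (-5.0, 5.0)}


@dataclass(frozen=True)
class PVLParams:
    """PVL free parameters: utility shape alpha in (0,1), loss aversion
    lam in (0,5), recency/learning A in (0,1), consistency c in (0,5)."""

    alpha: float
    lam: float
    A: float
    c: float

    def __post_init__(self) -> None:
        for name, (lo, hi) in PVL_BOUNDS.items():
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name}={v} outside open bounds ({lo}, {hi})")

    def to_array(self) -> np.ndarray:
        return np.array([self.alpha, self.lam, self.A, self.c], dtype=np.float64)


@dataclass(frozen=True)
class EVLParams:
    """EVL free parameters: loss-attention w in (0,1), recency phi in (0,1),
    consistency c_evl in (-5,5)."""

    w: float
    phi: float
    c_evl: float

    def __post_init__(self) -> None:
        for name, (lo, hi) in EVL_BOUNDS.items():
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name}={v} outside open bounds ({lo}, {hi})")

    def to_array(self) -> np.ndarray:
        # Packed into the 4-wide layout used by the likelihood kernel.
        return np.array([self.w, self.phi, self.c_evl, 0.0], dtype=np.float64)


def n_free_params(model: str) -> int:
    return 3 if model == "evl" else 4


def params_from_array(model: str, arr: np.ndarray):
    if model == "evl":
        return EVLParams(w=float(arr[0]), phi=float(arr[1]), c_evl=float(arr[2]))
    return PVLParams(alpha=float(arr[0]), lam=float(arr[1]), A=float(arr[2]), c=float(arr[3]))


# ---------------------------------------------------------------------------
# Component operations
# ---------------------------------------------------------------------------

def prospect_utility(x: float, alpha: float, lam: float) -> float:
    """Prospect utility of a net outcome: diminishing sensitivity via the
    shape exponent alpha and asymmetric weighting of losses via lam."""
    if x >= 0:
        return x ** alpha
    return -lam * (-x) ** alpha


def evl_valence(win: float, loss: float, w: float) -> float:
    """EVL valence: attention-weighted combination (1-w)·win - w·|loss|."""
    return (1.0 - w) * win - w * abs(loss)


def decay_update(E: np.ndarray, chosen: str | int, u: float, A: float) -> np.ndarray:
    """Decay-reinforcement rule: all expectancies decay by A, the chosen
    deck additionally gains the current utility."""
    j = DECK_INDEX[chosen] if isinstance(chosen, str) else int(chosen)
    if not 0 <= j < 4:
        raise ValueError(f"invalid deck {chosen!r}")
    out = A * np.asarray(E, dtype=float)
    out[j] += u
    return out


def delta_update(E: np.ndarray, chosen: str | int, u: float, a: float) -> np.ndarray:
    """Delta rule: the chosen deck's expectancy moves toward u by step a."""
    j = DECK_INDEX[chosen] if isinstance(chosen, str) else int(chosen)
    if not 0 <= j < 4:
        raise ValueError(f"invalid deck {chosen!r}")
    out = np.asarray(E, dtype=float).copy()
    out[j] += a * (u - out[j])
    return out


def choice_sensitivity_pvl(c: float) -> float:
    """PVL softmax sensitivity theta = 3^c - 1 (trial-independent)."""
    return 3.0 ** c - 1.0


def choice_sensitivity_evl(c_evl: float, t: int) -> float:
    """EVL trial-dependent sensitivity theta(t) = (t/10)^c."""
    if t < 1:
        raise ValueError("trial index must be >= 1")
    return (t / 10.0) ** c_evl


def choice_probabilities(
    E: np.ndarray, theta: float, available: tuple[str, ...] = DECKS
) -> np.ndarray:
    """Softmax choice probabilities p_j ∝ exp(theta·E_j) over available decks.

    Computed with max-subtraction so theta·E magnitudes up to ~700 stay
    finite; unavailable decks receive probability zero.
    """
    if len(available) == 0:
        raise ValueError("at least one deck must be available")
    E = np.asarray(E, dtype=float)
    mask = np.zeros(4, dtype=bool)
    for d in available:
        mask[DECK_INDEX[d]] = True
    v = theta * E[mask]
    v = v - v.max()
    w = np.exp(v)
    p = np.zeros(4)
    p[mask] = w / w.sum()
    return p


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

@njit(cache=True)
def _loglik_kernel(choices, wins, losses, horizons, params, model_id):  # pragma: no cover
    """Per-subject session log-likelihoods.

    choices : (n, T) int64 deck indices; wins/losses : (n, T) float64;
    horizons : (n,) int64; params : (n, 4) float64 natural-scale values
    (EVL uses the first three slots); model_id : 0 evl, 1 pvl_delta,
    2 pvl_decay.
    """
    n = choices.shape[0]
    out = np.zeros(n)
    for i in range(n):
        E = np.zeros(4)
        ll = 0.0
        p0 = params[i, 0]
        p1 = params[i, 1]
        p2 = params[i, 2]
        p3 = params[i, 3]
        theta = 0.0
        if model_id != 0:
            theta = 3.0 ** p3 - 1.0
        for t in range(horizons[i]):
            ch = choices[i, t]
            if model_id == 0:
                theta = ((t + 1) / 10.0) ** p2
            # log softmax with max-subtraction
            m = theta * E[0]
            for j in range(1, 4):
                v = theta * E[j]
                if v > m:
                    m = v
            s = 0.0
            for j in range(4):
                s += np.exp(theta * E[j] - m)
            ll += theta * E[ch] - m - np.log(s)
            # utility of the realized outcome
            if model_id == 0:
                u = (1.0 - p0) * wins[i, t] - p0 * np.abs(losses[i, t])
            else:
                x = wins[i, t] + losses[i, t]
                if x >= 0.0:
                    u = x ** p0
                else:
                    u = -p1 * (-x) ** p0
            # learning update
            if model_id == 2:
                for j in range(4):
                    E[j] = p2 * E[j]
                E[ch] = E[ch] + u
            elif model_id == 1:
                E[ch] = E[ch] + p2 * (u - E[ch])
            else:
                E[ch] = E[ch] + p1 * (u - E[ch])
        out[i] = ll
    return out


def pack_sessions(sessions: list[Session]):
    """Pack sessions into the padded arrays the likelihood kernel consumes."""
    n = len(sessions)
    T = max((len(s) for s in sessions), default=0)
    choices = np.zeros((n, T), dtype=np.int64)
    wins = np.zeros((n, T), dtype=np.float64)
    losses = np.zeros((n, T), dtype=np.float64)
    horizons = np.zeros(n, dtype=np.int64)
    for i, s in enumerate(sessions):
        m = len(s)
        choices[i, :m] = s.choice_array()
        wins[i, :m] = s.win_array()
        losses[i, :m] = s.loss_array()
        horizons[i] = s.modeling_horizon
    return choices, wins, losses, horizons


def cohort_loglik(
    choices: np.ndarray,
    wins: np.ndarray,
    losses: np.ndarray,
    horizons: np.ndarray,
    params: np.ndarray,
    model: str,
) -> np.ndarray:
    """Vectorized per-subject log-likelihoods for packed session arrays."""
    if model not in _MODEL_ID:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return _loglik_kernel(choices, wins, losses, horizons, params, _MODEL_ID[model])


def session_loglik(params, session: Session, model: str) -> float:
    """Log-likelihood of one session's choices up to its modeling horizon.

    Expectancies start at zero, each trial contributes log p(chosen deck)
    under the softmax before the outcome is observed, and the realized
    outcome then updates expectancies.
    """
    if model not in _MODEL_ID:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    arr = params.to_array() if hasattr(params, "to_array") else np.asarray(params, float)
    if arr.shape[0] == 3:
        arr = np.append(arr, 0.0)
    c, w, l, h = pack_sessions([session])
    ll = float(_loglik_kernel(c, w, l, h, arr[None, :], _MODEL_ID[model])[0])
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood within parameter bounds")
    return ll


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def simulate_agent(
    params,
    schedule: PayoffSchedule,
    model: str,
    n_trials: int = 100,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sim",
    group: str = "sim",
) -> Session:
    """Simulate one agent playing the task.

    On each trial the agent chooses among the non-depleted decks from the
    softmax over current expectancies, draws that deck's next card, and
    updates expectancies exactly as the likelihood assumes. The same seed
    and parameters reproduce the identical session.
    """
    if model not in _MODEL_ID:
        raise ValueError(f"unknown model {model!r}")
    if n_trials > 4 * CARDS_PER_DECK:
        raise ValueError(f"n_trials={n_trials} exceeds the {4 * CARDS_PER_DECK} cards available")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = params.to_array() if hasattr(params, "to_array") else np.asarray(params, float)
    E = np.zeros(4)
    drawn = np.zeros(4, dtype=int)
    trials: list[Trial] = []
    for t in range(1, n_trials + 1):
        available = tuple(d for d in DECKS if drawn[DECK_INDEX[d]] < CARDS_PER_DECK)
        if model == "evl":
            theta = choice_sensitivity_evl(arr[2], t)
        else:
            theta = choice_sensitivity_pvl(arr[3])
        p = choice_probabilities(E, theta, available)
        j = int(rng.choice(4, p=p))
        deck = DECKS[j]
        outcome = schedule.outcome(deck, drawn[j])
        drawn[j] += 1
        if model == "evl":
            u = evl_valence(outcome.win, outcome.loss, arr[0])
            E = delta_update(E, j, u, arr[1])
        else:
            u = prospect_utility(outcome.win + outcome.loss, arr[0], arr[1])
            E = decay_update(E, j, u, arr[2]) if model == "pvl_decay" else delta_update(E, j, u, arr[2])
        trials.append(Trial(subject_id=subject_id, trial_index=t, deck=deck, outcome=outcome))
    return Session(subject_id=subject_id, group=group, trials=trials)
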