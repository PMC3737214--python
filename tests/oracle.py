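"""Independent naive per-trial likelihood oracle.

Deliberately written as a plain-Python transcription of the model
equations — scalar arithmetic, explicit loops, no shared code with the
package's vectorized likelihood kernel — so it can serve as an
independent check of `igtrl.models.session_loglik`.
"""

import math

_DECKS = {"A": 0, "B": 1, "C": 2, "D": 3}


def naive_session_loglik(params, session, model):
    """params: dict of natural-scale values keyed by parameter name."""
    E = [0.0, 0.0, 0.0, 0.0]
    ll = 0.0
    for t, trial in enumerate(session.trials[: session.modeling_horizon], start=1):
        if model == "evl":
            theta = (t / 10.0) ** params["c_evl"]
        else:
            theta = 3.0 ** params["c"] - 1.0
        ch = _DECKS[trial.deck]
        denom = sum(math.exp(theta * (E[j] - max(E))) for j in range(4))
        ll += theta * (E[ch] - max(E)) - math.log(denom)
        win, loss = trial.outcome.win, trial.outcome.loss
        if model == "evl":
            u = (1.0 - params["w"]) * win - params["w"] * abs(loss)
            E[ch] = E[ch] + params["phi"] * (u - E[ch])
        else:
            x = win + loss
            if x >= 0:
                u = x ** params["alpha"]
            else:
                u = -params["lam"] * (-x) ** params["alpha"]
            if model == "pvl_decay":
                E = [params["A"] * e for e in E]
                E[ch] = E[ch] + u
            else:
                E[ch] = E[ch] + params["A"] * (u - E[ch])
    return ll


def brute_force_hdi(draws, mass=0.95):
    """All-pairs shortest interval containing >= mass of the draws."""
    x = sorted(draws)
    n = len(x)
    need = math.ceil(mass * n)
    best = None
    for i in range(n):
        for j in range(i, n):
            if j - i + 1 >= need:
                width = x[j] - x[i]
                if best is None or width < best[0]:
                    best = (width, x[i], x[j])
                break  # larger j only widens
    return best[1], best[2]
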