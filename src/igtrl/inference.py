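"""Parameter estimation and group comparison.

Two estimation routes are provided:

* per-subject maximum likelihood (``fit_mle``) — bounded multistart
  quasi-Newton optimization on the probit latent scale; used for model
  comparison (BIC, one-step-ahead log-loss) and as an oracle for the
  Bayesian fits;
* hierarchical Bayesian analysis (``fit_hba``) — each group is fit with
  its own hierarchy: subject latents z_i ~ Normal(mu, sigma) per
  parameter (probit-mapped to the natural scale), hypermeans mu ~
  Normal(0, 1.5^2), hyper-SDs sigma ~ HalfNormal(1). Sampling is
  Metropolis-within-Gibbs: a vectorized blocked random-walk Metropolis
  step on each subject's latent vector plus componentwise passes per
  parameter (subjects are conditionally independent given the hypers, so
  all proposals are evaluated in one likelihood-kernel call), a joint
  "shift" move translating a whole latent column together with its
  hypermean (decorrelates the hypermean/latent funnel), conjugate Gibbs
  updates for mu (and the age slope beta), and log-scale random-walk
  Metropolis for sigma. Proposal scales adapt during warmup
  (Robbins-Monro, targeting 25% acceptance for blocked and 44% for
  scalar moves) and are frozen afterwards.

Group contrasts are evaluated on the natural scale: each draw's
(mu, sigma) is mapped to the group-level mean of the transformed normal,
E[natural] = lo + (hi-lo)*Phi(mu/sqrt(1+sigma^2)), differences are taken
draw-wise, and a difference is called credible when its 95% highest
density interval excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import qmc

from .cohort import CohortDataset
from .models import MODELS, cohort_loglik, n_free_params, pack_sessions, params_from_array
from .task import Session
from .transforms import PARAM_NAMES, param_bounds, to_natural

HYPERMEAN_PRIOR_SD = 1.5
HYPERSD_PRIOR_SCALE = 1.0
AGE_SLOPE_PRIOR_SD = 1.0
RHAT_THRESHOLD = 1.1


# ---------------------------------------------------------------------------
# Highest density interval
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HDInterval:
    low: float
    high: float
    mass: float = 0.95

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("HDI low must be <= high")

    def contains(self, x: float) -> bool:
        return self.low <= x <= self.high


def compute_hdi(draws, mass: float = 0.95) -> HDInterval:
    """Shortest contiguous interval containing >= ``mass`` of the draws.

    Over the sorted draws, every window of ceil(mass*n) consecutive values
    is a candidate; the narrowest one is returned (lowest window on ties).
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    if x.size < 2:
        raise ValueError("need at least 2 draws for an HDI")
    if not np.all(np.isfinite(x)):
        raise ValueError("draws must be finite")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    m = int(np.ceil(mass * x.size))
    m = min(max(m, 2), x.size)
    widths = x[m - 1 :] - x[: x.size - m + 1]
    i = int(np.argmin(widths))
    return HDInterval(low=float(x[i]), high=float(x[i + m - 1]), mass=mass)


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class MLEstimate:
    params: object
    latent: np.ndarray
    loglik: float
    converged: bool
    n_starts: int
    model: str


def _nll_factory(sessions: list[Session], model: str):
    bounds = param_bounds(model)
    choices, wins, losses, horizons = pack_sessions(sessions)
    n = len(sessions)

    def nll(z: np.ndarray) -> float:
        nat = to_natural(z, bounds)
        if model == "evl":
            nat = np.append(nat, 0.0)
        params = np.broadcast_to(nat, (n, nat.size))
        ll = cohort_loglik(choices, wins, losses, horizons, np.ascontiguousarray(params), model).sum()
        return -float(ll) if np.isfinite(ll) else 1e12

    return nll


def fit_mle(
    session: Session | list[Session], model: str, n_starts: int = 10, seed: int = 0
) -> MLEstimate:
    """Best-of-multistart maximum-likelihood fit of one session (or of a
    shared parameter set across several sessions).

    Optimization runs on the unconstrained latent scale (so natural
    parameters stay strictly inside their bounds); starts are a seeded
    Latin hypercube over latent [-2, 2]^k plus the origin.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    sessions = session if isinstance(session, list) else [session]
    for s in sessions:
        if s.modeling_horizon < 10:
            warnings.warn(
                f"subject {s.subject_id}: modeling horizon "
                f"{s.modeling_horizon} < 10; fit may be unstable"
            )
    k = n_free_params(model)
    nll = _nll_factory(sessions, model)
    sampler = qmc.LatinHypercube(d=k, seed=seed)
    starts = [np.zeros(k)]
    if n_starts > 1:
        starts += list(qmc.scale(sampler.random(n_starts - 1), [-2.0] * k, [2.0] * k))
    best = None
    any_converged = False
    for z0 in starts:
        res = minimize(nll, z0, method="L-BFGS-B")
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    bounds = param_bounds(model)
    nat = to_natural(best.x, bounds)
    # keep strictly inside the open bounds when the optimizer rides an edge
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    eps = 1e-9 * (hi - lo)
    nat = np.clip(nat, lo + eps, hi - eps)
    return MLEstimate(
        params=params_from_array(model, np.append(nat, 0.0) if k == 3 else nat),
        latent=best.x.copy(),
        loglik=-float(best.fun),
        converged=any_converged,
        n_starts=len(starts),
        model=model,
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    bic: dict[str, float]
    log_loss: dict[str, float]
    selected: str
    per_subject_bic: dict[str, np.ndarray]


def bic_score(loglik: float, k: int, horizon: int) -> float:
    """Bayesian information criterion k·ln(horizon) - 2·loglik."""
    return k * np.log(horizon) - 2.0 * loglik


def compare_models(
    dataset: CohortDataset,
    models: list[str] = list(MODELS),
    n_starts: int = 10,
    seed: int = 0,
) -> ModelComparison:
    """Compare candidate models on summed per-subject BIC from multistart
    MLE, with mean one-step-ahead predictive log-loss (per-trial negative
    log probability of the next choice under the fitted parameters) as a
    secondary criterion. The model with the lowest summed BIC is selected.
    """
    if not models:
        raise ValueError("model list must not be empty")
    bic: dict[str, float] = {}
    log_loss: dict[str, float] = {}
    per_subject: dict[str, np.ndarray] = {}
    for model in models:
        k = n_free_params(model)
        subj_bic = []
        subj_ll = []
        for i, sess in enumerate(dataset.sessions):
            est = fit_mle(sess, model, n_starts=n_starts, seed=seed + 1000 * i)
            h = max(sess.modeling_horizon, 1)
            subj_bic.append(bic_score(est.loglik, k, h))
            subj_ll.append(-est.loglik / h)
        per_subject[model] = np.asarray(subj_bic)
        bic[model] = float(np.sum(subj_bic))
        log_loss[model] = float(np.mean(subj_ll))
    selected = min(bic, key=bic.get)
    return ModelComparison(bic=bic, log_loss=log_loss, selected=selected, per_subject_bic=per_subject)


# ---------------------------------------------------------------------------
# Hierarchical Bayesian analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    thin: int = 5
    seed: int = 0

    @classmethod
    def smoke(cls, seed: int = 0) -> "MCMCConfig":
        """Reduced desk-scale profile."""
        return cls(chains=2, warmup=200, draws=200, thin=5, seed=seed)


@dataclass
class GroupPosterior:
    """Posterior draws for one group's hierarchy.

    Arrays are shaped (chains, draws, ...); ``group_mean`` holds the
    natural-scale group-level mean implied by each (mu, sigma) draw.
    """

    group: str
    model: str
    param_names: tuple[str, ...]
    subject_ids: list[str]
    mu: np.ndarray            # (chains, draws, k) latent hypermeans
    sigma: np.ndarray         # (chains, draws, k) latent hyper-SDs
    subject_params: np.ndarray  # (chains, draws, n, k) natural scale
    group_mean: np.ndarray    # (chains, draws, k) natural scale
    beta: np.ndarray | None = None  # (chains, draws, k) age slopes
    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)
    converged: bool = True

    def group_mean_draws(self, param: str) -> np.ndarray:
        j = self.param_names.index(param)
        return self.group_mean[:, :, j].ravel()

    def subject_posterior_means(self) -> np.ndarray:
        """(n, k) posterior means of subject-level natural parameters."""
        return self.subject_params.mean(axis=(0, 1))


@dataclass
class Posterior:
    model: str
    config: MCMCConfig
    groups: dict[str, GroupPosterior]
    covariates: str | None = None

    @property
    def converged(self) -> bool:
        return all(g.converged for g in self.groups.values())

    def __getitem__(self, group: str) -> GroupPosterior:
        return self.groups[group]


def _halfnormal_logpdf(sigma: np.ndarray, scale: float) -> np.ndarray:
    return -0.5 * (sigma / scale) ** 2


def _fit_group_hba(
    sessions: list[Session],
    model: str,
    config: MCMCConfig,
    seed: int,
    ages: np.ndarray | None,
) -> GroupPosterior:
    names = PARAM_NAMES[model]
    k = len(names)
    bounds = param_bounds(model)
    n = len(sessions)
    choices, wins, losses, horizons = pack_sessions(sessions)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def loglik_all(Z: np.ndarray) -> np.ndarray:
        nat = lo + (hi - lo) * ndtr(Z)
        if k == 3:
            nat = np.concatenate([nat, np.zeros((n, 1))], axis=1)
        return cohort_loglik(choices, wins, losses, horizons, nat, model)

    use_age = ages is not None
    a = ages if use_age else np.zeros(n)

    mu_store = np.empty((config.chains, config.draws, k))
    sig_store = np.empty((config.chains, config.draws, k))
    subj_store = np.empty((config.chains, config.draws, n, k))
    beta_store = np.empty((config.chains, config.draws, k)) if use_age else None

    total = config.warmup + config.draws * config.thin
    for chain in range(config.chains):
        rng = np.random.default_rng(seed + 101 * chain)
        Z = 0.1 * rng.standard_normal((n, k))
        mu = np.zeros(k)
        sigma = np.full(k, 0.5)
        beta = np.zeros(k)
        step_z = np.full(n, 0.3)
        step_zc = np.full(k, 0.3)
        step_sh = np.full(k, 0.3)
        step_s = np.full(k, 0.3)
        ll = loglik_all(Z)
        kept = 0
        for sweep in range(total):
            in_warmup = sweep < config.warmup
            m_i = mu[None, :] + (beta[None, :] * a[:, None] if use_age else 0.0)
            # --- subject latents: blocked RW Metropolis, vectorized ---
            prop = Z + step_z[:, None] * rng.standard_normal((n, k))
            ll_prop = loglik_all(prop)
            lp_cur = -0.5 * (((Z - m_i) / sigma[None, :]) ** 2).sum(axis=1)
            lp_prop = -0.5 * (((prop - m_i) / sigma[None, :]) ** 2).sum(axis=1)
            log_acc = (ll_prop + lp_prop) - (ll + lp_cur)
            accept = np.log(rng.uniform(size=n)) < log_acc
            Z[accept] = prop[accept]
            ll[accept] = ll_prop[accept]
            if in_warmup:
                step_z *= np.exp(0.05 * (accept.astype(float) - 0.25))
                np.clip(step_z, 1e-3, 5.0, out=step_z)
            # --- subject latents: componentwise passes ---
            for kk in range(k):
                prop = Z.copy()
                prop[:, kk] += step_zc[kk] * rng.standard_normal(n)
                ll_prop = loglik_all(prop)
                dlp = -0.5 * (
                    ((prop[:, kk] - m_i[:, kk]) ** 2 - (Z[:, kk] - m_i[:, kk]) ** 2)
                    / sigma[kk] ** 2
                )
                accept = np.log(rng.uniform(size=n)) < (ll_prop - ll + dlp)
                Z[accept] = prop[accept]
                ll[accept] = ll_prop[accept]
                if in_warmup:
                    step_zc[kk] *= np.exp(0.05 * (accept.mean() - 0.44))
                    step_zc[kk] = min(max(step_zc[kk], 1e-3), 5.0)
            # --- joint shift of one latent column and its hypermean ---
            for kk in range(k):
                delta = step_sh[kk] * rng.standard_normal()
                prop = Z.copy()
                prop[:, kk] += delta
                mu_prop = mu[kk] + delta
                ll_prop = loglik_all(prop)
                dlp = 0.5 * (mu[kk] ** 2 - mu_prop**2) / HYPERMEAN_PRIOR_SD**2
                if np.log(rng.uniform()) < (ll_prop.sum() - ll.sum() + dlp):
                    Z = prop
                    ll = ll_prop
                    mu[kk] = mu_prop
                    acc = 1.0
                else:
                    acc = 0.0
                if in_warmup:
                    step_sh[kk] *= np.exp(0.05 * (acc - 0.25))
                    step_sh[kk] = min(max(step_sh[kk], 1e-3), 5.0)
            # --- hypermeans: conjugate Gibbs ---
            resid = Z - (beta[None, :] * a[:, None] if use_age else 0.0)
            prec = n / sigma**2 + 1.0 / HYPERMEAN_PRIOR_SD**2
            mean = (resid.sum(axis=0) / sigma**2) / prec
            mu = mean + rng.standard_normal(k) / np.sqrt(prec)
            # --- age slope: conjugate Gibbs ---
            if use_age:
                sa2 = float(np.sum(a**2))
                prec_b = sa2 / sigma**2 + 1.0 / AGE_SLOPE_PRIOR_SD**2
                mean_b = ((a[:, None] * (Z - mu[None, :])).sum(axis=0) / sigma**2) / prec_b
                beta = mean_b + rng.standard_normal(k) / np.sqrt(prec_b)
            # --- hyper-SDs: log-scale RW Metropolis ---
            m_i = mu[None, :] + (beta[None, :] * a[:, None] if use_age else 0.0)
            dev2 = ((Z - m_i) ** 2).sum(axis=0)
            log_sig_prop = np.log(sigma) + step_s * rng.standard_normal(k)
            sig_prop = np.exp(log_sig_prop)

            def sig_logpost(s):
                return (
                    -n * np.log(s)
                    - 0.5 * dev2 / s**2
                    + _halfnormal_logpdf(s, HYPERSD_PRIOR_SCALE)
                    + np.log(s)  # Jacobian of the log transform
                )

            log_acc_s = sig_logpost(sig_prop) - sig_logpost(sigma)
            acc_s = np.log(rng.uniform(size=k)) < log_acc_s
            sigma = np.where(acc_s, sig_prop, sigma)
            if in_warmup:
                step_s *= np.exp(0.05 * (acc_s.astype(float) - 0.44))
                np.clip(step_s, 1e-3, 5.0, out=step_s)
            # --- record ---
            if not in_warmup and (sweep - config.warmup) % config.thin == config.thin - 1:
                mu_store[chain, kept] = mu
                sig_store[chain, kept] = sigma
                subj_store[chain, kept] = lo + (hi - lo) * ndtr(Z)
                if use_age:
                    beta_store[chain, kept] = beta
                kept += 1
        assert kept == config.draws

    group_mean = lo + (hi - lo) * ndtr(mu_store / np.sqrt(1.0 + sig_store**2))

    import arviz as az

    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    for j, name in enumerate(names):
        for label, arr in (
            (f"group_mean_{name}", group_mean[:, :, j]),
            (f"mu_{name}", mu_store[:, :, j]),
            (f"sigma_{name}", sig_store[:, :, j]),
        ):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat[label] = float(az.rhat(arr))
                ess[label] = float(az.ess(arr))
    converged = all(np.isnan(v) or v <= RHAT_THRESHOLD for v in rhat.values())
    if not converged:
        worst = max(rhat, key=lambda q: rhat[q] if np.isfinite(rhat[q]) else 0)
        warnings.warn(
            f"group {sessions[0].group!r}: split-Rhat {rhat[worst]:.3f} for {worst} "
            f"exceeds {RHAT_THRESHOLD}; posterior flagged non-converged"
        )
    return GroupPosterior(
        group=sessions[0].group,
        model=model,
        param_names=names,
        subject_ids=[s.subject_id for s in sessions],
        mu=mu_store,
        sigma=sig_store,
        subject_params=subj_store,
        group_mean=group_mean,
        beta=beta_store,
        rhat=rhat,
        ess=ess,
        converged=converged,
    )


def fit_hba(
    dataset: CohortDataset,
    model: str = "pvl_decay",
    mcmc_config: MCMCConfig | None = None,
    covariates: str | None = None,
) -> Posterior:
    """Hierarchical Bayesian fit, one hierarchy per group.

    With ``covariates="age"``, each parameter's latent group mean gains a
    linear term beta * (age - cohort mean)/cohort SD; group means are then
    reported at the cohort-average age.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if covariates not in (None, "age"):
        raise ValueError("covariates must be None or 'age'")
    config = mcmc_config or MCMCConfig()
    groups = dataset.groups
    for g in groups:
        if len(dataset.by_group(g)) < 2:
            raise ValueError(f"group {g!r} needs at least 2 subjects")
    age_std = None
    if covariates == "age":
        all_ages = [s.age for s in dataset.sessions]
        if any(v is None for v in all_ages):
            raise ValueError("covariates='age' requires an age for every subject")
        arr = np.asarray(all_ages, dtype=float)
        age_std = {s.subject_id: (s.age - arr.mean()) / arr.std() for s in dataset.sessions}
    out: dict[str, GroupPosterior] = {}
    for gi, g in enumerate(groups):
        sessions = dataset.by_group(g)
        ages = (
            np.array([age_std[s.subject_id] for s in sessions]) if age_std is not None else None
        )
        out[g] = _fit_group_hba(
            sessions, model, config, seed=config.seed + 7919 * gi, ages=ages
        )
    return Posterior(model=model, config=config, groups=out, covariates=covariates)


# ---------------------------------------------------------------------------
# Group differences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupDifference:
    param: str
    group_a: str
    group_b: str
    mean: float
    hdi: HDInterval
    credible: bool


def group_difference(
    posterior: Posterior, param: str, group_a: str, group_b: str, mass: float = 0.95
) -> GroupDifference:
    """Draw-wise difference of natural-scale group means (a minus b) with
    its HDI; the difference is credible when the HDI excludes zero."""
    for g in (group_a, group_b):
        if g not in posterior.groups:
            raise KeyError(f"group {g!r} not in posterior")
    if param not in posterior.groups[group_a].param_names:
        raise KeyError(f"parameter {param!r} not in posterior")
    da = posterior[group_a].group_mean_draws(param)
    db = posterior[group_b].group_mean_draws(param)
    diff = da - db
    if group_a == group_b:
        return GroupDifference(param, group_a, group_b, 0.0, HDInterval(0.0, 0.0, mass), False)
    hdi = compute_hdi(diff, mass=mass)
    return GroupDifference(
        param=param,
        group_a=group_a,
        group_b=group_b,
        mean=float(diff.mean()),
        hdi=hdi,
        credible=not hdi.contains(0.0),
    )
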