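"""Synthetic four-group cohorts with the study's statistical structure.

The study cohort (57 women in four HIV-status x drug-use-history groups)
is not public, so analyses are exercised on synthetic cohorts that emulate
its design: group sizes 14/17/14/12, up to 100 trials per subject on the
modified IGT, choices generated by the PVL decay-reinforcement model with
group-level parameter distributions matching the published group summaries
(``PUBLISHED_PRESETS``), and ages drawn from the published group means/SDs.

Subject parameters are probit-transformed normals on the latent scale; the
latent hypermean/hyper-SD of each preset is calibrated in closed form so
the population mean and SD of the natural-scale draws equal the preset
values exactly (see :mod:`igtrl.transforms`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .models import PVLParams, params_from_array, simulate_agent
from .task import DECKS, Outcome, PayoffSchedule, Session, Trial, build_payoff_schedule
from .transforms import calibrate_latent, param_bounds, to_natural

GROUP_LABELS = ("HIV+/DU+", "HIV+/DU-", "HIV-/DU+", "HIV-/DU-")

# Published group summaries: natural-scale mean (SD) per PVL parameter.
PUBLISHED_PRESETS = {
    "HIV+/DU+": {"A": (0.20, 0.04), "alpha": (0.38, 0.04), "c": (0.49, 0.40), "lam": (0.06, 0.01)},
    "HIV+/DU-": {"A": (0.50, 0.19), "alpha": (0.26, 0.02), "c": (0.55, 0.38), "lam": (0.25, 0.16)},
    "HIV-/DU+": {"A": (0.21, 0.06), "alpha": (0.36, 0.03), "c": (0.62, 0.38), "lam": (0.07, 0.01)},
    "HIV-/DU-": {"A": (0.64, 0.18), "alpha": (0.18, 0.02), "c": (0.36, 0.30), "lam": (1.84, 0.75)},
}

# Published group ages: mean (SD), years.
AGE_PRESETS = {
    "HIV+/DU+": (43.3, 4.9),
    "HIV+/DU-": (38.8, 8.3),
    "HIV-/DU+": (40.6, 7.1),
    "HIV-/DU-": (33.5, 8.5),
}

DEFAULT_GROUP_SIZES = {"HIV+/DU+": 14, "HIV+/DU-": 17, "HIV-/DU+": 14, "HIV-/DU-": 12}
AGE_RANGE = (18.0, 80.0)


@dataclass(frozen=True)
class GroupSpec:
    """One group's generating distribution: natural-scale mean/SD targets
    per parameter (keys alpha, lam, A, c) plus an optional age distribution."""

    label: str
    n: int
    params: dict[str, tuple[float, float]]
    age: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label}: n must be >= 1")
        for name, (_, sd) in self.params.items():
            if sd < 0:
                raise ValueError(f"group {self.label}: hyper-SD for {name} must be >= 0")

    @classmethod
    def from_preset(cls, label: str, n: int | None = None) -> "GroupSpec":
        if label not in PUBLISHED_PRESETS:
            raise KeyError(f"no preset for group {label!r}")
        return cls(
            label=label,
            n=n if n is not None else DEFAULT_GROUP_SIZES[label],
            params=PUBLISHED_PRESETS[label],
            age=AGE_PRESETS[label],
        )


@dataclass(frozen=True)
class StudyDesign:
    """Full cohort recipe: ordered group specs, trials per subject, payoff
    escalation, generating model, master seed."""

    groups: tuple[GroupSpec, ...]
    n_trials: int = 100
    escalation_rate: float = 0.1
    model: str = "pvl_decay"
    seed: int = 0

    @classmethod
    def default(
        cls,
        seed: int = 0,
        n_trials: int = 100,
        group_sizes: tuple[int, int, int, int] | None = None,
    ) -> "StudyDesign":
        sizes = group_sizes or tuple(DEFAULT_GROUP_SIZES[g] for g in GROUP_LABELS)
        return cls(
            groups=tuple(GroupSpec.from_preset(g, n) for g, n in zip(GROUP_LABELS, sizes)),
            n_trials=n_trials,
            seed=seed,
        )


@dataclass
class CohortDataset:
    """A collection of labeled sessions (one per subject)."""

    sessions: list[Session] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.sessions]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.sessions)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.sessions:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def by_group(self, label: str) -> list[Session]:
        return [s for s in self.sessions if s.group == label]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sessions:
            for t in s.trials:
                rows.append(
                    {
                        "subject_id": s.subject_id,
                        "group": s.group,
                        "trial": t.trial_index,
                        "deck": t.deck,
                        "win": t.outcome.win,
                        "loss": t.outcome.loss,
                    }
                )
        return pd.DataFrame(rows)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"subject_id": s.subject_id, "group": s.group, "age": s.age} for s in self.sessions]
        )

    def depletion_rate(self) -> float:
        """Fraction of subjects whose modeling horizon was truncated by
        deck depletion."""
        if not self.sessions:
            return 0.0
        return float(np.mean([s.modeling_horizon < len(s) for s in self.sessions]))


def sample_group_parameters(spec: GroupSpec, seed: int, model: str = "pvl_decay") -> list:
    """Draw n parameter sets for one group.

    Each parameter is drawn as a probit-transformed normal on the latent
    scale, with latent (mu, sigma) calibrated so the population mean/SD on
    the natural scale equal the group's targets; every draw therefore lies
    strictly inside its bounds.
    """
    rng = np.random.default_rng(seed)
    bounds = param_bounds(model)
    from .transforms import PARAM_NAMES

    names = PARAM_NAMES[model]
    z = np.empty((spec.n, len(names)))
    for k, name in enumerate(names):
        mean, sd = spec.params[name]
        lo, hi = bounds[k]
        if sd == 0:
            from scipy.special import ndtri

            z[:, k] = ndtri((mean - lo) / (hi - lo))
        else:
            mu, sigma = calibrate_latent(mean, sd, lo, hi)
            z[:, k] = mu + sigma * rng.standard_normal(spec.n)
    natural = to_natural(z, bounds)
    return [params_from_array(model, natural[i]) for i in range(spec.n)]


def _sample_ages(spec: GroupSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.age is None:
        return np.full(spec.n, np.nan)
    mean, sd = spec.age
    lo, hi = AGE_RANGE
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=spec.n, random_state=rng)


def generate_cohort(design: StudyDesign, schedule: PayoffSchedule | None = None) -> CohortDataset:
    """Simulate one session per subject under the design's generating model.

    Deterministic given the design: parameters and ages for group g use
    seed ``design.seed + 10000*(g+1)``; subject session seeds are
    ``design.seed + ordinal`` with ordinals counted across the whole cohort.
    """
    if schedule is None:
        schedule = build_payoff_schedule(design.escalation_rate)
    sessions: list[Session] = []
    ordinal = 0
    for g, spec in enumerate(design.groups):
        params = sample_group_parameters(spec, seed=design.seed + 10000 * (g + 1), model=design.model)
        age_rng = np.random.default_rng(design.seed + 10000 * (g + 1) + 5000)
        ages = _sample_ages(spec, age_rng)
        for i in range(spec.n):
            ordinal += 1
            sid = f"S{ordinal:03d}"
            sess = simulate_agent(
                params[i],
                schedule,
                design.model,
                n_trials=design.n_trials,
                seed=design.seed + ordinal,
                subject_id=sid,
                group=spec.label,
            )
            sess.age = float(ages[i]) if np.isfinite(ages[i]) else None
            sessions.append(sess)
    return CohortDataset(sessions=sessions)


# ---------------------------------------------------------------------------
# Cohort CSV I/O
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("subject_id", "group", "trial", "deck", "win", "loss")


def write_cohort_csv(dataset: CohortDataset, path, metadata_path=None) -> None:
    dataset.to_frame().to_csv(path, index=False)
    if metadata_path is not None:
        dataset.metadata_frame().to_csv(metadata_path, index=False)


def read_cohort_csv(path, metadata_path=None) -> CohortDataset:
    """Read a long-format cohort CSV, validating structure row by row.

    Raises ``ValueError`` naming the offending rows for unknown deck
    labels, duplicated (subject, trial) pairs, non-contiguous trial
    indices, or missing columns.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing column(s): {missing}")
    bad_deck = df.loc[~df["deck"].isin(DECKS)]
    if len(bad_deck):
        rows = (bad_deck.index + 2).tolist()[:5]  # +2: header + 1-based
        raise ValueError(
            f"unknown deck label(s) {sorted(bad_deck['deck'].unique())} at CSV row(s) {rows}"
        )
    dup = df.duplicated(subset=["subject_id", "trial"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:5]
        raise ValueError(f"duplicated (subject_id, trial) pairs at CSV row(s) {rows}")

    ages: dict[str, float] = {}
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path)
        for _, r in meta.iterrows():
            if pd.notna(r.get("age")):
                ages[str(r["subject_id"])] = float(r["age"])

    sessions = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("trial")
        idx = grp["trial"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise ValueError(f"subject {sid}: trial indices not contiguous from 1")
        labels = grp["group"].unique()
        if len(labels) != 1:
            raise ValueError(f"subject {sid}: inconsistent group labels {labels.tolist()}")
        trials = [
            Trial(
                subject_id=str(sid),
                trial_index=int(t),
                deck=str(d),
                outcome=Outcome(int(w), int(l)),
            )
            for t, d, w, l in zip(grp["trial"], grp["deck"], grp["win"], grp["loss"])
        ]
        sessions.append(
            Session(
                subject_id=str(sid),
                group=str(labels[0]),
                trials=trials,
                age=ages.get(str(sid)),
            )
        )
    return CohortDataset(sessions=sessions)
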