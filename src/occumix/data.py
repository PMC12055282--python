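"""Core data containers: event records, datasets, model specifications.

The unit of analysis is one signalling event observed for one individual in
one observation window ("period": the stretch of video before or after the
tree-directed activity), scored for whether each of six accompanying
behaviours occurred at least once while the individual was visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

ACTIVITIES = ("drum", "stone_and_drum", "stone")
PERIODS = ("before", "after", "combined")
BEHAVIOURS = (
    "pant_hoot",
    "climax_scream",
    "piloerection",
    "swaying",
    "sound_surround",
    "alert_focus_environment",
)

#: fixed-effect term names: intercept plus the two activity contrasts
#: (dummy coding with drumming as the reference level)
TERM_NAMES = ("intercept", "beh_st_dr", "beh_st")

#: columns every event table must carry
REQUIRED_COLUMNS = (
    "individual_id",
    "site",
    "activity",
    "period",
    "duration_s",
    "behaviour",
    "occurred",
)


class OccurrenceRecord(NamedTuple):
    """One signalling event x one behaviour x one observation window."""

    individual_id: str
    site: str
    activity: str
    period: str
    duration_s: float
    behaviour: str
    occurred: int
    event_id: str = ""


def _validate_events(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing required columns: {missing}")
    for col, allowed in (
        ("activity", ACTIVITIES),
        ("period", PERIODS),
        ("behaviour", BEHAVIOURS),
    ):
        bad = sorted(set(df[col].astype(str)) - set(allowed))
        if bad:
            raise ValueError(f"unknown {col} label(s): {bad}; allowed: {list(allowed)}")
    occ = df["occurred"].to_numpy()
    if not np.isin(occ, (0, 1)).all():
        bad_rows = df.index[~np.isin(occ, (0, 1))].tolist()
        raise ValueError(f"occurred must be 0/1; offending rows (0-based): {bad_rows[:10]}")
    dur = df["duration_s"].to_numpy(dtype=float)
    if not np.all(dur >= 1):
        bad_rows = df.index[dur < 1].tolist()
        raise ValueError(f"duration_s must be >= 1; offending rows (0-based): {bad_rows[:10]}")
    if df[list(REQUIRED_COLUMNS)].isna().any().any():
        raise ValueError("missing values are not permitted in model columns")


@dataclass
class Dataset:
    """A validated table of occurrence records.

    Wraps a tidy :class:`pandas.DataFrame` with one row per
    event x behaviour x period.  ``metadata`` records provenance (the
    generating simulation config, or the source file path).
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        _validate_events(self.df)

    @property
    def individuals(self) -> set:
        return set(self.df["individual_id"].astype(str))

    @property
    def records(self) -> list[OccurrenceRecord]:
        cols = list(REQUIRED_COLUMNS)
        has_event = "event_id" in self.df.columns
        recs = []
        for row in self.df.itertuples(index=False):
            recs.append(
                OccurrenceRecord(
                    individual_id=str(row.individual_id),
                    site=str(row.site),
                    activity=row.activity,
                    period=row.period,
                    duration_s=float(row.duration_s),
                    behaviour=row.behaviour,
                    occurred=int(row.occurred),
                    event_id=str(row.event_id) if has_event else "",
                )
            )
        return recs

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, behaviour: str, period: str) -> "Dataset":
        """Rows for one (behaviour, period) model."""
        mask = (self.df["behaviour"] == behaviour) & (self.df["period"] == period)
        sub = self.df.loc[mask]
        if sub.empty:
            raise ValueError(f"no records for behaviour={behaviour!r}, period={period!r}")
        return Dataset(sub.copy(), metadata=dict(self.metadata))

    def equals(self, other: "Dataset") -> bool:
        a = self.df[list(REQUIRED_COLUMNS)].astype(str).reset_index(drop=True)
        b = other.df[list(REQUIRED_COLUMNS)].astype(str).reset_index(drop=True)
        return a.equals(b)


def dataset_from_records(records: Iterable[OccurrenceRecord], metadata: dict | None = None) -> Dataset:
    df = pd.DataFrame([r._asdict() for r in records])
    return Dataset(df, metadata=metadata or {})


@dataclass(frozen=True)
class ModelSpec:
    """Which (behaviour, period) is modelled and with which fixed effects.

    ``include_activity=False`` gives the intercept-only reduced model used in
    the likelihood-ratio test for the activity-type effect.
    """

    behaviour: str
    period: str
    include_activity: bool = True

    def __post_init__(self) -> None:
        if self.behaviour not in BEHAVIOURS:
            raise ValueError(f"unknown behaviour {self.behaviour!r}")
        if self.period not in PERIODS:
            raise ValueError(f"unknown period {self.period!r}")

    @property
    def n_fixed(self) -> int:
        return 3 if self.include_activity else 1

    def reduced(self) -> "ModelSpec":
        return ModelSpec(self.behaviour, self.period, include_activity=False)

    def label(self) -> str:
        return f"{self.behaviour}_{self.period}"


#: the study's model battery: four behaviours in both windows, swaying only
#: before (it occurred almost never afterwards), climax screams only after
#: (they occurred almost never beforehand)
DEFAULT_MODEL_BATTERY: tuple[ModelSpec, ...] = tuple(
    ModelSpec(b, p)
    for b in BEHAVIOURS
    for p in ("before", "after")
    if not (b == "climax_scream" and p == "before")
    and not (b == "swaying" and p == "after")
)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the occurrence model.

    beta  : (3,) fixed effects on the logit scale — intercept, contrast
            stone_and_drum vs drum, contrast stone vs drum.
    sigma : SD of the individual random intercept, >= 0.
    B     : per-second baseline occurrence probability in (0, 1); enters the
            model only through the duration offset.
    """

    beta: tuple
    sigma: float
    B: float

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        if beta.ndim != 1:
            raise ValueError("beta must be a 1-D vector")
        object.__setattr__(self, "beta", tuple(float(b) for b in beta))
        if not np.all(np.isfinite(beta)):
            raise ValueError("beta must be finite")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not (0.0 < self.B < 1.0):
            raise ValueError(f"B must lie strictly inside (0, 1), got {self.B}")

    @property
    def beta_array(self) -> np.ndarray:
        return np.asarray(self.beta, dtype=float)


@dataclass
class FittedModel:
    """Result of maximizing the marginal likelihood for one model."""

    params: ModelParams
    se_beta: np.ndarray
    loglik: float
    converged: bool
    boundary_sigma: bool
    B_fixed: bool
    n_obs: int
    n_individuals: int
    model_spec: ModelSpec
    separation: bool = False
    messages: list = field(default_factory=list)

    @property
    def term_names(self) -> tuple:
        return TERM_NAMES if self.model_spec.include_activity else TERM_NAMES[:1]


@dataclass
class SimulationConfig:
    """Ground truth and design for a synthetic ethogram dataset.

    Defaults mirror the study design wherever the design is known: durations
    are integer seconds in [1, 61] (visibility windows ran from 1 s to
    1 min 1 s), activity type is a three-level factor dummy coded with
    drumming as reference, and occurrence is Bernoulli on the logit scale
    with an individual random intercept and the duration offset.
    """

    n_individuals: int = 28
    events_per_individual: int | Sequence[int] = 5
    activity_probs: tuple = (0.5, 0.15, 0.35)
    true_B: float = 0.05
    true_beta: tuple = (0.0, 0.0, 0.0)
    true_sigma: float = 1.0
    seed: int = 0
    duration_probs: Sequence[float] | None = None  # over integers 1..61; None = uniform
    behaviour: str = "pant_hoot"
    period: str = "before"
    site: str = "site_1"
    mechanism: str = "model"  # "model" or "per_second" (cross-check generator)

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        probs = np.asarray(self.activity_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(
                "activity_probs must be a 3-vector simplex summing to 1 within 1e-12"
            )
        if not (0.0 < self.true_B < 1.0):
            raise ValueError(f"true_B must lie strictly inside (0, 1), got {self.true_B}")
        if self.true_sigma < 0:
            raise ValueError(f"true_sigma must be >= 0, got {self.true_sigma}")
        beta = np.asarray(self.true_beta, dtype=float)
        if beta.shape != (3,):
            raise ValueError("true_beta must have 3 components (intercept + 2 contrasts)")
        if np.isscalar(self.events_per_individual):
            if int(self.events_per_individual) < 1:
                raise ValueError("events_per_individual must be >= 1")
        else:
            counts = np.asarray(self.events_per_individual, dtype=int)
            if counts.shape != (self.n_individuals,) or (counts < 1).any():
                raise ValueError(
                    "per-individual event counts need one entry >= 1 per individual"
                )
        if self.duration_probs is not None:
            dp = np.asarray(self.duration_probs, dtype=float)
            if dp.shape != (61,) or (dp < 0).any() or abs(dp.sum() - 1.0) > 1e-9:
                raise ValueError("duration_probs must be 61 non-negative values summing to 1")
        if self.behaviour not in BEHAVIOURS:
            raise ValueError(f"unknown behaviour {self.behaviour!r}")
        if self.period not in PERIODS:
            raise ValueError(f"unknown period {self.period!r}")
        if self.mechanism not in ("model", "per_second"):
            raise ValueError("mechanism must be 'model' or 'per_second'")

    @property
    def event_counts(self) -> np.ndarray:
        if np.isscalar(self.events_per_individual):
            return np.full(self.n_individuals, int(self.events_per_individual))
        return np.asarray(self.events_per_individual, dtype=int)
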