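"""Synthetic cohorts for the retroactive-avoidance design.

Each participant completes ``n_trials`` binary trials.  A trial's outcome is
the XOR of two bits: a *prestored* bit drawn before the session and a *live*
bit drawn at response time (in the original apparatus both came from a
hardware quantum RNG; here a seeded PRNG stands in, which is statistically
indistinguishable for calibration purposes).  Outcome bit 1 shows a negative
masked picture, 0 a neutral one, so under fair bits the per-participant count
of negative pictures is Binomial(n_trials, 1/2) with chance level
n_trials / 2.

An avoidance effect is injected by biasing the *live* bit conditionally on
the prestored bit so that the XOR is Bernoulli(p_negative) with
p_negative < 1/2, preserving the two-bit trial schema in both regimes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrialRecord",
    "ParticipantRecord",
    "CohortSpec",
    "FIVE_LAB_SIZES",
    "VALENCE_BY_OUTCOME",
    "generate_trials",
    "generate_participant",
    "generate_cohort",
    "simulate_null_counts",
    "cohort_to_frame",
    "trials_to_frame",
    "effect_probability",
]

#: Outcome-bit to picture-valence mapping (fixed design constant).
VALENCE_BY_OUTCOME = {0: "neutral", 1: "negative"}

#: Per-lab sizes of the five-lab replication cohort, in descending size
#: (Germany, Italy, Russia, France, Sweden); total N = 2004.
FIVE_LAB_SIZES = (
    ("Germany", 1413),
    ("Italy", 235),
    ("Russia", 154),
    ("France", 103),
    ("Sweden", 99),
)


@dataclass(frozen=True)
class TrialRecord:
    participant_id: str
    trial_index: int  # 1..n_trials
    prestored_bit: int
    live_bit: int
    outcome_bit: int  # prestored XOR live
    valence: str  # VALENCE_BY_OUTCOME[outcome_bit]


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    lab_label: str
    collection_order: int
    n_trials: int
    negative_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.negative_count <= self.n_trials:
            raise ValueError(
                f"negative_count {self.negative_count} outside [0, {self.n_trials}]"
            )
        if self.collection_order < 1:
            raise ValueError("collection_order must be a positive integer")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a reproducible multi-lab cohort.

    ``labs`` is an ordered sequence of (label, size) pairs; participants from
    different labs are randomly interleaved in collection order, mimicking
    parallel multi-site data collection.
    """

    labs: tuple = FIVE_LAB_SIZES
    n_trials: int = 60
    p_negative: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        labs = tuple((str(label), int(size)) for label, size in self.labs)
        object.__setattr__(self, "labs", labs)
        labels = [label for label, _ in labs]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate lab labels in {labels}")
        if any(size < 1 for _, size in labs):
            raise ValueError("every lab size must be >= 1")
        if self.total_size < 2:
            raise ValueError("cohort must contain at least 2 participants")
        _check_probability(self.p_negative)
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def total_size(self) -> int:
        return sum(size for _, size in self.labs)


def _check_probability(p: float) -> None:
    if not 0.0 < p < 1.0:
        raise ValueError(f"p_negative must lie strictly in (0, 1), got {p}")


def generate_trials(
    participant_id: str,
    n_trials: int,
    p_negative: float,
    rng: np.random.Generator,
) -> list[TrialRecord]:
    """Trial-level records with the two-bit XOR randomization.

    The prestored bit is always fair.  The outcome bit is Bernoulli
    (p_negative) and the live bit is derived as outcome XOR prestored, i.e.
    the effect is carried entirely by the live bit while the XOR identity
    holds exactly on every trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    _check_probability(p_negative)
    prestored = rng.integers(0, 2, size=n_trials)
    outcome = (rng.random(n_trials) < p_negative).astype(np.int64)
    live = prestored ^ outcome
    return [
        TrialRecord(
            participant_id=participant_id,
            trial_index=i + 1,
            prestored_bit=int(prestored[i]),
            live_bit=int(live[i]),
            outcome_bit=int(outcome[i]),
            valence=VALENCE_BY_OUTCOME[int(outcome[i])],
        )
        for i in range(n_trials)
    ]


def generate_participant(
    lab_label: str,
    order: int,
    n_trials: int,
    p_negative: float,
    rng: np.random.Generator,
    participant_id: str | None = None,
) -> ParticipantRecord:
    """Aggregate one participant: negative_count ~ Binomial(n_trials, p_negative)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    _check_probability(p_negative)
    count = int(rng.binomial(n_trials, p_negative))
    return ParticipantRecord(
        participant_id=participant_id or f"{lab_label}-{order:05d}",
        lab_label=lab_label,
        collection_order=order,
        n_trials=n_trials,
        negative_count=count,
    )


def generate_cohort(spec: CohortSpec) -> list[ParticipantRecord]:
    """Full multi-lab cohort, randomly interleaved, ordered 1..N.

    A pure function of the spec: the same seed reproduces the cohort
    bit-for-bit.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.repeat(
        [label for label, _ in spec.labs],
        [size for _, size in spec.labs],
    )
    rng.shuffle(labels)
    counts = rng.binomial(spec.n_trials, spec.p_negative, size=labels.size)
    per_lab_serial: dict[str, int] = {}
    records = []
    for order, (label, count) in enumerate(zip(labels, counts), start=1):
        serial = per_lab_serial.get(label, 0) + 1
        per_lab_serial[label] = serial
        records.append(
            ParticipantRecord(
                participant_id=f"{label}-{serial:05d}",
                lab_label=str(label),
                collection_order=order,
                n_trials=spec.n_trials,
                negative_count=int(count),
            )
        )
    return records


def simulate_null_counts(
    n_participants: int,
    n_trials: int = 60,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """I.i.d. Binomial(n_trials, 1/2) negative counts for a null cohort.

    Equivalent to aggregating n_participants * n_trials fair bits; a cohort
    of 2328 participants with 60 trials each consumes 139,680 bits.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    return rng.binomial(n_trials, 0.5, size=n_participants)


def effect_probability(d: float, n_trials: int = 60) -> float:
    """Per-trial negative probability giving standardized count effect d.

    Solves (n_trials/2 - n_trials*p) / sqrt(n_trials*p*(1-p)) = d; an
    avoidance effect of d = 0.3 at 60 trials corresponds to p ~ 0.4806.
    """
    from scipy.optimize import brentq

    if d == 0:
        return 0.5
    mu0 = n_trials / 2.0

    def gap(p: float) -> float:
        return (mu0 - n_trials * p) / np.sqrt(n_trials * p * (1 - p)) - d

    return float(brentq(gap, 1e-6, 1 - 1e-6))


def cohort_to_frame(records) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "lab": [r.lab_label for r in records],
            "collection_order": [r.collection_order for r in records],
            "n_trials": [r.n_trials for r in records],
            "negative_count": [r.negative_count for r in records],
        }
    )


def trials_to_frame(trials) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in trials],
            "trial_index": [t.trial_index for t in trials],
            "prestored_bit": [t.prestored_bit for t in trials],
            "live_bit": [t.live_bit for t in trials],
            "outcome_bit": [t.outcome_bit for t in trials],
            "valence": [t.valence for t in trials],
        }
    )
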