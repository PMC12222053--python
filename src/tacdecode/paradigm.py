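"""Experimental paradigm and behavioral simulation for the tactile-illusion study.

The paradigm is a block design: in every trial one tactile stimulus type
(Aristotle, Reverse or Asynchronous) is applied twice for 15 s, with a
"how many stimuli?" question (Q1, buttons 1/2) after the first epoch and a
"how far apart?" question (Q2, buttons 1..4) after the second, followed by a
rest period.  A trial therefore cycles stim -> Q1 -> stim -> Q2 -> rest.

Behavior is Bernoulli at the trial level: each responded trial is either an
illusion trial or not.  Under the Aristotle stimulus the illusory percept is
"two objects" (Q1 = 2); under Reverse and Asynchronous it is "one object"
(Q1 = 1).  Both stimulation epochs of a trial share the trial's Q1 response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("Aristotle", "Reverse", "Asynchronous")

#: Q1 button that counts as the illusory percept, per stimulus condition.
ILLUSORY_Q1 = {"Aristotle": 2, "Reverse": 1, "Asynchronous": 1}

EVENT_COLUMNS = [
    "subject",
    "session",
    "trial",
    "condition",
    "epoch1_onset_s",
    "epoch2_onset_s",
    "epoch_duration_s",
    "q1_response",
    "q2_response",
]


class ConfigurationError(ValueError):
    """Raised for invalid paradigm or behavior configurations."""


@dataclass(frozen=True)
class ParadigmConfig:
    """Timing and structure of one participant's scanning paradigm.

    Durations are in seconds.  With the defaults a trial cycle is
    15 + 3 + 15 + 6 + 9 = 48 s, a session holds 15 trials (5 per condition)
    and lasts 720 s, and two sessions give 1,440 s per participant.
    """

    n_sessions: int = 2
    n_trials_per_condition_per_session: int = 5
    stim_duration_s: float = 15.0
    q1_duration_s: float = 3.0
    q2_duration_s: float = 6.0
    rest_duration_s: float = 9.0
    tr_s: float = 3.0
    conditions: tuple[str, ...] = CONDITIONS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stim_duration_s", "q1_duration_s", "q2_duration_s",
                     "rest_duration_s", "tr_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.n_sessions < 0 or self.n_trials_per_condition_per_session < 0:
            raise ConfigurationError("counts must be non-negative")
        if not self.conditions:
            raise ConfigurationError("at least one condition required")

    @property
    def trial_cycle_s(self) -> float:
        return (2 * self.stim_duration_s + self.q1_duration_s
                + self.q2_duration_s + self.rest_duration_s)

    @property
    def n_trials_per_session(self) -> int:
        return len(self.conditions) * self.n_trials_per_condition_per_session

    @property
    def session_duration_s(self) -> float:
        return self.n_trials_per_session * self.trial_cycle_s

    @property
    def total_duration_s(self) -> float:
        return self.n_sessions * self.session_duration_s

    @property
    def n_trs_per_session(self) -> int:
        n = self.session_duration_s / self.tr_s
        return int(round(n))


def generate_paradigm(config: ParadigmConfig, n_subjects: int) -> pd.DataFrame:
    """Build the trial-level event table for a cohort.

    Per subject and session, the condition sequence (each condition repeated
    ``n_trials_per_condition_per_session`` times) is shuffled with a seed
    derived from ``(config.seed, subject, session)`` so tables are
    bit-reproducible.  Response columns are left empty (NaN).
    """
    if n_subjects < 0:
        raise ConfigurationError("n_subjects must be non-negative")
    rows = []
    for subject in range(1, n_subjects + 1):
        for session in range(1, config.n_sessions + 1):
            rng = np.random.default_rng([config.seed, subject, session])
            sequence = np.repeat(
                np.arange(len(config.conditions)),
                config.n_trials_per_condition_per_session,
            )
            rng.shuffle(sequence)
            for trial, cond_idx in enumerate(sequence, start=1):
                start = (trial - 1) * config.trial_cycle_s
                rows.append({
                    "subject": subject,
                    "session": session,
                    "trial": trial,
                    "condition": config.conditions[cond_idx],
                    "epoch1_onset_s": start,
                    "epoch2_onset_s": start + config.stim_duration_s
                    + config.q1_duration_s,
                    "epoch_duration_s": config.stim_duration_s,
                    "q1_response": np.nan,
                    "q2_response": np.nan,
                })
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return events


@dataclass(frozen=True)
class BehaviorModel:
    """Per-condition response distributions.

    ``illusion_prob`` is the probability that a *responded* trial is an
    illusion trial; ``nonresponse_prob`` the probability that a trial gets no
    button press at all (both questions missing).  ``q2_dist`` is a
    categorical distribution over the four distance buttons.  Defaults
    reproduce the cohort-level response frequencies of the study's behavioral
    table (epoch counts 544/596, 212/594, 48/590; 4/600, 6/600, 10/600
    non-responses), with distance distributions ordered
    Aristotle > Asynchronous > Reverse in the mean.
    """

    illusion_prob: dict = field(default_factory=lambda: {
        "Aristotle": 544 / 596,
        "Reverse": 212 / 594,
        "Asynchronous": 48 / 590,
    })
    nonresponse_prob: dict = field(default_factory=lambda: {
        "Aristotle": 2 / 300,
        "Reverse": 3 / 300,
        "Asynchronous": 5 / 300,
    })
    q2_dist: dict = field(default_factory=lambda: {
        "Aristotle": (0.05, 0.15, 0.35, 0.45),
        "Reverse": (0.45, 0.35, 0.15, 0.05),
        "Asynchronous": (0.10, 0.30, 0.40, 0.20),
    })
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, p in self.illusion_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"illusion_prob[{cond}] not in [0,1]")
        for cond, p in self.nonresponse_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"nonresponse_prob[{cond}] not in [0,1]")
        for cond, dist in self.q2_dist.items():
            if abs(sum(dist) - 1.0) > 1e-9 or min(dist) < 0:
                raise ConfigurationError(f"q2_dist[{cond}] is not a distribution")


def simulate_behavior(events: pd.DataFrame, model: BehaviorModel) -> pd.DataFrame:
    """Fill Q1/Q2 responses of an empty event table from a BehaviorModel.

    Returns a copy; the input is not modified.  Unknown condition names
    raise ``ConfigurationError``.
    """
    if events["q1_response"].notna().any():
        raise ValueError("event table already has responses")
    unknown = set(events["condition"]) - set(model.illusion_prob)
    if unknown:
        raise ConfigurationError(f"unknown condition(s): {sorted(unknown)}")
    rng = np.random.default_rng(model.seed)
    out = events.copy()
    q1 = np.full(len(out), np.nan)
    q2 = np.full(len(out), np.nan)
    # iterate in row order for reproducibility
    for i, (_, row) in enumerate(out.iterrows()):
        cond = row["condition"]
        if rng.random() < model.nonresponse_prob.get(cond, 0.0):
            continue
        illusory = rng.random() < model.illusion_prob[cond]
        ill_q1 = ILLUSORY_Q1[cond]
        q1[i] = ill_q1 if illusory else (3 - ill_q1)
        q2[i] = 1 + rng.choice(4, p=np.asarray(model.q2_dist[cond]))
    out["q1_response"] = q1
    out["q2_response"] = q2
    return out


def assign_responses_from_counts(events: pd.DataFrame,
                                 counts: dict) -> pd.DataFrame:
    """Deterministically transcribe exact response counts onto an event table.

    ``counts`` maps condition -> ``{1: n_one, 2: n_two, None: n_nonresponse}``
    at the *trial* level.  Trials of each condition (in row order) are
    assigned Q1 = 1, then Q1 = 2, then no response.  Used to reconstruct a
    cohort whose response frequencies match a printed behavioral table
    exactly.  Q2 is left empty.
    """
    out = events.copy()
    q1 = np.full(len(out), np.nan)
    for cond, cnt in counts.items():
        idx = np.flatnonzero((out["condition"] == cond).to_numpy())
        n1, n2 = cnt.get(1, 0), cnt.get(2, 0)
        n_none = cnt.get(None, 0)
        if n1 + n2 + n_none != len(idx):
            raise ValueError(
                f"{cond}: counts sum to {n1 + n2 + n_none}, "
                f"but table has {len(idx)} trials")
        q1[idx[:n1]] = 1
        q1[idx[n1:n1 + n2]] = 2
    out["q1_response"] = q1
    out["q2_response"] = np.nan
    return out


def is_illusion_trial(events: pd.DataFrame) -> pd.Series:
    """Boolean series: responded trial whose Q1 is the illusory percept."""
    ill = events["condition"].map(ILLUSORY_Q1)
    return events["q1_response"].notna() & (events["q1_response"] == ill)


@dataclass
class BehaviorSummary:
    """Cohort- and subject-level behavioral summaries.

    ``illusion_rate``: per-condition proportion of illusion trials among
    responded trials.  ``mean_distance``: per-condition mean Q2 response.
    ``per_subject``: the same two quantities per subject (DataFrame indexed
    by subject with a column per condition, NaN where a subject has no
    responded trial of that condition).
    """

    illusion_rate: pd.Series
    mean_distance: pd.Series
    per_subject_rate: pd.DataFrame
    per_subject_distance: pd.DataFrame


def summarize_behavior(events: pd.DataFrame) -> BehaviorSummary:
    """Illusion rates and perceived distances, excluding non-responses.

    Raises ``ValueError`` if any condition has zero responded trials (the
    rate is then undefined).
    """
    ev = events.copy()
    ev["illusion"] = is_illusion_trial(ev)
    responded = ev[ev["q1_response"].notna()]
    rates = {}
    for cond in pd.unique(ev["condition"]):
        sub = responded[responded["condition"] == cond]
        if len(sub) == 0:
            raise ValueError(
                f"illusion rate undefined: no responded trials in {cond!r}")
        rates[cond] = sub["illusion"].mean()
    illusion_rate = pd.Series(rates, name="illusion_rate")
    mean_distance = (ev[ev["q2_response"].notna()]
                     .groupby("condition")["q2_response"].mean()
                     .rename("mean_distance"))
    per_subject_rate = (responded.groupby(["subject", "condition"])["illusion"]
                        .mean().unstack("condition"))
    per_subject_distance = (ev[ev["q2_response"].notna()]
                            .groupby(["subject", "condition"])["q2_response"]
                            .mean().unstack("condition"))
    return BehaviorSummary(illusion_rate, mean_distance,
                           per_subject_rate, per_subject_distance)


def write_events_tsv(events: pd.DataFrame, path) -> None:
    """Serialize as a BIDS-style events TSV, one row per stimulation epoch.

    Columns: onset, duration, trial_type, subject, session, trial, epoch,
    q1_response, q2_response; missing responses written as ``n/a``.
    """
    rows = []
    for _, r in events.iterrows():
        for epoch, onset in ((1, r["epoch1_onset_s"]), (2, r["epoch2_onset_s"])):
            rows.append({
                "onset": onset,
                "duration": r["epoch_duration_s"],
                "trial_type": r["condition"],
                "subject": r["subject"],
                "session": r["session"],
                "trial": r["trial"],
                "epoch": epoch,
                "q1_response": r["q1_response"],
                "q2_response": r["q2_response"],
            })
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path) -> pd.DataFrame:
    """Read a BIDS-style epoch-level events TSV back to a trial-level table."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    first = df[df["epoch"] == 1].rename(columns={"onset": "epoch1_onset_s"})
    second = df[df["epoch"] == 2][["subject", "session", "trial", "onset"]]
    second = second.rename(columns={"onset": "epoch2_onset_s"})
    merged = first.merge(second, on=["subject", "session", "trial"])
    merged = merged.rename(columns={"trial_type": "condition",
                                    "duration": "epoch_duration_s"})
    merged = merged[EVENT_COLUMNS]
    return merged.reset_index(drop=True)
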