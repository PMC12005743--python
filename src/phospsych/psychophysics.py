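"""Quaternary match-to-sample protocol: trial data model and simulator.

The human task: view a phosphene stimulus, then pick the matching identity
from a 4-way forced-choice screen of high-resolution faces, give a binary
confidence rating, and — when confidence is low — a second choice.  Top-1
correctness counts the first choice only; Top-2 counts either choice
(first-correct implies Top-2 correct).

The design: 36 subjects in six groups (G01-G06) of six, each group seeing
one of six multiple-choice question sets (MC1-MC6); groups 1-3 view
square-bitmap (NGB) phosphenes and groups 4-6 Gaussian (GB) phosphenes.
Each subject answers 720 trials: 9 PIQ levels x 16 facial classes x 5
facial conditions, never seeing the same test image twice.

Because recorded human data are optional inputs, the module also provides
a psychometric response simulator:

    p(correct | P, G) = 1/4 + (3/4 - lapse) * sigmoid(
        slope_pix * log2(P) + slope_gs * log2(G) - threshold_subject)

which reproduces the logarithmic accuracy trend across PIQ levels observed
in 4-way face matching, between-subject threshold variability, and the
confidence/second-choice mechanics.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .faces import human_conditions
from .phosphenes import piq_grid

N_SUBJECTS = 36
N_GROUPS = 6
N_MC_SETS = 6
N_OPTIONS = 4
CHANCE = 1.0 / N_OPTIONS

TRIAL_COLUMNS = [
    "subject_id",
    "group_id",
    "mode",
    "pixels",
    "grayscales",
    "class_id",
    "viewpoint_deg",
    "expression",
    "first_choice",
    "confidence",
    "second_choice",
    "response_time_s",
    "correct_top1",
    "correct_top2",
]


@dataclass(frozen=True)
class ChoiceSet:
    """One 4-way multiple-choice screen: the target plus 3 distractors."""

    target_class: int
    options: tuple[int, int, int, int]
    mc_set_id: int

    def __post_init__(self):
        if len(set(self.options)) != N_OPTIONS:
            raise ValueError("choice set must contain 4 distinct options")
        if self.target_class not in self.options:
            raise ValueError("target must be among the options")
        if not 1 <= self.mc_set_id <= N_MC_SETS:
            raise ValueError(f"mc_set_id must be 1..{N_MC_SETS}")


@dataclass
class PsychometricParams:
    """Simulated-observer sensitivity model.

    ``slope_pix`` / ``slope_gs``: accuracy gain per doubling of resolution /
    gray depth (logit units).  ``threshold``: population-mean offset;
    ``subject_sd``: between-subject SD of the threshold.  ``lapse_rate``:
    asymptotic error rate at ceiling quality.  These are synthetic-cohort
    configuration, not measured constants.
    """

    slope_pix: float = 1.0
    slope_gs: float = 0.5
    threshold: float = 7.0
    lapse_rate: float = 0.05
    subject_sd: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse rate outside [0, 0.1]")

    def p_correct(self, pixels: int, grayscales: int, threshold: float | None = None) -> float:
        th = self.threshold if threshold is None else threshold
        z = self.slope_pix * np.log2(pixels) + self.slope_gs * np.log2(grayscales) - th
        sig = special.expit(z)
        return CHANCE + (1.0 - CHANCE - self.lapse_rate) * sig


def n_choice_subsets(n_classes: int = 16, k: int = N_OPTIONS) -> int:
    """Number of distinct k-option screens drawable from n classes
    (e.g. C(16, 2) = 120 pairs, C(16, 4) = 1820 quadruples)."""
    return comb(n_classes, k)


def build_choice_sets(
    n_classes: int = 16,
    n_mc_sets: int = N_MC_SETS,
    seed: int = 0,
    n_piq_slots: int = 9,
) -> list[ChoiceSet]:
    """Construct the multiple-choice screens.

    For each MC set, target class and PIQ slot: 3 distractors sampled
    without replacement from the remaining classes.  Deterministic per seed.
    """
    if n_classes < N_OPTIONS:
        raise ValueError(f"need at least {N_OPTIONS} classes for a 4-way choice")
    rng = np.random.default_rng(seed)
    sets = []
    for mc in range(1, n_mc_sets + 1):
        for target in range(n_classes):
            others = np.array([c for c in range(n_classes) if c != target])
            for _slot in range(n_piq_slots):
                distractors = rng.choice(others, size=N_OPTIONS - 1, replace=False)
                options = [target, *distractors.tolist()]
                rng.shuffle(options)
                sets.append(ChoiceSet(target, tuple(options), mc))
    return sets


def human_design(n_subjects: int = N_SUBJECTS, n_classes: int = 16, seed: int = 0) -> pd.DataFrame:
    """The per-trial plan of the psychophysical experiment.

    Returns one row per (subject, trial): subject/group/mode assignment and
    the stimulus key (PIQ level, class, condition) with its choice screen.
    Groups 1-3 view NGB, 4-6 GB; each subject sees every (PIQ, class,
    condition) combination of the human grid exactly once (720 trials),
    in a seeded shuffled order interleaving PIQ levels.
    """
    if n_subjects % N_GROUPS:
        raise ValueError(f"{n_subjects} subjects do not divide into {N_GROUPS} groups")
    per_group = n_subjects // N_GROUPS
    grid = piq_grid("human")
    conds = human_conditions()
    choice_sets = {
        mc: build_choice_sets(n_classes, 1, seed=seed + mc, n_piq_slots=len(grid))
        for mc in range(1, N_MC_SETS + 1)
    }
    rng = np.random.default_rng([seed, 999])

    rows = []
    for s in range(n_subjects):
        group = s // per_group + 1  # G01..G06
        mode = "ngb" if group <= N_GROUPS // 2 else "gb"
        mc = group  # one MC question set per group
        trials = [
            (piq_i, piq, cls, cond)
            for piq_i, piq in enumerate(grid)
            for cls in range(n_classes)
            for cond in conds
        ]
        order = rng.permutation(len(trials))
        for t in order:
            piq_i, piq, cls, cond = trials[t]
            cs = choice_sets[mc][cls * len(grid) + piq_i]
            rows.append(
                dict(
                    subject_id=f"H{s + 1:02d}",
                    group_id=f"G{group:02d}",
                    mode=mode,
                    pixels=piq.pixels,
                    grayscales=piq.grayscales,
                    class_id=cls,
                    viewpoint_deg=cond.viewpoint_deg,
                    expression=cond.expression,
                    options=cs.options,
                )
            )
    return pd.DataFrame(rows)


def simulate_human_responses(
    plan: pd.DataFrame,
    params: PsychometricParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate observer decisions for every trial of a plan.

    Per trial the observer's posterior over the 4 options puts mass
    p = p_correct(P, G | subject threshold) on the target and (1 - p) / 3
    on each distractor.  The first choice samples that posterior;
    confidence is low with probability 1 - p; when low, the second choice
    samples the renormalized posterior over the remaining options.
    Response time is 1.4 s (the protocol's floor) plus lognormal jitter.
    """
    params = params or PsychometricParams()
    rng = np.random.default_rng(seed)
    subjects = plan["subject_id"].unique()
    thresholds = {
        s: params.threshold + rng.normal(0.0, params.subject_sd) for s in subjects
    }

    rows = []
    for rec in plan.itertuples(index=False):
        p = params.p_correct(rec.pixels, rec.grayscales, thresholds[rec.subject_id])
        options = list(rec.options)
        post = np.full(N_OPTIONS, (1.0 - p) / (N_OPTIONS - 1))
        post[options.index(rec.class_id)] = p
        first_i = rng.choice(N_OPTIONS, p=post)
        first = options[first_i]
        low_conf = rng.random() < (1.0 - p)
        second = None
        if low_conf:
            rest = post.copy()
            rest[first_i] = 0.0
            rest /= rest.sum()
            second = options[rng.choice(N_OPTIONS, p=rest)]
        top1 = first == rec.class_id
        top2 = top1 or (second == rec.class_id)
        rows.append(
            dict(
                subject_id=rec.subject_id,
                group_id=rec.group_id,
                mode=rec.mode,
                pixels=rec.pixels,
                grayscales=rec.grayscales,
                class_id=rec.class_id,
                viewpoint_deg=rec.viewpoint_deg,
                expression=rec.expression,
                first_choice=first,
                confidence="low" if low_conf else "high",
                second_choice=second if second is not None else pd.NA,
                response_time_s=1.4 + rng.lognormal(-0.5, 0.4),
                correct_top1=top1,
                correct_top2=top2,
            )
        )
    out = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    out["second_choice"] = out["second_choice"].astype("Int64")
    return out


def validate_trials(trials: pd.DataFrame) -> None:
    """Schema and invariant checks for a trial table; raises on violation."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing column(s): {', '.join(missing)}")
    extra = [c for c in trials.columns if c not in TRIAL_COLUMNS]
    if extra:
        raise ValueError(f"trial table has unexpected column(s): {', '.join(extra)}")
    if len(trials) == 0:
        return
    bad = trials[trials["correct_top1"] & ~trials["correct_top2"]]
    if len(bad):
        raise ValueError(
            f"{len(bad)} record(s) violate Top-1 => Top-2 (first row index {bad.index[0]})"
        )
    high = trials[trials["confidence"] == "high"]
    with_second = high[high["second_choice"].notna()]
    if len(with_second):
        raise ValueError(
            f"{len(with_second)} high-confidence record(s) carry a second choice "
            f"(first row index {with_second.index[0]})"
        )
    same = trials[
        trials["second_choice"].notna()
        & (trials["second_choice"] == trials["first_choice"])
    ]
    if len(same):
        raise ValueError("second choice must differ from the first choice")
    if (trials["response_time_s"] <= 0).any():
        raise ValueError("response times must be positive")


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write validated trial records to CSV (one row per trial)."""
    validate_trials(trials)
    trials.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial CSV; lossless round-trip with write_trials."""
    trials = pd.read_csv(
        path,
        dtype={
            "subject_id": str,
            "group_id": str,
            "mode": str,
            "confidence": str,
            "expression": str,
        },
    )
    if len(trials) == 0 and list(trials.columns) == TRIAL_COLUMNS:
        return trials
    for col in ("correct_top1", "correct_top2"):
        if col in trials.columns:
            trials[col] = trials[col].astype(bool)
    if "second_choice" in trials.columns:
        trials["second_choice"] = trials["second_choice"].astype("Int64")
    validate_trials(trials)
    return trials
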