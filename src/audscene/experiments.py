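"""Balanced psychophysics trial designs and participant exclusion rules.

Two yes/no detection experiments are designed here:

* Experiment 1 (scene size): 408 trials in 4 blocks of 102; within each
  block every one of the 51 categories is probed twice, present on exactly
  one of the two trials; scene size is drawn uniformly from 1-5 per trial.

* Experiment 2 (distortions): 3,468 unique distortion x category
  conditions (68 x 51), partitioned across 17 participants of 204 trials
  each so that every participant uses each distortion exactly 3 times and
  each category exactly 4 times. A complementary set of 17 participants
  repeats the assignment with target-present flags inverted, so each set
  of 34 covers every condition once present and once absent.

Exclusion rules: more than one failed headphone-check trial, or below 70%
accuracy on the ten catch trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrialPlan",
    "ResponseTable",
    "design_exp1",
    "design_exp2",
    "apply_exclusions",
]

N_CATEGORIES = 51
EXP1_BLOCKS = 4
EXP1_TRIALS_PER_BLOCK = 2 * N_CATEGORIES  # 102
EXP2_N_DISTORTIONS = 68
EXP2_GROUP = 17  # participants jointly covering all conditions once
EXP2_TRIALS = EXP2_N_DISTORTIONS * N_CATEGORIES // EXP2_GROUP  # 204
EXP2_DISTORTION_MULT = 3  # per participant
EXP2_CATEGORY_MULT = 4  # per participant
CATCH_ACCURACY_MIN = 0.70
HEADPHONE_FAILS_MAX = 1
MAX_SCENE_SIZE = 5


@dataclass(frozen=True)
class TrialPlan:
    """One participant's trial table."""

    trials: pd.DataFrame = field(repr=False)
    participant_id: int = 0
    experiment: str = "exp1"

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def design_exp1(seed: int, participant_id: int = 0,
                n_categories: int = N_CATEGORIES) -> TrialPlan:
    """Design one Experiment 1 participant: 4 blocks of 2 x 51 probes.

    Each block probes every category twice — once target-present, once
    target-absent — in seeded random order, with an independently uniform
    scene size (1-5) per trial.
    """
    rng = np.random.default_rng(seed)
    rows = []
    trial_id = 0
    for block in range(EXP1_BLOCKS):
        pairs = [(cat, present) for cat in range(n_categories)
                 for present in (True, False)]
        rng.shuffle(pairs)
        for cat, present in pairs:
            rows.append({
                "trial_id": trial_id,
                "block": block,
                "probe_category": cat,
                "target_present": present,
                "scene_size": int(rng.integers(1, MAX_SCENE_SIZE + 1)),
                "condition_ref": "",
            })
            trial_id += 1
    return TrialPlan(trials=pd.DataFrame(rows), participant_id=participant_id,
                     experiment="exp1")


def design_exp2(seed: int, n_distortions: int = EXP2_N_DISTORTIONS,
                n_categories: int = N_CATEGORIES,
                n_group: int = EXP2_GROUP) -> list[TrialPlan]:
    """Design 34 Experiment 2 participants (two complementary sets of 17).

    Each distortion x category condition is assigned to exactly one of the
    17 participants in a set via the balanced map
    ``participant = (distortion + category) mod 17`` composed with seeded
    random relabelings of distortions, categories and participants — which
    provably gives every participant each distortion 3 times and each
    category 4 times. Half of each participant's 204 trials are randomly
    designated target-present; the complementary set of 17 participants
    inverts those flags.
    """
    if n_distortions % n_group or (n_distortions * n_categories) % n_group:
        raise ValueError("distortion grid not divisible across the group")
    rng = np.random.default_rng(seed)
    d_perm = rng.permutation(n_distortions)
    c_perm = rng.permutation(n_categories)
    p_perm = rng.permutation(n_group)

    assignment: dict[int, list] = {p: [] for p in range(n_group)}
    for d in range(n_distortions):
        for c in range(n_categories):
            p = int(p_perm[(int(d_perm[d]) + int(c_perm[c])) % n_group])
            assignment[p].append((d, c))

    plans = []
    for p in range(n_group):
        conds = assignment[p]
        rng.shuffle(conds)
        n = len(conds)
        present = np.zeros(n, dtype=bool)
        present[rng.choice(n, size=n // 2, replace=False)] = True
        for flip, pid in ((False, p), (True, p + n_group)):
            order = rng.permutation(n)
            rows = [{
                "trial_id": t,
                "block": 0,
                "distortion_index": conds[i][0],
                "probe_category": conds[i][1],
                "target_present": bool(present[i] ^ flip),
                "condition_ref": f"d{conds[i][0]}xc{conds[i][1]}",
            } for t, i in enumerate(order)]
            plans.append(TrialPlan(trials=pd.DataFrame(rows),
                                   participant_id=pid, experiment="exp2"))
    plans.sort(key=lambda pl: pl.participant_id)
    return plans


@dataclass
class ResponseTable:
    """Per-participant responses plus screening outcomes."""

    responses: pd.DataFrame = field(repr=False)  # trial_id, response, catch_flag
    participant_id: int = 0
    headphone_fails: int = 0
    catch_correct: pd.Series | None = field(default=None, repr=False)

    @property
    def catch_score(self) -> float:
        """Fraction of catch trials answered correctly."""
        if self.catch_correct is not None:
            vals = np.asarray(self.catch_correct, dtype=float)
        else:
            catch = self.responses[self.responses["catch_flag"].astype(bool)]
            if "correct" not in catch.columns:
                raise ValueError("catch trials present but no 'correct' column")
            vals = catch["correct"].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError("no catch trials found")
        return float(vals.mean())


def apply_exclusions(tables: list[ResponseTable]) -> pd.DataFrame:
    """Screen participants on headphone-check and catch-trial criteria.

    Included iff ``headphone_fails <= 1`` and catch accuracy ``>= 0.70``
    (exactly 70% is not "below 70%" and is retained). Returns a DataFrame
    with one row per participant: included flag and the reason if excluded.
    """
    rows = []
    for table in tables:
        reasons = []
        if table.headphone_fails > HEADPHONE_FAILS_MAX:
            reasons.append("headphone_check")
        if table.catch_score < CATCH_ACCURACY_MIN:
            reasons.append("catch_trials")
        rows.append({
            "participant_id": table.participant_id,
            "included": not reasons,
            "reason": ";".join(reasons),
            "catch_score": table.catch_score,
            "headphone_fails": table.headphone_fails,
        })
    return pd.DataFrame(rows)
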