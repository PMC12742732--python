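"""Libet-clock judgment errors and intentional time binding scores.

In the intentional-binding task the participant watches a clock-face dot
and reports where it was when an event (their key press, or a tone)
occurred. Baseline blocks contain only the action or only the tone;
agency blocks pair a voluntary action with a tone after a fixed delay.
Binding is the shift of the mean judgment error in agency blocks relative
to the matching baseline block.

Sign convention (printed in every report): judgment errors are positive
when the event is reported *later* than it happened. With the classic
binding pattern -- actions drawn later toward the tone (positive action
binding) and tones drawn earlier toward the action (negative tone
binding) -- total binding is ``action_binding - tone_binding``, so mutual
attraction yields a positive total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ACTION_ONLY = "action_only"
TONE_ONLY = "tone_only"
AGENCY_JUDGE_ACTION = "agency_judge_action"
AGENCY_JUDGE_TONE = "agency_judge_tone"
CONDITIONS = (ACTION_ONLY, TONE_ONLY, AGENCY_JUDGE_ACTION, AGENCY_JUDGE_TONE)

#: Human-readable statement of the shipped sign convention.
SIGN_CONVENTION = (
    "positive error = reported later than actual; "
    "total_binding = action_binding - tone_binding"
)

DEFAULT_CLOCK_PERIOD_MS = 2560.0


@dataclass
class TrialRecord:
    """One clock judgment: where the dot was vs. where it was reported.

    Angles are in degrees on [0, 360); ``clock_period_ms`` is the time the
    dot takes for a full revolution, so angle differences map to
    milliseconds via ``period / 360``.
    """

    condition: str
    actual_deg: float
    reported_deg: float
    clock_period_ms: float = DEFAULT_CLOCK_PERIOD_MS
    valid: bool = True

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.clock_period_ms <= 0:
            raise ValueError("clock period must be positive")
        self.actual_deg = float(self.actual_deg) % 360.0
        self.reported_deg = float(self.reported_deg) % 360.0

    @property
    def actual_ms(self) -> float:
        return self.actual_deg / 360.0 * self.clock_period_ms

    @property
    def reported_ms(self) -> float:
        return self.reported_deg / 360.0 * self.clock_period_ms


@dataclass
class BindingScores:
    """Per-subject binding summary in milliseconds."""

    subject: str
    action_binding_ms: float
    tone_binding_ms: float
    total_binding_ms: float
    n_valid_trials: dict[str, int]
    convention: str = SIGN_CONVENTION


def judgment_error_ms(trial: TrialRecord) -> float:
    """Signed judgment error in ms; positive = reported later than actual.

    The angular difference is wrapped to (-180, 180] degrees before
    conversion, so judgments across the 0/360 boundary are handled.
    """
    if not trial.valid:
        raise ValueError("cannot score an invalid (missing-click) trial")
    delta_deg = ((trial.reported_deg - trial.actual_deg + 180.0) % 360.0) - 180.0
    return delta_deg / 360.0 * trial.clock_period_ms


def binding_scores(trials: Iterable[TrialRecord], subject: str = "S01") -> BindingScores:
    """Compute action, tone, and total binding for one subject.

    Invalid trials (missing clicks) are excluded listwise per condition and
    counted in ``n_valid_trials``. Raises if any required condition has no
    valid trial.
    """
    errors: dict[str, list[float]] = {c: [] for c in CONDITIONS}
    for tr in trials:
        if tr.valid:
            errors[tr.condition].append(judgment_error_ms(tr))
    empty = [c for c in CONDITIONS if not errors[c]]
    if empty:
        raise ValueError(f"no valid trials in condition(s): {', '.join(empty)}")
    action = float(np.mean(errors[AGENCY_JUDGE_ACTION]) - np.mean(errors[ACTION_ONLY]))
    tone = float(np.mean(errors[AGENCY_JUDGE_TONE]) - np.mean(errors[TONE_ONLY]))
    return BindingScores(
        subject=subject,
        action_binding_ms=action,
        tone_binding_ms=tone,
        total_binding_ms=action - tone,
        n_valid_trials={c: len(errors[c]) for c in CONDITIONS},
    )


def group_binding_table(
    scores_by_group: Mapping[str, Iterable[BindingScores]],
) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) of each binding measure per group.

    Groups with fewer than two subjects get an undefined (NaN) SD.
    """
    measures = {
        "action_binding_ms": lambda s: s.action_binding_ms,
        "tone_binding_ms": lambda s: s.tone_binding_ms,
        "total_binding_ms": lambda s: s.total_binding_ms,
    }
    rows = []
    for group, scores in scores_by_group.items():
        scores = list(scores)
        if not scores:
            raise ValueError(f"group {group!r} has no subjects")
        for measure, get in measures.items():
            vals = np.array([get(s) for s in scores], dtype=float)
            sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else float("nan")
            rows.append({
                "group": group,
                "measure": measure,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": sd,
            })
    return pd.DataFrame(rows)
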