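"""Attention-network-test scoring, physiology deltas, and brain-behavior links.

The ANT crosses three cue conditions (no, center, spatial) with two
target types (congruent, incongruent flankers).  Mean RT contrasts
yield three network efficiencies:

    alerting  = RT(no cue) - RT(center cue)
    orienting = RT(center cue) - RT(spatial cue)
    executive = RT(incongruent) - RT(congruent)

Group comparisons use the pooled two-sample t from the statistical
kernel; the altered-edge count N_alt is correlated (Pearson) against
the executive-RT increase, the rectal-temperature rise, and weight
loss across heat-exposed subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import statcore
from .statcore import TestResult

__all__ = [
    "AntEffects",
    "PhysiologyRecord",
    "condition_rt_summary",
    "ant_effects",
    "compare_group_effects",
    "physiology_deltas",
    "physiology_delta_table",
    "associate_network_outcomes",
]

CUES = ("no", "center", "spatial")
TARGETS = ("congruent", "incongruent")
EFFECT_NAMES = ("alerting", "orienting", "executive")


@dataclass(frozen=True)
class AntEffects:
    """Condition-mean RTs (ms) and the three derived network effects."""

    rt_by_condition: dict
    alerting_ms: float
    orienting_ms: float
    executive_ms: float

    def effect(self, name: str) -> float:
        return {
            "alerting": self.alerting_ms,
            "orienting": self.orienting_ms,
            "executive": self.executive_ms,
        }[name]


@dataclass(frozen=True)
class PhysiologyRecord:
    """Pre/post rectal temperature (C) and weight (kg) for one subject."""

    rectal_pre_c: float
    rectal_post_c: float
    weight_pre_kg: float
    weight_post_kg: float

    def __post_init__(self) -> None:
        for v in (self.rectal_pre_c, self.rectal_post_c,
                  self.weight_pre_kg, self.weight_post_kg):
            if v is None or not np.isfinite(v) or v <= 0:
                raise ValueError("physiology values must be present and positive")

    @property
    def delta_t_c(self) -> float:
        return self.rectal_post_c - self.rectal_pre_c

    @property
    def weight_loss_kg(self) -> float:
        return self.weight_pre_kg - self.weight_post_kg


def condition_rt_summary(trials: pd.DataFrame) -> dict:
    """Mean RT of correct, responded trials per cue and per target type.

    Cue means pool over targets; target means pool over cues.  Trials
    without a response (deadline hits) and error trials are excluded.
    Raises if any condition loses all of its trials.
    """
    required = {"cue", "target", "rt_ms", "responded", "correct"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    kept = trials[trials["responded"].astype(bool) & trials["correct"].astype(bool)]
    summary = {}
    for cue in CUES:
        sel = kept[kept["cue"] == cue]
        if sel.empty:
            raise ValueError(f"no retained trials for cue condition '{cue}'")
        summary[("cue", cue)] = float(sel["rt_ms"].mean())
    for tgt in TARGETS:
        sel = kept[kept["target"] == tgt]
        if sel.empty:
            raise ValueError(f"no retained trials for target condition '{tgt}'")
        summary[("target", tgt)] = float(sel["rt_ms"].mean())
    return summary


def ant_effects(summary: dict) -> AntEffects:
    """The three attention-network effects from condition-mean RTs."""
    try:
        no = summary[("cue", "no")]
        center = summary[("cue", "center")]
        spatial = summary[("cue", "spatial")]
        congruent = summary[("target", "congruent")]
        incongruent = summary[("target", "incongruent")]
    except KeyError as exc:
        raise ValueError(f"missing condition mean: {exc.args[0]}") from exc
    return AntEffects(
        rt_by_condition=dict(summary),
        alerting_ms=no - center,
        orienting_ms=center - spatial,
        executive_ms=incongruent - congruent,
    )


def compare_group_effects(effects_ht: list, effects_nc: list) -> dict:
    """Pooled two-sample t per network effect, HT vs NC.

    df = n_HT + n_NC - 2; positive t means the HT group's effect is
    larger.
    """
    if len(effects_ht) < 2 or len(effects_nc) < 2:
        raise ValueError("need at least 2 subjects per group")
    out = {}
    for name in EFFECT_NAMES:
        a = [e.effect(name) for e in effects_ht]
        b = [e.effect(name) for e in effects_nc]
        out[name] = statcore.two_sample_t(a, b)
    return out


def physiology_deltas(record: PhysiologyRecord) -> tuple:
    """(temperature rise C, weight loss kg) for one subject."""
    return record.delta_t_c, record.weight_loss_kg


def physiology_delta_table(physio: pd.DataFrame) -> pd.DataFrame:
    """Per-subject deltas recomputed from the raw pre/post columns."""
    records = physio.apply(
        lambda row: PhysiologyRecord(
            row["rectal_pre_c"], row["rectal_post_c"],
            row["weight_pre_kg"], row["weight_post_kg"],
        ),
        axis=1,
    )
    return pd.DataFrame(
        dict(
            subject_id=physio["subject_id"].to_numpy(),
            delta_t_c=[r.delta_t_c for r in records],
            weight_loss_kg=[r.weight_loss_kg for r in records],
        )
    )


def associate_network_outcomes(n_alt: pd.Series, outcomes: pd.DataFrame) -> dict:
    """Pearson correlation of the altered-edge count with each outcome.

    ``n_alt`` and ``outcomes`` are indexed by subject id (heat-exposed
    subjects only); indices must match exactly.  Returns a
    ``{outcome_name: TestResult}`` mapping where the statistic is r.
    """
    if len(n_alt) < 3:
        raise ValueError("need at least 3 subjects")
    if set(n_alt.index) != set(outcomes.index):
        raise ValueError("subject ids of n_alt and outcomes do not align")
    aligned = outcomes.loc[n_alt.index]
    return {
        col: statcore.pearson_corr(n_alt.to_numpy(dtype=float),
                                   aligned[col].to_numpy(dtype=float))
        for col in aligned.columns
    }
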