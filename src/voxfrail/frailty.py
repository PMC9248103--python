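"""Frailty-index scoring: CHS (Fried phenotype), SOF, and FRAIL.

Each scorer maps raw criterion fields of a participant to named
criterion flags, an integer score, and a robust / pre-frail / frail
category:

* **CHS** (five criteria; frail at >= 3, pre-frail at 1-2): weight loss
  (unintentional >= 4.5 kg or > 5% of body weight in the past year),
  exhaustion (less energy to do the things you want), weakness
  (dominant-hand grip below Asian cut-offs: < 28 kg men, < 18 kg
  women), slowness (gait speed < 1.0 m/s over 4 m; participants unable
  to walk count as slow), and low physical activity (deterioration in
  activities of daily living).
* **SOF** (three criteria; frail at >= 2): weight loss (> 5%/year,
  intentional or not), inability to rise from a chair five times
  without using the arms, and a reduced energy level ("do you feel full
  of energy?" answered no).
* **FRAIL** (five criteria; frail at 3-5): Fatigue, Resistance (chair
  stand), Ambulation (gait < 1.0 m/s), Illness (>= 8 drugs as a
  polypharmacy proxy), and Loss of weight (self-reported >= 5%/year).

Boundary conventions (strict vs inclusive comparisons) follow the
operational wording of each criterion and are collected in
:class:`FrailtyThresholds` so they can be changed in one place.
Missing inputs never crash a scorer: a missing criterion contributes 0,
is listed in ``missing_criteria``, and the assessment is flagged
``incomplete`` whenever the missing information could change the
category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Participant",
    "FrailtyAssessment",
    "FrailtyThresholds",
    "score_chs",
    "score_sof",
    "score_frail",
    "score_all",
    "INDEX_NAMES",
]

INDEX_NAMES = ("CHS", "SOF", "FRAIL")


@dataclass(frozen=True)
class FrailtyThresholds:
    """Criterion cut-offs; defaults follow the operational definitions."""

    grip_cutoff_male_kg: float = 28.0   # weakness: strict <
    grip_cutoff_female_kg: float = 18.0
    gait_cutoff_m_s: float = 1.0        # slowness/ambulation: strict <
    chs_weight_loss_kg: float = 4.5     # inclusive >= ("at least 4.5 kg")
    chs_weight_loss_pct: float = 5.0    # strict > ("> 5% of the body weight")
    sof_weight_loss_pct: float = 5.0    # strict > ("> 5%")
    frail_weight_loss_pct: float = 5.0  # inclusive >= (">= 5%")
    drug_count_cutoff: int = 8          # inclusive >= ("eight drugs or more")
    chs_frail_min: int = 3
    sof_frail_min: int = 2
    frail_frail_min: int = 3


@dataclass
class Participant:
    """Raw criterion fields and demographics for one subject.

    ``None`` (or NaN) marks a missing value.  A missing gait speed
    together with ``cannot_walk=True`` marks a participant who could
    not perform the walking test and is classified as slow.
    """

    id: str
    sex: str  # "male" | "female"
    age_years: float | None = None
    body_weight_kg: float | None = None
    bmi: float | None = None
    weight_loss_pct_year: float | None = None
    weight_loss_kg_year: float | None = None
    unintentional: bool | None = None
    exhaustion_answer: str | None = None  # yes/no: less energy to do things
    grip_kg: float | None = None
    gait_speed_m_s: float | None = None
    cannot_walk: bool = False
    adl_deterioration: str | None = None  # yes/no
    chair_stand_able: bool | None = None  # able to rise 5x without arms
    energy_full_answer: str | None = None  # yes/no: "do you feel full of energy?"
    drug_count: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")

    @classmethod
    def from_row(cls, row: Mapping) -> "Participant":
        """Build a Participant from a mapping/Series with matching keys."""
        def get(key, default=None):
            v = row.get(key, default) if hasattr(row, "get") else getattr(row, key, default)
            if isinstance(v, float) and math.isnan(v):
                return None
            return v

        return cls(
            id=str(get("id")),
            sex=get("sex"),
            age_years=get("age_years"),
            body_weight_kg=get("body_weight_kg"),
            bmi=get("bmi"),
            weight_loss_pct_year=get("weight_loss_pct_year"),
            weight_loss_kg_year=get("weight_loss_kg_year"),
            unintentional=get("unintentional"),
            exhaustion_answer=get("exhaustion_answer"),
            grip_kg=get("grip_kg"),
            gait_speed_m_s=get("gait_speed_m_s"),
            cannot_walk=bool(get("cannot_walk", False) or False),
            adl_deterioration=get("adl_deterioration"),
            chair_stand_able=get("chair_stand_able"),
            energy_full_answer=get("energy_full_answer"),
            drug_count=get("drug_count"),
        )


@dataclass
class FrailtyAssessment:
    index: str
    criteria: dict  # name -> bool (missing criteria excluded)
    score: int
    category: str  # robust | pre-frail | frail
    missing_criteria: list = field(default_factory=list)
    incomplete: bool = False

    def as_dict(self) -> dict:
        return {
            "index": self.index,
            "score": self.score,
            "category": self.category,
            "missing": ";".join(self.missing_criteria),
            "incomplete": self.incomplete,
            **{f"crit_{k}": v for k, v in self.criteria.items()},
        }


def _yes(answer) -> bool | None:
    if answer is None:
        return None
    if isinstance(answer, bool):
        return answer
    return str(answer).strip().lower() in ("yes", "y", "true", "1")


def _category(score: int, frail_min: int) -> str:
    if score >= frail_min:
        return "frail"
    return "pre-frail" if score >= 1 else "robust"


def _assemble(index: str, flags: dict, frail_min: int) -> FrailtyAssessment:
    missing = sorted(k for k, v in flags.items() if v is None)
    present = {k: bool(v) for k, v in flags.items() if v is not None}
    if len(missing) == len(flags):
        raise ValueError(f"{index}: all criterion inputs missing")
    score = sum(present.values())
    category = _category(score, frail_min)
    # missing criteria could push the score across the frail threshold
    incomplete = bool(missing) and score < frail_min <= score + len(missing)
    return FrailtyAssessment(index, present, score, category, missing, incomplete)


def _weight_loss_chs(p: Participant, th: FrailtyThresholds) -> bool | None:
    if p.weight_loss_kg_year is None and p.weight_loss_pct_year is None:
        return None
    unint = p.unintentional if p.unintentional is not None else True
    kg = p.weight_loss_kg_year is not None and p.weight_loss_kg_year >= th.chs_weight_loss_kg
    pct = p.weight_loss_pct_year is not None and p.weight_loss_pct_year > th.chs_weight_loss_pct
    return bool(unint and (kg or pct))


def _slowness(p: Participant, th: FrailtyThresholds) -> bool | None:
    if p.gait_speed_m_s is not None:
        return p.gait_speed_m_s < th.gait_cutoff_m_s
    return True if p.cannot_walk else None


def score_chs(p: Participant, thresholds: FrailtyThresholds = FrailtyThresholds()) -> FrailtyAssessment:
    """Score the five-criterion Fried phenotype (CHS index)."""
    th = thresholds
    grip_cut = th.grip_cutoff_male_kg if p.sex == "male" else th.grip_cutoff_female_kg
    flags = {
        "weight_loss": _weight_loss_chs(p, th),
        "exhaustion": _yes(p.exhaustion_answer),
        "weakness": None if p.grip_kg is None else p.grip_kg < grip_cut,
        "slowness": _slowness(p, th),
        "low_activity": _yes(p.adl_deterioration),
    }
    return _assemble("CHS", flags, th.chs_frail_min)


def score_sof(p: Participant, thresholds: FrailtyThresholds = FrailtyThresholds()) -> FrailtyAssessment:
    """Score the three-criterion SOF index."""
    th = thresholds
    energy = _yes(p.energy_full_answer)
    flags = {
        "weight_loss": (
            None if p.weight_loss_pct_year is None
            else p.weight_loss_pct_year > th.sof_weight_loss_pct
        ),
        "chair_stand": None if p.chair_stand_able is None else not p.chair_stand_able,
        "reduced_energy": None if energy is None else not energy,
    }
    return _assemble("SOF", flags, th.sof_frail_min)


def score_frail(p: Participant, thresholds: FrailtyThresholds = FrailtyThresholds()) -> FrailtyAssessment:
    """Score the five-item FRAIL index (Fatigue, Resistance, Ambulation,
    Illness, Loss of weight)."""
    th = thresholds
    flags = {
        "fatigue": _yes(p.exhaustion_answer),
        "resistance": None if p.chair_stand_able is None else not p.chair_stand_able,
        "ambulation": _slowness(p, th),
        "illness": None if p.drug_count is None else p.drug_count >= th.drug_count_cutoff,
        "weight_loss": (
            None if p.weight_loss_pct_year is None
            else p.weight_loss_pct_year >= th.frail_weight_loss_pct
        ),
    }
    return _assemble("FRAIL", flags, th.frail_frail_min)


_SCORERS = {"CHS": score_chs, "SOF": score_sof, "FRAIL": score_frail}


def score_all(
    participants: pd.DataFrame,
    thresholds: FrailtyThresholds = FrailtyThresholds(),
    indices: Iterable[str] = INDEX_NAMES,
) -> pd.DataFrame:
    """Score every participant on every index.

    Returns one row per participant per index with the score, category,
    and the binary outcome column ``frail`` (frail vs robust/pre-frail
    combined) used throughout the association analysis.
    """
    if participants.empty:
        raise ValueError("participant table is empty")
    ids = participants["id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate participant ids: {dupes}")
    rows = []
    for _, r in participants.iterrows():
        p = Participant.from_row(r)
        for index in indices:
            try:
                a = _SCORERS[index](p, thresholds)
                frail = a.category == "frail"
            except ValueError:  # every criterion input missing for this index
                names = _ALL_CRITERIA[index]
                a = FrailtyAssessment(index, {}, 0, "unknown", list(names), True)
                frail = None
            rows.append({"id": p.id, "sex": p.sex, **a.as_dict(), "frail": frail})
    return pd.DataFrame(rows)


_ALL_CRITERIA = {
    "CHS": ("exhaustion", "low_activity", "slowness", "weakness", "weight_loss"),
    "SOF": ("chair_stand", "reduced_energy", "weight_loss"),
    "FRAIL": ("ambulation", "fatigue", "illness", "resistance", "weight_loss"),
}
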