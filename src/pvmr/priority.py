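"""Semiquantitative clinical-priority triage of disproportionality signals.

Each detected signal is scored 0–2 on four criteria and the points summed:

* clinical relevance — membership in the EMA Designated Medical Event list
  (DME, 2 points), Important Medical Event list (IME, 1) or neither (0);
* reporting rate — target-AE reports as a fraction of all reports for the
  drug: >=10% -> 2, 1–10% -> 1, <1% -> 0;
* reported case-fatality rate — death-outcome reports among target-AE
  reports: >50% -> 2, 25–50% -> 1, <25% -> 0;
* signal stability — how many of the three disproportionality methods
  (ROR, PRR, IC) flagged the pair: 3 of 3 -> 2, 2 of 3 -> 1, else 0.

Total 0–2 is low, 3–5 moderate and 6–8 high priority.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

RELEVANCE_POINTS = {"DME": 2, "IME": 1, "none": 0}
CRITERIA = ("clinical_relevance", "reporting_rate", "fatality_rate", "stability")


@dataclass(frozen=True, slots=True)
class PriorityInput:
    clinical_relevance: str  # DME | IME | none
    reporting_rate: float    # target-AE reports / all reports for the drug
    fatality_rate: float     # death-outcome reports / target-AE reports
    stability: int           # 0-3 disproportionality methods positive

    def __post_init__(self) -> None:
        if self.clinical_relevance not in RELEVANCE_POINTS:
            raise ValueError(f"clinical_relevance must be one of {sorted(RELEVANCE_POINTS)}")
        for name in ("reporting_rate", "fatality_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.stability not in (0, 1, 2, 3):
            raise ValueError(f"stability must be in 0..3, got {self.stability}")


@dataclass(frozen=True, slots=True)
class PriorityScore:
    component_points: dict[str, int]
    total: int
    category: str  # low | moderate | high

    def to_json(self) -> str:
        return json.dumps(
            {"components": self.component_points, "total": self.total, "category": self.category},
            sort_keys=True,
        )


def _reporting_rate_points(rate: float) -> int:
    if rate >= 0.10:
        return 2
    if rate >= 0.01:
        return 1
    return 0


def _fatality_points(rate: float) -> int:
    if rate > 0.50:
        return 2
    if rate >= 0.25:
        return 1
    return 0


def _stability_points(stability: int) -> int:
    return {3: 2, 2: 1}.get(stability, 0)


def categorize(total: int) -> str:
    if not 0 <= total <= 8:
        raise ValueError(f"total out of range: {total}")
    if total <= 2:
        return "low"
    if total <= 5:
        return "moderate"
    return "high"


def score_priority(p: PriorityInput) -> PriorityScore:
    """Apply the four-criterion rubric and band the total.

    The rate bands are half-open ([0.01, 0.10) scores 1) so every rate maps
    to exactly one band; the fatality 1-point band is closed, [0.25, 0.50].
    """
    components = {
        "clinical_relevance": RELEVANCE_POINTS[p.clinical_relevance],
        "reporting_rate": _reporting_rate_points(p.reporting_rate),
        "fatality_rate": _fatality_points(p.fatality_rate),
        "stability": _stability_points(p.stability),
    }
    total = sum(components.values())
    return PriorityScore(components, total, categorize(total))
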