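"""Rule-based chronic-endometritis (CE) severity grading from morphometry.

Four criteria vote independently — stromal fibrosis, arteriolar lumen area,
arteriolar diameter, and CD138+ plasma-cell count — and a sample receives a
definite grade only when the votes are unanimous (the fibrosis vote being
compatible rather than specific for moderate vs severe). Discordant records
come back ``indeterminate`` with the per-criterion votes attached, making the
conflict explicit instead of inventing a tie-break the underlying rule set
does not define.

Ranges (both endpoints inclusive, compared at the printed resolution —
integers for area, 0.1 µm for diameter):

====================  ==========  ============  ===========  ========
criterion             mild        moderate      severe       none
====================  ==========  ============  ===========  ========
fibrosis              absent      present       present      —
lumen area (µm²)      150–449     100–149       ≤ 99         ≥ 450
diameter (µm)         10.0–19.9   8.0–9.9       ≤ 7.9        ≥ 20.0
CD138+ count          ≤ 1         2–3           ≥ 4          —
====================  ==========  ============  ===========  ========
"""

from __future__ import annotations

from dataclasses import dataclass, field

GRADES = ("mild", "moderate", "severe")


@dataclass
class MorphometryRecord:
    """Pre-measured morphometry for one sample."""

    fibrosis: bool
    lumen_area: float  # µm²
    diameter: float  # µm
    cd138_count: int

    def validate(self) -> None:
        if self.lumen_area <= 0:
            raise ValueError("lumen_area must be > 0")
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        if self.cd138_count < 0:
            raise ValueError("cd138_count must be >= 0")


@dataclass
class SeverityGrade:
    """Grading outcome: overall grade plus the per-criterion votes."""

    grade: str  # mild | moderate | severe | indeterminate
    votes: dict = field(default_factory=dict)


def _vote_lumen(area: float) -> str | None:
    a = round(area)  # printed resolution: integers
    if a <= 99:
        return "severe"
    if 100 <= a <= 149:
        return "moderate"
    if 150 <= a <= 449:
        return "mild"
    return None


def _vote_diameter(d: float) -> str | None:
    d = round(d * 10) / 10.0  # printed resolution: 0.1 µm
    if d <= 7.9:
        return "severe"
    if 8.0 <= d <= 9.9:
        return "moderate"
    if 10.0 <= d <= 19.9:
        return "mild"
    return None


def _vote_cd138(n: int) -> str:
    if n <= 1:
        return "mild"
    if n <= 3:
        return "moderate"
    return "severe"


def grade(record: MorphometryRecord) -> SeverityGrade:
    """Grade one morphometry record.

    Returns the unanimous grade, or ``indeterminate`` when the criteria
    disagree or a measurement falls outside every defined range.
    """
    record.validate()
    votes = {
        "fibrosis": "mild" if not record.fibrosis else "moderate|severe",
        "lumen": _vote_lumen(record.lumen_area),
        "diameter": _vote_diameter(record.diameter),
        "cd138": _vote_cd138(record.cd138_count),
    }
    candidates = set(GRADES)
    candidates &= {"mild"} if not record.fibrosis else {"moderate", "severe"}
    for crit in ("lumen", "diameter", "cd138"):
        v = votes[crit]
        candidates &= {v} if v is not None else set()
    overall = candidates.pop() if len(candidates) == 1 else "indeterminate"
    return SeverityGrade(grade=overall, votes=votes)
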