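"""Severity banding and PASI aggregation.

A dermatologist grades erythema and scaling of a local lesion image on a
0-4 scale each; the scene's severity group is the sum of the two grades
mapped onto five bands: healthy (0), mild (1-2), moderate (3-4),
severe (5-6), very severe (7-8).

The full-body PASI score weights the (erythema + thickness + scale) sum of
each body region by that region's area grade (0-6) and a fixed regional
weight: 0.1 head, 0.2 upper extremities, 0.3 trunk, 0.4 lower extremities;
the total ranges from 0 to 72.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SEVERITY_GROUPS", "SeverityLabel", "severity_group",
           "PASIRegionScores", "pasi_score"]

SEVERITY_GROUPS = ("healthy", "mild", "moderate", "severe", "very_severe")

_BANDS = [(0, 0, "healthy"), (1, 2, "mild"), (3, 4, "moderate"),
          (5, 6, "severe"), (7, 8, "very_severe")]

REGION_WEIGHTS = {"head": 0.1, "upper": 0.2, "trunk": 0.3, "lower": 0.4}


@dataclass(frozen=True)
class SeverityLabel:
    group: str
    score_sum: int


def severity_group(erythema_score: int, scale_score: int) -> SeverityLabel:
    """Map the (erythema, scale) grade pair to its 5-band severity label."""
    for name, score in ((("erythema_score"), erythema_score),
                        (("scale_score"), scale_score)):
        if not (0 <= int(score) <= 4):
            raise ValueError(f"{name} must be in 0..4, got {score}")
    total = int(erythema_score) + int(scale_score)
    for lo, hi, group in _BANDS:
        if lo <= total <= hi:
            return SeverityLabel(group=group, score_sum=total)
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass(frozen=True)
class RegionScore:
    """Grades for one body region: E, T, S in 0-4, area grade A in 0-6."""

    erythema: int
    thickness: int
    scale: int
    area: int

    def __post_init__(self) -> None:
        for name, v, hi in (("erythema", self.erythema, 4),
                            ("thickness", self.thickness, 4),
                            ("scale", self.scale, 4),
                            ("area", self.area, 6)):
            if not (0 <= int(v) <= hi):
                raise ValueError(f"{name} must be in 0..{hi}, got {v}")


@dataclass(frozen=True)
class PASIRegionScores:
    head: RegionScore
    upper: RegionScore
    trunk: RegionScore
    lower: RegionScore


def pasi_score(scores: PASIRegionScores) -> float:
    """Weighted PASI total over the four body regions (range 0-72)."""
    total = 0.0
    for region, weight in REGION_WEIGHTS.items():
        r: RegionScore = getattr(scores, region)
        total += weight * (r.erythema + r.thickness + r.scale) * r.area
    return total
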