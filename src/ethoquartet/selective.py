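"""Selective interactions in mixed-genotype quartets.

In a 2 wt + 2 Del/+ cage each animal has one same-genotype partner out of
three, so under indifferent partner choice the expected proportion of
same-genotype interaction is 1/3 (computed from the composition, not
hard-coded, so other compositions are supported).  Contact time, approach
counts and mean contact durations are split by partner genotype per focal
animal, and the same-genotype proportions are tested against the chance
level with a Shapiro-gated one-sample t / Wilcoxon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    APPROACH_CONTACT,
    CONTACT,
    Ethogram,
    GroupDesign,
)
from .stats import TestResult, gated_two_sample_test, test_vs_value

__all__ = [
    "PartnerBreakdown",
    "partition_by_partner_genotype",
    "test_vs_chance",
    "compare_mean_durations",
    "breakdown_table",
]


@dataclass
class PartnerBreakdown:
    """Per-focal-animal interaction totals split by partner genotype.

    Durations are in frames (the canonical unit of the event tables).
    ``proportion_same`` is NaN when the focal animal never interacted.
    """

    animal_id: str
    genotype: str
    contact_frames_same: float
    contact_frames_diff: float
    approaches_same: int
    approaches_diff: int
    mean_duration_same: float   # frames; NaN when no contact with that class
    mean_duration_diff: float

    @property
    def proportion_same_time(self) -> float:
        total = self.contact_frames_same + self.contact_frames_diff
        return self.contact_frames_same / total if total > 0 else float("nan")

    @property
    def proportion_same_approaches(self) -> float:
        total = self.approaches_same + self.approaches_diff
        return self.approaches_same / total if total > 0 else float("nan")


def partition_by_partner_genotype(
    ethogram: Ethogram,
    design: GroupDesign,
    cage_id: str,
    n_frames: int,
    fractional_multi_partner: bool = False,
) -> dict[str, PartnerBreakdown]:
    """Split each focal animal's contacts by partner genotype.

    Contact time uses all per-pair contact frames; a frame with several
    simultaneous partners credits a full frame to each partner by default
    (``fractional_multi_partner=True`` switches to 1/k attribution).
    Approaches are approach-contact events of the focal animal; mean
    durations are means of per-pair contact interval lengths in frames.
    """
    design.validate_mixed_quartet(cage_id)
    members = design.cage_members(cage_id)
    out: dict[str, PartnerBreakdown] = {}
    for focal in members:
        partners = [p for p in members if p != focal]
        pair_masks = {
            p: ethogram.mask(n_frames, CONTACT, actor=focal, partner=p)
            for p in partners
        }
        if fractional_multi_partner:
            k = np.zeros(n_frames)
            for m in pair_masks.values():
                k += m
            weights = {
                p: np.divide(m, k, out=np.zeros(n_frames), where=k > 0)
                for p, m in pair_masks.items()
            }
            frames = {p: float(w.sum()) for p, w in weights.items()}
        else:
            frames = {p: float(m.sum()) for p, m in pair_masks.items()}
        same = [p for p in partners if design.same_genotype(focal, p)]
        diff = [p for p in partners if not design.same_genotype(focal, p)]
        durations_same = [
            e.duration_frames
            for p in same
            for e in ethogram.by_type(CONTACT, actor=focal, partner=p)
        ]
        durations_diff = [
            e.duration_frames
            for p in diff
            for e in ethogram.by_type(CONTACT, actor=focal, partner=p)
        ]
        out[focal] = PartnerBreakdown(
            animal_id=focal,
            genotype=design.genotype[focal],
            contact_frames_same=sum(frames[p] for p in same),
            contact_frames_diff=sum(frames[p] for p in diff),
            approaches_same=sum(
                ethogram.count(APPROACH_CONTACT, actor=focal, partner=p)
                for p in same
            ),
            approaches_diff=sum(
                ethogram.count(APPROACH_CONTACT, actor=focal, partner=p)
                for p in diff
            ),
            mean_duration_same=(
                float(np.mean(durations_same)) if durations_same else float("nan")
            ),
            mean_duration_diff=(
                float(np.mean(durations_diff)) if durations_diff else float("nan")
            ),
        )
    return out


@dataclass
class ChanceTestResult:
    group: str
    n: int
    mean_proportion: float
    chance_level: float
    result: TestResult


def test_vs_chance(
    proportions, chance_level: float = 1.0 / 3.0, group: str = ""
) -> ChanceTestResult:
    """Test same-genotype interaction proportions against the chance level."""
    x = np.asarray(proportions, float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValueError("test_vs_chance needs n >= 3 finite proportions")
    res = test_vs_value(x, chance_level)
    return ChanceTestResult(
        group=group, n=len(x), mean_proportion=float(x.mean()),
        chance_level=chance_level, result=res,
    )


def compare_mean_durations(
    breakdowns: list[PartnerBreakdown],
) -> TestResult:
    """Paired comparison of same- vs different-genotype mean contact
    durations across focal animals (normality-gated paired t / Wilcoxon)."""
    pairs = [
        (b.mean_duration_same, b.mean_duration_diff)
        for b in breakdowns
        if np.isfinite(b.mean_duration_same) and np.isfinite(b.mean_duration_diff)
    ]
    if len(pairs) < 3:
        raise ValueError("compare_mean_durations needs n >= 3 complete pairs")
    same = np.array([p[0] for p in pairs])
    diff = np.array([p[1] for p in pairs])
    return gated_two_sample_test(same, diff, paired=True)


def breakdown_table(breakdowns: dict[str, PartnerBreakdown]) -> pd.DataFrame:
    rows = [
        {
            "animal_id": b.animal_id,
            "genotype": b.genotype,
            "proportion_same_time": b.proportion_same_time,
            "proportion_same_approaches": b.proportion_same_approaches,
            "mean_dur_same": b.mean_duration_same,
            "mean_dur_diff": b.mean_duration_diff,
        }
        for b in breakdowns.values()
    ]
    return pd.DataFrame(rows)
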