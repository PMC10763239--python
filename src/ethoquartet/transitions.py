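"""Exclusive behavioural events and transition analysis.

The overlapping ethogram is decomposed into 12 mutually exclusive per-frame
states per animal (move, idle, the specific contact types and their named
combinations, a catch-all "other contact", and "undetected"), so that each
animal is engaged in exactly one event at each time frame.  Transition
proportions p(A->B) divide the number of A-to-B transitions by the total
number of occurrences of A; genotype comparisons Bonferroni-correct over
the 12 x 11 = 132 ordered label pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .kinematics import speed_cm_s
from .model import Ethogram, EventInterval, TrajectorySet
from .stats import cohens_d, gated_two_sample_test

__all__ = [
    "EXCLUSIVE_LABELS",
    "TransitionMatrix",
    "assign_exclusive_labels",
    "merge_to_exclusive_events",
    "count_transitions",
    "compare_transitions",
    "n_ordered_label_pairs",
]

MOVE = "move"
IDLE = "idle"
NN = "nose-nose"
NG = "nose-anogenital"
NG_PASS = "passive nose-anogenital"
SS = "side-side"
SS_HTT = "side-side head-to-tail"
NN_SS = "nose-nose & side-side"
NG_SS_HTT = "nose-anogenital & side-side head-to-tail"
NG_PASS_SS_HTT = "passive nose-anogenital & side-side head-to-tail"
OTHER_CONTACT = "other contact"
UNDETECTED = "undetected"

#: The 12 exclusive per-frame states, in precedence order (an "undetected"
#: frame wins over everything; combined states win over their components;
#: any remaining contact frame falls into "other contact"; a detected
#: non-contact frame is "move" or "idle" by the speed threshold).
EXCLUSIVE_LABELS: tuple[str, ...] = (
    UNDETECTED, NN_SS, NG_SS_HTT, NG_PASS_SS_HTT, NN, NG, NG_PASS,
    SS, SS_HTT, OTHER_CONTACT, MOVE, IDLE,
)

#: Display order used in output tables (alphabetic stability not needed;
#: simple first, contacts after, undetected last).
LABEL_ORDER: tuple[str, ...] = (
    MOVE, IDLE, NN, NG, NG_PASS, SS, SS_HTT, NN_SS, NG_SS_HTT,
    NG_PASS_SS_HTT, OTHER_CONTACT, UNDETECTED,
)


def n_ordered_label_pairs() -> int:
    """Number of ordered pairs of distinct exclusive labels (the Bonferroni
    factor of the transition comparison)."""
    k = len(EXCLUSIVE_LABELS)
    return k * (k - 1)


def assign_exclusive_labels(
    ethogram: Ethogram,
    traj: TrajectorySet,
    config: AnalysisConfig,
) -> dict[str, np.ndarray]:
    """One exclusive label per animal per frame, by precedence.

    The combined states require the two component contacts with the *same*
    partner on the same frame.  Precedence (highest first): undetected,
    nose-nose & side-side, (passive) nose-anogenital & side-side
    head-to-tail, nose-nose, nose-anogenital, passive nose-anogenital,
    side-side, side-side head-to-tail, other contact, move, idle.
    """
    n = traj.n_frames
    labels: dict[str, np.ndarray] = {}
    for aid in traj.animals:
        track = traj.track(aid)
        partners = [p for p in traj.animals if p != aid]
        nn = np.zeros(n, bool)
        ng = np.zeros(n, bool)
        ng_pass = np.zeros(n, bool)
        ss = np.zeros(n, bool)
        ss_htt = np.zeros(n, bool)
        nn_ss = np.zeros(n, bool)
        ng_ss_htt = np.zeros(n, bool)
        ng_pass_ss_htt = np.zeros(n, bool)
        contact = np.zeros(n, bool)
        for p in partners:
            c = ethogram.mask(n, "contact", actor=aid, partner=p)
            nn_p = ethogram.mask(n, "nose-nose", actor=aid, partner=p)
            ng_p = ethogram.mask(n, "nose-anogenital", actor=aid, partner=p)
            ngr_p = ethogram.mask(n, "nose-anogenital", actor=p, partner=aid)
            ss_p = ethogram.mask(n, "side-side", actor=aid, partner=p)
            htt_p = ethogram.mask(n, "side-side head-to-tail", actor=aid, partner=p)
            contact |= c
            nn |= nn_p
            ng |= ng_p
            ng_pass |= ngr_p
            ss |= ss_p
            ss_htt |= htt_p
            nn_ss |= nn_p & ss_p
            ng_ss_htt |= ng_p & htt_p
            ng_pass_ss_htt |= ngr_p & htt_p
        speed = speed_cm_s(track, traj.fps)
        with np.errstate(invalid="ignore"):
            moving = speed > config.speed_threshold_cm_s
        undet = ~track.detected
        idx = np.select(
            [
                undet,
                nn_ss,
                ng_ss_htt,
                ng_pass_ss_htt,
                nn,
                ng,
                ng_pass,
                ss,
                ss_htt,
                contact,
                moving,
            ],
            [EXCLUSIVE_LABELS.index(l) for l in (
                UNDETECTED, NN_SS, NG_SS_HTT, NG_PASS_SS_HTT, NN, NG,
                NG_PASS, SS, SS_HTT, OTHER_CONTACT, MOVE,
            )],
            default=EXCLUSIVE_LABELS.index(IDLE),
        )
        labels[aid] = idx.astype(np.int8)
    return labels


def merge_to_exclusive_events(
    labels: np.ndarray, actor: str = ""
) -> list[EventInterval]:
    """Run-length encode a per-frame label sequence into exclusive intervals.

    Concatenating the returned intervals reproduces the label sequence
    exactly; consecutive intervals never share a label.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [labels.size - 1]))
    return [
        EventInterval(
            EXCLUSIVE_LABELS[int(labels[s])], actor, frozenset(), int(s), int(e)
        )
        for s, e in zip(starts, ends)
    ]


@dataclass
class TransitionMatrix:
    """Transition counts and proportions over the 12 exclusive labels.

    ``occurrences[A]`` counts every occurrence of A including a final,
    successor-less one, matching a denominator of "total number of
    occurrences of event A"; with ``exclude_terminal=True`` the proportions
    instead divide by the number of occurrences that have a successor, so
    rows normalise exactly to 1.
    """

    counts: np.ndarray       # (12, 12) int, counts[A, B] = n(A -> B)
    occurrences: np.ndarray  # (12,) int
    terminal: int | None     # label index of the final interval, or None
    labels: tuple[str, ...] = EXCLUSIVE_LABELS

    def proportions(self, exclude_terminal: bool = False) -> np.ndarray:
        denom = self.occurrences.astype(float).copy()
        if exclude_terminal and self.terminal is not None:
            denom[self.terminal] -= 1
        with np.errstate(divide="ignore", invalid="ignore"):
            p = self.counts / denom[:, None]
        p[denom == 0] = np.nan
        return p

    def proportion(self, a: str, b: str, exclude_terminal: bool = False) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.proportions(exclude_terminal)[i, j])


def count_transitions(
    events: list[EventInterval] | np.ndarray,
) -> TransitionMatrix:
    """Count ordered transitions between consecutive exclusive intervals.

    Accepts either the interval list from :func:`merge_to_exclusive_events`
    or a raw per-frame label-index sequence.  A single-interval sequence
    yields a zero matrix with n(A) = 1 for that label.
    """
    if isinstance(events, np.ndarray):
        seq = [int(l) for l in events[
            np.concatenate(([True], events[1:] != events[:-1]))
        ]] if events.size else []
    else:
        seq = [EXCLUSIVE_LABELS.index(e.event_type) for e in events]
    k = len(EXCLUSIVE_LABELS)
    counts = np.zeros((k, k), dtype=np.int64)
    occ = np.zeros(k, dtype=np.int64)
    for lab in seq:
        occ[lab] += 1
    for a, b in zip(seq, seq[1:]):
        counts[a, b] += 1
    terminal = seq[-1] if seq else None
    return TransitionMatrix(counts=counts, occurrences=occ, terminal=terminal)


def transitions_table(matrix: TransitionMatrix, animal_id: str = "") -> pd.DataFrame:
    """Tidy per-ordered-pair counts and proportions."""
    p = matrix.proportions()
    rows = []
    for a in LABEL_ORDER:
        i = EXCLUSIVE_LABELS.index(a)
        for b in LABEL_ORDER:
            if a == b:
                continue
            j = EXCLUSIVE_LABELS.index(b)
            rows.append(
                {
                    "animal_id": animal_id,
                    "from": a,
                    "to": b,
                    "count": int(matrix.counts[i, j]),
                    "occurrences_from": int(matrix.occurrences[i]),
                    "proportion": float(p[i, j]),
                }
            )
    return pd.DataFrame(rows)


def compare_transitions(
    matrices_a: list[TransitionMatrix],
    matrices_b: list[TransitionMatrix],
    group_a: str = "wt",
    group_b: str = "del",
    alpha_gate: float = 0.05,
) -> pd.DataFrame:
    """Per-ordered-pair genotype comparison of transition proportions.

    For each of the 132 ordered pairs of distinct labels, individuals'
    proportions are compared between the groups with a Shapiro-Wilk-gated
    Student t-test / Mann-Whitney U; raw p-values are Bonferroni-multiplied
    by 132 (capped at 1) and the effect size is Cohen's d on the raw
    proportions.  Individuals in which the source event never occurs are
    dropped; pairs with fewer than 2 usable individuals per group, or zero
    variance in both groups, are emitted with ``skipped=True``.
    """
    if len(matrices_a) < 2 or len(matrices_b) < 2:
        raise ValueError("need at least 2 individuals per group")
    n_tests = n_ordered_label_pairs()
    props_a = np.array([m.proportions() for m in matrices_a])
    props_b = np.array([m.proportions() for m in matrices_b])
    rows = []
    for a in LABEL_ORDER:
        i = EXCLUSIVE_LABELS.index(a)
        for b in LABEL_ORDER:
            if a == b:
                continue
            j = EXCLUSIVE_LABELS.index(b)
            xa = props_a[:, i, j]
            xb = props_b[:, i, j]
            xa = xa[np.isfinite(xa)]
            xb = xb[np.isfinite(xb)]
            row = {
                "from": a, "to": b,
                "n_" + group_a: len(xa), "n_" + group_b: len(xb),
            }
            both_const = (
                len(xa) > 0 and len(xb) > 0
                and np.ptp(xa) == 0 and np.ptp(xb) == 0
            )
            if len(xa) < 2 or len(xb) < 2 or both_const:
                row.update(
                    statistic=np.nan, p_raw=np.nan, p_corrected=np.nan,
                    cohens_d=np.nan, test="", skipped=True,
                )
            else:
                res = gated_two_sample_test(xa, xb, paired=False, alpha=alpha_gate)
                row.update(
                    statistic=res.statistic,
                    p_raw=res.p,
                    p_corrected=min(1.0, res.p * n_tests),
                    cohens_d=cohens_d(xa, xb),
                    test=res.test,
                    skipped=False,
                )
            rows.append(row)
    return pd.DataFrame(rows)
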