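"""Monte-Carlo calibration and cross-validation suites.

Seeded, repeatable checks that the statistics layer is calibrated under the
synthetic null conditions (type-I error of the mixed model, rejection rate
of the chance-level test), that scripted genotype effects are recovered
with the correct sign, and that the vectorised detector agrees with the
naive per-frame labeller on batches of simulated recordings.
"""

from __future__ import annotations

import numpy as np

from .bruteforce import compare_detector_to_bruteforce
from .config import AnalysisConfig
from .detection import detect_all
from .model import CONTACT
from .selective import test_vs_chance
from .simulate import (
    SimulationConfig,
    simulate_null_phenotype,
    simulate_pair_with_usv,
    simulate_quartet,
    uniform_partner_null,
)
from .stats import cohens_d, fit_genotype_lmm

__all__ = [
    "lmm_type1_error",
    "chance_test_rejection_rate",
    "speed_effect_sign_recovery",
    "contact_duration_effect_recovery",
    "detector_oracle_agreement",
]


def lmm_type1_error(
    n_replicates: int = 500,
    n_cages: int = 8,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the genotype LMM on null phenotypes.

    Each replicate draws per-animal values with a cage random effect and no
    genotype effect (8 cages x 4 animals by default) and fits the
    random-intercept model; returns the fraction of Wald p-values below
    ``alpha``.  A calibrated model stays near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        df = simulate_null_phenotype(
            n_cages=n_cages, seed=int(rng.integers(2**31 - 1))
        )
        res = fit_genotype_lmm(df)
        if np.isfinite(res.p) and res.p < alpha:
            rejections += 1
    return rejections / n_replicates


def chance_test_rejection_rate(
    n_replicates: int = 1000,
    n_animals: int = 16,
    n_choices: int = 250,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the test against the 1/3 chance level when partner
    choice really is uniform (each animal's proportion estimated from
    ``n_choices`` independent draws)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        props = uniform_partner_null(
            n_choices, seed=int(rng.integers(2**31 - 1)),
            n_replicates=n_animals,
        )
        res = test_vs_chance(props)
        if np.isfinite(res.result.p) and res.result.p < alpha:
            rejections += 1
    return rejections / n_replicates


def speed_effect_sign_recovery(
    n_replicates: int = 100,
    n_cages: int = 8,
    speed_mult: float = 1.3,
    duration_s: float = 120.0,
    seed: int = 0,
) -> float:
    """Fraction of replicates in which the LMM on per-animal distance
    travelled recovers a positive Del/+ coefficient when Del/+ animals move
    ``speed_mult`` times faster."""
    rng = np.random.default_rng(seed)
    correct = 0
    sc = SimulationConfig(
        n_animals=4, duration_s=duration_s, del_speed_mult=speed_mult
    )
    for _ in range(n_replicates):
        rows = []
        for c in range(n_cages):
            traj, design, _ = simulate_quartet(
                sc, seed=int(rng.integers(2**31 - 1)), cage_id=f"c{c}"
            )
            for aid in traj.animals:
                t = traj.track(aid)
                steps = np.hypot(*(t.center[1:] - t.center[:-1]).T)
                rows.append(
                    {
                        "value": float(steps.sum()),
                        "genotype": design.genotype[aid],
                        "cage": f"c{c}",
                    }
                )
        import pandas as pd

        res = fit_genotype_lmm(pd.DataFrame(rows))
        if res.beta > 0:
            correct += 1
    return correct / n_replicates


def contact_duration_effect_recovery(
    n_replicates: int = 100,
    n_cages: int = 6,
    leave_mult: float = 2.0,
    duration_s: float = 300.0,
    seed: int = 0,
    config: AnalysisConfig | None = None,
) -> float:
    """Fraction of replicates in which doubling the Del/+ contact-leaving
    rate yields shorter detected mean contact durations for Del/+ animals
    (Cohen's d of Del/+ vs wt per-animal mean durations below 0)."""
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    sc = SimulationConfig(
        n_animals=4, duration_s=duration_s, del_leave_mult=leave_mult
    )
    correct = 0
    for _ in range(n_replicates):
        del_means, wt_means = [], []
        for c in range(n_cages):
            traj, design, _ = simulate_quartet(
                sc, seed=int(rng.integers(2**31 - 1)), cage_id=f"c{c}"
            )
            eth = detect_all(traj, config)
            for aid in traj.animals:
                durations = [
                    e.duration_frames for e in eth.by_type(CONTACT, actor=aid)
                ]
                if not durations:
                    continue
                target = (
                    del_means if design.genotype[aid] == "del" else wt_means
                )
                target.append(float(np.mean(durations)))
        d = cohens_d(del_means, wt_means)
        if np.isfinite(d) and d < 0:
            correct += 1
    return correct / n_replicates


def detector_oracle_agreement(
    n_trajectories: int = 100,
    n_frames: int = 1000,
    seed: int = 0,
    n_quartets: int = 20,
    config: AnalysisConfig | None = None,
) -> float:
    """Fraction of random scripted trajectories on which the vectorised
    detector's intervals exactly equal the run-length-encoded brute-force
    per-frame labels, for every event type."""
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    duration = n_frames / 30.0
    agreeing = 0
    for i in range(n_trajectories):
        sub = int(rng.integers(2**31 - 1))
        if i < n_quartets:
            traj, _, _ = simulate_quartet(
                SimulationConfig(
                    n_animals=4, duration_s=duration,
                    detection_dropout=0.02 if i % 2 else 0.0,
                ),
                seed=sub,
            )
        else:
            traj, _, _, _ = simulate_pair_with_usv(
                SimulationConfig(
                    n_animals=2, duration_s=duration,
                    detection_dropout=0.02 if i % 2 else 0.0,
                ),
                seed=sub,
            )
        mism = compare_detector_to_bruteforce(traj, config)
        if all(v == 0 for v in mism.values()):
            agreeing += 1
    return agreeing / n_trajectories
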