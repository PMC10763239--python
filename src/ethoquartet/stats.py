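"""Genotype-comparison statistics.

The central model is a linear mixed model with genotype as fixed factor and
cage (quartet or pair) as random intercept, fitted by REML with a Wald test
on the genotype coefficient.  Around it: per-cage z-score profiles of
mutant animals (centred and reduced by the whole cage's mean and sample
SD), normality-gated parametric/non-parametric test selection (Shapiro-Wilk
gate, plus a Fisher-Snedecor equal-variance gate for unpaired t), and
Cohen's d with an (n-1)-weighted pooled SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LMMResult",
    "TestResult",
    "ZScoreProfile",
    "fit_genotype_lmm",
    "cage_zscore_profile",
    "gated_two_sample_test",
    "test_vs_value",
    "cohens_d",
]


@dataclass
class LMMResult:
    beta: float
    se: float
    p: float
    log_likelihood: float
    n: int
    n_groups: int
    converged: bool
    singular: bool

    @property
    def flagged(self) -> bool:
        return self.singular or not self.converged


@dataclass
class TestResult:
    statistic: float
    p: float
    test: str            # 't', 'paired-t', 'wilcoxon', 'mann-whitney', 'one-sample-t'
    n: tuple[int, ...]
    effect_size: float | None = None
    gates: dict = field(default_factory=dict)
    degenerate: bool = False


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> tuple[bool, float]:
    """Shapiro-Wilk gate; constant samples count as non-normal."""
    x = np.asarray(x, float)
    if len(x) < 3 or np.ptp(x) == 0:
        return False, np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = sps.shapiro(x)
    return p > alpha, float(p)


def _equal_variance(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> tuple[bool, float]:
    """Two-sided F test of variance equality (Fisher-Snedecor)."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 or vb == 0:
        return False, np.nan
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2.0 * min(sps.f.cdf(f, dfa, dfb), sps.f.sf(f, dfa, dfb))
    return p > alpha, float(min(p, 1.0))


def cohens_d(a, b) -> float:
    """(mean a - mean b) / pooled SD, pooled with n-1 weights.

    Returns NaN (flagged undefined) when the pooled SD is zero.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("cohens_d needs n >= 2 per sample")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
        na + nb - 2
    )
    if sp2 == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def gated_two_sample_test(
    a, b, paired: bool = False, alpha: float = 0.05
) -> TestResult:
    """Student's t-test when both samples pass the Shapiro-Wilk gate (and,
    unpaired, the equal-variance gate), else the non-parametric counterpart
    (Wilcoxon signed-rank if paired, Mann-Whitney U if not)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("gated test needs n >= 3 per sample")
    if paired and len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    norm_a, p_a = _is_normal(a, alpha)
    norm_b, p_b = _is_normal(b, alpha)
    gates = {"shapiro_p_a": p_a, "shapiro_p_b": p_b}
    parametric = norm_a and norm_b
    if not paired and parametric:
        eq, p_var = _equal_variance(a, b, alpha)
        gates["fisher_p"] = p_var
        parametric = parametric and eq
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return TestResult(
            statistic=0.0, p=1.0, test="degenerate", n=(len(a), len(b)),
            gates=gates, degenerate=True,
        )
    if paired:
        if np.all(a == b):
            return TestResult(0.0, 1.0, "degenerate", (len(a), len(b)),
                              gates=gates, degenerate=True)
        if parametric:
            stat, p = sps.ttest_rel(a, b)
            test = "paired-t"
        else:
            stat, p = sps.wilcoxon(a, b)
            test = "wilcoxon"
    else:
        if parametric:
            stat, p = sps.ttest_ind(a, b)
            test = "t"
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann-whitney"
    return TestResult(
        statistic=float(stat), p=float(p), test=test, n=(len(a), len(b)),
        effect_size=cohens_d(a, b) if len(a) > 1 and len(b) > 1 else None,
        gates=gates,
    )


def test_vs_value(x, value: float, alpha: float = 0.05) -> TestResult:
    """One-sample test of ``x`` against ``value``: t if Shapiro passes,
    else Wilcoxon signed-rank on the differences.  Zero-variance input is
    returned as a degenerate result without a p-value."""
    x = np.asarray(x, float)
    if len(x) < 3:
        raise ValueError("one-sample test needs n >= 3")
    if np.ptp(x) == 0:
        stat = 0.0 if x[0] == value else np.nan
        return TestResult(
            statistic=stat, p=np.nan, test="degenerate", n=(len(x),),
            degenerate=True,
        )
    normal, p_sh = _is_normal(x, alpha)
    if normal:
        stat, p = sps.ttest_1samp(x, value)
        test = "one-sample-t"
    else:
        diff = x - value
        if np.all(diff == 0):
            return TestResult(0.0, 1.0, "wilcoxon", (len(x),), degenerate=True)
        stat, p = sps.wilcoxon(diff)
        test = "wilcoxon"
    return TestResult(
        statistic=float(stat), p=float(p), test=test, n=(len(x),),
        gates={"shapiro_p": p_sh},
    )


def fit_genotype_lmm(
    values: pd.DataFrame | dict,
    design=None,
) -> LMMResult:
    """Random-intercept LMM of a per-animal variable on genotype.

    ``values`` is either a tidy DataFrame with columns value, genotype
    ('wt'/'del') and cage, or a mapping animal_id -> value combined with a
    :class:`~ethoquartet.model.GroupDesign`.  Genotype is coded wt=0,
    del=1, so beta is the del - wt shift.  Fitted by REML; the p-value is
    the Wald z test of the genotype coefficient.
    """
    import statsmodels.api as sm

    if isinstance(values, dict):
        if design is None:
            raise ValueError("a GroupDesign is required with a value mapping")
        df = pd.DataFrame(
            {
                "value": list(values.values()),
                "genotype": [design.genotype[a] for a in values],
                "cage": [design.cage[a] for a in values],
            }
        )
    else:
        df = values.copy()
    for col in ("value", "genotype", "cage"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    if df["cage"].nunique() < 2:
        raise ValueError("LMM needs at least 2 cages")
    if df["genotype"].nunique() < 2:
        raise ValueError("LMM needs both genotypes")
    if np.ptp(df["value"].to_numpy(float)) == 0:
        return LMMResult(
            beta=0.0, se=np.nan, p=np.nan, log_likelihood=np.nan,
            n=len(df), n_groups=df["cage"].nunique(),
            converged=False, singular=True,
        )
    df = df.assign(g=(df["genotype"] == "del").astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula("value ~ g", groups="cage", data=df)
        fit = model.fit(reml=True)
    beta = float(fit.params["g"])
    se = float(fit.bse["g"])
    p = float(fit.pvalues["g"])
    re_var = float(np.squeeze(fit.cov_re))
    return LMMResult(
        beta=beta, se=se, p=p, log_likelihood=float(fit.llf),
        n=len(df), n_groups=df["cage"].nunique(),
        converged=bool(fit.converged), singular=re_var <= 1e-10,
    )


@dataclass
class ZScoreProfile:
    """Per-mutant-animal cage z-scores for one variable, with the test vs 0."""

    z: dict[str, float]          # del animal -> z-score
    excluded_cages: list[str]
    test: TestResult | None


def cage_zscore_profile(values: dict[str, float], design) -> ZScoreProfile:
    """Centre/reduce each animal's value by its whole cage's mean and
    sample SD (N-1), then test the Del/+ z-scores against 0 (Shapiro-gated
    one-sample t / Wilcoxon).  Cages with zero SD are excluded with a
    warning."""
    z: dict[str, float] = {}
    excluded: list[str] = []
    for cage_id in design.cages():
        members = [a for a in design.cage_members(cage_id) if a in values]
        if len(members) < 2:
            continue
        vals = np.array([values[a] for a in members], float)
        sd = vals.std(ddof=1)
        if sd == 0:
            excluded.append(cage_id)
            warnings.warn(
                f"cage {cage_id}: zero SD, z-scores undefined", stacklevel=2
            )
            continue
        mean = vals.mean()
        for a, v in zip(members, vals):
            if design.genotype[a] == "del":
                z[a] = float((v - mean) / sd)
    test = None
    if len(z) >= 3:
        test = test_vs_value(np.array(list(z.values())), 0.0)
    return ZScoreProfile(z=z, excluded_cages=excluded, test=test)
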