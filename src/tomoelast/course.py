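"""Longitudinal disease-course statistics.

Covers the relapsing-remitting paradigm correlation maps (voxelwise Pearson
r of the stiffness time course against a phase-indexed template, with
parametric two-sided P values), the random-intercept mixed model of
stiffness against disability score, and the classical group tests used on
regional means (paired/Welch t tests, repeated-measures one-way ANOVA,
Holm-Bonferroni correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .cohort import EAE_PHASES
from .params import ParamMap

#: template values per EAE phase: linear softening baseline -> peak,
#: partial remission recovery, relapse drop.  Pearson r is affine-invariant,
#: so only the ordinal shape of these constants matters.
TEMPLATE_VALUES = {
    "baseline": 1.00, "pre-onset": 0.67, "onset": 0.33,
    "peak": 0.00, "remission": 0.60, "relapse": 0.20,
}


@dataclass
class ParadigmTemplate:
    phases: Tuple[str, ...]
    values: Tuple[float, ...]

    def __post_init__(self):
        if len(self.phases) < 3:
            raise ValueError("a paradigm needs at least 3 phases")
        if len(set(self.values)) < 2:
            raise ValueError("template must not be constant")


def paradigm_template(phases: Sequence[str] = EAE_PHASES) -> ParadigmTemplate:
    """Relapsing-remitting template subset to the available phases."""
    phases = tuple(phases)
    unknown = set(phases) - set(EAE_PHASES)
    if unknown:
        raise ValueError(f"unknown phases {sorted(unknown)}")
    order = [p for p in EAE_PHASES if p in phases]
    if tuple(order) != phases:
        raise ValueError("phases must follow the EAE phase order")
    if len(phases) < 3:
        raise ValueError("a paradigm needs at least 3 phases")
    return ParadigmTemplate(phases, tuple(TEMPLATE_VALUES[p] for p in phases))


@dataclass
class ParadigmFitMaps:
    r: ParamMap
    p: ParamMap
    n_timepoints: int
    n_constant_series: int


def paradigm_fit_maps(maps: Sequence[ParamMap],
                      template: ParadigmTemplate) -> ParadigmFitMaps:
    """Voxelwise Pearson correlation of the time course with the template.

    One map per template phase, on a common grid; a voxel is used only if
    valid at every phase.  P values are parametric and two-sided, from
    t = r sqrt((T-2)/(1-r^2)) with T-2 degrees of freedom; voxels with a
    constant time series are masked and counted.
    """
    if len(maps) != len(template.phases):
        raise ValueError("need exactly one map per template phase")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("maps must share one grid")
    T = len(maps)
    X = np.stack([m.values for m in maps])          # (T, *grid)
    valid = np.all(np.stack([m.mask for m in maps]), axis=0)

    t = np.asarray(template.values, dtype=float)
    t_c = t - t.mean()
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    st = np.sqrt((t_c ** 2).sum())
    constant = valid & (sx == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.tensordot(t_c, Xc, axes=1) / (sx * st)
    r = np.clip(r, -1.0, 1.0)
    ok = valid & ~constant & np.isfinite(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((T - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(tstat), T - 2)

    spacing = maps[0].spacing
    rmap = ParamMap(np.where(ok, r, np.nan), "1", spacing, mask=ok, name="r")
    pmap = ParamMap(np.where(ok, p, np.nan), "1", spacing, mask=ok, name="P")
    return ParadigmFitMaps(rmap, pmap, T, int(constant.sum()))


# --------------------------------------------------------------------------
# mixed model
# --------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    intercept: float
    slope: float            # m/s per score unit
    slope_se: float
    slope_p: float
    slope_ci: Tuple[float, float]
    random_intercept_sd: float
    residual_sd: float
    n_observations: int
    n_subjects: int


def mixed_model_fit(table: pd.DataFrame, value: str = "value",
                    score: str = "score",
                    subject: str = "subject") -> MixedModelResult:
    """Random-intercept linear mixed model value ~ score, (1 | subject).

    Fit by restricted maximum likelihood; the slope's P value and 95 % CI
    are Wald-based.
    """
    df = table[[subject, score, value]].dropna()
    n_subj = df[subject].nunique()
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if df[score].nunique() < 2:
        raise ValueError("no fixed-effect variance: score is constant")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(f"{value} ~ {score}", df, groups=df[subject])
        res = model.fit(reml=True, method=["lbfgs", "powell"])
    ci = res.conf_int().loc[score]
    return MixedModelResult(
        intercept=float(res.params["Intercept"]),
        slope=float(res.params[score]),
        slope_se=float(res.bse[score]),
        slope_p=float(res.pvalues[score]),
        slope_ci=(float(ci[0]), float(ci[1])),
        random_intercept_sd=float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0))),
        residual_sd=float(np.sqrt(res.scale)),
        n_observations=int(len(df)),
        n_subjects=int(n_subj),
    )


# --------------------------------------------------------------------------
# classical tests
# --------------------------------------------------------------------------

def pearson_corr(x, y) -> Tuple[float, float]:
    """Pearson r with two-sided t-based P value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("inputs must not be constant")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def t_test(x, y, paired: bool = False, welch: bool = True) -> Tuple[float, float]:
    """Two-sided t test; unpaired defaults to the Welch correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal lengths")
        if len(x) < 2:
            raise ValueError("need n >= 2 per arm")
        if np.ptp(x - y) == 0 and np.all(x == y):
            return 0.0, 1.0
        res = sps.ttest_rel(x, y)
    else:
        if len(x) < 2 or len(y) < 2:
            raise ValueError("need n >= 2 per arm")
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            raise ValueError("zero variance in both arms")
        res = sps.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def rm_anova(matrix: np.ndarray) -> Tuple[float, float]:
    """One-way repeated-measures ANOVA on a (subjects x timepoints) matrix.

    Subjects with any missing value are dropped (listwise deletion, with a
    warning reporting how many); F has (T-1, (T-1)(n-1)) degrees of freedom.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a subjects x timepoints matrix")
    complete = ~np.isnan(m).any(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} incomplete subject(s)", stacklevel=2)
    m = m[complete]
    n, T = m.shape
    if n < 2 or T < 2:
        raise ValueError("need >= 2 subjects and >= 2 timepoints")
    grand = m.mean()
    ss_time = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_subj = T * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = max(ss_total - ss_time - ss_subj, 0.0)
    df_time = T - 1
    df_err = (T - 1) * (n - 1)
    if ss_time <= 1e-12 * max(ss_total, 1e-300):
        return 0.0, 1.0  # no timepoint effect at all
    if ss_err == 0.0:
        return float("inf"), 0.0
    F = (ss_time / df_time) / (ss_err / df_err)
    return float(F), float(sps.f.sf(F, df_time, df_err))


def holm_bonferroni(pvals) -> np.ndarray:
    """Step-down Holm-adjusted P values, in the original order."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]
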