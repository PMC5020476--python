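"""Cohort statistics: two-group tests, rank correlation, hypertension staging,
and the random-intercept linear mixed-effects model for aortic distensibility.

Group contrasts use the Mann-Whitney U test (exact two-tailed p by enumeration
for small untied samples, normal approximation with tie and continuity
correction otherwise) and Spearman's rank correlation.  Regional distensibility
is modelled as

    D_ij = b0 + b1 * age_at_repair_i + b2 * age_at_mri_i
           + location contrasts + u_i + e_ij

with a subject-level random intercept u_i absorbing intra-patient correlation
of the four aortic measurement sites, fit by REML.  Location enters through a
treatment contrast with the descending aorta at the diaphragm — the site least
affected by coarctation — as the reference level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lumen import AORTIC_LOCATIONS

EXACT_MW_LIMIT = 12  # n + m at or below this (and no ties): exact enumeration

DISTENSIBILITY_REFERENCE_LOCATION = "descending aorta at diaphragm"


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    degenerate: bool = False

    def __iter__(self):  # allow ``u, p = mann_whitney(...)``
        return iter((self.u, self.p))


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U is computed with midrank tie handling.  For pooled sizes n+m <= 12 with
    no ties the two-tailed p comes from the exact permutation distribution;
    otherwise the normal approximation with tie correction and continuity
    correction is used.  Two completely identical samples are reported as
    p = 1 with a ``degenerate`` flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(u=x.size * y.size / 2.0, p=1.0, degenerate=True)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-tailed p (t approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rank correlation undefined: zero variance in ranks")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def stage_hypertension_adult(systolic: float, diastolic: float) -> str:
    """Adult (>= 18 y) blood-pressure stage from cuff systolic/diastolic.

    Stage 1: systolic 140-159 and/or diastolic 90-99 mmHg; stage 2: systolic
    160-179 and/or diastolic 100-109 mmHg; the higher of the two component
    stages wins; above the stage-2 ranges -> ``"above-stage2"``.
    """

    def component(value: float, s1_lo: float, s2_lo: float, above_lo: float) -> int:
        if value >= above_lo:
            return 3
        if value >= s2_lo:
            return 2
        if value >= s1_lo:
            return 1
        return 0

    stage = max(component(systolic, 140, 160, 180), component(diastolic, 90, 100, 110))
    return ("normal", "stage1", "stage2", "above-stage2")[stage]


@dataclass(frozen=True)
class LmeFit:
    """Random-intercept LME fit summary for regional distensibility."""

    fixed_effects: pd.DataFrame  # index: term; columns: coef, se, pvalue
    random_intercept_sd: float
    residual_sd: float
    n_subjects: int
    n_observations: int
    converged: bool = True
    reml: bool = True

    def coef(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "coef"])


def fit_distensibility_lme(
    table: pd.DataFrame,
    reference: str = DISTENSIBILITY_REFERENCE_LOCATION,
    reml: bool = True,
) -> LmeFit:
    """Fit the regional-distensibility mixed model on a long-format table.

    ``table`` needs columns ``subject_id, location, distensibility,
    age_at_repair, age_at_mri``; locations must come from the aortic
    controlled vocabulary.  Returns fixed-effect coefficients with Wald
    standard errors and p-values on a t distribution with residual degrees of
    freedom (n_observations - n_fixed_effects), plus the random-intercept and
    residual standard deviations.
    """
    import statsmodels.formula.api as smf

    required = {"subject_id", "location", "distensibility", "age_at_repair", "age_at_mri"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad = set(table["location"]) - set(AORTIC_LOCATIONS)
    if bad:
        raise ValueError(f"unknown locations: {sorted(bad)}")
    if table["location"].nunique() < 2:
        raise ValueError("singular design: need at least 2 measurement locations")
    obs_per_subject = table.groupby("subject_id").size()
    if (obs_per_subject >= 2).sum() < 2:
        raise ValueError("need at least 2 subjects with at least 2 locations each")

    data = table.copy()
    levels = [reference] + [loc for loc in AORTIC_LOCATIONS if loc != reference]
    data["location"] = pd.Categorical(data["location"], categories=levels)

    model = smf.mixedlm(
        "distensibility ~ age_at_repair + age_at_mri + C(location)",
        data=data,
        groups=data["subject_id"],
    )
    fit = None
    errors: list[str] = []
    for method in ("bfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                # boundary variance estimates are legitimate outcomes
                warnings.simplefilter("ignore")
                candidate = model.fit(reml=reml, method=[method])
        except (np.linalg.LinAlgError, ValueError) as exc:
            errors.append(f"{method}: {exc}")
            continue
        if candidate.converged:
            fit = candidate
            break
        errors.append(f"{method}: optimizer did not converge")
    if fit is None:
        raise RuntimeError("LME did not converge; attempts: " + "; ".join(errors))

    fe_names = list(fit.fe_params.index)
    coefs = fit.fe_params.to_numpy()
    ses = fit.bse_fe.to_numpy()
    df_resid = len(data) - len(fe_names)
    tvals = coefs / ses
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df=df_resid)
    fixed = pd.DataFrame({"coef": coefs, "se": ses, "pvalue": pvals}, index=fe_names)

    return LmeFit(
        fixed_effects=fixed,
        random_intercept_sd=float(np.sqrt(fit.cov_re.iloc[0, 0])),
        residual_sd=float(np.sqrt(fit.scale)),
        n_subjects=int(data["subject_id"].nunique()),
        n_observations=int(len(data)),
        converged=bool(fit.converged),
        reml=reml,
    )


def group_comparison_table(records: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Mann-Whitney comparison of every numeric column between two groups.

    Returns rows ``variable, patient_mean, patient_sd, control_mean,
    control_sd, n_patients, n_controls, p_value``; columns with fewer than two
    finite values in either group are skipped.
    """
    groups = sorted(records[group_col].unique())
    if set(groups) != {"control", "patient"}:
        raise ValueError("records must contain exactly the groups 'patient' and 'control'")
    pat = records[records[group_col] == "patient"]
    ctl = records[records[group_col] == "control"]
    rows = []
    for col in records.columns:
        if col == group_col or not pd.api.types.is_numeric_dtype(records[col]):
            continue
        xp = pat[col].dropna().to_numpy(dtype=float)
        xc = ctl[col].dropna().to_numpy(dtype=float)
        if xp.size < 2 or xc.size < 2:
            continue
        res = mann_whitney(xp, xc)
        rows.append(
            {
                "variable": col,
                "patient_mean": xp.mean(),
                "patient_sd": xp.std(ddof=1),
                "control_mean": xc.mean(),
                "control_sd": xc.std(ddof=1),
                "n_patients": xp.size,
                "n_controls": xc.size,
                "p_value": res.p,
            }
        )
    return pd.DataFrame(rows)
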