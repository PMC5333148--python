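"""Per-protein differential abundance, variance attribution and the
demographic/clinical group tests.

Differential abundance fits, for each protein eigengene,

    abundance ~ group + age + gender + nicotine + cannabis + alcohol + mandrax

and reports the omnibus group p-value together with the three pairwise
contrasts (MAP-Control, MAP-MA, MA-Control) under the single-step
max-|t| Tukey adjustment (see :mod:`srmdti.linmod`).

Demographic variables are tested with a normality-gated branch
(Shapiro-Wilk on residuals -> one-way ANOVA, else tie-corrected
Kruskal-Wallis); categorical traits with the tie-corrected
Kruskal-Wallis statistic on the binary indicator, which equals
((N-1)/N) times the Pearson chi-square of the group x trait table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .linmod import DEFAULT_COVARIATES, fit_group_model

logger = logging.getLogger(__name__)

EPQRS_SCORES = ("epqrs_psychoticism", "epqrs_extraversion", "epqrs_neuroticism")
PANSS_SCORES = ("panss_positive", "panss_negative", "panss_total")


@dataclass
class DiffAbundanceResult:
    protein_id: str
    omnibus_p: float
    pairwise: list  # of dicts: contrast, estimate, t, p_raw, adjusted_p
    covariates_used: list
    alpha: float = 0.05

    @property
    def significant_contrasts(self):
        return [c["contrast"] for c in self.pairwise
                if c["adjusted_p"] < self.alpha]


def _align(matrix: pd.DataFrame, cohort: pd.DataFrame):
    cohort = cohort.set_index("subject_id") if "subject_id" in cohort.columns \
        else cohort
    missing = [s for s in matrix.columns if s not in cohort.index]
    if missing:
        raise ValueError(f"subjects absent from cohort table: {missing}")
    c = cohort.loc[list(matrix.columns)].reset_index()
    return matrix, c


def differential_abundance(matrix: pd.DataFrame, cohort: pd.DataFrame,
                           covariates=DEFAULT_COVARIATES,
                           alpha: float = 0.05):
    """Covariate-adjusted group comparison for every protein.

    ``matrix`` is protein x subject (eigengenes); returns a list of
    :class:`DiffAbundanceResult`, Tukey-adjusted p < ``alpha`` marking a
    significant contrast.
    """
    matrix, c = _align(matrix, cohort)
    fit = fit_group_model(matrix.to_numpy(float).T, list(matrix.index), c,
                          covariates)
    out = []
    for j, pid in enumerate(fit.response_ids):
        pairwise = [{
            "contrast": f"{a}-{b}",
            "estimate": float(fit.estimates[i, j]),
            "t": float(fit.t_stats[i, j]),
            "p_raw": float(fit.raw_p[i, j]),
            "adjusted_p": float(fit.adjusted_p[i, j]),
        } for i, (a, b) in enumerate(fit.contrasts)]
        out.append(DiffAbundanceResult(
            protein_id=pid, omnibus_p=float(fit.omnibus_p[j]),
            pairwise=pairwise, covariates_used=fit.covariates_used,
            alpha=alpha))
    return out


@dataclass
class VarianceFractions:
    protein_id: str
    fractions: dict  # term -> fraction in [0, 1]; sums to 1
    method: str = "variance_components"


def _vc_fractions(y, c, cat_terms, cont_terms):
    """Random-intercept variance components for categorical terms, fixed
    explained share for continuous ones, via statsmodels MixedLM."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = c.copy()
    df["_y"] = y
    vc = {t: f"0 + C({t})" for t in cat_terms}
    fixed = "_y ~ 1" + "".join(f" + {t}" for t in cont_terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(fixed, df, groups=np.ones(len(df)), vc_formula=vc)
        res = model.fit(reml=True, method="lbfgs", maxiter=200)
    if not res.converged:
        raise RuntimeError("MixedLM did not converge")
    comps = {t: max(float(res.vcomp[i]), 0.0) for i, t in enumerate(vc)}
    resid = float(res.scale)
    cont = {}
    for t in cont_terms:
        b = float(res.params.get(t, 0.0))
        cont[t] = b * b * float(np.var(df[t].to_numpy(float), ddof=1))
    total = sum(comps.values()) + sum(cont.values()) + resid
    frac = {t: v / total for t, v in {**comps, **cont}.items()}
    frac["residual"] = resid / total
    return frac


def _anova_fractions(y, c, cat_terms, cont_terms):
    """Fallback: sequential sum-of-squares partial R^2."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = c.copy()
    df["_y"] = y
    terms = list(cont_terms) + [f"C({t})" for t in cat_terms]
    res = smf.ols("_y ~ " + " + ".join(terms), df).fit()
    tab = sm.stats.anova_lm(res, typ=1)
    ss = tab["sum_sq"]
    total = float(ss.sum())
    frac = {}
    for t in cont_terms:
        frac[t] = float(ss.get(t, 0.0)) / total
    for t in cat_terms:
        frac[t] = float(ss.get(f"C({t})", 0.0)) / total
    frac["residual"] = float(ss["Residual"]) / total
    return frac


def variance_fractions(matrix: pd.DataFrame, cohort: pd.DataFrame,
                       covariates=DEFAULT_COVARIATES):
    """Per-protein share of abundance variance attributable to each
    covariate (plus residual), normalized to sum to 1."""
    matrix, c = _align(matrix, cohort)
    c = c.copy()
    if "gender" in c.columns:
        c["gender"] = (c["gender"].astype(str).str.upper() == "M").astype(int)
    cat_terms = [t for t in covariates if t != "age" and t in c.columns
                 and c[t].nunique() > 1]
    cont_terms = [t for t in covariates if t == "age" and t in c.columns]
    out = []
    for pid, row in matrix.iterrows():
        y = row.to_numpy(float)
        try:
            frac = _vc_fractions(y, c, cat_terms, cont_terms)
            method = "variance_components"
        except Exception as exc:  # non-convergence contract
            logger.warning("variance components failed for %s (%s); "
                           "falling back to sequential SS", pid, exc)
            frac = _anova_fractions(y, c, cat_terms, cont_terms)
            method = "sequential_ss"
        s = sum(frac.values())
        frac = {k: v / s for k, v in frac.items()}
        out.append(VarianceFractions(pid, frac, method))
    return out


def demographic_group_test(values, groups):
    """Normality-gated omnibus test for a continuous demographic variable.

    Shapiro-Wilk on the group-mean residuals decides the branch: p >= 0.05
    -> one-way ANOVA; otherwise tie-corrected Kruskal-Wallis.  Returns
    (statistic, p, branch).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2 or len(values) < 3:
        raise ValueError("need at least 2 groups and 3 values")
    if np.ptp(values) == 0:
        raise ValueError("constant values: group test undefined")
    resid = values - pd.Series(values).groupby(pd.Series(groups)).transform("mean").to_numpy()
    if np.ptp(resid) == 0:
        # identical within groups -> normality vacuous; use KW
        sw_p = 0.0
    else:
        sw_p = float(stats.shapiro(resid).pvalue)
    samples = [values[groups == g] for g in np.unique(groups)]
    if sw_p >= 0.05:
        res = stats.f_oneway(*samples)
        return float(res.statistic), float(res.pvalue), "anova"
    if all(np.ptp(s) == 0 for s in samples) and \
            len({s[0] for s in samples}) == 1:
        return 0.0, 1.0, "kruskal"
    res = stats.kruskal(*samples)
    return float(res.statistic), float(res.pvalue), "kruskal"


def categorical_group_test(counts, totals=None, plain_chi2: bool = False):
    """Group association test for a binary trait.

    ``counts`` is either a (groups x 2) contingency table, or the per-group
    "yes" counts with ``totals`` giving group sizes.  The statistic is
    ((N-1)/N) x Pearson chi-square — identically the tie-corrected
    Kruskal-Wallis statistic on the 0/1 indicator; ``plain_chi2=True``
    reports the uncorrected Pearson chi-square instead.  p comes from the
    chi-square distribution with (groups - 1) df.
    """
    counts = np.asarray(counts, dtype=float)
    if totals is not None:
        totals = np.asarray(totals, dtype=float)
        counts = np.column_stack([counts, totals - counts])
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("expected a groups x 2 contingency table")
    if (counts < 0).any():
        raise ValueError("negative cell counts")
    row_tot = counts.sum(axis=1)
    if (row_tot == 0).any():
        raise ValueError("empty group row")
    col_tot = counts.sum(axis=0)
    if (col_tot == 0).any():
        warnings.warn("trait constant across the cohort; statistic 0")
        return 0.0, 1.0
    N = counts.sum()
    expected = np.outer(row_tot, col_tot) / N
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    stat = chi2 if plain_chi2 else (N - 1) / N * chi2
    p = float(stats.chi2.sf(stat, counts.shape[0] - 1))
    return stat, p


@dataclass
class PsychometricAssociation:
    protein_id: str
    score: str
    scope: str
    rho: float
    p: float
    n: int
    nominal: bool
    bonferroni: bool


def psychometric_correlation(matrix: pd.DataFrame, cohort: pd.DataFrame,
                             nominal_alpha: float = 0.05,
                             bonferroni_alpha: float = 0.01):
    """Spearman correlation of each protein with the EPQR-S scores across
    all subjects, and with PANSS scores within the MAP group.  Flags
    nominal (p < 0.05) and Bonferroni-level (p < 0.01) associations;
    associations with < 5 pairs or a constant score are skipped with a
    warning."""
    matrix, c = _align(matrix, cohort)
    out = []

    def _run(scores, mask, scope):
        sub = c[mask]
        for score in scores:
            if score not in c.columns:
                continue
            y = sub[score].to_numpy(float)
            ok = ~np.isnan(y)
            if ok.sum() < 5:
                warnings.warn(f"{score} ({scope}): <5 paired observations; "
                              "skipped")
                continue
            if np.ptp(y[ok]) == 0:
                warnings.warn(f"{score} ({scope}): constant score; skipped")
                continue
            for pid, row in matrix.iterrows():
                x = row.to_numpy(float)[mask.to_numpy()][ok]
                res = stats.spearmanr(x, y[ok])
                out.append(PsychometricAssociation(
                    protein_id=pid, score=score, scope=scope,
                    rho=float(res.statistic), p=float(res.pvalue),
                    n=int(ok.sum()),
                    nominal=res.pvalue < nominal_alpha,
                    bonferroni=res.pvalue < bonferroni_alpha))

    _run(EPQRS_SCORES, pd.Series(True, index=c.index), "all")
    _run(PANSS_SCORES, c["group"] == "MAP", "MAP")
    return out


def table_one(cohort: pd.DataFrame):
    """Demographic/clinical summary: the categorical traits via
    :func:`categorical_group_test`, the continuous ones via the
    normality-gated branch.  Returns a tidy DataFrame."""
    c = cohort.copy()
    groups = c["group"].to_numpy()
    rows = []
    gm = (c["gender"].astype(str).str.upper() == "M").astype(int) \
        if "gender" in c.columns else None
    cat = {"gender": gm}
    for t in ("nicotine", "cannabis", "alcohol", "mandrax"):
        if t in c.columns:
            cat[t] = c[t].astype(int)
    order = [g for g in ("Control", "MA", "MAP") if g in set(groups)]
    for name, v in cat.items():
        if v is None:
            continue
        yes = [int(v[groups == g].sum()) for g in order]
        tot = [int((groups == g).sum()) for g in order]
        stat, p = categorical_group_test(yes, tot)
        rows.append({"variable": name, "kind": "categorical",
                     "statistic": stat, "p": p,
                     **{f"n_{g}": y for g, y in zip(order, yes)}})
    for name in ("age", "education_years", "epqrs_total",
                 *EPQRS_SCORES):
        if name not in c.columns:
            continue
        stat, p, branch = demographic_group_test(c[name].to_numpy(float),
                                                 groups)
        rows.append({"variable": name, "kind": branch,
                     "statistic": stat, "p": p})
    return pd.DataFrame(rows)
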