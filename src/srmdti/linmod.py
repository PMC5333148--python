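"""Covariate-adjusted group comparison with single-step Tukey correction.

The workhorse shared by the protein-abundance and DTI-ROI layers: every
response (an eigengene, or one ROI x metric vector) is modelled as

    y ~ group + age + gender + nicotine + cannabis + alcohol + mandrax

by ordinary least squares, and all pairwise group contrasts are tested
jointly with the single-step max-|t| (Tukey-type) familywise adjustment,
i.e. the adjusted p-value of contrast i is P(max_j |T_j| >= |t_i|) under
the joint null, where (T_1..T_k) follows a multivariate t with the
contrast correlation induced by the design.  With three groups the three
pairwise contrasts are linearly dependent (rank 2), so the reference
distribution is evaluated by a large common-random-number Monte-Carlo
sample of max|T| (T = Z / sqrt(W/df), Z Gaussian with the possibly
singular contrast correlation, W ~ chi-square(df)), cached per design.
Using one shared sample makes the adjusted p-values exactly monotone in
|t|, and taking max(raw, familywise) enforces adjusted >= raw.  A
single-contrast family collapses to the exact t-test p-value.

All responses sharing one design matrix are fitted in a single
multi-response least-squares pass, which is what makes the
1000-protein null simulations cheap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: covariates adjusted for in every group model
DEFAULT_COVARIATES = ("age", "gender", "nicotine", "cannabis", "alcohol", "mandrax")

#: canonical group order; pairwise contrasts are reported in this order
GROUP_ORDER = ("Control", "MA", "MAP")

_MC_SAMPLES = 200_000
_MC_SEED = 912662  # fixed: the reference sample is part of the method, not data
_maxabs_cache: dict = {}


def _contrast_names(groups):
    names = []
    for i in range(len(groups) - 1, -1, -1):
        for j in range(len(groups)):
            if j < i:
                names.append((groups[i], groups[j]))
    # order for 3 groups: (MAP,Control),(MAP,MA),(MA,Control)
    return names


def max_abs_t_reference(corr: np.ndarray, df: int) -> np.ndarray:
    """Sorted Monte-Carlo sample of max_j |T_j| for the given contrast
    correlation (may be singular) and residual degrees of freedom."""
    key = (df, corr.round(10).tobytes(), corr.shape[0])
    hit = _maxabs_cache.get(key)
    if hit is not None:
        return hit
    rng = np.random.default_rng(_MC_SEED)
    # factor a possibly singular correlation via eigendecomposition
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    factor = v * np.sqrt(w)
    z = rng.standard_normal((_MC_SAMPLES, corr.shape[0])) @ factor.T
    chi = rng.chisquare(df, _MC_SAMPLES)
    t = z / np.sqrt(chi / df)[:, None]
    sample = np.sort(np.abs(t).max(axis=1))
    _maxabs_cache[key] = sample
    return sample


def tukey_adjust(t_stats: np.ndarray, corr: np.ndarray, df: int) -> np.ndarray:
    """Single-step max-|t| adjusted p-values for a family of contrasts.

    ``t_stats`` may be (k,) or (k, m) for m responses sharing the design.
    """
    t_stats = np.atleast_1d(np.asarray(t_stats, dtype=float))
    raw = 2.0 * stats.t.sf(np.abs(t_stats), df)
    if corr.shape[0] == 1:
        return raw  # single contrast: exact t-test p (k = 2 collapse)
    sample = max_abs_t_reference(corr, df)
    n = sample.size
    idx = np.searchsorted(sample, np.abs(t_stats), side="left")
    fam = (n - idx) / n
    return np.maximum(raw, fam)


@dataclass
class GroupFit:
    """Joint fit of one design over m responses."""

    response_ids: list
    groups: list
    contrasts: list           # list of (a, b) meaning mean(a) - mean(b)
    estimates: np.ndarray     # k x m contrast estimates
    t_stats: np.ndarray       # k x m
    raw_p: np.ndarray         # k x m
    adjusted_p: np.ndarray    # k x m
    omnibus_f: np.ndarray     # m
    omnibus_p: np.ndarray     # m
    df_resid: int
    covariates_used: list
    dropped_covariates: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, rid in enumerate(self.response_ids):
            for i, (a, b) in enumerate(self.contrasts):
                rows.append({
                    "response": rid,
                    "contrast": f"{a}-{b}",
                    "estimate": self.estimates[i, j],
                    "t": self.t_stats[i, j],
                    "p_raw": self.raw_p[i, j],
                    "p_tukey": self.adjusted_p[i, j],
                    "omnibus_p": self.omnibus_p[j],
                })
        return pd.DataFrame(rows)


def build_design(cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES):
    """Design matrix [intercept | group dummies (ref = first) | covariates].

    Constant covariates are dropped with a warning (rank-deficiency
    contract).  Gender is encoded as an M indicator.
    """
    groups = [g for g in GROUP_ORDER if g in set(cohort["group"])]
    extra = sorted(set(cohort["group"]) - set(GROUP_ORDER))
    groups += extra
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n = len(cohort)
    cols = [np.ones(n)]
    names = ["Intercept"]
    for g in groups[1:]:
        cols.append((cohort["group"] == g).to_numpy(float))
        names.append(f"group[{g}]")
    used, dropped = [], []
    for cov in covariates:
        if cov not in cohort.columns:
            dropped.append(cov)
            continue
        v = cohort[cov]
        if cov == "gender":
            v = (v.astype(str).str.upper() == "M").astype(float)
        v = v.to_numpy(float)
        if np.ptp(v) == 0:
            dropped.append(cov)
            continue
        cols.append(v)
        names.append(cov)
        used.append(cov)
    if dropped:
        msg = f"dropping constant/missing covariates: {dropped}"
        warnings.warn(msg)
        logger.warning(msg)
    X = np.column_stack(cols)
    return X, names, groups, used, dropped


def fit_group_model(Y, response_ids, cohort: pd.DataFrame,
                    covariates=DEFAULT_COVARIATES) -> GroupFit:
    """Fit ``response ~ group + covariates`` for every column of Y jointly.

    Y : (n_subjects, m) array aligned with ``cohort`` rows.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != len(cohort):
        raise ValueError("response rows must align with cohort rows")
    const = np.ptp(Y, axis=0) == 0
    if const.any():
        bad = [response_ids[j] for j in np.flatnonzero(const)]
        raise ValueError(f"constant response vector(s): {bad}")
    X, names, groups, used, dropped = build_design(cohort, covariates)
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValueError("not enough subjects for the requested design")
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df

    # pairwise contrasts on the group-mean scale
    k = len(groups)
    gcols = {g: (0 if i == 0 else i) for i, g in enumerate(groups)}
    pairs = _contrast_names(groups)
    C = np.zeros((len(pairs), p))
    for r, (a, b) in enumerate(pairs):
        if gcols[a] > 0:
            C[r, gcols[a]] = 1.0
        if gcols[b] > 0:
            C[r, gcols[b]] -= 1.0
    G = C @ XtX_inv @ C.T
    d = np.sqrt(np.diag(G))
    corr = G / np.outer(d, d)
    est = C @ beta
    se = d[:, None] * np.sqrt(sigma2)[None, :]
    t = est / se
    raw = 2.0 * stats.t.sf(np.abs(t), df)
    adj = tukey_adjust(t, corr, df)

    # omnibus Wald F on the group dummies
    gidx = [gcols[g] for g in groups[1:]]
    Cg = np.zeros((k - 1, p))
    for r, i in enumerate(gidx):
        Cg[r, i] = 1.0
    M_inv = np.linalg.inv(Cg @ XtX_inv @ Cg.T)
    cb = Cg @ beta                                    # (k-1) x m
    quad = np.einsum("im,ij,jm->m", cb, M_inv, cb)
    F = quad / ((k - 1) * sigma2)
    omni_p = stats.f.sf(F, k - 1, df)

    return GroupFit(
        response_ids=list(response_ids), groups=groups, contrasts=pairs,
        estimates=est, t_stats=t, raw_p=raw, adjusted_p=adj,
        omnibus_f=F, omnibus_p=omni_p, df_resid=df,
        covariates_used=used, dropped_covariates=dropped,
    )
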