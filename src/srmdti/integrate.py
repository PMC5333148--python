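"""Cross-modal protein x DTI correlation screens.

Every protein eigengene is correlated (Pearson) with every ROI x metric
vector, either across all subjects or within one group.  Two-sided
p-values come from the exact t transform with n - 2 df; associations are
flagged at the nominal 0.05 level and at the Bonferroni-level 0.001
(0.05 over 48 ROIs).  Nominally significant associations are screened
for single-point influence by leave-one-out recomputation, the
p-value grid is stratified by a nested cutoff scheme, and the
control-vs-patient asymmetry in nominal association counts is tested
with an exact two-tailed sign test over paired units (per protein by
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dti import RoiMatrix

SCOPES = ("all", "Control", "MA", "MAP")
NOMINAL_ALPHA = 0.05
BONFERRONI_ALPHA = 0.001  # 0.05 / 48 ROIs, at the printed precision


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def _loo_r(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out Pearson r for every point, via sum updates."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    m = n - 1
    ex = (sx - x) / m
    ey = (sy - y) / m
    vx = (sxx - x * x) / m - ex ** 2
    vy = (syy - y * y) / m - ey ** 2
    cov = (sxy - x * y) / m - ex * ey
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.sqrt(vx * vy)
    # constant-after-removal: maximal attenuation
    return np.nan_to_num(r, nan=0.0)


def influence_screen(x, y, alpha: float = NOMINAL_ALPHA):
    """Single-point influence diagnostic for a correlation.

    Recomputes r with each observation left out; the association is
    flagged if any removal moves the p-value from below ``alpha`` to
    above it.  Returns (flag, r_loo_extreme) with the most attenuating
    leave-one-out coefficient (the one of smallest |r|)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("influence screening needs >= 5 paired points")
    r_full = float(np.corrcoef(x, y)[0, 1])
    p_full = float(_pearson_p(np.array([r_full]), len(x))[0])
    r_loo = _loo_r(x, y)
    p_loo = _pearson_p(r_loo, len(x) - 1)
    extreme = float(r_loo[np.argmin(np.abs(r_loo))])
    flag = bool(p_full < alpha and (p_loo >= alpha).any())
    return flag, extreme


def crossmodal_correlate(matrix: pd.DataFrame, r: RoiMatrix,
                         cohort: pd.DataFrame, scope: str = "all",
                         nominal_alpha: float = NOMINAL_ALPHA,
                         bonferroni_alpha: float = BONFERRONI_ALPHA,
                         influence: bool = True) -> pd.DataFrame:
    """Pearson r, p and flags for every protein x ROI x metric pair within
    the scope's subjects.  Returns a tidy AssociationGrid frame with
    columns protein, roi, metric, scope, r, p, n, nominal, bonferroni,
    influence_flag, r_loo_extreme."""
    cohort = cohort.set_index("subject_id") if "subject_id" in cohort.columns \
        else cohort
    subjects = [s for s in matrix.columns if s in r.wide.index]
    if scope != "all":
        subjects = [s for s in subjects if cohort.loc[s, "group"] == scope]
    n = len(subjects)
    if n < 5:
        raise ValueError(f"scope {scope!r} has fewer than 5 subjects")
    P = matrix[subjects].to_numpy(float)          # proteins x n
    D = r.wide.loc[subjects].to_numpy(float)      # n x cells
    cells = list(r.wide.columns)

    keep_p = P.std(axis=1) > 0
    keep_d = D.std(axis=0) > 0
    if not keep_p.all() or not keep_d.all():
        warnings.warn("constant vectors skipped in correlation screen")

    Pz = P - P.mean(axis=1, keepdims=True)
    Pz /= np.where(P.std(axis=1, keepdims=True) == 0, np.nan,
                   P.std(axis=1, keepdims=True))
    Dz = D - D.mean(axis=0, keepdims=True)
    Dz /= np.where(D.std(axis=0, keepdims=True) == 0, np.nan,
                   D.std(axis=0, keepdims=True))
    R = (Pz @ Dz) / n
    Pv = _pearson_p(R, n)

    prot_ids = np.repeat(list(matrix.index), len(cells))
    roi_ids = np.tile([c[0] for c in cells], len(matrix.index))
    metric_ids = np.tile([c[1] for c in cells], len(matrix.index))
    grid = pd.DataFrame({
        "protein": prot_ids, "roi": roi_ids, "metric": metric_ids,
        "scope": scope, "r": R.ravel(), "p": Pv.ravel(), "n": n,
    }).dropna(subset=["r"]).reset_index(drop=True)
    grid["nominal"] = grid["p"] < nominal_alpha
    grid["bonferroni"] = grid["p"] < bonferroni_alpha
    grid["influence_flag"] = False
    grid["r_loo_extreme"] = grid["r"]
    if influence:
        dcols = {c: i for i, c in enumerate(cells)}
        pidx = {p: i for i, p in enumerate(matrix.index)}
        for i in grid.index[grid["nominal"]]:
            row = grid.loc[i]
            x = P[pidx[row["protein"]]]
            y = D[:, dcols[(row["roi"], row["metric"])]]
            flag, extreme = influence_screen(x, y, nominal_alpha)
            grid.loc[i, "influence_flag"] = flag
            grid.loc[i, "r_loo_extreme"] = extreme
    return grid


@dataclass
class CutoffStratification:
    cutoffs: tuple
    counts: dict  # scope -> [count at each cutoff], nested


def stratify_pvalues(grid: pd.DataFrame,
                     cutoffs=(0.05, 0.01, 0.001)) -> CutoffStratification:
    """Count associations per scope inside each (nested) p-value stratum."""
    cutoffs = tuple(cutoffs)
    if list(cutoffs) != sorted(cutoffs, reverse=True):
        warnings.warn("cutoffs were not sorted; sorting descending")
        cutoffs = tuple(sorted(cutoffs, reverse=True))
    counts = {}
    if len(grid):
        for scope, sub in grid.groupby("scope"):
            counts[scope] = [int((sub["p"] < c).sum()) for c in cutoffs]
    return CutoffStratification(cutoffs=cutoffs, counts=counts)


@dataclass
class SignTestResult:
    n_control: int
    n_patient: int
    sign_test_p: float
    n_pairs: int
    n_ties: int
    pairing_unit: str
    per_unit: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def compare_association_counts(grid_control: pd.DataFrame,
                               grid_patient: pd.DataFrame,
                               pairing_unit: str = "protein",
                               alpha: float = NOMINAL_ALPHA) -> SignTestResult:
    """Exact two-tailed sign test on per-unit nominal association counts.

    Both grids must span the same protein x ROI x metric universe; units
    (default: proteins) are scored by which grid has more associations
    with p < ``alpha``; ties are dropped; the p-value is the exact
    two-sided binomial probability at 1/2."""
    units = {"protein": ["protein"], "roi": ["roi"],
             "protein_metric": ["protein", "metric"]}
    if pairing_unit not in units:
        raise ValueError(f"unknown pairing unit {pairing_unit!r}")
    key = units[pairing_unit]
    uc = set(map(tuple, grid_control[["protein", "roi", "metric"]]
                 .drop_duplicates().itertuples(index=False)))
    up = set(map(tuple, grid_patient[["protein", "roi", "metric"]]
                 .drop_duplicates().itertuples(index=False)))
    if uc != up:
        raise ValueError("grids cover different protein x roi x metric "
                         "universes")

    def unit_counts(g):
        return (g.assign(hit=g["p"] < alpha).groupby(key)["hit"].sum())

    a = unit_counts(grid_control)
    b = unit_counts(grid_patient)
    both = pd.concat([a.rename("control"), b.rename("patient")], axis=1)
    both = both.fillna(0)
    wins = int((both["control"] > both["patient"]).sum())
    losses = int((both["control"] < both["patient"]).sum())
    ties = int((both["control"] == both["patient"]).sum())
    m = wins + losses
    if m == 0:
        warnings.warn("all paired units tied; sign test p = 1")
        p = 1.0
    else:
        p = float(stats.binomtest(wins, m, 0.5).pvalue)
    return SignTestResult(
        n_control=int(both["control"].sum()),
        n_patient=int(both["patient"].sum()),
        sign_test_p=p, n_pairs=m, n_ties=ties,
        pairing_unit=pairing_unit, per_unit=both.reset_index())
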