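"""ROI-level DTI group statistics and p-value clustering.

The unit of analysis is the subject x ROI x metric table of regional
mean diffusion parameters over the 48 white-matter labels of the
JHU ICBM-DTI-81 atlas (FA unitless in [0,1]; MD/AD/RD diffusivities in
mm^2/s with MD = (AD + 2*RD)/3 by the eigenvalue definitions).  Each of
the 48 x 4 response vectors goes through the same covariate-adjusted
model and Tukey machinery as the protein layer; the resulting omnibus
p-value matrix is hierarchically clustered (1 - Pearson distance,
average linkage) so bilateral symmetry of the group effects can be
inspected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .linmod import DEFAULT_COVARIATES, fit_group_model

METRICS = ("FA", "MD", "AD", "RD")


def load_atlas() -> pd.DataFrame:
    """The bundled JHU ICBM-DTI-81 label list: 48 ROIs with hemisphere
    (L/R/M) and bilateral pair ids."""
    with resources.files("srmdti.data").joinpath(
            "jhu_icbm_dti81_labels.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


@dataclass
class RoiMatrix:
    """Subject x (ROI, metric) diffusion summaries.

    ``wide`` has subjects as the index and a (roi, metric) MultiIndex on
    columns.
    """

    wide: pd.DataFrame

    def __post_init__(self):
        if not isinstance(self.wide.columns, pd.MultiIndex):
            raise ValueError("RoiMatrix needs (roi, metric) columns")
        self.wide = self.wide.sort_index(axis=1)

    @property
    def subjects(self):
        return list(self.wide.index)

    @property
    def rois(self):
        return list(dict.fromkeys(self.wide.columns.get_level_values(0)))

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame) -> "RoiMatrix":
        need = {"subject", "roi", "metric", "value"}
        if not need.issubset(tidy.columns):
            raise ValueError(f"tidy ROI table needs columns {sorted(need)}")
        wide = tidy.pivot_table(index="subject", columns=["roi", "metric"],
                                values="value", aggfunc="first")
        return cls(wide)

    def to_tidy(self) -> pd.DataFrame:
        t = self.wide.stack(["roi", "metric"], future_stack=True)
        t.name = "value"
        return t.reset_index().rename(columns={"level_0": "subject",
                                               "subject_id": "subject"})

    def metric(self, metric: str) -> pd.DataFrame:
        return self.wide.xs(metric, axis=1, level=1)


@dataclass
class RoiAnovaGrid:
    """Per-(roi, metric) omnibus and pairwise Tukey results."""

    table: pd.DataFrame     # rows: roi, metric, omnibus_p, per-contrast cols
    contrasts: list
    covariates_used: list

    def omnibus_matrix(self) -> pd.DataFrame:
        """ROI x metric matrix of omnibus p-values."""
        return self.table.pivot(index="roi", columns="metric",
                                values="omnibus_p")

    def map_elevated(self, alpha: float = 0.05) -> pd.DataFrame:
        """Cells where MAP exceeds both MA and Control at Tukey-adjusted
        p < alpha."""
        t = self.table
        flag = (
            (t["p_MAP-Control"] < alpha) & (t["est_MAP-Control"] > 0)
            & (t["p_MAP-MA"] < alpha) & (t["est_MAP-MA"] > 0)
        )
        return t.loc[flag, ["roi", "metric", "omnibus_p",
                            "p_MAP-Control", "p_MAP-MA"]]


def roi_group_anova(r: RoiMatrix, cohort: pd.DataFrame,
                    covariates=DEFAULT_COVARIATES,
                    across_family: str = "per_metric") -> RoiAnovaGrid:
    """Covariate-adjusted group comparison of every (roi, metric) vector.

    Identical model and single-step Tukey adjustment as the protein
    layer.  Across the 48 x 4 grid an additional Bonferroni-adjusted
    omnibus column is reported, with the family either each metric's 48
    ROIs (``per_metric``) or the full grid (``global``).
    """
    cohort = cohort.set_index("subject_id") if "subject_id" in cohort.columns \
        else cohort
    missing = [s for s in r.subjects if s not in cohort.index]
    if missing:
        raise ValueError(f"subjects absent from cohort table: {missing}")
    c = cohort.loc[r.subjects].reset_index()
    ids = list(r.wide.columns)
    fit = fit_group_model(r.wide.to_numpy(float), ids, c, covariates)
    rows = []
    for j, (roi, metric) in enumerate(ids):
        row = {"roi": roi, "metric": metric,
               "omnibus_p": float(fit.omnibus_p[j])}
        for i, (a, b) in enumerate(fit.contrasts):
            row[f"est_{a}-{b}"] = float(fit.estimates[i, j])
            row[f"p_{a}-{b}"] = float(fit.adjusted_p[i, j])
        rows.append(row)
    table = pd.DataFrame(rows)
    if across_family == "global":
        fam = len(table)
        table["omnibus_p_bonferroni"] = np.minimum(table["omnibus_p"] * fam, 1.0)
    else:
        fam = table.groupby("metric")["omnibus_p"].transform("size")
        table["omnibus_p_bonferroni"] = np.minimum(table["omnibus_p"] * fam, 1.0)
    return RoiAnovaGrid(table=table,
                        contrasts=[f"{a}-{b}" for a, b in fit.contrasts],
                        covariates_used=fit.covariates_used)


@dataclass
class PvalueClustering:
    leaf_order: list          # roi ids, clustered order; degenerate rows last
    linkage: np.ndarray       # scipy linkage matrix over the clustered rows
    labels: pd.DataFrame      # roi, hemisphere for symmetry inspection
    degenerate: list = field(default_factory=list)
    input_order: list = field(default_factory=list)  # row order fed to linkage


def pvalue_cluster(grid: RoiAnovaGrid, atlas: pd.DataFrame | None = None,
                   transform: str = "raw") -> PvalueClustering:
    """Average-linkage clustering of the ROI x metric omnibus-p matrix
    under the 1 - Pearson correlation distance.

    ``transform='neglog'`` clusters -log10 p instead of raw p.  Rows with
    zero variance (undefined correlation) are placed last with a warning.
    """
    mat = grid.omnibus_matrix()
    if transform == "neglog":
        mat = -np.log10(mat)
    X = mat.to_numpy(float)
    ok = X.std(axis=1) > 0
    degenerate = [mat.index[i] for i in np.flatnonzero(~ok)]
    if degenerate:
        warnings.warn(f"constant p-value row(s) placed last: {degenerate}")
    Z = None
    input_order = list(mat.index[ok])
    order = list(input_order)
    if ok.sum() >= 2:
        d = pdist(X[ok], metric="correlation")
        Z = hierarchy.linkage(d, method="average")
        order = [input_order[i] for i in hierarchy.leaves_list(Z)]
    order += degenerate
    if atlas is None:
        atlas = load_atlas()
    lab = atlas.set_index("roi_id").reindex(order)
    labels = pd.DataFrame({"roi": order,
                           "hemisphere": lab["hemisphere"].to_numpy(object)})
    return PvalueClustering(leaf_order=order, linkage=Z, labels=labels,
                            degenerate=degenerate, input_order=input_order)


def leaf_newick(clustering: PvalueClustering) -> str:
    """Newick-like text rendering of the row dendrogram (leaf ordering and
    merge heights); degenerate rows are appended at zero height."""
    if clustering.linkage is None:
        return "(" + ",".join(map(str, clustering.leaf_order)) + ");"
    tree = hierarchy.to_tree(clustering.linkage)
    idx_names = dict(enumerate(clustering.input_order))

    def render(node, parent_h):
        if node.is_leaf():
            return f"{idx_names[node.id]}:{parent_h - 0.0:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{max(parent_h - node.dist, 0.0):.6g}"

    core = render(tree, tree.dist)
    extras = "".join(f",{r}:0" for r in clustering.degenerate)
    return f"({core}{extras});"


@dataclass
class TensorReport:
    n_checked: int
    violations: pd.DataFrame  # subject, roi, issue, value

    @property
    def ok(self):
        return self.violations.empty


def validate_tensor_metrics(r: RoiMatrix, rtol: float = 1e-4) -> TensorReport:
    """Check the eigenvalue identity MD = (AD + 2*RD)/3 per cell (relative
    tolerance ``rtol``), FA in [0, 1], and AD >= RD.  Reporting only."""
    rows = []
    md = r.metric("MD")
    ad = r.metric("AD")
    rd = r.metric("RD")
    fa = r.metric("FA")
    implied = (ad + 2 * rd) / 3
    rel = ((md - implied).abs() / implied.abs())
    for subj in md.index:
        for roi in md.columns:
            if rel.loc[subj, roi] > rtol:
                rows.append({"subject": subj, "roi": roi,
                             "issue": "MD != (AD+2RD)/3",
                             "value": float(md.loc[subj, roi])})
            v = fa.loc[subj, roi]
            if not (0.0 <= v <= 1.0):
                rows.append({"subject": subj, "roi": roi,
                             "issue": "FA outside [0,1]", "value": float(v)})
            if ad.loc[subj, roi] < rd.loc[subj, roi]:
                rows.append({"subject": subj, "roi": roi,
                             "issue": "AD < RD",
                             "value": float(ad.loc[subj, roi])})
    return TensorReport(n_checked=md.size,
                        violations=pd.DataFrame(
                            rows, columns=["subject", "roi", "issue", "value"]))
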