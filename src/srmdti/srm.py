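"""Transition-level SRM quality control and eigengene summarization.

Takes a Skyline-style long table of transition peak areas (one row per
protein / peptide / transition / subject / injection replicate) through
the fixed preprocessing pipeline:

    log2 -> per-run median normalization -> between-run-interference
    filter -> duplicate-CV filter -> per-protein eigengene

and yields one abundance value per protein per subject (the first
right-singular vector of the row-standardized transition x subject
matrix, scaled by its singular value), plus an auditable QC report.

A *run* is one injection, identified by (subject, replicate).  The
between-run-interference score of a transition is the Pearson
correlation, across runs, between its log2 intensity and the per-run
mean log2 intensity over all transitions of the same peptide; a clean
transition tracks its peptide, an interfered one does not.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("protein", "peptide", "transition", "subject", "replicate",
                    "intensity")

#: a transition missing in more than this fraction of runs is dropped
MISSING_RUN_FRACTION = 0.20


@dataclass
class TransitionTable:
    """Long-form transition intensities with pipeline-stage bookkeeping.

    ``data`` columns: protein, peptide, transition, subject, replicate,
    intensity.  Stage flags record which operations have been applied so
    the pipeline order (log2 -> normalize -> interference -> CV) can be
    enforced.
    """

    data: pd.DataFrame
    log_scale: bool = False
    normalized: bool = False
    interference_filtered: bool = False
    cv_filtered: bool = False
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"transition table missing column(s): {missing}")
        dup = self.data.duplicated(["transition", "subject", "replicate"])
        if dup.any():
            row = self.data[dup].iloc[0]
            raise ValueError(
                "duplicate transition/run row: transition "
                f"{row['transition']} subject {row['subject']} "
                f"replicate {row['replicate']}")

    def _evolve(self, data, note, **flags):
        kw = dict(log_scale=self.log_scale, normalized=self.normalized,
                  interference_filtered=self.interference_filtered,
                  cv_filtered=self.cv_filtered,
                  provenance=self.provenance + [note])
        kw.update(flags)
        return TransitionTable(data.reset_index(drop=True), **kw)

    @property
    def run_ids(self):
        return list(self.data.groupby(["subject", "replicate"]).groups)

    def pivot(self) -> pd.DataFrame:
        """transition x run matrix of intensities."""
        return self.data.pivot_table(
            index="transition", columns=["subject", "replicate"],
            values="intensity", aggfunc="first")

    def transition_meta(self) -> pd.DataFrame:
        return (self.data[["protein", "peptide", "transition"]]
                .drop_duplicates().set_index("transition"))


@dataclass
class QcReport:
    """Record of every QC decision taken on a cohort."""

    interference_scores: dict = field(default_factory=dict)
    excluded_interference: set = field(default_factory=set)
    cv_fail_fraction: dict = field(default_factory=dict)
    excluded_cv: set = field(default_factory=set)
    outlier_subjects: set = field(default_factory=set)
    dropped_proteins: list = field(default_factory=list)
    imputations: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def to_json(self, path=None):
        d = asdict(self)
        for k in ("excluded_interference", "excluded_cv", "outlier_subjects"):
            d[k] = sorted(d[k])
        s = json.dumps(d, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _impute_missing(t: TransitionTable):
    """Drop transitions missing in >20% of runs; impute the rest with the
    run's peptide mean (raw scale).  Returns (frame, notes)."""
    df = t.data.copy()
    notes = []
    n_runs = df.groupby(["subject", "replicate"]).ngroups
    miss = df["intensity"].isna()
    if not miss.any():
        # also treat absent rows per transition as missing-by-omission
        counts = df.groupby("transition")["intensity"].size()
        if (counts < (1 - MISSING_RUN_FRACTION) * n_runs).any():
            bad = counts[counts < (1 - MISSING_RUN_FRACTION) * n_runs].index
            notes += [f"dropped transition {x}: present in <80% of runs"
                      for x in bad]
            df = df[~df["transition"].isin(bad)]
        return df, notes
    frac = miss.groupby(df["transition"]).mean()
    bad = frac[frac > MISSING_RUN_FRACTION].index
    if len(bad):
        notes += [f"dropped transition {x}: missing in "
                  f"{frac[x]:.0%} of runs" for x in bad]
        df = df[~df["transition"].isin(bad)]
    pep_mean = (df.groupby(["peptide", "subject", "replicate"])["intensity"]
                .transform("mean"))
    todo = df["intensity"].isna()
    for _, row in df[todo].iterrows():
        notes.append(f"imputed transition {row['transition']} subject "
                     f"{row['subject']} rep {row['replicate']} with run "
                     "peptide mean")
    df = df.assign(intensity=df["intensity"].fillna(pep_mean))
    if df["intensity"].isna().any():
        df = df.dropna(subset=["intensity"])
    return df, notes


def log2_transform(t: TransitionTable) -> TransitionTable:
    """log2 the peak areas (variance stabilization).  Rejects a table that
    is already on the log scale, and any non-positive intensity left after
    missing-value handling."""
    if t.log_scale:
        raise ValueError("table is already log2-scale; refusing to re-apply")
    df, notes = _impute_missing(t)
    bad = df["intensity"] <= 0
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(
            f"non-positive intensity after imputation: transition "
            f"{row['transition']} subject {row['subject']} replicate "
            f"{row['replicate']} value {row['intensity']!r}")
    df = df.assign(intensity=np.log2(df["intensity"].to_numpy(float)))
    out = t._evolve(df, "log2", log_scale=True)
    out.provenance.extend(notes)
    return out


def normalize_runs(t: TransitionTable) -> TransitionTable:
    """Equalize run medians: shift each run (subject x replicate) so its
    median log2 intensity equals the global median of run medians.  Rank
    order within a run is preserved; applying twice is a no-op."""
    if not t.log_scale:
        raise ValueError("normalize_runs expects a log2-scale table")
    df = t.data
    med = df.groupby(["subject", "replicate"])["intensity"].median()
    if med.isna().any():
        run = med[med.isna()].index[0]
        raise ValueError(f"run {run} has no usable transitions")
    target = float(np.median(med.to_numpy()))
    shift = (target - med).rename("shift").reset_index()
    df = df.merge(shift, on=["subject", "replicate"])
    df = df.assign(intensity=df["intensity"] + df["shift"]).drop(columns="shift")
    return t._evolve(df, f"normalized run medians to {target:.6g}",
                     normalized=True)


def _interference_scores(t: TransitionTable) -> pd.Series:
    """Between-run-interference score for every transition.

    Zero-variance series score 0 (fail-safe: such transitions are
    excluded); a transition that is its peptide's only one trivially
    scores 1 (the per-run peptide mean is the transition itself).
    """
    mat = t.pivot()
    meta = t.transition_meta().loc[mat.index]
    scores = pd.Series(index=mat.index, dtype=float)
    for _, idx in meta.groupby("peptide").groups.items():
        sub = mat.loc[idx]
        pep_mean = sub.mean(axis=0)
        X = sub.to_numpy(float)
        m = pep_mean.to_numpy(float)
        for i, tid in enumerate(sub.index):
            x = X[i]
            ok = ~np.isnan(x) & ~np.isnan(m)
            if ok.sum() < 3:
                raise ValueError(
                    f"transition {tid}: fewer than 3 complete runs")
            xs, ms = x[ok], m[ok]
            if xs.std() == 0 or ms.std() == 0:
                scores[tid] = 0.0
            else:
                scores[tid] = float(np.corrcoef(xs, ms)[0, 1])
    return scores


def interference_score(t: TransitionTable, transition_id) -> float:
    """Score one transition: Pearson correlation across runs between the
    transition's log2 intensity and the per-run mean over all transitions
    of its peptide."""
    meta = t.transition_meta()
    if transition_id not in meta.index:
        raise KeyError(f"unknown transition {transition_id}")
    pep = meta.loc[transition_id, "peptide"]
    sub = TransitionTable(t.data[t.data["peptide"] == pep],
                          log_scale=t.log_scale, normalized=t.normalized)
    return float(_interference_scores(sub)[transition_id])


def filter_interference(t: TransitionTable, threshold: float = 0.8):
    """Drop transitions whose interference score falls below ``threshold``
    (default 0.8).  Returns (table, QcReport)."""
    scores = _interference_scores(t)
    excluded = set(scores.index[scores < threshold])
    report = QcReport(interference_scores=scores.to_dict(),
                      excluded_interference=excluded)
    df = t.data[~t.data["transition"].isin(excluded)]
    lost = set(t.data["protein"]) - set(df["protein"])
    for p in sorted(lost):
        msg = f"protein {p} lost all transitions to the interference filter"
        report.dropped_proteins.append(p)
        report.warnings.append(msg)
        logger.warning(msg)
    out = t._evolve(df, f"interference filter <{threshold}: "
                        f"excluded {len(excluded)}",
                    interference_filtered=True)
    return out, report


def cv_filter(t: TransitionTable, cv_threshold: float = 0.10,
              run_fraction: float = 0.10):
    """Exclude transitions whose duplicate-injection coefficient of
    variation exceeds ``cv_threshold`` in more than ``run_fraction`` of
    subjects.  CV = sd/mean of the raw-scale replicate intensities
    (log2 values are unlogged first)."""
    reps = t.data.groupby(["transition", "subject"])["intensity"].size()
    if (reps < 2).any():
        bad = reps[reps < 2].index[0]
        raise ValueError(
            f"CV filtering requires duplicate injections; transition "
            f"{bad[0]} subject {bad[1]} has a single replicate")
    df = t.data
    raw = np.exp2(df["intensity"].to_numpy(float)) if t.log_scale \
        else df["intensity"].to_numpy(float)
    work = df.assign(_raw=raw)
    g = work.groupby(["transition", "subject"])["_raw"]
    cv = g.std(ddof=1) / g.mean()
    fail = (cv > cv_threshold).groupby(level="transition").mean()
    excluded = set(fail.index[fail > run_fraction])
    report = QcReport(cv_fail_fraction=fail.to_dict(), excluded_cv=excluded)
    out_df = df[~df["transition"].isin(excluded)]
    lost = set(df["protein"]) - set(out_df["protein"])
    for p in sorted(lost):
        msg = f"protein {p} lost all transitions to the CV filter"
        report.dropped_proteins.append(p)
        report.warnings.append(msg)
        logger.warning(msg)
    out = t._evolve(out_df, f"CV filter >{cv_threshold} in >{run_fraction}"
                            f" of subjects: excluded {len(excluded)}",
                    cv_filtered=True)
    return out, report


def average_replicates(t: TransitionTable) -> pd.DataFrame:
    """transition x subject matrix with injection replicates averaged."""
    return t.data.pivot_table(index="transition", columns="subject",
                              values="intensity", aggfunc="mean")


def _eigengene(mat: pd.DataFrame, protein_id) -> pd.Series:
    X = mat.to_numpy(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.any():
        raise ValueError(f"protein {protein_id}: zero variance in every "
                         "transition")
    Z = (X[keep] - mu[keep]) / sd[keep]
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    eig = s[0] * vt[0]
    mean_profile = Z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=mat.columns, name=protein_id)


def protein_eigengene(t: TransitionTable, protein_id) -> pd.Series:
    """One abundance value per subject for ``protein_id``: the first right
    singular vector of the row-standardized transition x subject matrix
    (injection replicates averaged first), scaled by its singular value,
    sign-aligned to correlate positively with the mean transition profile.
    A single-transition protein reduces to that transition's standardized
    profile."""
    sub = t.data[t.data["protein"] == protein_id]
    if sub.empty:
        raise KeyError(f"protein {protein_id} has no surviving transitions")
    mat = sub.pivot_table(index="transition", columns="subject",
                          values="intensity", aggfunc="mean")
    return _eigengene(mat, protein_id)


def build_protein_matrix(t: TransitionTable) -> pd.DataFrame:
    """protein x subject eigengene matrix over all surviving proteins."""
    rows = {}
    for p, sub in t.data.groupby("protein", sort=False):
        mat = sub.pivot_table(index="transition", columns="subject",
                              values="intensity", aggfunc="mean")
        rows[p] = _eigengene(mat, p)
    m = pd.DataFrame(rows).T
    m.index.name = "protein"
    if m.isna().any().any():
        raise ValueError("eigengene matrix has missing cells")
    return m


def outlier_screen(m: pd.DataFrame) -> QcReport:
    """Flag subjects beyond 2 SD from the cohort mean on either (a) their
    mean Pearson correlation to all other subjects or (b) their scores on
    the first two principal components.  Reporting only; nothing removed."""
    if m.shape[1] < 3:
        raise ValueError("outlier screening needs at least 3 subjects")
    report = QcReport()
    X = m.to_numpy(float)
    subjects = list(m.columns)
    flagged = set()

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X.T)
    n = len(subjects)
    mean_corr = (corr.sum(axis=1) - 1.0) / (n - 1)
    if np.isnan(mean_corr).any():
        report.warnings.append("undefined subject correlations "
                               "(constant profile); skipped in screen")
        mean_corr = np.nan_to_num(mean_corr, nan=1.0)
    sd = mean_corr.std(ddof=1)
    if sd > 0:
        z = (mean_corr - mean_corr.mean()) / sd
        flagged |= {subjects[i] for i in np.flatnonzero(np.abs(z) > 2)}

    centered = (X - X.mean(axis=1, keepdims=True)).T  # subjects x proteins
    _, s, vt = np.linalg.svd(centered - centered.mean(axis=0), full_matrices=False)
    scores = (centered - centered.mean(axis=0)) @ vt[:2].T
    for k in range(min(2, scores.shape[1])):
        col = scores[:, k]
        sdk = col.std(ddof=1)
        if sdk > 0:
            z = (col - col.mean()) / sdk
            flagged |= {subjects[i] for i in np.flatnonzero(np.abs(z) > 2)}

    report.outlier_subjects = flagged
    return report


def preprocess(t: TransitionTable, interference_threshold: float = 0.8,
               cv_threshold: float = 0.10, cv_run_fraction: float = 0.10):
    """Run the full fixed-order pipeline; returns (ProteinMatrix, QcReport).

    The returned matrix is protein x subject; the report merges the
    interference, CV and outlier screens.
    """
    t = log2_transform(t)
    t = normalize_runs(t)
    t, rep_i = filter_interference(t, interference_threshold)
    t, rep_cv = cv_filter(t, cv_threshold, cv_run_fraction)
    matrix = build_protein_matrix(t)
    rep_out = outlier_screen(matrix)
    report = QcReport(
        interference_scores=rep_i.interference_scores,
        excluded_interference=rep_i.excluded_interference,
        cv_fail_fraction=rep_cv.cv_fail_fraction,
        excluded_cv=rep_cv.excluded_cv,
        outlier_subjects=rep_out.outlier_subjects,
        dropped_proteins=rep_i.dropped_proteins + rep_cv.dropped_proteins,
        imputations=[p for p in t.provenance if p.startswith("imputed")],
        warnings=rep_i.warnings + rep_cv.warnings + rep_out.warnings,
    )
    return matrix, report
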