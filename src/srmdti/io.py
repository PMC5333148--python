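"""Readers, writers, pipeline configuration and the end-to-end runner.

All tables travel as plain CSV/TSV (delimiter auto-detected on read);
numbers are serialized with 15 significant digits so every writer/reader
pair round-trips within 1e-12 relative tolerance.  ``run_pipeline`` executes
preprocess -> differential abundance -> DTI -> integration, persists
every intermediate, and returns a machine-readable run report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import srm, groupstats, dti, integrate
from .srm import TransitionTable, REQUIRED_COLUMNS
from .dti import RoiMatrix

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.15g"
REPORT_SCHEMA_VERSION = "1"


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_transition_table(path) -> TransitionTable:
    """Read a Skyline-style long transition export (CSV or TSV)."""
    df = _read_delimited(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    return TransitionTable(df)


def write_transition_table(t: TransitionTable, path):
    t.data.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_cohort_table(path) -> pd.DataFrame:
    df = _read_delimited(path)
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: cohort table needs subject_id and group")
    return df


def write_cohort_table(c: pd.DataFrame, path):
    c.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_protein_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index.name = "protein"
    return df


def write_protein_matrix(m: pd.DataFrame, path):
    m.to_csv(path, float_format=FLOAT_FORMAT)


def read_roi_matrix(path) -> RoiMatrix:
    df = _read_delimited(path)
    return RoiMatrix.from_tidy(df)


def write_roi_matrix(r: RoiMatrix, path):
    r.to_tidy().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_association_grid(grid: pd.DataFrame, path):
    grid.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_association_grid(path) -> pd.DataFrame:
    return _read_delimited(path)


@dataclass
class PipelineConfig:
    """Paths plus every analysis threshold, one file drives everything."""

    transition_table: str = ""
    cohort_table: str = ""
    roi_table: str = ""
    outdir: str = "results"
    interference_threshold: float = 0.8
    cv_threshold: float = 0.10
    cv_run_fraction: float = 0.10
    alpha: float = 0.05
    psychometric_bonferroni: float = 0.01
    dti_bonferroni: float = 0.001
    covariates: tuple = groupstats.DEFAULT_COVARIATES
    pairing_unit: str = "protein"
    seed: int = 0

    def __post_init__(self):
        for name in ("interference_threshold", "cv_threshold",
                     "cv_run_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]: {v}")
        for name in ("alpha", "psychometric_bonferroni", "dti_bonferroni"):
            v = getattr(self, name)
            if not (0 <= v <= 1):  # alpha 0 = report nothing, still valid
                raise ValueError(f"{name} must be in [0, 1]: {v}")

    @classmethod
    def from_yaml(cls, path, **overrides):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class RunReport:
    schema_version: str = REPORT_SCHEMA_VERSION
    config: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    wall_clock_s: float = 0.0
    status: str = "ok"
    error: str = ""

    def to_json(self, path=None):
        s = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(s)
        return s


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the full analysis from the three input tables, persisting
    every intermediate under ``cfg.outdir``."""
    t0 = time.time()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in asdict(cfg).items()})
    stage = "read"
    try:
        table = read_transition_table(cfg.transition_table)
        cohort = read_cohort_table(cfg.cohort_table)
        roi = read_roi_matrix(cfg.roi_table)
        report.stages["read"] = {
            "transition_rows": len(table.data),
            "subjects": int(cohort.shape[0]),
            "roi_cells": int(roi.wide.size),
        }

        stage = "preprocess"
        matrix, qc = srm.preprocess(
            table, cfg.interference_threshold, cfg.cv_threshold,
            cfg.cv_run_fraction)
        write_protein_matrix(matrix, out / "protein_matrix.csv")
        (out / "qc_report.json").write_text(qc.to_json())
        report.stages["preprocess"] = {
            "proteins": int(matrix.shape[0]),
            "excluded_interference": len(qc.excluded_interference),
            "excluded_cv": len(qc.excluded_cv),
            "outlier_subjects": sorted(qc.outlier_subjects),
        }

        stage = "diffabund"
        results = groupstats.differential_abundance(
            matrix, cohort, cfg.covariates, cfg.alpha)
        rows = []
        for r in results:
            for c in r.pairwise:
                rows.append({"protein": r.protein_id,
                             "omnibus_p": r.omnibus_p, **c})
        pd.DataFrame(rows).to_csv(out / "differential_abundance.csv",
                                  index=False, float_format=FLOAT_FORMAT)
        sig = sorted({r.protein_id for r in results
                      if r.significant_contrasts})
        psych = groupstats.psychometric_correlation(
            matrix, cohort, cfg.alpha, cfg.psychometric_bonferroni)
        pd.DataFrame([asdict(a) for a in psych]).to_csv(
            out / "psychometric_correlations.csv", index=False,
            float_format=FLOAT_FORMAT)
        report.stages["diffabund"] = {
            "proteins_tested": len(results),
            "significant_proteins": sig,
        }

        stage = "dti"
        grid = dti.roi_group_anova(roi, cohort, cfg.covariates)
        grid.table.to_csv(out / "roi_anova.csv", index=False,
                          float_format=FLOAT_FORMAT)
        clus = dti.pvalue_cluster(grid)
        (out / "roi_dendrogram.nwk").write_text(dti.leaf_newick(clus))
        elevated = grid.map_elevated(cfg.alpha)
        tensor = dti.validate_tensor_metrics(roi)
        report.stages["dti"] = {
            "cells_tested": len(grid.table),
            "map_elevated_cells": [f"{r}.{m}" for r, m in
                                   zip(elevated["roi"], elevated["metric"])],
            "tensor_violations": int(len(tensor.violations)),
        }

        stage = "integrate"
        grids = {}
        for scope in integrate.SCOPES:
            grids[scope] = integrate.crossmodal_correlate(
                matrix, roi, cohort, scope, cfg.alpha, cfg.dti_bonferroni)
        all_grid = pd.concat(grids.values(), ignore_index=True)
        write_association_grid(all_grid, out / "association_grid.csv")
        strat = integrate.stratify_pvalues(all_grid)
        patient = pd.concat([grids["MA"], grids["MAP"]], ignore_index=True)
        sign = integrate.compare_association_counts(
            grids["Control"], patient, cfg.pairing_unit, cfg.alpha)
        (out / "integration.json").write_text(json.dumps({
            "stratification": {"cutoffs": list(strat.cutoffs),
                               "counts": strat.counts},
            "sign_test": {"n_control": sign.n_control,
                          "n_patient": sign.n_patient,
                          "p": sign.sign_test_p,
                          "pairing_unit": sign.pairing_unit,
                          "n_pairs": sign.n_pairs, "n_ties": sign.n_ties},
        }, indent=2))
        report.stages["integrate"] = {
            "nominal_control": sign.n_control,
            "nominal_patient": sign.n_patient,
            "sign_test_p": sign.sign_test_p,
        }
    except Exception as exc:
        report.status = "error"
        report.error = f"stage {stage}: {exc}"
        report.wall_clock_s = time.time() - t0
        report.to_json(out / "run_report.json")
        raise
    report.wall_clock_s = time.time() - t0
    report.to_json(out / "run_report.json")
    return report
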