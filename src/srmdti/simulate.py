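"""Seedful synthetic cohort generator with known ground truth.

Emits all four inputs of the pipeline — a duplicate-injection
transition-level SRM table, the subject covariate table, the 48-ROI DTI
summary matrix and the psychometric scores — for a three-group cohort
(healthy controls, methamphetamine dependence, methamphetamine-associated
psychosis) with planted structure:

* group shifts of designated protein signals (in residual-SD units,
  optionally with a group-specific SD rescaling);
* interfered transitions that track an independent co-eluting signal
  instead of their protein (plus occasional run spikes), so the
  between-run-interference filter has a recoverable target;
* RD elevations in designated MAP tracts on the eigenvalue scale (MD
  inherits two thirds of an RD shift through MD = (AD + 2*RD)/3);
* protein-DTI co-linearity induced by shared latent factors within a
  scope (all subjects, or one group), so control-only couplings vanish
  in the patient groups by construction.

Transition intensities are built on the log2 scale as

    base(transition) + signal(protein, subject) + prep noise
    + run effect(injection) + replicate noise [+ interference]

and exponentiated to peak areas.  Demographic and psychometric
distributions copy the recorded cohort (per-group means/SDs, exact
gender and substance counts).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .dti import METRICS, RoiMatrix, load_atlas
from .srm import TransitionTable

LN2 = float(np.log(2.0))

#: the 43-protein serum panel (gene-style short codes)
PROTEIN_PANEL = (
    "APOC2 APOH HPTR A1AT PEDF A2AP AACT C1R CFAB CO4A "
    "ALBU APOA1 APOA2 APOA4 APOB APOC1 APOC3 APOD APOE APOM "
    "TTHY TRFE CERU CFAH CO3 CO5 CO6 CO9 CLUS CRP "
    "FIBA FIBB FIBG GELS HEMO HPT IC1 ITIH4 KNG1 PLMN "
    "RET4 SAMP VTDB"
).split()

GROUPS = ("Control", "MA", "MAP")


class GeneratorConfig:
    """Thin mapping wrapper over the generator's YAML configuration; all
    study conditions live in one file (``data/default_generator.yaml``)."""

    def __init__(self, raw: dict):
        self.raw = raw

    @classmethod
    def default(cls, seed: int | None = None) -> "GeneratorConfig":
        with resources.files("srmdti.data").joinpath(
                "default_generator.yaml").open() as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(raw)
        if seed is not None:
            cfg.raw["seed"] = int(seed)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(raw)
        if seed is not None:
            cfg.raw["seed"] = int(seed)
        cfg.validate()
        return cfg

    def __getitem__(self, key):
        return self.raw[key]

    def get(self, key, default=None):
        return self.raw.get(key, default)

    @property
    def seed(self):
        return int(self.raw.get("seed", 0))

    def replace(self, **kw) -> "GeneratorConfig":
        raw = copy.deepcopy(self.raw)
        raw.update(kw)
        return GeneratorConfig(raw)

    def nulled(self) -> "GeneratorConfig":
        """Copy with every planted effect removed."""
        raw = copy.deepcopy(self.raw)
        raw["protein_effects"] = []
        raw["roi_effects"] = []
        raw["coupling"] = []
        raw["interference"] = {"n_transitions": 0, "spike_magnitude": 0.0,
                               "spike_fraction": 0.0}
        return GeneratorConfig(raw)

    def validate(self):
        gs = self.raw["group_sizes"]
        if any(v < 3 for v in gs.values()):
            raise ValueError("group sizes must be >= 3")
        for sd_key in ("run_effect_sd", "transition_noise_sd",
                       "duplicate_cv_target"):
            if self.raw[sd_key] <= 0:
                raise ValueError(f"{sd_key} must be > 0")
        for block in self.raw.get("coupling", []):
            for cell in _block_cells(block):
                if not abs(cell[2]) < 1:
                    raise ValueError(
                        f"coupling target |r| must be < 1: {cell}")


def _block_cells(block: dict):
    """Normalize a coupling block to a list of (roi, metric, r)."""
    if "cells" in block:
        return [(c["roi"], c["metric"], float(c["r"]))
                for c in block["cells"]]
    return [(roi, block["metric"], float(block["r"]))
            for roi in block["rois"]]


def _block_proteins(block: dict):
    return list(block.get("proteins", [block["protein"]]
                          if "protein" in block else []))


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    true_signals: pd.DataFrame          # protein x subject, final signals
    interfered_transitions: list
    differential_proteins: dict         # protein -> list of effect dicts
    affected_roi_cells: list            # (roi, metric) with planted shifts
    couplings: list                     # dicts: protein, roi, metric, scope, r


@dataclass
class SimulatedCohort:
    transitions: TransitionTable
    cohort: pd.DataFrame
    roi: RoiMatrix
    psychometrics: pd.DataFrame
    truth: GroundTruth
    config: GeneratorConfig = field(repr=False, default=None)


def _assign_binary(rng, n, count):
    v = np.zeros(n, dtype=int)
    v[rng.choice(n, size=count, replace=False)] = 1
    return v


def _make_cohort(cfg, rng):
    gs = cfg["group_sizes"]
    rows = []
    for g in GROUPS:
        n = gs[g]
        prefix = {"Control": "C", "MA": "MA", "MAP": "MAP"}[g]
        for i in range(n):
            rows.append({"subject_id": f"{prefix}{i + 1:02d}", "group": g})
    c = pd.DataFrame(rows)
    cov = cfg["covariates"]
    for name in ("age", "education_years", "meth_duration_years"):
        vals = np.full(len(c), np.nan)
        for g in GROUPS:
            if g not in cov.get(name, {}):
                continue
            mu, sd = cov[name][g]
            m = (c["group"] == g).to_numpy()
            vals[m] = rng.normal(mu, sd, m.sum())
        c[name] = vals
    gender = np.empty(len(c), dtype=object)
    for g in GROUPS:
        m = (c["group"] == g).to_numpy()
        male = _assign_binary(rng, m.sum(), cov["gender_male"][g])
        gender[m] = np.where(male == 1, "M", "F")
    c["gender"] = gender
    for t in ("nicotine", "cannabis", "alcohol", "mandrax"):
        v = np.zeros(len(c), dtype=int)
        for g in GROUPS:
            m = (c["group"] == g).to_numpy()
            v[m] = _assign_binary(rng, m.sum(), cov[t][g])
        c[t] = v
    return c


def _make_psychometrics(cfg, cohort, rng):
    psy = cfg["psychometrics"]
    out = pd.DataFrame({"subject_id": cohort["subject_id"]})
    for name, per_group in psy.items():
        vals = np.full(len(cohort), np.nan)
        for g, (mu, sd) in per_group.items():
            m = (cohort["group"] == g).to_numpy()
            vals[m] = np.clip(np.round(rng.normal(mu, sd, m.sum())), 0, None)
        out[name] = vals
    return out


def _signal_variance_all(effects_for_protein, weights):
    """Across-cohort variance of a unit-residual signal with the given
    group shifts / SD rescalings; used to translate an 'all'-scope target
    correlation into latent loadings."""
    shifts = {g: 0.0 for g in GROUPS}
    scales = {g: 1.0 for g in GROUPS}
    for e in effects_for_protein:
        shifts[e["group"]] += float(e["shift"])
        scales[e["group"]] *= float(e.get("sd_scale", 1.0))
    mean = sum(weights[g] * shifts[g] for g in GROUPS)
    v = sum(weights[g] * (scales[g] ** 2 + shifts[g] ** 2) for g in GROUPS)
    v -= mean ** 2
    c = sum(weights[g] * scales[g] for g in GROUPS)
    return v, c


def _md_loading(beta, sig_a, sig_r):
    """Loading to mix into both AD and RD residuals so that the latent
    correlates with MD = (AD + 2 RD)/3 at ``beta``."""
    num = beta ** 2 * (sig_a ** 2 + 4 * sig_r ** 2)
    den = (sig_a + 2 * sig_r) ** 2 - 4 * beta ** 2 * sig_a * sig_r
    if den <= 0:
        raise ValueError(f"infeasible MD coupling target {beta}")
    return np.sign(beta) * np.sqrt(num / den)


def generate_cohort(cfg: GeneratorConfig | None = None,
                    seed: int | None = None) -> SimulatedCohort:
    """Generate one full synthetic cohort; deterministic for a fixed seed."""
    if cfg is None:
        cfg = GeneratorConfig.default(seed)
    elif seed is not None:
        cfg = cfg.replace(seed=int(seed))
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cohort = _make_cohort(cfg, rng)
    subjects = list(cohort["subject_id"])
    group_of = dict(zip(cohort["subject_id"], cohort["group"]))
    n = len(subjects)
    weights = {g: (cohort["group"] == g).mean() for g in GROUPS}

    n_prot = int(cfg["n_proteins"])
    proteins = list(PROTEIN_PANEL[:n_prot])
    if n_prot > len(PROTEIN_PANEL):
        proteins += [f"PROT{j:03d}" for j in range(len(PROTEIN_PANEL), n_prot)]
    z = rng.standard_normal((n_prot, n))
    pidx = {p: i for i, p in enumerate(proteins)}

    effects_by_protein: dict = {}
    for e in cfg.get("protein_effects", []):
        effects_by_protein.setdefault(e["protein"], []).append(e)

    # --- ROI residuals (AD / RD eigenvalue scale) ------------------------
    atlas = load_atlas()
    rois = list(atlas["roi_id"])
    rb = cfg["roi_baseline"]
    ad_mean = rng.uniform(*rb["ad_mean_range"], len(rois))
    rd_mean = ad_mean * rng.uniform(*rb["rd_fraction_range"], len(rois))
    sig_a, sig_r = float(rb["ad_sd"]), float(rb["rd_sd"])
    lam = float(rb["global_factor_loading"])
    ridx = {r: i for i, r in enumerate(rois)}
    g_global = rng.standard_normal(n)
    eps_a = (np.sqrt(1 - lam ** 2) * rng.standard_normal((n, len(rois)))
             + lam * g_global[:, None])
    eps_r = (np.sqrt(1 - lam ** 2) * rng.standard_normal((n, len(rois)))
             + lam * g_global[:, None])

    # --- latent-factor couplings ----------------------------------------
    couplings = []
    for block in cfg.get("coupling", []):
        scope = block["scope"]
        mask = np.ones(n, bool) if scope == "all" else \
            (cohort["group"] == scope).to_numpy()
        g_lat = rng.standard_normal(n)
        cells = _block_cells(block)
        prots = _block_proteins(block)
        # alternating per-protein sign keeps the panel median free of the
        # shared factor (median run-normalization would otherwise strip it)
        alternate = bool(block.get("alternate_sign", len(prots) > 1))
        # across-cohort couplings must allow for the group structure of the
        # protein (shifts inflate its cohort variance, SD rescaling damps
        # the within-group loading); within-group scopes need no correction
        ks = []
        for p in prots:
            v_p, c_p = (1.0, 1.0)
            if scope == "all":
                v_p, c_p = _signal_variance_all(
                    effects_by_protein.get(p, []), weights)
            ks.append(np.sqrt(v_p) / c_p)
        k = float(np.mean(ks))
        targets = {}
        for roi, metric, r in cells:
            t = r * k
            if abs(t) >= 0.99:
                raise ValueError(f"infeasible coupling {roi}-{metric} "
                                 f"(effective r {t:.3f})")
            targets[(roi, metric)] = t
        alpha = np.sqrt(max(abs(t) for t in targets.values()))
        for p_i, p in enumerate(prots):
            p_sign = -1.0 if (alternate and p_i % 2) else 1.0
            i = pidx[p]
            z[i, mask] = (np.sqrt(1 - alpha ** 2) * z[i, mask]
                          + p_sign * alpha * g_lat[mask])
            for (roi, metric), t in targets.items():
                couplings.append({
                    "protein": p, "roi": roi, "metric": metric,
                    "scope": scope, "r": p_sign * t / k})
        for (roi, metric), t in targets.items():
            beta = t / alpha
            if abs(beta) > 0.999:
                raise ValueError(f"infeasible coupling {roi}-{metric}")
            j = ridx[roi]
            if metric == "RD":
                eps_r[mask, j] = (np.sqrt(1 - beta ** 2) * eps_r[mask, j]
                                  + beta * g_lat[mask])
            elif metric == "AD":
                eps_a[mask, j] = (np.sqrt(1 - beta ** 2) * eps_a[mask, j]
                                  + beta * g_lat[mask])
            elif metric == "MD":
                b = _md_loading(beta, sig_a, sig_r)
                for eps in (eps_a, eps_r):
                    eps[mask, j] = (np.sqrt(1 - b ** 2) * eps[mask, j]
                                    + b * g_lat[mask])
            elif metric == "FA":
                # FA rises with AD and falls with RD; antisymmetric mix
                ka = rd_mean[j] * (ad_mean[j] + 2 * rd_mean[j])
                kr = ad_mean[j] * (ad_mean[j] + 2 * rd_mean[j])
                sa, sr = ka * sig_a, kr * sig_r
                b = beta * np.sqrt(sa ** 2 + sr ** 2) / (sa + sr)
                if abs(b) > 0.999:
                    raise ValueError(f"infeasible coupling {roi}-FA")
                eps_a[mask, j] = (np.sqrt(1 - b ** 2) * eps_a[mask, j]
                                  + b * g_lat[mask])
                eps_r[mask, j] = (np.sqrt(1 - b ** 2) * eps_r[mask, j]
                                  - b * g_lat[mask])
            else:
                raise ValueError(f"unknown metric {metric!r}")

    # --- protein group effects ------------------------------------------
    gmask = {g: (cohort["group"] == g).to_numpy() for g in GROUPS}
    for p, effs in effects_by_protein.items():
        i = pidx.get(p)
        if i is None:
            raise ValueError(f"protein_effects names unknown protein {p}")
        for e in effs:
            m = gmask[e["group"]]
            z[i, m] = (z[i, m] * float(e.get("sd_scale", 1.0))
                       + float(e["shift"]))
    true_signals = pd.DataFrame(z, index=proteins, columns=subjects)

    # --- ROI group effects and derived metrics ---------------------------
    affected = []
    for e in cfg.get("roi_effects", []):
        j = ridx[e["roi"]]
        m = gmask[e["group"]]
        if e["metric"] == "RD":
            eps_r[m, j] += float(e["shift"])
            affected.append((e["roi"], "RD"))
            affected.append((e["roi"], "MD"))
        elif e["metric"] == "AD":
            eps_a[m, j] += float(e["shift"])
            affected.append((e["roi"], "AD"))
            affected.append((e["roi"], "MD"))
        else:
            raise ValueError("roi_effects operate on the eigenvalue scale "
                             "(metric AD or RD)")
    AD = ad_mean[None, :] + sig_a * eps_a
    RD = rd_mean[None, :] + sig_r * eps_r
    AD = np.maximum(AD, RD * (1 + 1e-9))  # physically plausible tensors
    MD = (AD + 2 * RD) / 3
    FA = (AD - RD) / np.sqrt(AD ** 2 + 2 * RD ** 2)
    wide = pd.DataFrame(
        np.concatenate([FA, MD, AD, RD], axis=1), index=pd.Index(
            subjects, name="subject"),
        columns=pd.MultiIndex.from_tuples(
            [(r, m) for m in ("FA", "MD", "AD", "RD") for r in rois],
            names=["roi", "metric"]))
    roi_matrix = RoiMatrix(wide)

    # --- transitions ------------------------------------------------------
    lo_p, hi_p = cfg["peptides_per_protein"]
    lo_t, hi_t = cfg["transitions_per_peptide"]
    rows_protein, rows_peptide, rows_transition = [], [], []
    for p in proteins:
        n_pep = int(rng.integers(lo_p, hi_p + 1))
        for k in range(n_pep):
            pep = f"{p}_pep{k + 1}"
            n_tr = int(rng.integers(lo_t, hi_t + 1))
            for q in range(n_tr):
                rows_protein.append(p)
                rows_peptide.append(pep)
                rows_transition.append(f"{pep}_t{q + 1}")
    trans = pd.DataFrame({"protein": rows_protein, "peptide": rows_peptide,
                          "transition": rows_transition})
    n_tr_total = len(trans)

    icfg = cfg["interference"]
    n_int = int(icfg.get("n_transitions", 0))
    pep_sizes = trans.groupby("peptide")["transition"].size()
    prot_sizes = trans.groupby("protein")["transition"].size()
    pep_prot = trans.drop_duplicates("peptide").set_index("peptide")["protein"]
    # plant only where the protein keeps >= 2 clean transitions even if the
    # whole peptide were lost, so QC failures never erase a panel protein
    eligible_peps = sorted(
        pep for pep, k in pep_sizes.items()
        if k >= 3 and prot_sizes[pep_prot[pep]] - k >= 2)
    if n_int > len(eligible_peps):
        raise ValueError("not enough >=3-transition peptides to plant "
                         f"{n_int} interfered transitions")
    interfered = []
    if n_int:
        # at most one interfered transition per peptide so the per-run
        # peptide mean stays anchored to the protein signal
        peps = rng.choice(np.asarray(eligible_peps, dtype=object),
                          size=n_int, replace=False)
        for pep in peps:
            cands = trans.loc[trans["peptide"] == pep, "transition"]
            interfered.append(str(rng.choice(cands.to_numpy())))
        interfered = sorted(interfered)
    interfered_set = set(interfered)

    n_rep = int(cfg["replicate_count"])
    base = rng.uniform(*cfg["base_intensity_log2"], n_tr_total)
    noise_sd = float(cfg["transition_noise_sd"])
    rep_sd = float(cfg["duplicate_cv_target"]) / LN2
    run_sd = float(cfg["run_effect_sd"])
    run_effect = rng.normal(0.0, run_sd, (n, n_rep))

    sig = np.empty((n_tr_total, n))
    for t_i, (tid, p) in enumerate(zip(trans["transition"], trans["protein"])):
        if tid in interfered_set:
            sig[t_i] = rng.standard_normal(n)  # co-eluting, protein-blind
        else:
            sig[t_i] = z[pidx[p]]
    bio = rng.normal(0.0, noise_sd, (n_tr_total, n))

    spike_mag = float(icfg.get("spike_magnitude", 0.0))
    spike_frac = float(icfg.get("spike_fraction", 0.0))

    frames = []
    for rep in range(n_rep):
        log2v = (base[:, None] + sig + bio + run_effect[None, :, rep]
                 + rng.normal(0.0, rep_sd, (n_tr_total, n)))
        if interfered and spike_mag > 0:
            for t_i in np.flatnonzero(
                    trans["transition"].isin(interfered_set)):
                hits = rng.random(n) < spike_frac
                log2v[t_i, hits] += rng.normal(0.0, spike_mag, hits.sum())
        df = pd.DataFrame(log2v, columns=subjects)
        df = pd.concat([trans, df], axis=1).melt(
            id_vars=["protein", "peptide", "transition"],
            var_name="subject", value_name="log2")
        df["replicate"] = rep + 1
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    long["intensity"] = np.exp2(long["log2"].to_numpy())
    long = long.drop(columns="log2")
    table = TransitionTable(
        long[["protein", "peptide", "transition", "subject", "replicate",
              "intensity"]])

    psycho = _make_psychometrics(cfg, cohort, rng)
    cohort_full = cohort.merge(psycho, on="subject_id")

    truth = GroundTruth(
        true_signals=true_signals,
        interfered_transitions=list(interfered),
        differential_proteins={p: effs
                               for p, effs in effects_by_protein.items()},
        affected_roi_cells=sorted(set(affected)),
        couplings=couplings,
    )
    return SimulatedCohort(transitions=table, cohort=cohort_full,
                           roi=roi_matrix, psychometrics=psycho,
                           truth=truth, config=cfg)


def null_cohort(cfg: GeneratorConfig | None = None,
                seed: int | None = None) -> SimulatedCohort:
    """Same cohort machinery with every planted effect removed; the
    ground-truth lists come back empty."""
    if cfg is None:
        cfg = GeneratorConfig.default(seed)
    elif seed is not None:
        cfg = cfg.replace(seed=int(seed))
    return generate_cohort(cfg.nulled())
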