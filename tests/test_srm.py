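"""Transition QC and eigengene summarization."""

import numpy as np
import pandas as pd
import pytest
from sympy import log as symlog

from srmdti import srm
from conftest import make_transition_table, random_table


def _simple(values_by_run, tid="t1", **kw):
    return make_transition_table({tid: values_by_run}, **kw)


class TestLog2:
    @pytest.mark.parametrize("raw, expected", [
        (8.0, 3.0),
        (1.0, 0.0),
        # independent high-precision evaluation of log2(10)
        (10.0, float(symlog(10, 2).evalf(30))),
    ])
    def test_known_values(self, raw, expected):
        t = _simple({("S1", 1): raw, ("S2", 1): raw * 2})
        out = srm.log2_transform(t)
        got = out.data.loc[out.data["subject"] == "S1", "intensity"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_with_record_id(self):
        t = _simple({("S1", 1): 100.0, ("S2", 1): -3.0})
        with pytest.raises(ValueError, match="S2"):
            srm.log2_transform(t)

    def test_rejects_rerun(self):
        t = srm.log2_transform(_simple({("S1", 1): 4.0, ("S2", 1): 2.0}))
        with pytest.raises(ValueError, match="already log2"):
            srm.log2_transform(t)

    def test_drops_mostly_missing_transition(self):
        vals = {("S%d" % i, 1): 100.0 for i in range(10)}
        sparse = {("S%d" % i, 1): (200.0 if i < 3 else np.nan)
                  for i in range(10)}
        t = make_transition_table({"P1|pep|t1": vals, "P1|pep|t2": sparse})
        out = srm.log2_transform(t)
        assert set(out.data["transition"]) == {"t1"}


class TestNormalizeRuns:
    def test_run_medians_equalized(self):
        rng = np.random.default_rng(0)
        t = random_table(rng, n_transitions=5, n_subjects=4)
        out = srm.normalize_runs(t)
        med = out.data.groupby(["subject", "replicate"])["intensity"].median()
        # brute-force recomputation: every run median equals the global one
        assert np.allclose(med, np.median(med), atol=1e-12)

    def test_two_run_shift(self):
        t = make_transition_table({
            "P1|pep|t%d" % i: {("A", 1): 10 + d, ("B", 1): 12 + d}
            for i, d in enumerate([-1.0, 0.0, 1.0])}, log_scale=True)
        out = srm.normalize_runs(t)
        med = out.data.groupby("subject")["intensity"].median()
        assert med["A"] == med["B"] == 11.0

    def test_idempotent_and_rank_preserving(self):
        rng = np.random.default_rng(1)
        t = random_table(rng, n_transitions=7, n_subjects=5)
        once = srm.normalize_runs(t)
        twice = srm.normalize_runs(once)
        pd.testing.assert_series_equal(once.data["intensity"],
                                       twice.data["intensity"])
        for (s, r), sub in t.data.groupby(["subject", "replicate"]):
            before = sub.sort_values("transition")["intensity"].rank()
            after = (once.data[(once.data.subject == s)
                               & (once.data.replicate == r)]
                     .sort_values("transition")["intensity"].rank())
            assert (before.to_numpy() == after.to_numpy()).all()

    def test_run_without_usable_transitions_is_named(self):
        df = pd.DataFrame({
            "protein": "P1", "peptide": "pep", "transition": ["t1", "t1"],
            "subject": ["A", "B"], "replicate": 1,
            "intensity": [10.0, np.nan]})
        t = srm.TransitionTable(df, log_scale=True)
        with pytest.raises(ValueError, match="B"):
            srm.normalize_runs(t)


class TestInterference:
    def test_transition_tracking_peptide_mean_scores_one(self):
        base = {("S%d" % i, 1): float(v)
                for i, v in enumerate([10, 12, 9, 14])}
        t = make_transition_table({
            "P1|pep|t1": base,
            "P1|pep|t2": {k: v + 1.0 for k, v in base.items()},
        }, log_scale=True)
        assert srm.interference_score(t, "t1") == pytest.approx(1.0)

    def test_negated_mean_scores_minus_one(self):
        # with t2 = -3*t1 + c the per-run peptide mean is -t1 + c/2
        base = {("S%d" % i, 1): float(v)
                for i, v in enumerate([10, 12, 9, 14])}
        t = make_transition_table({
            "P1|pep|t1": base,
            "P1|pep|t2": {k: -3.0 * v + 40.0 for k, v in base.items()},
        }, log_scale=True)
        assert srm.interference_score(t, "t1") == pytest.approx(-1.0)

    def test_spiked_transition_scores_below_clean_textbook_pearson(self):
        runs = [("S%d" % i, 1) for i in range(4)]
        sig = [10.0, 12.0, 9.0, 14.0]
        spike = [0.0, 0.0, 6.0, 0.0]
        vals = {
            "P1|pep|a": dict(zip(runs, sig)),
            "P1|pep|b": dict(zip(runs, [v + 0.5 for v in sig])),
            "P1|pep|c": dict(zip(runs, [v + s for v, s in zip(sig, spike)])),
        }
        t = make_transition_table(vals, log_scale=True)

        def pearson(x, y):  # textbook formula, independent of numpy.corrcoef
            x, y = np.asarray(x), np.asarray(y)
            xm, ym = x - x.mean(), y - y.mean()
            return float((xm * ym).sum()
                         / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))

        mean_by_run = np.mean([list(v[r] for r in runs)
                               for v in vals.values()], axis=0)
        for name, series in [("a", sig), ("b", [v + 0.5 for v in sig]),
                             ("c", [v + s for v, s in zip(sig, spike)])]:
            assert srm.interference_score(t, name) == pytest.approx(
                pearson(series, mean_by_run), abs=1e-12)
        s = {n: srm.interference_score(t, n) for n in "abc"}
        assert s["c"] < s["a"] and s["c"] < s["b"]

    def test_score_invariances(self):
        rng = np.random.default_rng(2)
        t = random_table(rng, n_transitions=3, n_subjects=6)
        s0 = srm.interference_score(srm.normalize_runs(t), "t0")
        # a constant added to one run is removed by run normalization,
        # leaving the downstream score unchanged
        shifted = t.data.copy()
        first_run = shifted["subject"] == "S0"
        shifted.loc[first_run, "intensity"] += 5.0
        t2 = srm.TransitionTable(shifted, log_scale=True)
        assert srm.interference_score(
            srm.normalize_runs(t2), "t0") == pytest.approx(s0, abs=1e-10)
        # additive offset of the scored transition leaves the score alone
        # (Pearson is location-free in both series)
        scaled = t.data.copy()
        m = scaled["transition"] == "t0"
        scaled.loc[m, "intensity"] = scaled.loc[m, "intensity"] + 3.0
        t3 = srm.TransitionTable(scaled, log_scale=True)
        assert srm.interference_score(t3, "t0") == pytest.approx(
            srm.interference_score(t, "t0"), abs=1e-12)

    def test_filter_keeps_clean_table(self):
        base = {("S%d" % i, 1): float(v)
                for i, v in enumerate([10, 12, 9, 14])}
        t = make_transition_table({
            "P1|pep|t1": base,
            "P1|pep|t2": {k: v + 1.0 for k, v in base.items()},
        }, log_scale=True)
        out, rep = srm.filter_interference(t)
        assert rep.excluded_interference == set()
        assert len(out.data) == len(t.data)

    def test_threshold_one_excludes_noisy(self):
        rng = np.random.default_rng(3)
        t = random_table(rng, n_transitions=3, n_subjects=6)
        out, rep = srm.filter_interference(t, threshold=1.0)
        scores = rep.interference_scores
        assert rep.excluded_interference == {k for k, v in scores.items()
                                             if v < 1.0}


class TestCvFilter:
    def test_identical_duplicates_nothing_excluded(self):
        vals = {("S%d" % i, r): 1000.0 + i for i in range(5) for r in (1, 2)}
        t = _simple(vals)
        out, rep = srm.cv_filter(t)
        assert rep.excluded_cv == set()
        assert max(rep.cv_fail_fraction.values()) == 0.0

    def test_hand_computed_cv_exclusion(self):
        # duplicate pair (100, 150): sd = 35.355, mean = 125, CV = 0.2828
        vals = {}
        for i in range(20):
            hot = i < 3
            vals[("S%02d" % i, 1)] = 100.0
            vals[("S%02d" % i, 2)] = 150.0 if hot else 100.0
        good = {("S%02d" % i, r): 500.0 for i in range(20) for r in (1, 2)}
        t = make_transition_table({"P1|pep|bad": vals, "P1|pep|good": good})
        cv = np.std([100, 150], ddof=1) / np.mean([100, 150])
        assert cv == pytest.approx(0.28284, abs=1e-4)
        out, rep = srm.cv_filter(t)
        assert rep.cv_fail_fraction["bad"] == pytest.approx(0.15)
        assert rep.excluded_cv == {"bad"}
        assert set(out.data["transition"]) == {"good"}

    def test_infinite_threshold_vacuous(self):
        rng = np.random.default_rng(4)
        t = random_table(rng, n_transitions=4, n_subjects=5, n_reps=2)
        _, rep = srm.cv_filter(t, cv_threshold=np.inf)
        assert rep.excluded_cv == set()

    def test_single_replicate_rejected(self):
        t = _simple({("S1", 1): 10.0, ("S2", 1): 12.0})
        with pytest.raises(ValueError, match="duplicate"):
            srm.cv_filter(t)


def _power_iteration_pc(Z, n_iter=10_000, tol=1e-14):
    """Independent oracle: principal eigenvector of Z'Z by power iteration,
    returned as the PC-score vector scaled like the first singular pair."""
    C = Z.T @ Z
    v = np.ones(C.shape[0]) / np.sqrt(C.shape[0])
    lam = 0.0
    for _ in range(n_iter):
        w = C @ v
        lam_new = np.linalg.norm(w)
        w = w / lam_new
        if abs(lam_new - lam) < tol and np.linalg.norm(w - v) < tol:
            v = w
            break
        v, lam = w, lam_new
    return np.sqrt(lam) * v


class TestEigengene:
    def test_single_transition_is_standardized_profile(self):
        vals = {("S%d" % i, 1): float(v)
                for i, v in enumerate([10, 12, 9, 14, 11])}
        t = _simple(vals, log_scale=True)
        eig = srm.protein_eigengene(t, "P1")
        x = np.array([10, 12, 9, 14, 11], float)
        expected = (x - x.mean()) / x.std(ddof=1)
        got = eig[["S%d" % i for i in range(5)]].to_numpy()
        assert np.allclose(got, expected, atol=1e-12)

    def test_two_identical_transitions(self):
        base = {("S%d" % i, 1): float(v)
                for i, v in enumerate([10, 12, 9, 14])}
        t = make_transition_table({"P1|pep|t1": base, "P1|pep|t2": base},
                                  log_scale=True)
        eig = srm.protein_eigengene(t, "P1")
        x = np.array([10, 12, 9, 14], float)
        prof = (x - x.mean()) / x.std(ddof=1)
        r = np.corrcoef(eig[["S%d" % i for i in range(4)]], prof)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(4, 10))
        vals = {f"P1|pep|t{i}": {(f"S{j:02d}", 1): X[i, j]
                                 for j in range(10)} for i in range(4)}
        t = make_transition_table(vals, log_scale=True)
        eig = srm.protein_eigengene(t, "P1")
        Z = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        oracle = _power_iteration_pc(Z)
        got = eig[[f"S{j:02d}" for j in range(10)]].to_numpy()
        if np.dot(got, oracle) < 0:
            oracle = -oracle
        assert np.allclose(got, oracle, atol=1e-8)

    def test_first_pc_explains_most_variance(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            k, n = rng.integers(2, 7), rng.integers(5, 21)
            X = rng.normal(size=(k, n))
            Z = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1,
                                                       keepdims=True)
            vals = {f"P1|pep|t{i}": {(f"S{j:02d}", 1): X[i, j]
                                     for j in range(n)} for i in range(k)}
            t = make_transition_table(vals, log_scale=True)
            eig = srm.protein_eigengene(
                t, "P1")[[f"S{j:02d}" for j in range(n)]].to_numpy()
            # variance along the eigengene >= along any single transition
            var_eig = (eig ** 2).sum()
            proj = np.array([((Z @ z) ** 2).sum() / (z @ z)
                             for z in Z])
            assert var_eig >= proj.max() - 1e-10

    def test_constant_protein_rejected(self):
        vals = {("S%d" % i, 1): 5.0 for i in range(4)}
        t = _simple(vals, log_scale=True)
        with pytest.raises(ValueError, match="zero variance"):
            srm.protein_eigengene(t, "P1")


class TestOutlierScreen:
    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(20, 12)),
                         columns=[f"S{j}" for j in range(12)])
        m["S0"] += 10.0
        rep = srm.outlier_screen(m)
        assert "S0" in rep.outlier_subjects

    def test_homogeneous_cohort_no_flags(self):
        prof = np.arange(10, dtype=float)
        m = pd.DataFrame({f"S{j}": prof for j in range(8)})
        rep = srm.outlier_screen(m)
        assert rep.outlier_subjects == set()

    def test_null_flag_rate_loose(self):
        rng = np.random.default_rng(8)
        fracs = []
        for _ in range(5):
            m = pd.DataFrame(rng.normal(size=(30, 42)),
                             columns=[f"S{j}" for j in range(42)])
            rep = srm.outlier_screen(m)
            fracs.append(len(rep.outlier_subjects) / 42)
        assert np.mean(fracs) < 0.15

    def test_too_few_subjects(self):
        m = pd.DataFrame(np.ones((4, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            srm.outlier_screen(m)


def test_eigengene_recovers_generator_truth(default_sim, preprocessed):
    """On the default synthetic cohort, eigengenes track the generator's
    true protein signals for proteins with >= 2 clean transitions."""
    matrix, _ = preprocessed
    truth = default_sim.truth.true_signals
    interfered = set(default_sim.truth.interfered_transitions)
    trans = default_sim.transitions.data
    clean_counts = (trans[~trans["transition"].isin(interfered)]
                    .groupby("protein")["transition"].nunique())
    for p in matrix.index:
        if clean_counts.get(p, 0) < 2:
            continue
        r = np.corrcoef(matrix.loc[p, truth.columns], truth.loc[p])[0, 1]
        assert abs(r) >= 0.9, p
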