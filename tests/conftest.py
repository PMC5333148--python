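import numpy as np
import pandas as pd
import pytest

from srmdti import simulate, srm


def make_transition_table(values, log_scale=False, normalized=False):
    """Build a TransitionTable from {transition: {(subject, rep): value}}
    with a single protein/peptide unless ids encode otherwise
    (transition ids of the form 'protein|peptide|name')."""
    rows = []
    for tid, runs in values.items():
        if "|" in tid:
            protein, peptide, name = tid.split("|")
        else:
            protein, peptide, name = "P1", "P1_pep1", tid
        for (subj, rep), v in runs.items():
            rows.append({"protein": protein, "peptide": peptide,
                         "transition": name, "subject": subj,
                         "replicate": rep, "intensity": v})
    return srm.TransitionTable(pd.DataFrame(rows), log_scale=log_scale,
                               normalized=normalized)


def random_table(rng, n_transitions=5, n_subjects=4, n_reps=1,
                 log_scale=True):
    rows = []
    for t in range(n_transitions):
        for s in range(n_subjects):
            for r in range(n_reps):
                rows.append({
                    "protein": "P1", "peptide": f"pep{t // 3 + 1}",
                    "transition": f"t{t}", "subject": f"S{s}",
                    "replicate": r + 1,
                    "intensity": rng.normal(15, 2) if log_scale
                    else rng.uniform(1e4, 1e6)})
    return srm.TransitionTable(pd.DataFrame(rows), log_scale=log_scale)


@pytest.fixture(scope="session")
def default_sim():
    return simulate.generate_cohort(seed=11)


@pytest.fixture(scope="session")
def preprocessed(default_sim):
    return srm.preprocess(default_sim.transitions)


@pytest.fixture(scope="session")
def protein_matrix(preprocessed):
    return preprocessed[0]
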