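"""Packaged reference tables for the worked screening example.

The tables transcribe the published score, MM/GBSA and consensus-rank
tables for the allosteric-inhibitor candidates of the mutant EGFR kinase
(ten screened compounds plus the reference inhibitor EAI001), so that the
screening-triage pipeline runs offline end to end.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_candidate_scores",
    "load_mmgbsa_table",
    "load_mmgbsa_components",
    "load_consensus_ranks",
    "load_external_criteria_ranks",
    "data_path",
]


def data_path(name: str):
    """Filesystem path of a packaged data file."""
    return resources.files("kinasecv") / "data" / name


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(data_path(name)) as p:
        return pd.read_csv(p)


def load_candidate_scores() -> pd.DataFrame:
    """Docking scores (kcal/mol, lower better) and ML-predicted affinity
    scores (unitless, higher better) for the candidates and EAI001."""
    return _read("candidate_scores.csv")


def load_mmgbsa_table() -> pd.DataFrame:
    """Full published MM/GBSA table: component means (VDW, EEL, EGB,
    ESURF), printed aggregates (dG_gas, dG_solv, dG_total) and SD."""
    return _read("mmgbsa_summary.csv")


def load_mmgbsa_components() -> pd.DataFrame:
    """Component-mean columns only (input to :func:`aggregate_mmgbsa`)."""
    return load_mmgbsa_table()[["compound", "VDW", "EEL", "EGB", "ESURF"]]


def load_consensus_ranks() -> pd.DataFrame:
    """Published compound x criterion rank matrix (1 = best)."""
    return _read("consensus_ranks.csv")


def load_external_criteria_ranks() -> pd.DataFrame:
    """The two externally supplied structural criteria (alphaC-helix
    displacement and salt-bridge distance ranks) that cannot be recomputed
    from the score/energy tables alone."""
    return _read("external_criteria_ranks.csv")
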