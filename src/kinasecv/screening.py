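"""Virtual-screening post-processing: MM/GBSA aggregation and lead selection.

End-point MM/GBSA binding free energies decompose into gas-phase molecular
mechanics terms (van der Waals VDW + electrostatics EEL = dG_gas) and
solvation terms (generalized-Born polar EGB + nonpolar surface ESURF =
dG_solv); their sum is dG_total.  Candidate compounds are triaged by
ranking them under several criteria (ML-predicted affinity, docking score,
MM/GBSA total, plus externally supplied structural criteria) and selecting
compounds that place in the top-k ranks in at least m criteria.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COMPONENT_COLUMNS",
    "binding_free_energy",
    "aggregate_mmgbsa",
    "validate_energy_table",
    "filter_above_reference",
    "rank_by",
    "select_multicriteria",
    "CRITERION_DIRECTIONS",
]

COMPONENT_COLUMNS = ("VDW", "EEL", "EGB", "ESURF")

#: default sort direction per scoring criterion. ``asc`` means lower is
#: better (docking scores and binding free energies in kcal/mol), ``desc``
#: means higher is better (ML-predicted affinity).
CRITERION_DIRECTIONS = {
    "ml_score": "desc",
    "docking_score": "asc",
    "dG_total": "asc",
}


def binding_free_energy(dG_complex: float, dG_protein: float, dG_ligand: float) -> float:
    """Bound-minus-free binding free energy (kcal/mol).

    ``dG_bind = dG_complex - (dG_protein + dG_ligand)``.
    """
    out = float(dG_complex) - (float(dG_protein) + float(dG_ligand))
    if not np.isfinite(out):
        raise ValueError("binding_free_energy requires finite inputs")
    return out


def aggregate_mmgbsa(components: pd.DataFrame) -> pd.DataFrame:
    """Aggregate MM/GBSA component rows into per-compound energy summaries.

    *components* must hold columns ``compound, VDW, EEL, EGB, ESURF`` with
    either one summary row per compound or per-frame rows.  Components are
    averaged per compound and combined exactly:
    ``dG_gas = VDW + EEL``, ``dG_solv = EGB + ESURF``,
    ``dG_total = dG_gas + dG_solv``.  With per-frame rows the sample SD of
    the per-frame totals is reported; for single-row compounds SD is NaN.
    Input compound order is preserved.
    """
    if "compound" not in components.columns:
        raise ValueError("missing required column 'compound'")
    for col in COMPONENT_COLUMNS:
        if col not in components.columns:
            raise ValueError(f"missing required component column {col!r}")
    if len(components) == 0:
        raise ValueError("empty component table")
    if components[list(COMPONENT_COLUMNS)].isna().any().any():
        raise ValueError("component table contains missing values")
    order = list(dict.fromkeys(components["compound"]))
    rows = []
    for compound in order:
        sub = components.loc[components["compound"] == compound, list(COMPONENT_COLUMNS)]
        means = sub.mean()
        gas = means["VDW"] + means["EEL"]
        solv = means["EGB"] + means["ESURF"]
        per_frame_totals = sub.sum(axis=1)
        sd = float(per_frame_totals.std(ddof=1)) if len(sub) > 1 else float("nan")
        rows.append({
            "compound": compound,
            **{c: float(means[c]) for c in COMPONENT_COLUMNS},
            "dG_gas": float(gas),
            "dG_solv": float(solv),
            "dG_total": float(gas + solv),
            "sd": sd,
        })
    return pd.DataFrame(rows)


def validate_energy_table(published: pd.DataFrame, tol: float = 0.02) -> pd.DataFrame:
    """Check printed aggregate columns against recomputed component sums.

    *published* holds per-compound component means plus printed ``dG_gas``,
    ``dG_solv`` and ``dG_total`` columns.  Each aggregate is recomputed from
    the components and compared at *tol* (kcal/mol; the default 0.02 allows
    for rounding of components printed to 2 decimals).  Returns a table of
    deviations with a ``consistent`` flag -- inconsistent rows are reported,
    never silently accepted.
    """
    recomputed = aggregate_mmgbsa(published[["compound", *COMPONENT_COLUMNS]])
    recomputed = recomputed.set_index("compound")
    out = []
    for _, row in published.iterrows():
        comp = row["compound"]
        devs = {}
        for col in ("dG_gas", "dG_solv", "dG_total"):
            if col in published.columns:
                devs[f"delta_{col}"] = float(row[col] - recomputed.loc[comp, col])
        max_dev = max(abs(v) for v in devs.values()) if devs else 0.0
        out.append({"compound": comp, **devs, "max_abs_deviation": max_dev,
                    "consistent": max_dev <= tol})
    return pd.DataFrame(out)


def _resolve_reference(scores: pd.DataFrame, reference, criterion: str) -> float:
    if isinstance(reference, str):
        match = scores.loc[scores["compound"] == reference, criterion]
        if len(match) != 1:
            raise ValueError(
                f"reference compound {reference!r} matched {len(match)} rows"
            )
        return float(match.iloc[0])
    return float(reference)


def filter_above_reference(scores: pd.DataFrame, reference,
                           criterion: str = "ml_score",
                           direction: str | None = None) -> list[str]:
    """Compounds scoring strictly better than a reference on one criterion.

    *reference* is a compound id present in the table or a numeric value.
    Direction defaults to the criterion's registered convention
    (higher-better for ML scores, lower-better for docking scores).
    The reference compound itself is never returned.
    """
    if criterion not in scores.columns:
        raise ValueError(f"unknown criterion column {criterion!r}")
    direction = direction or CRITERION_DIRECTIONS.get(criterion, "desc")
    ref_value = _resolve_reference(scores, reference, criterion)
    values = scores[criterion].astype(float)
    better = values > ref_value if direction == "desc" else values < ref_value
    if isinstance(reference, str):
        better &= scores["compound"] != reference
    return scores.loc[better, "compound"].tolist()


def rank_by(values, direction: str = "asc", ties: str = "stable") -> np.ndarray:
    """Integer ranks, 1 = best under the stated direction.

    ``ties="stable"`` resolves equal values by input order, producing
    distinct consecutive ranks (the convention used when listed score
    tables carry distinct ranks for tied scores); ``ties="competition"``
    gives min-rank style shared ranks.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("rank_by requires finite values")
    if direction not in ("asc", "desc"):
        raise ValueError(f"direction must be 'asc' or 'desc', got {direction!r}")
    key = values if direction == "asc" else -values
    if ties == "stable":
        order = np.argsort(key, kind="stable")
        ranks = np.empty(len(values), dtype=int)
        ranks[order] = np.arange(1, len(values) + 1)
        return ranks
    if ties == "competition":
        return stats.rankdata(key, method="min").astype(int)
    raise ValueError(f"unknown tie policy {ties!r}")


def select_multicriteria(ranks: pd.DataFrame, top_k: int = 5,
                         min_criteria: int = 3) -> list[str]:
    """Compounds ranking <= *top_k* in at least *min_criteria* criteria.

    *ranks* is indexed by compound (or has a ``compound`` column) with one
    integer-rank column per criterion.  Returns the selected compounds in
    input order.
    """
    if "compound" in ranks.columns:
        ranks = ranks.set_index("compound")
    n_criteria = ranks.shape[1]
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not 1 <= min_criteria <= n_criteria:
        raise ValueError(
            f"min_criteria must be in 1..{n_criteria}, got {min_criteria}"
        )
    if ranks.isna().any().any():
        missing = [
            f"{comp}/{crit}"
            for comp, row in ranks.iterrows()
            for crit, v in row.items() if pd.isna(v)
        ]
        raise ValueError(f"missing ranks for: {', '.join(missing)}")
    hits = (ranks <= top_k).sum(axis=1)
    return ranks.index[hits >= min_criteria].tolist()
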