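"""End-to-end report generation with deterministic provenance.

Two orchestrated runs are provided: a conformational-state report
(classification, band populations, free-energy surface, kernel densities,
block averages) from a CV table, and a screening report (MM/GBSA
aggregation, per-criterion ranking, multicriteria lead selection,
printed-table validation) from score and energy tables.  Every run writes
a manifest recording the package version, all numeric parameters and
SHA-256 checksums of the inputs, so a report can be regenerated
bit-identically from its manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .blocks import block_average
from .cv import read_cv_table
from .landscape import free_energy_surface, kde_density
from .screening import (
    CRITERION_DIRECTIONS,
    aggregate_mmgbsa,
    rank_by,
    select_multicriteria,
    validate_energy_table,
)
from .states import (
    STATE_LABELS,
    StateThresholds,
    band_populations,
    classify_frames,
    population_fractions,
)

__all__ = ["run_state_report", "run_screen_report"]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, parameters: dict, inputs: dict) -> None:
    manifest = {
        "tool": "kinasecv",
        "version": __version__,
        "stage": stage,
        "parameters": parameters,
        "inputs": {str(p): _sha256(p) for p in inputs.values()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_state_report(cv_table, outdir, thresholds: StateThresholds | None = None,
                     channels: tuple[str, str] | None = None,
                     windows: list[tuple[float, float]] | None = None,
                     temperature: float = 300.0, n_bins: int = 100,
                     n_blocks: int = 5,
                     confidence_level: float = 0.95) -> dict:
    """Run the conformational-state analysis chain on one CV table.

    Writes ``populations.csv``, ``bands.csv``, ``fes.csv``,
    ``kde_<channel>.csv``, ``blockstats.csv`` and ``manifest.json`` under
    *outdir*.  Any stage failure aborts before outputs are written.
    Returns the population table as a DataFrame-backed dict for
    convenience.
    """
    cv_table = Path(cv_table)
    if not cv_table.exists():
        raise FileNotFoundError(f"state_report: CV table not found: {cv_table}")
    thr = thresholds or StateThresholds()

    series = read_cv_table(cv_table)
    if channels is None:
        channels = tuple(series.channel_names[:2])
    if len(channels) < 2:
        raise ValueError("state_report: need two CV channels")
    full_window = (float(series.times_ns[0]),
                   float(series.times_ns[-1]) + 1e-9)
    windows = windows or [full_window]

    # --- compute everything first, then write (no partial outputs) ---
    pop_rows, band_rows, block_rows = [], [], []
    for window in windows:
        sub = series.window(window)
        labels = classify_frames(sub, thr, channels=channels)
        for est in population_fractions(labels, confidence_level=confidence_level,
                                        states=STATE_LABELS, window=window):
            pop_rows.append({
                "state": est.state,
                "fraction": est.fraction,
                "ci_half_width": est.ci_half_width,
                "n_frames": est.n_frames,
                "window_start_ns": window[0],
                "window_end_ns": window[1],
            })
        bands = band_populations(sub.channel(channels[0]),
                                 thr.band_cutpoints_1d)
        for band, frac in bands.items():
            band_rows.append({
                "channel": channels[0], "band": band, "fraction": frac,
                "window_start_ns": window[0], "window_end_ns": window[1],
            })
        bs = block_average(sub.channel(channels[0]), n_blocks=n_blocks,
                           channel=channels[0])
        block_rows.append({
            "channel": channels[0], "window_start_ns": window[0],
            "window_end_ns": window[1], "n_blocks": bs.n_blocks,
            "mean": bs.mean, "uncertainty": bs.uncertainty,
            "n_frames": bs.n_frames,
        })

    fes = free_energy_surface(series, channels=channels, n_bins=n_bins,
                              temperature=temperature)
    kdes = {ch: kde_density(series.channel(ch)) for ch in channels}

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(pop_rows).to_csv(outdir / "populations.csv", index=False)
    pd.DataFrame(band_rows).to_csv(outdir / "bands.csv", index=False)
    pd.DataFrame(block_rows).to_csv(outdir / "blockstats.csv", index=False)
    fes.to_dataframe().to_csv(outdir / "fes.csv", index=False)
    for ch, curve in kdes.items():
        pd.DataFrame({"grid": curve.grid, "density": curve.density}).to_csv(
            outdir / f"kde_{ch}.csv", index=False)
    _write_manifest(outdir, "state_report", {
        "thresholds": {
            "inactive_d1_gt": thr.inactive_d1_gt,
            "inactive_d2_gt": thr.inactive_d2_gt,
            "active_d1_lt": thr.active_d1_lt,
            "active_d2_lt": thr.active_d2_lt,
            "band_cutpoints_1d": list(thr.band_cutpoints_1d),
        },
        "channels": list(channels),
        "windows": [list(w) for w in windows],
        "temperature": temperature,
        "n_bins": n_bins,
        "n_blocks": n_blocks,
        "confidence_level": confidence_level,
        "kde_bandwidths": {ch: kdes[ch].bandwidth for ch in kdes},
    }, {"cv_table": cv_table})
    return {"populations": pd.DataFrame(pop_rows)}


def run_screen_report(scores_table, energies_table, outdir,
                      extra_ranks_table=None, top_k: int = 5,
                      min_criteria: int = 3, ties: str = "stable",
                      validation_tol: float = 0.02) -> dict:
    """Run the screening-triage chain: aggregate, rank, select, validate.

    *scores_table* needs ``compound, ml_score, docking_score``;
    *energies_table* needs ``compound, VDW, EEL, EGB, ESURF`` (and may
    carry printed aggregate columns, which are then validated against the
    recomputed sums).  *extra_ranks_table* optionally supplies externally
    computed criterion ranks (e.g. structural displacement criteria) to
    merge into the rank matrix.  Writes ``energy_summary.csv``,
    ``ranks.csv``, ``selected.csv``, ``validation.csv`` and
    ``manifest.json``.
    """
    inputs = {"scores": Path(scores_table), "energies": Path(energies_table)}
    if extra_ranks_table is not None:
        inputs["extra_ranks"] = Path(extra_ranks_table)
    for name, p in inputs.items():
        if not p.exists():
            raise FileNotFoundError(f"screen_report: {name} table not found: {p}")

    scores = pd.read_csv(inputs["scores"])
    energies = pd.read_csv(inputs["energies"])
    if len(scores) == 0:
        raise ValueError("screen_report: empty score table")
    summary = aggregate_mmgbsa(energies)

    validation = None
    if {"dG_gas", "dG_solv", "dG_total"} & set(energies.columns):
        validation = validate_energy_table(energies, tol=validation_tol)

    merged = scores.merge(summary[["compound", "dG_total"]], on="compound",
                          how="inner")
    if len(merged) != len(scores):
        missing = sorted(set(scores["compound"]) - set(summary["compound"]))
        raise ValueError(f"screen_report: no energies for compound(s) {missing}")
    ranks = pd.DataFrame({"compound": merged["compound"]})
    ranks["ml_score_rank"] = rank_by(merged["ml_score"],
                                     CRITERION_DIRECTIONS["ml_score"], ties=ties)
    ranks["docking_rank"] = rank_by(merged["docking_score"],
                                    CRITERION_DIRECTIONS["docking_score"], ties=ties)
    ranks["mmgbsa_rank"] = rank_by(merged["dG_total"],
                                   CRITERION_DIRECTIONS["dG_total"], ties=ties)
    if extra_ranks_table is not None:
        extra = pd.read_csv(inputs["extra_ranks"])
        ranks = ranks.merge(extra, on="compound", how="left")
    selected = select_multicriteria(ranks, top_k=top_k, min_criteria=min_criteria)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(outdir / "energy_summary.csv", index=False)
    ranks.to_csv(outdir / "ranks.csv", index=False)
    pd.DataFrame({"compound": selected}).to_csv(outdir / "selected.csv", index=False)
    if validation is not None:
        validation.to_csv(outdir / "validation.csv", index=False)
    _write_manifest(outdir, "screen_report", {
        "top_k": top_k, "min_criteria": min_criteria, "ties": ties,
        "validation_tol": validation_tol,
    }, inputs)
    return {"summary": summary, "ranks": ranks, "selected": selected,
            "validation": validation}
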