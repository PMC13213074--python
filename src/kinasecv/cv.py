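"""Collective-variable series and structure-based distance extraction.

The analyses in this package operate on one or more named collective
variables (CVs) -- inter-atom distances in angstroms -- sampled over the
frames of a molecular-dynamics trajectory.  The canonical pair for EGFR
kinase-domain state assignment is the K745(NZ)-E762(CD) salt-bridge
distance and an E762-D855 inter-residue distance reporting on alphaC-helix
position.  The pipeline contract is a delimited text table; distances can
also be measured directly on single-model PDB structures.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CVFrameSeries",
    "StructureAtoms",
    "atom_pair_distance",
    "read_cv_table",
    "write_cv_table",
    "time_window_mask",
]

#: canonical channel names used throughout the package
CHANNEL_SALT_BRIDGE = "d_K745_E762"
CHANNEL_HELIX = "d_E762_D855"


def time_window_mask(times_ns: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    """Boolean mask selecting frames whose time falls in ``[start, end)`` ns.

    Windows are half-open so that consecutive windows (e.g. 0-2000 ns and
    8000-10000 ns of a 10-us run) partition the trajectory without overlap.
    ``window=None`` selects every frame.
    """
    times_ns = np.asarray(times_ns, dtype=float)
    if window is None:
        return np.ones(times_ns.shape, dtype=bool)
    start, end = float(window[0]), float(window[1])
    if not end > start:
        raise ValueError(f"empty time window [{start}, {end})")
    return (times_ns >= start) & (times_ns < end)


@dataclass
class CVFrameSeries:
    """Time-ordered values of named collective variables.

    Parameters
    ----------
    frames
        0-based frame indices.
    times_ns
        Frame times in nanoseconds, strictly increasing.
    channels
        Mapping of channel name to per-frame values.  Channels whose name
        starts with ``d_`` are distances and must be non-negative.
    true_state
        Optional hidden-state labels (integers) carried alongside by the
        synthetic generator for ground-truth testing.
    """

    frames: np.ndarray
    times_ns: np.ndarray
    channels: dict[str, np.ndarray]
    true_state: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if self.true_state is not None:
            self.true_state = np.asarray(self.true_state, dtype=np.int64)
        n = len(self.frames)
        if len(self.times_ns) != n:
            raise ValueError("frames and times_ns must have equal length")
        if n == 0:
            raise ValueError("CVFrameSeries must contain at least one frame")
        if n > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise ValueError("times_ns must be strictly increasing")
        for name, values in self.channels.items():
            if len(values) != n:
                raise ValueError(f"channel {name!r} length {len(values)} != {n} frames")
            if name.startswith("d_") and np.any(values < 0):
                raise ValueError(f"distance channel {name!r} contains negative values")
        if self.true_state is not None and len(self.true_state) != n:
            raise ValueError("true_state length does not match frame count")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            )
        return self.channels[name]

    def window(self, window: tuple[float, float] | None) -> "CVFrameSeries":
        """Sub-series of frames with time in ``[start, end)`` ns."""
        mask = time_window_mask(self.times_ns, window)
        if not mask.any():
            raise ValueError(f"time window {window} selects no frames")
        return CVFrameSeries(
            frames=self.frames[mask],
            times_ns=self.times_ns[mask],
            channels={k: v[mask] for k, v in self.channels.items()},
            true_state=None if self.true_state is None else self.true_state[mask],
            metadata=dict(self.metadata),
        )

    def to_dataframe(self, include_state: bool = True) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {"frame": self.frames, "time_ns": self.times_ns}
        data.update(self.channels)
        if include_state and self.true_state is not None:
            data["true_state"] = self.true_state
        return pd.DataFrame(data)


def write_cv_table(series: CVFrameSeries, path, include_state: bool = True,
                   decimals: int | None = None) -> None:
    """Write a CV series as a CSV table ``frame,time_ns,<channel>...``.

    Full floating-point precision is kept by default so a written table
    reads back to the same series; pass ``decimals`` to round distances
    for compact human-facing exports.
    """
    df = series.to_dataframe(include_state=include_state)
    float_format = None if decimals is None else f"%.{decimals}f"
    df.to_csv(path, index=False, float_format=float_format)


def read_cv_table(path, column_map: dict[str, str] | None = None,
                  delimiter: str | None = None) -> CVFrameSeries:
    """Read a delimited CV table into a validated :class:`CVFrameSeries`.

    Parameters
    ----------
    path
        CSV/TSV file with a header row containing at least ``frame`` and
        ``time_ns`` plus one or more value columns.
    column_map
        Optional mapping of file column name to canonical name, e.g.
        ``{"dist1": "d_K745_E762"}``.  Unmapped columns keep their names.
    delimiter
        Field separator; autodetected between comma and tab when omitted.

    Rows with non-numeric or blank cells are rejected with an error naming
    the offending line numbers (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    if column_map:
        df = df.rename(columns=column_map)
    for required in ("frame", "time_ns"):
        if required not in df.columns:
            raise ValueError(f"missing required column {required!r} in {path}")
    value_cols = [c for c in df.columns if c != "true_state"]
    bad_lines: list[int] = []
    numeric = {}
    for col in value_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            bad_lines.extend((df.index[bad] + 2).tolist())
        numeric[col] = coerced.to_numpy()
    if bad_lines:
        lines = ", ".join(str(x) for x in sorted(set(bad_lines)))
        raise ValueError(f"non-numeric or blank cells in {path} at line(s): {lines}")
    channels = {
        c: numeric[c] for c in value_cols if c not in ("frame", "time_ns")
    }
    if not channels:
        raise ValueError(f"no CV channel columns found in {path}")
    true_state = None
    if "true_state" in df.columns:
        true_state = pd.to_numeric(df["true_state"], errors="coerce")
        if true_state.isna().any():
            bad = (df.index[true_state.isna()] + 2).tolist()
            raise ValueError(f"non-numeric true_state cells at line(s): {bad}")
        true_state = true_state.to_numpy(dtype=np.int64)
    return CVFrameSeries(
        frames=numeric["frame"].astype(np.int64),
        times_ns=numeric["time_ns"],
        channels=channels,
        true_state=true_state,
        metadata={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# structures

_SELECTION_RE = re.compile(r"^(?P<chain>[^:]+):(?P<resnum>-?\d+)(?P<icode>[A-Za-z]?):(?P<atom>\S+)$")


class StructureAtoms:
    """Per-atom records of a single-model protein structure.

    Wraps a biotite ``AtomArray`` (first model, alternate locations reduced
    to blank/first) and resolves string selections of the form
    ``chain:resnum[insertion-code]:atomname``, e.g. ``"A:745:NZ"``.
    """

    def __init__(self, atoms) -> None:
        self.atoms = atoms

    @classmethod
    def from_pdb(cls, path) -> "StructureAtoms":
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, altloc="first")
        return cls(atoms)

    def select_one(self, selection: str) -> np.ndarray:
        """Coordinates of the single atom matching *selection*.

        Raises ``ValueError`` naming the selection and the match count when
        it resolves to zero or more than one atom.
        """
        m = _SELECTION_RE.match(selection)
        if m is None:
            raise ValueError(
                f"bad atom selection {selection!r}; expected 'chain:resnum:atomname'"
            )
        chain = m.group("chain")
        resnum = int(m.group("resnum"))
        icode = m.group("icode") or ""
        atom_name = m.group("atom")
        a = self.atoms
        mask = (a.chain_id == chain) & (a.res_id == resnum) & (a.atom_name == atom_name)
        if hasattr(a, "ins_code"):
            mask &= a.ins_code == icode
        n = int(mask.sum())
        if n != 1:
            raise ValueError(
                f"selection {selection!r} matched {n} atoms (expected exactly 1)"
            )
        return np.asarray(a.coord[mask][0], dtype=float)


def atom_pair_distance(structure: StructureAtoms, sel_a: str, sel_b: str) -> float:
    """Euclidean distance (angstrom) between two uniquely selected atoms."""
    xa = structure.select_one(sel_a)
    xb = structure.select_one(sel_b)
    return float(np.linalg.norm(xa - xb))
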