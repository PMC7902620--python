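"""Domain containers and file I/O for conformational ensembles, scattering
profiles and chemical-shift tables.

Unit conventions
----------------
All coordinates are stored internally in **nanometres** and all momentum
transfers in **inverse nanometres**.  Conversions happen only at file
boundaries: PDB coordinates (Angstrom) are multiplied by 0.1 on read and by
10 on write; SAXS profiles read with ``q_unit="inv_angstrom"`` have q
multiplied by 10.  XYZ trajectories are read and written in nm as-is.

Residue indices are 1-based in every file format and in the public
:class:`ShiftTable` records; array indexing inside the package is 0-based.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .exceptions import EmptyInputError, FormatError

__all__ = [
    "Ensemble",
    "SAXSProfile",
    "ShiftTable",
    "BACKBONE_ATOMS",
    "read_ca_trajectory",
    "write_ca_trajectory",
    "read_saxs_profile",
    "write_saxs_profile",
    "read_shift_table",
    "write_shift_table",
]

#: Backbone nuclei handled by the chemical-shift pipeline.  File-format
#: names N, CA, CB, H, HA correspond to the amide nitrogen (N^H), alpha and
#: beta carbons (C^alpha, C^beta), amide proton (H^N) and alpha proton
#: (H^alpha).
BACKBONE_ATOMS = ("N", "CA", "CB", "H", "HA")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Ensemble:
    """An ordered set of conformations of a single C-alpha trace.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_residues, 3)`` with positions in nm.
        Frame order is meaningful (time order for trajectory-derived
        ensembles) and is preserved exactly by all I/O routines.
    residue_names
        Optional sequence of three-letter residue codes, one per residue.
    label
        Free-text identifier carried through reports.
    """

    coords: np.ndarray
    residue_names: list[str] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError(
                f"coords must have shape (n_frames, n_residues, 3), "
                f"got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise EmptyInputError("ensemble has no frames")
        if self.coords.shape[1] < 2:
            raise FormatError("ensemble must have at least 2 residues")
        if not np.isfinite(self.coords).all():
            raise FormatError("ensemble coordinates contain non-finite values")
        if self.residue_names is not None:
            self.residue_names = list(self.residue_names)
            if len(self.residue_names) != self.coords.shape[1]:
                raise FormatError(
                    "residue_names length does not match residue count"
                )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def bond_vectors(self) -> np.ndarray:
        """Consecutive C-alpha difference vectors, shape (n_frames, N-1, 3)."""
        return np.diff(self.coords, axis=1)


@dataclass
class SAXSProfile:
    """A small-angle scattering curve: intensity versus momentum transfer.

    ``q`` is in nm^-1 and must be strictly increasing; ``sigma`` (per-point
    experimental uncertainty, same arbitrary units as ``I``) may be ``None``
    for simulated curves.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise FormatError("q and I must be 1-D arrays of equal length")
        if np.any(self.q <= 0):
            raise FormatError("q values must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise FormatError("q values must be strictly increasing")
        if not (np.isfinite(self.q).all() and np.isfinite(self.I).all()):
            raise FormatError("profile contains non-finite values")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise FormatError("sigma length does not match q")
            if np.any(~np.isfinite(self.sigma)) or np.any(self.sigma <= 0):
                raise FormatError("sigma values must be positive and finite")

    def __len__(self) -> int:
        return self.q.size


@dataclass
class ShiftTable:
    """Per-residue, per-atom chemical shifts in p.p.m.

    Backed by a DataFrame with columns ``res_index`` (1-based int),
    ``res_name`` (3-letter code), ``atom`` (one of :data:`BACKBONE_ATOMS`)
    and ``shift`` (float, p.p.m.).  At most one record may exist per
    ``(res_index, atom)`` pair.
    """

    records: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records).copy()
        required = ["res_index", "res_name", "atom", "shift"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"shift table missing columns: {missing}")
        if len(df) == 0:
            raise EmptyInputError("shift table has no records")
        try:
            df["res_index"] = df["res_index"].astype(int)
            df["shift"] = df["shift"].astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric value in shift table: {exc}") from exc
        df["res_name"] = df["res_name"].astype(str).str.upper()
        df["atom"] = df["atom"].astype(str).str.upper()
        bad = sorted(set(df["atom"]) - set(BACKBONE_ATOMS))
        if bad:
            raise FormatError(
                f"unknown atom name(s) {bad}; allowed atoms are "
                f"{list(BACKBONE_ATOMS)}"
            )
        if not np.isfinite(df["shift"]).all():
            raise FormatError("shift values must be finite")
        dup = df.duplicated(subset=["res_index", "atom"])
        if dup.any():
            pairs = df.loc[dup, ["res_index", "atom"]].to_records(index=False)
            raise FormatError(f"duplicate (res_index, atom) records: {list(pairs)}")
        self.records = df[required].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def atom_series(self, atom: str) -> pd.Series:
        """Shifts for one atom type, indexed by residue index."""
        sel = self.records[self.records["atom"] == atom.upper()]
        return sel.set_index("res_index")["shift"]

    def reference_map(self) -> dict[tuple[str, str], float]:
        """(res_name, atom) -> shift lookup, for random-coil reference tables.

        Raises if the same (res_name, atom) pair carries conflicting values.
        """
        out: dict[tuple[str, str], float] = {}
        for row in self.records.itertuples(index=False):
            key = (row.res_name, row.atom)
            if key in out and not np.isclose(out[key], row.shift):
                raise FormatError(
                    f"conflicting reference shifts for {key}: "
                    f"{out[key]} vs {row.shift}"
                )
            out[key] = row.shift
        return out


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

def _infer_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("pdb", "xyz"):
            raise FormatError(f"unsupported trajectory format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("pdb", "xyz"):
        return suffix
    raise FormatError(
        f"cannot infer trajectory format from {path!r}; pass format="
    )


def _pdb_model_ca_counts(path: str | os.PathLike) -> list[int]:
    """Per-MODEL CA counts from raw text, for diagnostic error messages."""
    counts: list[int] = []
    current: int | None = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                current = 0
            elif line.startswith("ENDMDL"):
                counts.append(current or 0)
                current = None
            elif line.startswith(("ATOM", "HETATM")):
                if line[12:16].strip() == "CA":
                    if current is None:  # model-less single-structure file
                        current = 0
                    current += 1
    if current is not None:
        counts.append(current)
    return counts


def read_ca_trajectory(
    path: str | os.PathLike, format: str | None = None
) -> Ensemble:
    """Read a C-alpha trace ensemble from a multi-model PDB or XYZ file.

    PDB coordinates (Angstrom) are converted to nm; XYZ files are taken to
    be in nm already.  Every model/block must contain the same number of
    CA atoms, in residue order.
    """
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        return _read_pdb(path)
    return _read_xyz(path)


def _read_pdb(path: str | os.PathLike) -> Ensemble:
    pdbf = PDBFile.read(str(path))
    try:
        stack = pdbf.get_structure(model=None)
    except Exception as exc:
        counts = _pdb_model_ca_counts(path)
        if len(set(counts)) > 1:
            ref = counts[0]
            bad = next(i for i, c in enumerate(counts) if c != ref)
            raise FormatError(
                f"inconsistent CA count across models: model {bad + 1} has "
                f"{counts[bad]} CA atoms, model 1 has {ref}"
            ) from exc
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    mask = stack.atom_name == "CA"
    if not mask.any():
        raise EmptyInputError(f"no CA atoms found in {path}")
    ca = stack[:, mask]
    names = list(ca.res_name)
    return Ensemble(
        coords=ca.coord * 0.1,  # Angstrom -> nm
        residue_names=names,
        label=str(path),
    )


def _read_xyz(path: str | os.PathLike) -> Ensemble:
    frames: list[np.ndarray] = []
    names: list[str] | None = None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(
                f"{path}: expected atom count at line {i + 1}"
            ) from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError(
                f"{path}: truncated frame {len(frames) + 1} "
                f"(expected {n} atoms, found {len(block)})"
            )
        coords = np.empty((n, 3))
        frame_names = []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path}: malformed atom line in frame {len(frames) + 1}"
                )
            frame_names.append(parts[0])
            coords[j] = [float(p) for p in parts[1:4]]
        if frames and coords.shape[0] != frames[0].shape[0]:
            raise FormatError(
                f"{path}: frame {len(frames) + 1} has {coords.shape[0]} "
                f"atoms, frame 1 has {frames[0].shape[0]}"
            )
        if names is None:
            names = frame_names
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise EmptyInputError(f"no frames found in {path}")
    res_names = names if names and any(n != "CA" for n in names) else None
    return Ensemble(coords=np.stack(frames), residue_names=res_names,
                    label=str(path))


def write_ca_trajectory(
    ensemble: Ensemble, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write an ensemble as a multi-model PDB (Angstrom) or XYZ (nm) file.

    PDB output uses a single chain ``A``, residue numbering 1..N and atom
    name CA, so the file round-trips through :func:`read_ca_trajectory`.
    """
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        _write_pdb(ensemble, path)
    else:
        _write_xyz(ensemble, path)


def _write_pdb(ensemble: Ensemble, path: str | os.PathLike) -> None:
    n_frames, n_res = ensemble.n_frames, ensemble.n_residues
    names = ensemble.residue_names or ["GLY"] * n_res
    stack = struc.AtomArrayStack(n_frames, n_res)
    stack.chain_id = np.full(n_res, "A")
    stack.res_id = np.arange(1, n_res + 1)
    stack.res_name = np.array([n[:3].upper() for n in names])
    stack.atom_name = np.full(n_res, "CA")
    stack.element = np.full(n_res, "C")
    stack.hetero = np.zeros(n_res, dtype=bool)
    stack.coord = ensemble.coords * 10.0  # nm -> Angstrom
    pdbf = PDBFile()
    pdbf.set_structure(stack)
    pdbf.write(str(path))


def _write_xyz(ensemble: Ensemble, path: str | os.PathLike) -> None:
    names = ensemble.residue_names or ["CA"] * ensemble.n_residues
    with open(path, "w") as fh:
        for t in range(ensemble.n_frames):
            fh.write(f"{ensemble.n_residues}\n")
            fh.write(f"frame {t}\n")
            for name, (x, y, z) in zip(names, ensemble.coords[t]):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# SAXS profile I/O
# ---------------------------------------------------------------------------

def read_saxs_profile(
    path: str | os.PathLike,
    q_unit: str = "inv_nm",
    min_points: int = 5,
) -> SAXSProfile:
    """Read a 2- or 3-column ASCII scattering profile (q, I[, sigma]).

    Columns may be separated by whitespace or commas; ``#`` lines are
    comments.  ``q_unit="inv_angstrom"`` converts q to nm^-1 (factor 10).
    Profiles with fewer than ``min_points`` points are rejected as too
    short to support the scale-and-background fit.
    """
    if q_unit not in ("inv_nm", "inv_angstrom"):
        raise FormatError(f"unknown q_unit {q_unit!r}")
    with open(path) as fh:
        text = fh.read().replace(",", " ")
    try:
        data = np.loadtxt(io.StringIO(text), comments="#", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"cannot parse SAXS profile {path}: {exc}") from exc
    if data.shape[0] < min_points:
        raise FormatError(
            f"SAXS profile {path} has only {data.shape[0]} points; "
            f"at least {min_points} required"
        )
    if data.shape[1] not in (2, 3):
        raise FormatError(
            f"SAXS profile {path} must have 2 or 3 columns, "
            f"found {data.shape[1]}"
        )
    q = data[:, 0]
    if q_unit == "inv_angstrom":
        q = q * 10.0
    sigma = data[:, 2] if data.shape[1] == 3 else None
    try:
        return SAXSProfile(q=q, I=data[:, 1], sigma=sigma, label=str(path))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_saxs_profile(profile: SAXSProfile, path: str | os.PathLike) -> None:
    """Write a profile as 3-column (or 2-column if sigma absent) ASCII, q in nm^-1."""
    cols = [profile.q, profile.I]
    if profile.sigma is not None:
        cols.append(profile.sigma)
    header = "q[1/nm] I[a.u.]" + (" sigma[a.u.]" if profile.sigma is not None else "")
    np.savetxt(path, np.column_stack(cols), header=header, fmt="%.8g")


# ---------------------------------------------------------------------------
# Chemical-shift table I/O
# ---------------------------------------------------------------------------

def read_shift_table(path: str | os.PathLike) -> ShiftTable:
    """Read a TSV shift table with header res_index, res_name, atom, shift."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot parse shift table {path}: {exc}") from exc
    try:
        return ShiftTable(records=df, label=str(path))
    except (FormatError, EmptyInputError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_shift_table(table: ShiftTable, path: str | os.PathLike) -> None:
    table.records.to_csv(path, sep="\t", index=False)
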