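"""Readers and writers for the delimited-text and PDB formats the pipeline touches.

CSV dialect: comma-delimited, '.' decimal, UTF-8, '#' comment lines.
PDB files are parsed with biotite; coordinates stay in Å with 1-based
residue numbering preserved from the input.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyStructureError, InvalidInputError, SchemaError
from .fret import FretRecord
from .structures import Structure, Trajectory, make_atom_table

__all__ = [
    "read_fret_table",
    "write_fret_table",
    "read_pdb",
    "write_pdb",
    "read_manifest",
    "write_report",
]

_FRET_COLUMNS = ["donor_conc", "acceptor_conc", "fret"]


def read_fret_table(path, strict: bool = False) -> list[FretRecord]:
    """Read per-region FRET records from CSV with headers donor_conc, acceptor_conc, fret[, cell_id].

    Malformed rows (non-numeric or out-of-range values) are rejected with
    their line numbers — dropped with a warning by default, or raised as a
    :class:`SchemaError` when ``strict``.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in _FRET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    records: list[FretRecord] = []
    bad: list[str] = []
    # header is line 1 of non-comment content; track true file line numbers
    with open(path, encoding="utf-8") as fh:
        data_lines = [i + 1 for i, ln in enumerate(fh) if ln.strip() and not ln.lstrip().startswith("#")]
    body_lines = data_lines[1:]
    for k, (_, row) in enumerate(df.iterrows()):
        lineno = body_lines[k] if k < len(body_lines) else -1
        try:
            rec = FretRecord(
                donor_conc=float(row["donor_conc"]),
                acceptor_conc=float(row["acceptor_conc"]),
                fret=float(row["fret"]),
                cell_id=str(row["cell_id"]) if "cell_id" in df.columns and pd.notna(row["cell_id"]) else "",
            )
        except (TypeError, ValueError) as exc:
            bad.append(f"line {lineno}: {exc}")
            continue
        records.append(rec)
    if bad:
        msg = f"{path}: rejected {len(bad)} row(s): " + "; ".join(bad)
        if strict:
            raise SchemaError(msg)
        warnings.warn(msg, stacklevel=2)
    return records


def write_fret_table(records, path) -> None:
    df = pd.DataFrame(
        {
            "donor_conc": [r.donor_conc for r in records],
            "acceptor_conc": [r.acceptor_conc for r in records],
            "fret": [r.fret for r in records],
            "cell_id": [r.cell_id for r in records],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def _from_atom_array(arr) -> tuple[pd.DataFrame, np.ndarray]:
    atoms = make_atom_table(
        chain=arr.chain_id,
        res_id=arr.res_id,
        res_name=arr.res_name,
        atom_name=arr.atom_name,
        element=arr.element,
    )
    return atoms, np.asarray(arr.coord, dtype=float)


def read_pdb(path, multi_model: bool = False, include_het: bool = False):
    """Parse a PDB file into a :class:`Structure` (or :class:`Trajectory`).

    With ``multi_model``, MODEL/ENDMDL blocks become trajectory frames (all
    models must share the atom table).  HETATM records are excluded unless
    ``include_het``.
    """
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    try:
        obj = pdb.get_structure(f) if multi_model else pdb.get_structure(f, model=1)
    except Exception as exc:  # biotite raises on inconsistent models / no atoms
        raise EmptyStructureError(f"{path}: {exc}") from exc
    if not include_het:
        obj = obj[..., ~obj.hetero]
    if obj.array_length() == 0:
        raise EmptyStructureError(f"{path}: no ATOM records after filtering")
    if multi_model:
        atoms, _ = _from_atom_array(obj[0])
        coords = np.asarray(obj.coord, dtype=float)
        return Trajectory(atoms, coords)
    atoms, coords = _from_atom_array(obj)
    return Structure(atoms, coords)


def write_pdb(obj, path) -> None:
    """Write a Structure (single model) or Trajectory (multi-model) as PDB."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if isinstance(obj, Trajectory):
        atoms, frames = obj.atoms, obj.coords
    elif isinstance(obj, Structure):
        atoms, frames = obj.atoms, obj.coords[None]
    else:
        raise InvalidInputError(f"cannot write object of type {type(obj)} as PDB")
    n = len(atoms)
    arr = struc.AtomArray(n)
    arr.chain_id = atoms["chain"].to_numpy(dtype="U4")
    arr.res_id = atoms["res_id"].to_numpy(dtype=int)
    arr.res_name = atoms["res_name"].to_numpy(dtype="U5")
    arr.atom_name = atoms["atom_name"].to_numpy(dtype="U6")
    arr.element = atoms["element"].to_numpy(dtype="U2")
    stack = struc.stack([arr] * frames.shape[0])
    stack.coord = np.asarray(frames, dtype=np.float32)
    f = pdb.PDBFile()
    pdb.set_structure(f, stack if frames.shape[0] > 1 else stack[0])
    f.write(str(path))


def read_manifest(path) -> pd.DataFrame:
    """Batch manifest CSV: path, kind, pixel_area, detector_variance[, label]."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = ["path", "kind", "pixel_area", "detector_variance"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: manifest missing column(s) {missing}")
    kinds = set(df["kind"].unique())
    allowed = {"tiff", "text"}
    if not kinds <= allowed:
        raise SchemaError(f"{path}: unknown kind(s) {sorted(kinds - allowed)}; allowed {sorted(allowed)}")
    base = path.parent
    resolved = []
    for p in df["path"]:
        q = Path(p)
        if not q.is_absolute():
            q = base / q
        if not q.exists():
            raise SchemaError(f"{path}: listed file does not exist: {q}")
        resolved.append(str(q))
    df = df.assign(path=resolved)
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("Infinity" if obj > 0 else "-Infinity")
    return obj


def write_report(results: dict, path) -> None:
    """JSON summary with deterministic field ordering; atomic write."""
    path = Path(path)
    payload = json.dumps(_jsonable(results), indent=2, sort_keys=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(payload + "\n", encoding="utf-8")
    tmp.replace(path)
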