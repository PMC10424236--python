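"""Readers and writers for the pipeline's text formats.

* PDB (via biotite): one bead per residue, chains A/B for the two DNA
  molecules and chain I for ions; coordinates converted nm -> Angstrom
  at the format's fixed 3-decimal precision.
* Multi-frame XYZ with a box record on the comment line (coordinates in
  nm at 9 significant digits).
* Window time-series files: '#'-headed two-column text (sample index,
  reaction coordinate in nm) carrying the window centre and force
  constant — the layout consumed by standard WHAM tools.
* PMF tables as TSV, and a lossless JSON representation of a full
  SystemState.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .simulate import UmbrellaWindow, WindowRecord
from .structure import MoleculeModel, SimulationBox, SystemState
from .wham import PMFProfile

__all__ = [
    "ParseError",
    "write_pdb",
    "read_pdb_coordinates",
    "write_xyz",
    "read_xyz",
    "write_window_series",
    "read_window_series",
    "read_window_series_list",
    "write_pmf_tsv",
    "read_pmf_tsv",
    "save_state_json",
    "load_state_json",
]

NM_TO_ANGSTROM = 10.0


class ParseError(ValueError):
    """Malformed input file; the message carries the file position."""


# ---------------------------------------------------------------------------
# PDB

def _ion_name(charge: float) -> str:
    if charge > 1.5:
        return "CA"
    if charge > 0:
        return "NA"
    return "CL"


def write_pdb(state: SystemState, path: str | Path) -> None:
    """Write the assembled system as a PDB file (chains A, B, I)."""
    n = state.n_particles
    arr = struc.AtomArray(n)
    coords = []
    chain, res_name, atom_name, element, res_id, hetero = [], [], [], [], [], []
    for chain_id, mol in (("A", state.molecule_a), ("B", state.molecule_b)):
        coords.append(mol.positions)
        chain += [chain_id] * mol.n_bp
        res_name += ["DNA"] * mol.n_bp
        atom_name += ["P"] * mol.n_bp
        element += ["P"] * mol.n_bp
        res_id += list(range(1, mol.n_bp + 1))
        hetero += [False] * mol.n_bp
    coords.append(state.ion_positions)
    for k, q in enumerate(state.ion_charges):
        name = _ion_name(q)
        chain.append("I")
        res_name.append(name)
        atom_name.append(name)
        element.append(name)
        res_id.append(k + 1)
        hetero.append(True)
    arr.coord = np.vstack(coords) * NM_TO_ANGSTROM
    arr.chain_id = np.array(chain)
    arr.res_name = np.array(res_name)
    arr.atom_name = np.array(atom_name)
    arr.element = np.array(element)
    arr.res_id = np.array(res_id)
    arr.hetero = np.array(hetero)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def read_pdb_coordinates(path: str | Path) -> dict[str, np.ndarray]:
    """Read a pipeline PDB back; returns per-chain coordinates in nm."""
    arr = pdbio.PDBFile.read(str(path)).get_structure(model=1)
    return {
        str(c): arr.coord[arr.chain_id == c] / NM_TO_ANGSTROM
        for c in np.unique(arr.chain_id)
    }


# ---------------------------------------------------------------------------
# XYZ

def write_xyz(
    frames: list[np.ndarray],
    path: str | Path,
    labels: list[str] | None = None,
    box_edge: float | None = None,
    mode: str = "w",
) -> None:
    """Write a multi-frame XYZ trajectory (coordinates in nm)."""
    with open(path, mode) as fh:
        for frame in frames:
            frame = np.asarray(frame, dtype=float).reshape(-1, 3)
            names = labels if labels is not None else ["X"] * len(frame)
            box_note = f" box_nm={box_edge:.9g}" if box_edge is not None else ""
            fh.write(f"{len(frame)}\n")
            fh.write(f"units=nm{box_note}\n")
            for name, (x, y, z) in zip(names, frame):
                fh.write(f"{name} {x:.9g} {y:.9g} {z:.9g}\n")


def read_xyz(path: str | Path) -> tuple[list[np.ndarray], list[str], float | None]:
    """Read a multi-frame XYZ file; returns (frames, labels, box_edge)."""
    frames: list[np.ndarray] = []
    labels: list[str] = []
    box_edge: float | None = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}: line {i + 1}: expected atom count") from exc
        comment = lines[i + 1]
        for token in comment.split():
            if token.startswith("box_nm="):
                box_edge = float(token.split("=", 1)[1])
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ParseError(f"{path}: line {i + 1}: truncated frame")
        coords = np.empty((n, 3))
        frame_labels = []
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}: line {i + 3 + j}: expected 'name x y z'")
            frame_labels.append(parts[0])
            coords[j] = [float(p) for p in parts[1:4]]
        frames.append(coords)
        labels = frame_labels
        i += 2 + n
    return frames, labels, box_edge


# ---------------------------------------------------------------------------
# window time series

def write_window_series(record: WindowRecord, path: str | Path) -> None:
    """Two-column text: sample index, reaction coordinate (nm)."""
    w = record.window
    with open(path, "w") as fh:
        fh.write(
            f"# center={w.center:.9g} force_k={w.force_k:.9g} "
            f"seed={record.seed} n={len(record.rc_series)}\n"
        )
        for k, r in enumerate(record.rc_series):
            fh.write(f"{k} {r:.9g}\n")


def read_window_series(path: str | Path) -> WindowRecord:
    """Parse a window series file back into a WindowRecord (no frames)."""
    with open(path) as fh:
        lines = fh.readlines()
    if not lines or not lines[0].startswith("#"):
        raise ParseError(f"{path}: line 1: missing '#' metadata header")
    meta: dict[str, str] = {}
    for token in lines[0][1:].split():
        if "=" in token:
            key, val = token.split("=", 1)
            meta[key] = val
    try:
        center = float(meta["center"])
        force_k = float(meta["force_k"])
    except KeyError as exc:
        raise ParseError(
            f"{path}: line 1: header must define center= and force_k="
        ) from exc
    seed = int(meta.get("seed", 0))
    values = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path}: line {ln}: expected 'index value'")
        values.append(float(parts[1]))
    if not values:
        raise ParseError(f"{path}: no samples found")
    return WindowRecord(UmbrellaWindow(center, force_k), np.array(values),
                        seed=seed)


def read_window_series_list(list_path: str | Path) -> list[WindowRecord]:
    """Load windows from a metadata list file.

    Each non-comment line names one series file plus its window
    parameters: ``filename center force_k`` (whitespace-separated,
    filenames relative to the list file).  The listed centre and force
    constant take precedence over any header in the series file, the
    layout used by WHAM command-line tools.
    """
    list_path = Path(list_path)
    records = []
    for ln, line in enumerate(list_path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ParseError(
                f"{list_path}: line {ln}: expected 'filename center force_k'"
            )
        series_path = list_path.parent / parts[0]
        rec = read_window_series(series_path)
        window = UmbrellaWindow(float(parts[1]), float(parts[2]))
        records.append(WindowRecord(window, rec.rc_series, seed=rec.seed))
    if not records:
        raise ParseError(f"{list_path}: no window entries found")
    return records


# ---------------------------------------------------------------------------
# PMF tables

def write_pmf_tsv(profile: PMFProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# reference_r_nm={profile.reference_r:.9g}\n")
        fh.write("r_nm\tv_eff_kJ_mol\tstderr\n")
        stderr = (profile.stderr if profile.stderr is not None
                  else np.full_like(profile.v_eff, np.nan))
        for r, v, s in zip(profile.bin_centers, profile.v_eff, stderr):
            fh.write(f"{r:.9g}\t{v:.9g}\t{s:.9g}\n")


def read_pmf_tsv(path: str | Path) -> PMFProfile:
    with open(path) as fh:
        lines = fh.readlines()
    if not lines or not lines[0].startswith("#"):
        raise ParseError(f"{path}: line 1: missing reference header")
    reference_r = float(lines[0].split("=", 1)[1])
    rows = [line.split("\t") for line in lines[2:] if line.strip()]
    data = np.array([[float(v) for v in row] for row in rows])
    stderr = data[:, 2] if not np.all(np.isnan(data[:, 2])) else None
    return PMFProfile(data[:, 0], data[:, 1], reference_r, stderr=stderr)


# ---------------------------------------------------------------------------
# lossless SystemState round-trip

def _mol_to_dict(mol: MoleculeModel) -> dict:
    return {
        "topology": mol.topology,
        "n_bp": mol.n_bp,
        "positions": mol.positions.tolist(),
        "charges": mol.charges.tolist(),
        "bead_radius": mol.bead_radius,
    }


def _mol_from_dict(d: dict) -> MoleculeModel:
    return MoleculeModel(
        d["topology"], d["n_bp"], np.array(d["positions"]),
        np.array(d["charges"]), d["bead_radius"],
    )


def save_state_json(state: SystemState, path: str | Path) -> None:
    """Serialise a SystemState with full floating-point precision."""
    payload = {
        "molecule_a": _mol_to_dict(state.molecule_a),
        "molecule_b": _mol_to_dict(state.molecule_b),
        "ion_positions": state.ion_positions.tolist(),
        "ion_charges": state.ion_charges.tolist(),
        "box": {"edge": state.box.edge, "periodic": state.box.periodic},
    }
    Path(path).write_text(json.dumps(payload))


def load_state_json(path: str | Path) -> SystemState:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    return SystemState(
        _mol_from_dict(payload["molecule_a"]),
        _mol_from_dict(payload["molecule_b"]),
        np.array(payload["ion_positions"]).reshape(-1, 3),
        np.array(payload["ion_charges"]),
        SimulationBox(payload["box"]["edge"], payload["box"]["periodic"]),
    )
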