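"""Conformational-ensemble containers and I/O.

An ensemble is an immutable topology (ordered atom records) plus an ordered
stack of coordinate frames in Å; frame index is the only time axis.  Ensembles
interchange as multi-model PDB (fixed columns, occupancy/B written 1.00/0.00)
or XYZ trajectories, with force-field-like per-atom parameters supplied by a
TSV table keyed on (residue_name, atom_name).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .constants import default_param_table_path

_PARAM_COLUMNS = ("mass", "charge", "lj_epsilon", "lj_rmin_half", "gb_radius")


@dataclass(frozen=True)
class AtomRecord:
    index: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain: str = "A"
    mass: float | None = None
    charge: float | None = None
    lj_epsilon: float | None = None
    lj_rmin_half: float | None = None
    gb_radius: float | None = None


@dataclass(frozen=True)
class ConformerEnsemble:
    """Topology plus an (n_frames, n_atoms, 3) coordinate array in Å."""

    atoms: tuple[AtomRecord, ...]
    frames: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if frames.shape[0] < 1:
            raise ValueError("an ensemble needs at least one frame")
        if frames.shape[1] != len(self.atoms):
            raise ValueError(
                f"{frames.shape[1]} coordinates per frame but {len(self.atoms)} atoms"
            )
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def _param_array(self, name: str) -> np.ndarray:
        vals = [getattr(a, name) for a in self.atoms]
        for a, v in zip(self.atoms, vals):
            if v is None:
                raise ValueError(
                    f"atom {a.residue_name}{a.residue_id}:{a.name} has no {name}; "
                    "merge a parameter table first"
                )
        return np.asarray(vals, dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return self._param_array("mass")

    @property
    def charges(self) -> np.ndarray:
        return self._param_array("charge")

    @property
    def lj_epsilon(self) -> np.ndarray:
        return self._param_array("lj_epsilon")

    @property
    def lj_rmin_half(self) -> np.ndarray:
        return self._param_array("lj_rmin_half")

    @property
    def gb_radius(self) -> np.ndarray:
        return self._param_array("gb_radius")

    @property
    def residue_ids(self) -> np.ndarray:
        return np.asarray([a.residue_id for a in self.atoms], dtype=int)

    def subsample(self, n_frames: int) -> "ConformerEnsemble":
        """Evenly spaced frame extraction (at most ``n_frames`` frames)."""
        if n_frames >= self.n_frames:
            return self
        idx = np.linspace(0, self.n_frames - 1, n_frames).round().astype(int)
        return replace(self, frames=self.frames[idx])


@dataclass(frozen=True)
class Selection:
    """Atom predicate over residue ids/names, atom names, and chain.

    ``residue_range`` is a 1-based inclusive (start, end) pair; any criterion
    left as None is not applied.  Resolves to a stable, ordered index subset.
    """

    residue_range: tuple[int, int] | None = None
    residue_ids: frozenset[int] | None = None
    residue_names: frozenset[str] | None = None
    atom_names: frozenset[str] | None = None
    chains: frozenset[str] | None = None
    heavy_only: bool = False

    def mask(self, atoms) -> np.ndarray:
        keep = np.ones(len(atoms), dtype=bool)
        for i, a in enumerate(atoms):
            ok = True
            if self.residue_range is not None:
                ok &= self.residue_range[0] <= a.residue_id <= self.residue_range[1]
            if self.residue_ids is not None:
                ok &= a.residue_id in self.residue_ids
            if self.residue_names is not None:
                ok &= a.residue_name in self.residue_names
            if self.atom_names is not None:
                ok &= a.name in self.atom_names
            if self.chains is not None:
                ok &= a.chain in self.chains
            if self.heavy_only:
                ok &= a.element.upper() != "H"
            keep[i] = ok
        return keep


def select(ens: ConformerEnsemble, sel: Selection) -> ConformerEnsemble:
    """Restrict an ensemble to the atoms matching ``sel`` (order preserved)."""
    mask = sel.mask(ens.atoms)
    if not mask.any():
        raise ValueError("selection matches no atoms")
    atoms = tuple(a for a, m in zip(ens.atoms, mask) if m)
    return ConformerEnsemble(atoms, ens.frames[:, mask, :], ens.provenance)


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def _validate_pdb_models(lines) -> None:
    """Pre-scan MODEL blocks so errors name the offending model/line."""
    counts, current, model_no, in_model = [], 0, 0, False
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model, model_no, current = True, model_no + 1, 0
        elif rec == "ENDMDL":
            counts.append((model_no, current))
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current += 1
            try:
                [float(line[i:i + 8]) for i in (30, 38, 46)]
            except ValueError:
                raise ValueError(f"unparseable coordinates at line {lineno}") from None
    if in_model:
        counts.append((model_no, current))
    if not counts and current:
        counts.append((1, current))
    if len({c for _, c in counts}) > 1:
        bad = next((m, c) for m, c in counts if c != counts[0][1])
        raise ValueError(
            f"inconsistent atom count in model {bad[0]}: {bad[1]} atoms "
            f"(model 1 has {counts[0][1]})"
        )


def read_multimodel_pdb(path) -> ConformerEnsemble:
    """Read a multi-model PDB into an ensemble (one frame per MODEL).

    Elements come from columns 77-78 with an atom-name fallback; parameter
    fields stay unset until a table is merged with :func:`merge_parameters`.
    """
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    _validate_pdb_models(lines)
    pdb = PDBFile.read(io.StringIO("".join(lines)))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    atoms = []
    for i in range(stack.array_length()):
        element = str(stack.element[i]).strip()
        name = str(stack.atom_name[i])
        atoms.append(
            AtomRecord(
                index=i,
                name=name,
                element=element if element else _infer_element(name),
                residue_id=int(stack.res_id[i]),
                residue_name=str(stack.res_name[i]),
                chain=str(stack.chain_id[i]) or "A",
            )
        )
    return ConformerEnsemble(tuple(atoms), stack.coord.astype(float), provenance=str(path))


def write_multimodel_pdb(ens: ConformerEnsemble, path) -> None:
    """Write an ensemble as a multi-model PDB (occupancy 1.00, B 0.00)."""
    n = ens.n_atoms
    stack = struc.AtomArrayStack(ens.n_frames, n)
    stack.coord = ens.frames.astype(np.float32)
    stack.chain_id = np.array([a.chain for a in ens.atoms])
    stack.res_id = ens.residue_ids
    stack.res_name = np.array([a.residue_name for a in ens.atoms])
    stack.atom_name = np.array([a.name for a in ens.atoms])
    stack.element = np.array([a.element for a in ens.atoms])
    stack.hetero = np.zeros(n, dtype=bool)
    stack.set_annotation("occupancy", np.ones(n))
    stack.set_annotation("b_factor", np.zeros(n))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_xyz_traj(path, template: ConformerEnsemble) -> ConformerEnsemble:
    """Read an XYZ trajectory onto an existing topology (frames appended in order)."""
    frames = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    i, frame_no = 0, 0
    while i < len(lines):
        try:
            count = int(lines[i])
        except ValueError:
            raise ValueError(f"expected atom count at frame {frame_no}") from None
        frame_no += 1
        if count != template.n_atoms:
            raise ValueError(
                f"frame {frame_no} has {count} atoms, template has {template.n_atoms}"
            )
        block = lines[i + 2:i + 2 + count]
        if len(block) < count:
            raise ValueError(f"truncated frame {frame_no}")
        coords = np.array([[float(x) for x in ln.split()[1:4]] for ln in block])
        frames.append(coords)
        i += 2 + count
    if not frames:
        raise ValueError(f"no frames in {path}")
    return replace(template, frames=np.asarray(frames), provenance=str(path))


def write_xyz_traj(ens: ConformerEnsemble, path) -> None:
    with open(path, "w") as fh:
        for f in range(ens.n_frames):
            fh.write(f"{ens.n_atoms}\nframe {f}\n")
            for a, (x, y, z) in zip(ens.atoms, ens.frames[f]):
                fh.write(f"{a.element:<2s} {x:12.5f} {y:12.5f} {z:12.5f}\n")


class ParamTable:
    """Per-atom parameter lookup keyed by (residue_name, atom_name)."""

    def __init__(self, rows: dict[tuple[str, str], dict[str, float]]):
        self._rows = rows

    def __contains__(self, key) -> bool:
        return tuple(key) in self._rows

    def lookup(self, residue_name: str, atom_name: str) -> dict[str, float]:
        key = (residue_name, atom_name)
        if key not in self._rows:
            raise KeyError(f"no parameters for atom {atom_name!r} of residue {residue_name!r}")
        return self._rows[key]

    def __len__(self) -> int:
        return len(self._rows)


def read_param_table(path=None) -> ParamTable:
    """Read a parameter TSV; default is the shipped bead table."""
    if path is None:
        path = default_param_table_path()
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = {"residue_name", "atom_name", *_PARAM_COLUMNS} - set(table.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    rows: dict[tuple[str, str], dict[str, float]] = {}
    for _, row in table.iterrows():
        key = (str(row["residue_name"]), str(row["atom_name"]))
        if key in rows:
            raise ValueError(f"duplicate parameter key {key}")
        rows[key] = {c: float(row[c]) for c in _PARAM_COLUMNS}
    return ParamTable(rows)


def merge_parameters(ens: ConformerEnsemble, table: ParamTable) -> ConformerEnsemble:
    """Return an ensemble whose atoms carry the table's parameters."""
    atoms = []
    for a in ens.atoms:
        try:
            params = table.lookup(a.residue_name, a.name)
        except KeyError:
            raise KeyError(
                f"parameter table lacks atom {a.name!r} of residue "
                f"{a.residue_name!r} (residue id {a.residue_id})"
            ) from None
        atoms.append(replace(a, **params))
    return replace(ens, atoms=tuple(atoms))
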