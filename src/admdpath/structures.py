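"""Structural data model: conformations, topology, paths, PDB/XYZ I/O, Rg.

A :class:`Topology` holds everything static about a chain (sequence, atom
metadata, masses, backbone bookkeeping); a :class:`Conformation` is one set of
coordinates referencing a topology; a :class:`Path` is an ordered stack of
frames with fixed endpoints and a time increment, the central object of the
least-action machinery.

Coordinates are Å throughout.  Residue numbering is 1-based; terminal caps
(acetyl / amide) occupy residue indices 0 and ``n_residues + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path as FilePath

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

__all__ = [
    "Topology",
    "Conformation",
    "Path",
    "read_pdb",
    "write_pdb",
    "read_xyz",
    "write_xyz",
    "radius_of_gyration",
    "local_minimize",
    "MinimizationResult",
]

# Standard atomic weights (amu), sufficient for peptides.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "ZN": 65.38,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "DPR": "p",  # D-proline, lower-case = D-amino acid
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_BACKBONE_NAMES = ("N", "H", "CA", "C", "O")


class TopologyError(ValueError):
    """Inconsistent or unresolvable chain bookkeeping."""


@dataclass
class Topology:
    """Static description of a chain: sequence, atoms, masses, backbone maps.

    ``sequence`` uses 1-letter codes, lower-case meaning a D-amino acid.
    ``residue_index`` is per-atom and 1-based; cap atoms carry 0 (N-terminal
    acetyl) or ``n_residues + 1`` (C-terminal amide).
    """

    sequence: str
    atom_names: np.ndarray          # (N,) str
    elements: np.ndarray            # (N,) str
    residue_index: np.ndarray       # (N,) int, per atom
    residue_names: np.ndarray       # (N,) str, 3-letter per atom
    masses: np.ndarray = None       # (N,) float, amu (reduced units: 1.0)
    caps: tuple[bool, bool] = (False, False)

    def __post_init__(self):
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype="U3")
        if self.masses is None:
            self.masses = np.array(
                [ATOMIC_MASSES.get(e.upper(), 12.011) for e in self.elements]
            )
        self.masses = np.asarray(self.masses, float)
        if np.any(self.masses <= 0):
            raise TopologyError("masses must be strictly positive")
        if np.any(np.diff(self.residue_index) < 0):
            raise TopologyError("residue_index must be non-decreasing")
        if len(self.sequence) != self.n_residues:
            raise TopologyError(
                f"sequence length {len(self.sequence)} != residue count "
                f"{self.n_residues}"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        """Number of amino-acid residues (caps excluded)."""
        mask = (self.residue_index >= 1) & (self.residue_index <= self._max_res)
        return len(np.unique(self.residue_index[mask]))

    @property
    def _max_res(self) -> int:
        idx = self.residue_index
        if self.caps[1]:
            return int(idx.max()) - 1
        return int(idx.max())

    @property
    def calpha_indices(self) -> np.ndarray:
        """Atom index of the Cα of each residue, in residue order."""
        out = []
        for r in range(1, self._max_res + 1):
            hits = np.flatnonzero(
                (self.residue_index == r) & (self.atom_names == "CA")
            )
            if len(hits) != 1:
                raise TopologyError(f"residue {r}: expected one CA, got {len(hits)}")
            out.append(hits[0])
        return np.array(out, dtype=int)

    @property
    def chirality_flags(self) -> list[str]:
        return ["D" if c.islower() else "L" for c in self.sequence]

    def backbone_sets(self) -> list[dict[str, int | None]]:
        """Per-residue indices of backbone N, H, CA, C, O (``None`` if absent)."""
        out = []
        for r in range(1, self._max_res + 1):
            in_res = self.residue_index == r
            entry: dict[str, int | None] = {}
            for name in _BACKBONE_NAMES:
                hits = np.flatnonzero(in_res & (self.atom_names == name))
                entry[name] = int(hits[0]) if len(hits) else None
            for key in ("N", "CA", "C"):
                if entry[key] is None and not self.is_bead_model:
                    raise TopologyError(f"residue {r}: backbone atom {key} missing")
            out.append(entry)
        return out

    @property
    def is_bead_model(self) -> bool:
        """True for Cα-only (one bead per residue) chains."""
        return bool(np.all(self.atom_names == "CA"))


@dataclass
class Conformation:
    """One structural frame: per-atom positions plus a shared topology."""

    positions: np.ndarray           # (N, 3) Å
    topology: Topology

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if self.positions.shape[0] != self.topology.n_atoms:
            raise ValueError(
                f"{self.positions.shape[0]} positions for "
                f"{self.topology.n_atoms}-atom topology"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    # Metadata delegated to the topology, so a Conformation is self-describing.
    @property
    def atom_names(self) -> np.ndarray:
        return self.topology.atom_names

    @property
    def elements(self) -> np.ndarray:
        return self.topology.elements

    @property
    def residue_index(self) -> np.ndarray:
        return self.topology.residue_index

    @property
    def residue_names(self) -> np.ndarray:
        return self.topology.residue_names

    @property
    def chirality_flags(self) -> list[str]:
        return self.topology.chirality_flags

    def copy(self) -> "Conformation":
        return Conformation(self.positions.copy(), self.topology)

    def calpha_positions(self) -> np.ndarray:
        return self.positions[self.topology.calpha_indices]


@dataclass
class Path:
    """Ordered frames q_0 .. q_P with fixed endpoints and time increment Δ.

    ``coords`` has shape (P+1, N, 3); frames 0 and P are the boundary states
    and are never altered by optimization.
    """

    coords: np.ndarray
    topology: Topology
    delta_t: float = 1.0
    fixed_endpoints: bool = True

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 3:
            raise ValueError("a path needs >= 3 frames (2 endpoints + interior)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("frame size does not match topology")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_segments(self) -> int:
        """P: number of time slices."""
        return self.n_frames - 1

    @property
    def tau(self) -> float:
        """Total path duration τ = PΔ."""
        return self.n_segments * self.delta_t

    def times(self) -> np.ndarray:
        """t_j = jΔ for j = 0..P."""
        return np.arange(self.n_frames) * self.delta_t

    def frame(self, j: int) -> Conformation:
        return Conformation(self.coords[j].copy(), self.topology)

    @property
    def frames(self) -> list[Conformation]:
        return [self.frame(j) for j in range(self.n_frames)]

    @classmethod
    def from_frames(cls, frames: list[Conformation], delta_t: float = 1.0) -> "Path":
        top = frames[0].topology
        for f in frames[1:]:
            if f.topology.n_atoms != top.n_atoms:
                raise ValueError("all frames must share one topology")
        return cls(np.stack([f.positions for f in frames]), top, delta_t)


# ---------------------------------------------------------------------------
# PDB / XYZ I/O (biotite does the record-level work)
# ---------------------------------------------------------------------------

def _topology_from_atom_array(arr: struc.AtomArray) -> Topology:
    res_ids = arr.res_id
    res_names = arr.res_name
    caps_n = bool(np.any(res_names == "ACE"))
    caps_c = bool(np.any(res_names == "NH2"))
    # Renumber so amino acids run 1..n with caps at 0 and n+1.
    uniq = []
    for rid, rname in zip(res_ids, res_names):
        if not uniq or uniq[-1][0] != rid:
            uniq.append((rid, rname))
    aa = [(rid, rn) for rid, rn in uniq if rn not in ("ACE", "NH2")]
    mapping = {}
    for newidx, (rid, _) in enumerate(aa, start=1):
        mapping[rid] = newidx
    for rid, rn in uniq:
        if rn == "ACE":
            mapping[rid] = 0
        elif rn == "NH2":
            mapping[rid] = len(aa) + 1
    sequence = "".join(THREE_TO_ONE.get(rn, "X") for _, rn in aa)
    new_index = np.array([mapping[r] for r in res_ids], dtype=int)
    elements = np.array([e if e else "C" for e in arr.element], dtype="U2")
    return Topology(
        sequence=sequence,
        atom_names=arr.atom_name,
        elements=elements,
        residue_index=new_index,
        residue_names=res_names,
        caps=(caps_n, caps_c),
    )


def read_pdb(path_to_file, model_index: int | None = None):
    """Read one model of a PDB file.

    Parameters
    ----------
    path_to_file:
        PDB file name.
    model_index:
        1-based model number for multi-model files; ``None`` selects the
        first model.

    Returns
    -------
    (Conformation, Topology)
    """
    fp = FilePath(path_to_file)
    if not fp.exists():
        raise FileNotFoundError(f"no such PDB file: {fp}")
    pdb_file = pdbio.PDBFile.read(str(fp))
    n_models = pdb_file.get_model_count()
    model = 1 if model_index is None else int(model_index)
    if not 1 <= model <= n_models:
        raise IndexError(f"model_index {model} out of range (1..{n_models})")
    arr = pdb_file.get_structure(model=model)
    if arr.array_length() == 0:
        raise ValueError(f"no ATOM records in {fp}")
    top = _topology_from_atom_array(arr)
    conf = Conformation(arr.coord, top)
    return conf, top


def read_pdb_path(path_to_file, delta_t: float = 1.0) -> Path:
    """Read a multi-model PDB as a Path (frames in model order)."""
    pdb_file = pdbio.PDBFile.read(str(path_to_file))
    stack = pdb_file.get_structure()
    if stack.stack_depth() < 3:
        # Fall back onto replicating frames is not meaningful; caller error.
        raise ValueError("trajectory PDB needs >= 3 models")
    top = _topology_from_atom_array(stack[0])
    return Path(stack.coord, top, delta_t=delta_t)


def _atom_array_from(conf_or_top, positions) -> struc.AtomArray:
    top = conf_or_top
    n = top.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(positions, float)
    arr.atom_name = top.atom_names
    arr.element = np.char.upper(top.elements)
    arr.res_name = top.residue_names
    # Re-map internal numbering (caps at 0/n+1) onto sequential PDB res_ids.
    arr.res_id = top.residue_index + (1 if top.caps[0] else 0)
    arr.chain_id = np.full(n, "A", dtype="U1")
    arr.hetero = np.isin(top.residue_names, ("ACE", "NH2"))
    arr.set_annotation("occupancy", np.full(n, 1.0))
    arr.set_annotation("b_factor", np.full(n, 0.0))
    return arr


def write_pdb(conformations, path_to_file) -> None:
    """Write one Conformation (single model) or a Path/list (multi-model).

    Coordinates are printed as fixed-point %8.3f, occupancy 1.00 and
    B-factor 0.00, the plain single-chain convention.
    """
    if isinstance(conformations, Conformation):
        top = conformations.topology
        obj = _atom_array_from(top, conformations.positions)
    else:
        if isinstance(conformations, Path):
            top = conformations.topology
            coords = conformations.coords
        else:
            frames = list(conformations)
            top = frames[0].topology
            coords = np.stack([f.positions for f in frames])
        arrays = [_atom_array_from(top, c) for c in coords]
        obj = struc.stack(arrays)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(obj)
    pdb_file.write(str(path_to_file))


def write_xyz(conformations, path_to_file) -> None:
    """Write XYZ (element x y z); multi-frame files are concatenated blocks."""
    if isinstance(conformations, Conformation):
        coords = conformations.positions[None]
        top = conformations.topology
    elif isinstance(conformations, Path):
        coords, top = conformations.coords, conformations.topology
    else:
        frames = list(conformations)
        coords = np.stack([f.positions for f in frames])
        top = frames[0].topology
    with open(path_to_file, "w") as fh:
        for j, frame in enumerate(coords):
            fh.write(f"{top.n_atoms}\n")
            fh.write(f"frame {j}\n")
            for el, (x, y, z) in zip(top.elements, frame):
                fh.write(f"{el:<2s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


def read_xyz(path_to_file, topology: Topology | None = None):
    """Read an XYZ file; returns a list of Conformations.

    If ``topology`` is None a minimal one is synthesized (one residue,
    elements as read, unit masses for unknown elements).
    """
    frames = []
    with open(path_to_file) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].split()[0])
        block = lines[i + 2: i + 2 + n]
        elements, coords = [], []
        for line in block:
            parts = line.split()
            elements.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        if topology is None:
            topology = Topology(
                sequence="X",
                atom_names=np.array([f"X{k+1}" for k in range(n)]),
                elements=np.array(elements),
                residue_index=np.ones(n, dtype=int),
                residue_names=np.full(n, "UNK"),
            )
        frames.append(Conformation(np.array(coords), topology))
        i += 2 + n
    return frames


# ---------------------------------------------------------------------------
# Elementary metrics & minimization
# ---------------------------------------------------------------------------

def radius_of_gyration(conf, topology: Topology | None = None,
                       weighting: str = "mass") -> float:
    """Radius of gyration in Å.

    ``weighting`` is ``"mass"`` (default, Σ m_I |r_I − r_com|² / Σ m_I under
    the square root), ``"uniform"``, or ``"calpha"`` (uniform over Cα only).
    """
    top = topology if topology is not None else conf.topology
    pos = conf.positions if isinstance(conf, Conformation) else np.asarray(conf, float)
    if weighting == "mass":
        w = top.masses
    elif weighting == "uniform":
        w = np.ones(pos.shape[0])
    elif weighting == "calpha":
        idx = top.calpha_indices
        pos = pos[idx]
        w = np.ones(len(idx))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    com = (pos * w[:, None]).sum(0) / w.sum()
    return float(np.sqrt((w * ((pos - com) ** 2).sum(1)).sum() / w.sum()))


@dataclass
class MinimizationResult:
    conformation: "Conformation"
    energy: float
    grad_norm: float
    n_iterations: int
    converged: bool
    message: str = ""


def local_minimize(conf: Conformation, potential, tolerance: float = 1e-4,
                   max_iterations: int = 100_000) -> MinimizationResult:
    """Local energy minimization (L-BFGS) under an arbitrary potential.

    Stops when the max-norm of the gradient falls below ``tolerance``
    (energy units / Å).  The returned energy never exceeds the input energy.
    Non-convergence within ``max_iterations`` is reported via
    ``MinimizationResult.converged``, not raised.
    """
    from scipy.optimize import minimize as _sp_minimize

    x0 = conf.positions.ravel().copy()
    shape = conf.positions.shape

    def fun(x):
        p = x.reshape(shape)
        return potential.energy(p), potential.gradient(p).ravel()

    res = _sp_minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iterations, "gtol": tolerance,
                 "ftol": 1e-14, "maxfun": 10 * max_iterations + 100},
    )
    x_best = res.x
    gnorm = float(np.max(np.abs(potential.gradient(x_best.reshape(shape)))))
    if gnorm > tolerance and x_best.size <= 300:
        # quasi-Newton stalls on flat quadratic basins; finish with a Newton
        # root solve on the gradient (small systems only)
        from scipy.optimize import root as _sp_root

        sol = _sp_root(lambda x: potential.gradient(x.reshape(shape)).ravel(),
                       x_best, method="hybr")
        e_new = potential.energy(sol.x.reshape(shape))
        g_new = float(np.max(np.abs(potential.gradient(sol.x.reshape(shape)))))
        if g_new < gnorm and e_new <= res.fun + 1e-9 * max(1.0, abs(res.fun)):
            x_best = sol.x
            gnorm = g_new
            res.fun = e_new
    out = Conformation(x_best.reshape(shape), conf.topology)
    e_in = potential.energy(conf.positions)
    if res.fun > e_in:
        out = conf.copy()  # never accept an uphill "minimization"
        return MinimizationResult(out, e_in,
                                  float(np.max(np.abs(potential.gradient(conf.positions)))),
                                  int(res.nit), False, "no downhill step found")
    return MinimizationResult(out, float(res.fun), gnorm, int(res.nit),
                              bool(gnorm <= tolerance or res.success),
                              str(res.message))
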