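"""Synthetic systems and crafted fixtures for every pipeline stage.

The centerpiece is a 23-residue Cα-bead mimic of the ββα mini-protein
BBA5: an N-terminal β-hairpin contact set over residues 1-10, a C-terminal
α-helix (i, i+3)/(i, i+4) ladder over residues 11-23, and the
hairpin-helix hydrophobic-core contacts, realized as actual bead geometry
and wrapped in a funneled Gō potential.  The mimic shares only the contact
topology of the real protein, not its NMR geometry; it exists so folding
pathways between an extended rod and a compact ββα-like state are
meaningful at desk scale.

Also here: crafted all-atom backbone scenes with an exact number of
hydrogen bonds (constructive oracles for the H-bond detector), single
particle states on the analytic toy landscapes, and seeded random trial
paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .action import ActionParams, init_trial_path
from .analysis import ContactCriteria, contact_pairs_of
from .potentials import GoModelSpec, GoPotential, PotentialModel
from .structures import Conformation, Topology, Path, local_minimize

__all__ = [
    "BBA5_SEQUENCE", "MimicSpec", "MimicSystem", "make_bba5_mimic",
    "make_hbond_fixture", "make_random_path", "particle2d",
    "helix_contact_pairs", "discrete_rod_rg",
]

# 23-residue sequence, lower-case p = D-proline at position 4.
BBA5_SEQUENCE = "YRVpSYDFSRSDELAKLLRQHAG"


def helix_contact_pairs(first: int = 11, last: int = 23) -> list:
    """(i, i+3) and (i, i+4) pairs within a helix residue range."""
    pairs = [(i, i + 3) for i in range(first, last - 2)]
    pairs += [(i, i + 4) for i in range(first, last - 3)]
    return sorted(pairs)


@dataclass
class MimicSpec:
    """Contact topology and parameters of the 23-bead ββα mimic."""

    n_residues: int = 23
    hairpin_contacts: tuple = ((1, 7), (1, 8), (1, 9), (2, 7), (3, 6))
    helix_range: tuple = (11, 23)
    core_contacts: tuple = ((8, 14), (14, 17), (14, 18))
    seed: int = 0
    bond_length: float = 3.8
    contact_epsilon: float = 1.0
    bond_k: float = 100.0
    repulsion_sigma: float = 4.0

    @property
    def helix_contacts(self) -> list:
        return helix_contact_pairs(*self.helix_range)

    @property
    def hbond_proxy_pairs(self) -> list:
        """Bead-model stand-in for the backbone hydrogen-bond registry.

        An α-helix hydrogen bond links residue i's carbonyl to residue
        (i+4)'s amide, and a β-hairpin's bonds link the cross-strand rung
        pairs; on a Cα chain those registries are proxied by the (i, i+4)
        helix contacts plus the hairpin rung contacts.
        """
        first, last = self.helix_range
        pairs = [(i, i + 4) for i in range(first, last - 3)]
        pairs += [p for p in ((1, 8), (2, 7), (3, 6))
                  if p in set(map(tuple, self.hairpin_contacts))]
        return sorted(pairs)

    def required_pairs(self) -> list:
        pairs = set(map(tuple, self.hairpin_contacts))
        pairs |= set(map(tuple, self.core_contacts))
        pairs |= set(self.helix_contacts)
        for i, j in pairs:
            if not (1 <= i < j <= self.n_residues):
                raise ValueError(f"pair ({i},{j}) outside residues 1..{self.n_residues}")
            if j - i < 3:
                raise ValueError(f"pair ({i},{j}): sequence separation < 3")
        return sorted(pairs)


@dataclass
class MimicSystem:
    native: Conformation
    extended: Conformation
    go_spec: GoModelSpec
    potential: GoPotential
    spec: MimicSpec


class UnrealizableContactsError(ValueError):
    def __init__(self, pairs):
        self.pairs = pairs
        super().__init__(f"contact set not realizable; violating pairs: {pairs}")


def bead_topology(sequence: str) -> Topology:
    """Cα-only topology with unit bead masses (reduced units)."""
    n = len(sequence)
    return Topology(
        sequence=sequence,
        atom_names=np.full(n, "CA"),
        elements=np.full(n, "C"),
        residue_index=np.arange(1, n + 1),
        residue_names=np.full(n, "GLY"),
        masses=np.ones(n),
    )


class _RestraintEmbedding(PotentialModel):
    """Distance-restraint objective used to embed a contact set as geometry."""

    name = "restraint-embedding"

    def __init__(self, n: int, bond_length: float, targets: dict,
                 repulsion_sigma: float):
        self.b_i = np.arange(n - 1)
        self.b_j = np.arange(1, n)
        self.b0 = bond_length
        items = sorted(targets.items())
        self.t_i = np.array([p[0] - 1 for p, _ in items], int)
        self.t_j = np.array([p[1] - 1 for p, _ in items], int)
        self.t0 = np.array([d for _, d in items])
        iu, ju = np.triu_indices(n, k=2)
        skip = {(i, j) for i, j in zip(self.t_i, self.t_j)}
        keep = np.array([(i, j) not in skip for i, j in zip(iu, ju)])
        self.r_i, self.r_j = iu[keep], ju[keep]
        self.sigma = repulsion_sigma

    def energy(self, positions):
        e, _ = self._eval(np.asarray(positions, float))
        return e

    def gradient(self, positions):
        _, g = self._eval(np.asarray(positions, float))
        return g

    def _eval(self, p):
        grad = np.zeros_like(p)
        energy = 0.0
        for ii, jj, r0, k in ((self.b_i, self.b_j, self.b0, 50.0),
                              (self.t_i, self.t_j, self.t0, 10.0)):
            rvec = p[jj] - p[ii]
            r = np.linalg.norm(rvec, axis=1)
            dr = r - r0
            energy += float(k * np.sum(dr ** 2))
            coef = (2 * k * dr / r)[:, None] * rvec
            np.add.at(grad, jj, coef)
            np.add.at(grad, ii, -coef)
        rvec = p[self.r_j] - p[self.r_i]
        r = np.linalg.norm(rvec, axis=1)
        inside = r < self.sigma
        if np.any(inside):
            dr = self.sigma - r[inside]
            energy += float(20.0 * np.sum(dr ** 2))
            coef = (-2 * 20.0 * dr / r[inside])[:, None] * rvec[inside]
            np.add.at(grad, self.r_j[inside], coef)
            np.add.at(grad, self.r_i[inside], -coef)
        return energy, grad


def _initial_mimic_layout(spec: MimicSpec, rng: np.random.Generator) -> np.ndarray:
    """Crude ββα layout: planar hairpin + ideal helix, jittered."""
    n = spec.n_residues
    pos = np.zeros((n, 3))
    # Hairpin strands: residues 1-4 down at x=0, turn 5, strand 6-10 up at x=4.8.
    for k in range(4):                      # residues 1..4
        pos[k] = (0.0, 11.4 - 3.8 * k, 0.0)
    pos[4] = (2.4, -1.4, 2.0)               # turn residue 5
    for k in range(5, 10):                  # residues 6..10
        pos[k] = (4.8, 3.8 * (k - 5), 0.0)
    # Helix: residues 11..23 on an ideal Cα spiral, axis along −y, packed
    # against strand B so the core contact (8, 14) can close.
    cx, cz, y11 = 9.0, 0.0, 15.9
    for k in range(13):                     # residues 11..23
        theta = np.radians(100.0 * k + 180.0)
        pos[10 + k] = (cx + 2.3 * np.cos(theta),
                       y11 - 1.5 * k,
                       cz + 2.3 * np.sin(theta))
    pos += rng.normal(0.0, 0.25, size=pos.shape)
    return pos


def make_bba5_mimic(spec: MimicSpec | None = None) -> MimicSystem:
    """Generate the 23-bead ββα mimic: native + extended endpoints + Gō model.

    The native geometry is produced by embedding the requested contact set
    (distance restraints at helix/hairpin-typical values) from a crude ββα
    layout, then polished under its own Gō potential; the final contact map
    is re-detected from the polished geometry, so the Gō model's native
    state satisfies exactly its own contact list.  The extended endpoint is
    a straight rod at the bond length (uniform 3.8 Å rise).

    Raises :class:`UnrealizableContactsError` when a requested pair cannot
    be realized below the contact cutoff.
    """
    spec = spec or MimicSpec()
    rng = np.random.default_rng(spec.seed)
    top = bead_topology(BBA5_SEQUENCE[: spec.n_residues].ljust(spec.n_residues, "A"))
    required = spec.required_pairs()

    # Stage 1: embed the contact set as geometry.
    helix = set(spec.helix_contacts)
    targets = {}
    for (i, j) in required:
        if (i, j) in helix:
            targets[(i, j)] = 5.15 if j - i == 3 else 6.15
        else:
            targets[(i, j)] = 5.5
    embed = _RestraintEmbedding(spec.n_residues, spec.bond_length, targets,
                                spec.repulsion_sigma)
    x0 = _initial_mimic_layout(spec, rng)
    res = local_minimize(Conformation(x0, top), embed,
                         tolerance=1e-6, max_iterations=20_000)
    native0 = res.conformation

    # Stage 2: wrap in a Gō potential and polish; iterate until the detected
    # contact map is self-consistent with the polished geometry.
    criteria = ContactCriteria()
    native = native0
    contact_map = None
    for _ in range(4):
        detected = set(contact_pairs_of(native, criteria)) | set(required)
        go_spec = GoModelSpec(
            native_conformation=native,
            contact_map=frozenset(detected),
            bond_k=spec.bond_k,
            contact_epsilon=spec.contact_epsilon,
            repulsion_sigma=spec.repulsion_sigma,
            bond_length=spec.bond_length,
        )
        potential = GoPotential(go_spec)
        native = local_minimize(native, potential,
                                tolerance=1e-6, max_iterations=20_000).conformation
        newmap = set(contact_pairs_of(native, criteria)) | set(required)
        if newmap == detected:
            contact_map = detected
            break
        contact_map = newmap
    go_spec = GoModelSpec(
        native_conformation=native,
        contact_map=frozenset(contact_map),
        bond_k=spec.bond_k,
        contact_epsilon=spec.contact_epsilon,
        repulsion_sigma=spec.repulsion_sigma,
        bond_length=spec.bond_length,
    )
    potential = GoPotential(go_spec)

    bad = [p for p in required if p not in set(contact_pairs_of(native, criteria))]
    if bad:
        raise UnrealizableContactsError(bad)

    # Extended endpoint: straight rod, uniform bond-length rise, centered.
    n = spec.n_residues
    x = (np.arange(n) - (n - 1) / 2.0) * spec.bond_length
    extended = Conformation(np.column_stack([x, np.zeros(n), np.zeros(n)]), top)

    return MimicSystem(native=native, extended=extended, go_spec=go_spec,
                       potential=potential, spec=spec)


def discrete_rod_rg(n: int, spacing: float) -> float:
    """Closed-form Rg of n equal-mass beads on a line at uniform spacing."""
    return spacing * np.sqrt((n * n - 1) / 12.0)


# ---------------------------------------------------------------------------
# Hydrogen-bond fixtures
# ---------------------------------------------------------------------------

def make_hbond_fixture(n_bonds: int, seed: int | None = None):
    """All-atom backbone scene with exactly ``n_bonds`` hydrogen bonds.

    Each bond is an isolated two-residue cluster: an acceptor carbonyl and a
    donor amide arranged collinearly (O···H-N, O-N 2.2 Å, angle 180°);
    clusters sit 30 Å apart so no unintended pair satisfies the criteria.
    With a ``seed``, every cluster is randomly rigidly rotated and
    translated — the internal geometry (and therefore the count) is
    invariant.

    Returns (Conformation, Topology).
    """
    if n_bonds < 0:
        raise ValueError("n_bonds must be >= 0")
    rng = np.random.default_rng(seed) if seed is not None else None
    n_clusters = max(1, n_bonds)
    atom_names, elements, res_index, coords = [], [], [], []
    for b in range(n_clusters):
        base = np.array([30.0 * b, 0.0, 0.0])
        bonded = b < n_bonds
        # acceptor residue: backbone with the carbonyl at the cluster origin
        acc = {
            "N": (-2.10, 0.90, 0.0), "H": (-2.80, 1.60, 0.0),
            "CA": (-1.50, 0.20, 0.0),
            "C": (0.0, 0.0, 0.0), "O": (1.23, 0.0, 0.0),
        }
        # donor residue: amide aimed at the acceptor O (or rotated away)
        if bonded:
            don = {
                "N": (3.43, 0.0, 0.0), "H": (2.42, 0.0, 0.0),
                "CA": (4.30, 1.10, 0.0), "C": (5.80, 1.10, 0.0),
                "O": (6.40, 2.20, 0.0),
            }
        else:
            don = {
                "N": (8.00, 0.0, 0.0), "H": (7.00, 0.0, 0.0),
                "CA": (8.90, 1.10, 0.0), "C": (10.40, 1.10, 0.0),
                "O": (11.00, 2.20, 0.0),
            }
        cluster = []
        for names in (acc, don):
            for nm in ("N", "H", "CA", "C", "O"):
                cluster.append(np.asarray(names[nm], float))
        cluster = np.array(cluster)
        if rng is not None:
            from scipy.spatial.transform import Rotation
            R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
            cluster = cluster @ R.T + rng.uniform(-3, 3, size=3)
        cluster = cluster + base
        for rr in range(2):
            for k, nm in enumerate(("N", "H", "CA", "C", "O")):
                atom_names.append(nm)
                elements.append(nm[0])
                res_index.append(2 * b + rr + 1)
                coords.append(cluster[5 * rr + k])
    n_res = 2 * n_clusters
    top = Topology(
        sequence="G" * n_res,
        atom_names=np.array(atom_names),
        elements=np.array(elements),
        residue_index=np.array(res_index),
        residue_names=np.full(len(atom_names), "GLY"),
    )
    return Conformation(np.array(coords), top), top


# ---------------------------------------------------------------------------
# Toy states & random paths
# ---------------------------------------------------------------------------

def particle2d(x: float, y: float, mass: float = 1.0) -> Conformation:
    """Single unit-mass particle at (x, y, 0) — a state on a 2-D toy surface."""
    top = Topology(
        sequence="X",
        atom_names=np.array(["CA"]),
        elements=np.array(["C"]),
        residue_index=np.array([1]),
        residue_names=np.array(["UNK"]),
        masses=np.array([mass]),
    )
    return Conformation(np.array([[x, y, 0.0]]), top)


def make_random_path(endpoints, P: int, seed: int, noise: float,
                     delta_t: float = 1.0, init_mode: str = "interpolate+noise") -> Path:
    """Seeded trial path (shared implementation with the engine's initializer)."""
    params = ActionParams(n_segments=P, delta_t=delta_t, seed=seed,
                          noise_amplitude=noise, init_mode=init_mode)
    return init_trial_path(endpoints, params)
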