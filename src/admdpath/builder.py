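"""All-atom chain construction at ideal geometry.

``build_extended`` assembles a capped peptide from a 1-letter sequence
(lower-case = D-amino acid) by placing the backbone with internal
coordinates (NeRF) at the requested (φ, ψ, ω) and grafting side chains and
hydrogens from ideal-geometry residue templates (superposed on the local
N-CA-C triad).  D-residues use the mirrored template, which inverts the Cα
improper; D-proline maps directly onto its own template.
"""

from __future__ import annotations

import numpy as np
import biotite.structure.info as struc_info

from .geometry import place_atom, kabsch_rotation
from .structures import Conformation, Topology, ONE_TO_THREE

__all__ = ["build_extended", "IDEAL_BACKBONE", "DEFAULT_EXTENDED_DIHEDRALS"]

# Ideal backbone geometry (Engh-Huber-like averages): lengths Å, angles deg.
IDEAL_BACKBONE = {
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "N-H": 1.010,
    "N-CA-C": 111.2, "CA-C-N": 116.6, "C-N-CA": 121.7,
    "CA-C-O": 120.5, "H-N-CA": 119.0,
    "CH3-C": 1.508,  # acetyl cap methyl-carbonyl bond
}

# Default extended-state backbone torsions (degrees): a β-like extended chain.
DEFAULT_EXTENDED_DIHEDRALS = (-135.0, 135.0, 180.0)

_TEMPLATE_CACHE: dict[tuple, tuple] = {}


def _template(res3: str, mirror: bool):
    """Ideal-geometry heavy-atom + hydrogen template for one residue type."""
    key = (res3, mirror)
    if key not in _TEMPLATE_CACHE:
        arr = struc_info.residue(res3)
        if arr is None:
            raise KeyError(f"no ideal-geometry template for residue {res3!r}")
        # Drop free-amino-acid artifacts (carboxylate OXT, second amide H).
        drop = np.isin(arr.atom_name, ("OXT", "HXT", "H2", "HN2"))
        arr = arr[~drop]
        coords = arr.coord.copy()
        if mirror:
            coords = coords * np.array([-1.0, 1.0, 1.0])
        _TEMPLATE_CACHE[key] = (list(arr.atom_name), list(arr.element), coords)
    return _TEMPLATE_CACHE[key]


def _res3_for(letter: str) -> tuple[str, bool]:
    """(template name, mirror?) for a 1-letter code; lower-case = D."""
    upper = letter.upper()
    if upper not in ONE_TO_THREE:
        raise KeyError(f"unknown residue letter {letter!r}")
    if letter == "p":
        return "DPR", False          # dedicated D-proline template
    if letter.islower():
        return ONE_TO_THREE[upper], True
    return ONE_TO_THREE[upper], False


def build_extended(sequence: str,
                   dihedrals: tuple[float, float, float] = DEFAULT_EXTENDED_DIHEDRALS,
                   caps: tuple[bool, bool] = (True, True)):
    """Build an all-atom chain at ideal geometry with uniform (φ, ψ, ω).

    Parameters
    ----------
    sequence:
        1-letter residue string; lower-case letters are D-amino acids
        (``"YRVpS..."`` style).
    dihedrals:
        Backbone (φ, ψ, ω) in degrees applied to every residue.
    caps:
        (N-terminal acetyl, C-terminal amide).

    Returns
    -------
    (Conformation, Topology)
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    phi, psi, omega = (float(v) for v in dihedrals)
    g = IDEAL_BACKBONE
    n_res = len(sequence)

    # --- backbone trace via NeRF -----------------------------------------
    N = [None] * (n_res + 2)
    CA = [None] * (n_res + 2)
    C = [None] * (n_res + 2)
    N[1] = np.zeros(3)
    CA[1] = np.array([g["N-CA"], 0.0, 0.0])
    ang = np.radians(180.0 - g["N-CA-C"])
    C[1] = CA[1] + g["CA-C"] * np.array([np.cos(ang), np.sin(ang), 0.0])
    def phi_for(r):
        # Proline's φ is fixed by its ring: −75° (L) / +75° (D).
        letter = sequence[r - 1]
        if letter == "P":
            return -75.0
        if letter == "p":
            return 75.0
        return phi

    for r in range(1, n_res):
        N[r + 1] = place_atom(N[r], CA[r], C[r], g["C-N"], g["CA-C-N"], psi)
        CA[r + 1] = place_atom(CA[r], C[r], N[r + 1], g["N-CA"], g["C-N-CA"], omega)
        C[r + 1] = place_atom(C[r], N[r + 1], CA[r + 1], g["CA-C"], g["N-CA-C"],
                              phi_for(r + 1))
    # Nitrogen following the last residue (amide cap N, or virtual); it fixes
    # ψ of the last residue and hence its carbonyl-O plane.  Without a C-cap
    # the last ψ is undefined, so a fixed convention (trans) is used.
    psi_last = psi if caps[1] else 180.0
    N_next = place_atom(N[n_res], CA[n_res], C[n_res], g["C-N"], g["CA-C-N"], psi_last)

    # Acetyl cap heavy atoms, extending backwards from residue 1.
    if caps[0]:
        C0 = place_atom(C[1], CA[1], N[1], g["C-N"], g["C-N-CA"], omega)
        CH3 = place_atom(CA[1], N[1], C0, g["CH3-C"], g["CA-C-N"], 180.0)
        O0 = place_atom(N[1], CH3, C0, g["C-O"], g["CA-C-O"], 180.0)

    atom_names: list[str] = []
    elements: list[str] = []
    res_index: list[int] = []
    res_names: list[str] = []
    coords: list[np.ndarray] = []

    def add(name, element, resi, resn, xyz):
        atom_names.append(name)
        elements.append(element)
        res_index.append(resi)
        res_names.append(resn)
        coords.append(np.asarray(xyz, float))

    if caps[0]:
        add("CH3", "C", 0, "ACE", CH3)
        add("C", "C", 0, "ACE", C0)
        add("O", "O", 0, "ACE", O0)

    for r in range(1, n_res + 1):
        letter = sequence[r - 1]
        res3, mirror = _res3_for(letter)
        names, elems, tcoords = _template(res3, mirror)
        t_idx = {n: i for i, n in enumerate(names)}
        triad_t = np.stack([tcoords[t_idx["N"]], tcoords[t_idx["CA"]],
                            tcoords[t_idx["C"]]])
        triad_b = np.stack([N[r], CA[r], C[r]])
        R, cm, ct = kabsch_rotation(triad_t, triad_b)
        placed = (tcoords - cm) @ R.T + ct

        add("N", "N", r, res3, N[r])
        # Amide hydrogen: in the peptide plane, anti (bisector of the N bonds).
        if res3 not in ("PRO", "DPR"):
            prev_c = C0 if (r == 1 and caps[0]) else (C[r - 1] if r > 1 else None)
            if prev_c is not None:
                u = N[r] - prev_c
                v = N[r] - CA[r]
                h_dir = u / np.linalg.norm(u) + v / np.linalg.norm(v)
                h = N[r] + g["N-H"] * h_dir / np.linalg.norm(h_dir)
                add("H", "H", r, res3, h)
            elif "H" in t_idx:       # free N-terminus: template orientation
                add("H", "H", r, res3, placed[t_idx["H"]])
        add("CA", "C", r, res3, CA[r])
        add("C", "C", r, res3, C[r])
        # Carbonyl O coplanar with CA-C-N(next), anti to the next nitrogen.
        nn = N[r + 1] if r < n_res else N_next
        add("O", "O", r, res3,
            place_atom(nn, CA[r], C[r], g["C-O"], g["CA-C-O"], 180.0))
        for i, nm in enumerate(names):
            if nm in ("N", "CA", "C", "O", "H"):
                continue
            add(nm, elems[i], r, res3, placed[i])

    if caps[1]:
        cap_res = n_res + 1
        add("N", "N", cap_res, "NH2", N_next)
        add("HN1", "H", cap_res, "NH2",
            place_atom(CA[n_res], C[n_res], N_next, g["N-H"], 119.0, 180.0))
        add("HN2", "H", cap_res, "NH2",
            place_atom(CA[n_res], C[n_res], N_next, g["N-H"], 119.0, 0.0))

    top = Topology(
        sequence=sequence,
        atom_names=np.array(atom_names),
        elements=np.array(elements),
        residue_index=np.array(res_index),
        residue_names=np.array(res_names),
        caps=caps,
    )
    return Conformation(np.stack(coords), top), top
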