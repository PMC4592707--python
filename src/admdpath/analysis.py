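"""Per-frame and per-pathway folding observables.

Implements the metric stack used to read a folding order off an optimized
pathway: RMSD (global and per-segment), radius of gyration, native-contact
and backbone hydrogen-bond counts under geometric criteria, per-pair
distance series, first-sustained-formation steps and orders, correlation,
and collapse diagnostics (fraction of native structure formed at a given
degree of Rg reduction).

A native contact exists between residues separated by at least
``min_sequence_separation`` in sequence whose Cα-Cα distance is below
``calpha_cutoff`` (default 6.5 Å).  A backbone hydrogen bond exists when a
carbonyl oxygen and an amide nitrogen are closer than the distance cutoff
(default 2.5 Å, O-N dialect as commonly printed; an O-H dialect is provided
since the short cutoff plausibly intends the hydrogen distance) and the
O···H-N bending angle at the hydrogen exceeds 135°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import rmsd_after_superposition
from .structures import Conformation, Path, radius_of_gyration

__all__ = [
    "ContactCriteria", "HBondCriteria", "ContactResult", "HBondResult",
    "PathwayMetrics", "CollapseDiagnostics",
    "rmsd", "local_rmsd", "native_contacts", "backbone_hbonds",
    "distance_series", "reduction_step", "formation_order", "pearson",
    "fraction_formed_at_rg", "compute_metrics",
]


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric native-contact definition on Cα positions."""

    calpha_cutoff: float = 6.5           # Å
    min_sequence_separation: int = 3     # |i−j| >= 3 ⇔ "more than two residues"

    def __post_init__(self):
        if self.calpha_cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_sequence_separation < 1:
            raise ValueError("separation must be >= 1")


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric backbone hydrogen-bond definition.

    ``distance_dialect`` selects which distance the cutoff applies to:
    ``"O-N"`` (acceptor oxygen to donor nitrogen, as printed) or ``"O-H"``
    (acceptor oxygen to amide hydrogen).
    """

    donor_acceptor_cutoff: float = 2.5   # Å
    angle_min: float = 135.0             # degrees, at the hydrogen
    distance_dialect: str = "O-N"

    def __post_init__(self):
        if self.donor_acceptor_cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.angle_min < 180:
            raise ValueError("angle_min must be in (0, 180)")
        if self.distance_dialect not in ("O-N", "O-H"):
            raise ValueError("distance_dialect must be 'O-N' or 'O-H'")


@dataclass
class ContactResult:
    count: int
    formed_pairs: list          # native pairs satisfied in the queried frame
    native_pairs: list          # the native pair set


@dataclass
class HBondResult:
    count: int
    formed_pairs: list          # (donor_residue, acceptor_residue)
    native_pairs: list


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def rmsd(conf: Conformation, ref: Conformation, selection=None) -> float:
    """Minimum RMSD (Å) over all rigid superpositions of ``conf`` onto ``ref``.

    ``selection`` is an optional array of atom indices used both for the
    superposition and the deviation.
    """
    a = conf.positions
    b = ref.positions
    if selection is not None:
        sel = np.asarray(selection, int)
        a, b = a[sel], b[sel]
    if a.shape != b.shape:
        raise ValueError("selections must align 1:1")
    return rmsd_after_superposition(b, a)


def backbone_rmsd(conf: Conformation, ref: Conformation) -> float:
    """RMSD over backbone N, CA, C, O atoms."""
    names = conf.topology.atom_names
    sel = np.flatnonzero(np.isin(names, ("N", "CA", "C", "O"))
                         & (conf.topology.residue_index >= 1))
    return rmsd(conf, ref, sel)


def _range_atoms(topology, residue_range) -> np.ndarray:
    lo, hi = residue_range
    if lo > hi or lo < 1 or hi > topology.n_residues:
        raise ValueError(f"residue range {residue_range} outside chain")
    idx = topology.residue_index
    sel = np.flatnonzero((idx >= lo) & (idx <= hi))
    if not len(sel):
        raise ValueError(f"empty residue range {residue_range}")
    return sel


def local_rmsd(path: Path, native: Conformation, residue_range) -> np.ndarray:
    """Per-frame RMSD over one residue range (superposition on that range)."""
    sel = _range_atoms(path.topology, residue_range)
    ref = native.positions[sel]
    return np.array([
        rmsd_after_superposition(ref, path.coords[j][sel])
        for j in range(path.n_frames)
    ])


# ---------------------------------------------------------------------------
# Contacts and hydrogen bonds
# ---------------------------------------------------------------------------

def _calpha_distances(conf: Conformation) -> tuple[np.ndarray, np.ndarray]:
    ca = conf.calpha_positions()
    diff = ca[:, None, :] - ca[None, :, :]
    return ca, np.sqrt((diff ** 2).sum(-1))


def contact_pairs_of(conf: Conformation,
                     criteria: ContactCriteria = ContactCriteria()) -> list:
    """All residue pairs of ``conf`` satisfying the contact criteria (1-based)."""
    _, dmat = _calpha_distances(conf)
    n = dmat.shape[0]
    pairs = []
    for i in range(n):
        for j in range(i + criteria.min_sequence_separation, n):
            if dmat[i, j] < criteria.calpha_cutoff:
                pairs.append((i + 1, j + 1))
    return pairs


def native_contacts(conf: Conformation, native: Conformation,
                    criteria: ContactCriteria = ContactCriteria()) -> ContactResult:
    """Count native contacts of ``native`` that are present in ``conf``.

    The native pair set is determined from the native structure under the
    same criteria; a native pair is "present" in ``conf`` when its Cα-Cα
    distance is below the cutoff (the sequence-separation rule is a property
    of the pair set, not re-tested per frame).
    """
    native_pairs = contact_pairs_of(native, criteria)
    _, dmat = _calpha_distances(conf)
    formed = [(i, j) for (i, j) in native_pairs
              if dmat[i - 1, j - 1] < criteria.calpha_cutoff]
    return ContactResult(len(formed), formed, native_pairs)


def _backbone_ohn(conf: Conformation):
    """Per-residue O (acceptor), N and H (donor) coordinates.

    Missing amide hydrogens are placed at ideal geometry: 1.01 Å from N, in
    the peptide plane, anti to the preceding carbonyl (bisector of the two
    N bonds).
    """
    top = conf.topology
    sets = top.backbone_sets()
    pos = conf.positions
    n_res = top.n_residues
    O = np.full((n_res, 3), np.nan)
    N = np.full((n_res, 3), np.nan)
    H = np.full((n_res, 3), np.nan)
    for r, entry in enumerate(sets):
        if entry["O"] is not None:
            O[r] = pos[entry["O"]]
        if entry["N"] is None:
            continue
        N[r] = pos[entry["N"]]
        if entry["H"] is not None:
            H[r] = pos[entry["H"]]
        else:
            resname = top.residue_names[entry["N"]]
            if resname in ("PRO", "DPR"):
                continue  # no amide hydrogen
            prev_c = sets[r - 1]["C"] if r > 0 else None
            if prev_c is None and top.caps[0]:
                ace_c = np.flatnonzero((top.residue_index == 0)
                                       & (top.atom_names == "C"))
                prev_c = int(ace_c[0]) if len(ace_c) else None
            if prev_c is None or entry["CA"] is None:
                continue
            u = N[r] - pos[prev_c]
            v = N[r] - pos[entry["CA"]]
            d = u / np.linalg.norm(u) + v / np.linalg.norm(v)
            H[r] = N[r] + 1.01 * d / np.linalg.norm(d)
    return O, N, H


def _hbond_pairs(O, N, H, criteria: HBondCriteria) -> list:
    """(donor_residue, acceptor_residue) 1-based pairs satisfying criteria."""
    n = len(O)
    pairs = []
    for d in range(n):          # donor residue: N-H
        if np.isnan(N[d, 0]) or np.isnan(H[d, 0]):
            continue
        for a in range(n):      # acceptor residue: C=O
            if a == d or np.isnan(O[a, 0]):
                continue
            if criteria.distance_dialect == "O-N":
                dist = np.linalg.norm(O[a] - N[d])
            else:
                dist = np.linalg.norm(O[a] - H[d])
            if dist >= criteria.donor_acceptor_cutoff:
                continue
            u = O[a] - H[d]
            v = N[d] - H[d]
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if angle > criteria.angle_min:
                pairs.append((d + 1, a + 1))
    return pairs


def backbone_hbonds(conf: Conformation, native: Conformation,
                    criteria: HBondCriteria = HBondCriteria()) -> HBondResult:
    """Count native backbone hydrogen bonds of ``native`` present in ``conf``."""
    if conf.topology.is_bead_model:
        raise ValueError("bead models carry no backbone O/H/N atoms")
    native_pairs = _hbond_pairs(*_backbone_ohn(native), criteria)
    frame_pairs = set(_hbond_pairs(*_backbone_ohn(conf), criteria))
    formed = [p for p in native_pairs if p in frame_pairs]
    return HBondResult(len(formed), formed, native_pairs)


# ---------------------------------------------------------------------------
# Series diagnostics
# ---------------------------------------------------------------------------

def distance_series(path: Path, residue_pair) -> np.ndarray:
    """Per-frame Cα-Cα distance (Å) for one 1-based residue pair."""
    i, j = residue_pair
    ca = path.topology.calpha_indices
    if not (1 <= i <= len(ca) and 1 <= j <= len(ca)):
        raise IndexError(f"residue pair {residue_pair} out of range")
    a = path.coords[:, ca[i - 1]]
    b = path.coords[:, ca[j - 1]]
    return np.linalg.norm(a - b, axis=1)


def reduction_step(series, fraction: float):
    """First frame at which a decaying series has lost ``fraction`` of its
    total initial-to-final change.

    Returns the first index j with
    series[j] <= series[-1] + (1 − fraction)(series[0] − series[-1]),
    or ``None`` if the level is never reached.
    """
    s = np.asarray(series, float)
    if s.size == 0:
        raise ValueError("series is empty")
    level = s[-1] + (1.0 - fraction) * (s[0] - s[-1])
    hits = np.flatnonzero(s <= level + 1e-12)
    return int(hits[0]) if len(hits) else None


def first_sustained_crossing(series, cutoff: float, persistence: int = 5):
    """First index at which ``series < cutoff`` holds for ``persistence``
    consecutive frames; ``None`` if never sustained."""
    below = np.asarray(series, float) < cutoff
    w = max(1, int(persistence))
    if below.size < w:
        return int(np.flatnonzero(below)[0]) if below.any() else None
    run = np.convolve(below.astype(int), np.ones(w, int), mode="valid")
    hits = np.flatnonzero(run == w)
    return int(hits[0]) if len(hits) else None


def formation_order(series_map: dict, cutoff: float = 6.5,
                    persistence: int = 5) -> list:
    """Order pairs by their first sustained crossing below ``cutoff``.

    ``series_map`` maps a residue pair to its distance series.  A pair is
    "formed" at the first frame from which the criterion holds for at least
    ``persistence`` consecutive frames (transient on/off flickering is
    ignored).  Returns ``[(pair, step), ...]`` sorted by step, ties broken
    by ascending pair index; never-formed pairs are omitted.
    """
    lengths = {len(np.asarray(s)) for s in series_map.values()}
    if len(lengths) > 1:
        raise ValueError("all series must share one length")
    events = []
    for pair in sorted(series_map):
        step = first_sustained_crossing(series_map[pair], cutoff, persistence)
        if step is not None:
            events.append((tuple(pair), step))
    events.sort(key=lambda e: (e[1], e[0]))
    return events


def pearson(series_a, series_b) -> float:
    """Product-moment correlation coefficient in [−1, 1]."""
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("series must have equal length >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance series")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Aggregate metrics
# ---------------------------------------------------------------------------

@dataclass
class PathwayMetrics:
    """Tidy per-frame series for one pathway (all series length P+1)."""

    rg: np.ndarray
    rmsd_to_native: np.ndarray
    potential_energy: np.ndarray
    total_energy: np.ndarray
    n_native_contacts: np.ndarray
    n_native_hbonds: np.ndarray | None
    native_contact_total: int
    native_hbond_total: int | None
    local_rmsd_ranges: dict = field(default_factory=dict)
    pair_distances: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "frame": np.arange(len(self.rg)),
            "rg": self.rg,
            "rmsd_to_native": self.rmsd_to_native,
            "potential_energy": self.potential_energy,
            "total_energy": self.total_energy,
            "n_native_contacts": self.n_native_contacts,
        }
        if self.n_native_hbonds is not None:
            data["n_native_hbonds"] = self.n_native_hbonds
        for rng, series in self.local_rmsd_ranges.items():
            data[f"local_rmsd_{rng[0]}_{rng[1]}"] = series
        for pair, series in self.pair_distances.items():
            data[f"d_{pair[0]}_{pair[1]}"] = series
        return pd.DataFrame(data)


@dataclass
class CollapseDiagnostics:
    percent_contacts: float
    percent_hbonds: float | None
    frame_index: int


def compute_metrics(path: Path, potential, native: Conformation,
                    contact_criteria: ContactCriteria = ContactCriteria(),
                    hbond_criteria: HBondCriteria | None = None,
                    hbond_proxy_pairs=None,
                    local_ranges=(), pair_list=(),
                    rg_weighting: str = "mass") -> PathwayMetrics:
    """All per-frame series for a pathway.

    For all-atom chains, hydrogen bonds are counted geometrically
    (``hbond_criteria``); for Cα-bead chains, an ``hbond_proxy_pairs``
    contact subset (e.g. the helix contacts) may stand in for the hydrogen
    bonds, since bead models carry no O/H/N atoms.

    ``total_energy[j]`` is K_j + V_j with the forward-difference kinetic
    energy of segment j (the last frame reuses the final segment).
    """
    F = path.n_frames
    masses = path.topology.masses[None, :, None]
    rg = np.array([radius_of_gyration(path.frame(j), weighting=rg_weighting)
                   for j in range(F)])
    rmsd_series = np.array([rmsd(path.frame(j), native) for j in range(F)])
    V = potential.energy_many(path.coords)
    diff = path.coords[:-1] - path.coords[1:]
    K = np.sum(masses * diff * diff, axis=(1, 2)) / (2 * path.delta_t ** 2)
    K = np.append(K, K[-1])
    native_pairs = contact_pairs_of(native, contact_criteria)
    ca = path.topology.calpha_indices
    ii = np.array([i - 1 for i, _ in native_pairs], int)
    jj = np.array([j - 1 for _, j in native_pairs], int)
    d = np.linalg.norm(path.coords[:, ca[ii]] - path.coords[:, ca[jj]], axis=2)
    n_contacts = (d < contact_criteria.calpha_cutoff).sum(axis=1)

    n_hb = None
    hb_total = None
    if hbond_proxy_pairs is not None:
        proxy = [tuple(p) for p in hbond_proxy_pairs]
        pi = np.array([p[0] - 1 for p in proxy], int)
        pj = np.array([p[1] - 1 for p in proxy], int)
        dp = np.linalg.norm(path.coords[:, ca[pi]] - path.coords[:, ca[pj]],
                            axis=2)
        n_hb = (dp < contact_criteria.calpha_cutoff).sum(axis=1)
        hb_total = len(proxy)
    elif hbond_criteria is not None and not path.topology.is_bead_model:
        res = [backbone_hbonds(path.frame(j), native, hbond_criteria)
               for j in range(F)]
        n_hb = np.array([r.count for r in res])
        hb_total = len(res[0].native_pairs)

    metrics = PathwayMetrics(
        rg=rg,
        rmsd_to_native=rmsd_series,
        potential_energy=np.asarray(V, float),
        total_energy=np.asarray(V, float) + K,
        n_native_contacts=n_contacts,
        n_native_hbonds=n_hb,
        native_contact_total=len(native_pairs),
        native_hbond_total=hb_total,
    )
    for rng in local_ranges:
        metrics.local_rmsd_ranges[tuple(rng)] = local_rmsd(path, native, rng)
    for pair in pair_list:
        metrics.pair_distances[tuple(pair)] = distance_series(path, pair)
    return metrics


def fraction_formed_at_rg(metrics: PathwayMetrics,
                          rg_reduction_fraction: float) -> CollapseDiagnostics:
    """Native structure formed at a given degree of chain compaction.

    Locates the first frame at which the Rg series has completed
    ``rg_reduction_fraction`` of its total initial→final reduction and
    reports the percentage of native contacts (and hydrogen bonds, when
    available) formed at that frame.  Percentages are on the 0-100 scale,
    reported to one decimal by the CLI.
    """
    j = reduction_step(metrics.rg, rg_reduction_fraction)
    if j is None:
        raise ValueError(
            f"Rg never completes {rg_reduction_fraction:.0%} of its reduction")
    pc = 100.0 * metrics.n_native_contacts[j] / metrics.native_contact_total
    ph = None
    if metrics.n_native_hbonds is not None and metrics.native_hbond_total:
        ph = 100.0 * metrics.n_native_hbonds[j] / metrics.native_hbond_total
    return CollapseDiagnostics(float(pc), ph if ph is None else float(ph), j)
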