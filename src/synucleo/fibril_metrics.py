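"""Structural-stability metrics for stacked-subunit (fibril) models.

Implements the geometric analyses used to follow fibril integrity along a
trajectory:

* inter-subunit (chain) centre-of-mass distances;
* residue contact maps (minimum inter-atomic distance below a cutoff,
  default 6.5 Å, strict);
* geometric hydrogen-bond detection (X–Y < 3.5 Å and X–H···Y angle > 135°),
  split into intra- and inter-subunit bonds, with
  inter = total − intra as a cross-check identity;
* salt-bridge counting between charged side-chain atoms (default
  Lys Nζ / Glu Cδ) within d0 = 4.5 Å, counted as
  SB = Σ_{i,j} S_{i,j} with S_{i,j} = 1 iff |r_i − r_j| − d0 ≤ 0;
* a Kabsch–Sander style secondary-structure assignment reduced to three
  states (H helix, E strand, C coil) and its windowed per-residue
  frame-fraction averages.

Threshold conventions follow the letter of each definition: the contact
cutoff is strict ("below 6.5 Å"), the salt-bridge criterion is inclusive
(r − d0 ≤ 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structio import Atom, Structure, Trajectory

__all__ = [
    "ContactMap",
    "HBond",
    "SaltBridgeCriterion",
    "SubunitDistanceSeries",
    "SSAssignment",
    "HydrogensRequiredError",
    "compute_subunit_distances",
    "contact_map",
    "detect_hbonds",
    "inter_subunit_hbonds",
    "count_salt_bridges",
    "list_salt_bridges",
    "assign_secondary_structure",
    "average_ss_fractions",
]

# standard atomic masses for COM weighting; unknown elements fall back to 1.0
_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971,
}

_BACKBONE_NAMES = {"N", "CA", "C", "O"}


class HydrogensRequiredError(ValueError):
    """Raised when hydrogen-dependent analysis is asked of an H-free model."""


@dataclass
class ContactMap:
    residue_labels: list[tuple[str, int]]
    contacts: np.ndarray  # symmetric boolean matrix, False diagonal
    cutoff: float = 6.5

    def __post_init__(self) -> None:
        c = np.asarray(self.contacts, dtype=bool)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("contacts must be a square matrix")
        if np.any(np.diag(c)):
            raise ValueError("contact-map diagonal must be False")
        if not np.array_equal(c, c.T):
            raise ValueError("contact map must be symmetric")
        self.contacts = c

    @property
    def n_contacts(self) -> int:
        return int(np.triu(self.contacts, 1).sum())


@dataclass
class HBond:
    donor_atom: Atom
    hydrogen_atom: Atom
    acceptor_atom: Atom
    distance_xy: float
    angle_xhy: float

    @property
    def is_intra_subunit(self) -> bool:
        return self.donor_atom.chain_id == self.acceptor_atom.chain_id


@dataclass(frozen=True)
class SaltBridgeCriterion:
    """Atom selectors and distance threshold for salt-bridge counting.

    Selectors are (residue_name, atom_name) pairs; by default only the
    Lys Nζ / Glu Cδ pairing is counted — Arg/Asp/His participate only if
    the user widens the selectors.
    """

    positive_atoms: tuple[tuple[str, str], ...] = (("LYS", "NZ"),)
    negative_atoms: tuple[tuple[str, str], ...] = (("GLU", "CD"),)
    d0: float = 4.5

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")


@dataclass
class SubunitDistanceSeries:
    chain_pair: tuple[str, str]
    values: np.ndarray  # Å per frame

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v


@dataclass
class SSAssignment:
    residue_labels: list[tuple[str, int]]
    per_frame_labels: np.ndarray  # (n_frames, n_residues) of 'H'/'E'/'C'
    averaged_fractions: np.ndarray  # (n_residues, 3) for (H, E, C)
    states: tuple[str, str, str] = ("H", "E", "C")


# ---------------------------------------------------------------------------
# subunit distances
# ---------------------------------------------------------------------------


def _scope_mask(structure: Structure, atom_scope: str) -> np.ndarray:
    if atom_scope == "all":
        return np.ones(structure.n_atoms, dtype=bool)
    if atom_scope == "backbone":
        return np.array([a.name in _BACKBONE_NAMES for a in structure.atoms])
    if atom_scope == "CA":
        return np.array([a.name == "CA" for a in structure.atoms])
    raise ValueError(f"unknown atom_scope {atom_scope!r}")


def _chain_com(coords: np.ndarray, idx: np.ndarray, masses: np.ndarray) -> np.ndarray:
    w = masses[idx]
    return (coords[idx] * w[:, None]).sum(axis=0) / w.sum()


def compute_subunit_distances(
    traj: Trajectory,
    pairs: Sequence[tuple[str, str]] | None = None,
    atom_scope: Literal["all", "backbone", "CA"] = "CA",
) -> list[SubunitDistanceSeries]:
    """Per-frame centre-of-mass distances between chain pairs.

    ``pairs`` defaults to all adjacent chain pairs in file order.  The COM
    uses standard atomic masses where the element is known (unit mass
    otherwise) over the selected atom scope; if the scope selects no atom
    of a chain, the scope falls back to all atoms of that chain.
    """
    top = traj.topology
    chains = top.chains
    if pairs is None:
        pairs = list(zip(chains[:-1], chains[1:]))
    for a, b in pairs:
        if a not in chains or b not in chains:
            raise ValueError(f"unknown chain in pair ({a}, {b}); have {chains}")
    masses = np.array([_MASSES.get(a.element.upper(), 1.0) for a in top.atoms])
    scoped = _scope_mask(top, atom_scope)
    chain_idx: dict[str, np.ndarray] = {}
    for c in chains:
        idx = np.array([i for i, a in enumerate(top.atoms) if a.chain_id == c])
        sel = idx[scoped[idx]]
        chain_idx[c] = sel if len(sel) else idx
    out = []
    for a, b in pairs:
        vals = np.empty(traj.n_frames)
        for k, coords in enumerate(traj.frames):
            ca = _chain_com(coords, chain_idx[a], masses)
            cb = _chain_com(coords, chain_idx[b], masses)
            vals[k] = float(np.linalg.norm(ca - cb))
        out.append(SubunitDistanceSeries((a, b), vals))
    return out


# ---------------------------------------------------------------------------
# contact map
# ---------------------------------------------------------------------------


def contact_map(
    frame: Structure,
    cutoff: float = 6.5,
    min_sequence_separation: int = 1,
    method: Literal["min_atom", "residue_com"] = "min_atom",
) -> ContactMap:
    """Residue contact map of one conformation.

    Two residues are in contact when their distance is strictly below
    ``cutoff`` (default 6.5 Å).  ``method='min_atom'`` (default) uses the
    minimum over all inter-residue atom pairs; ``'residue_com'`` uses
    residue centres of mass.  Within a chain, pairs with
    ``|i - j| < min_sequence_separation`` are excluded; the diagonal is
    always False; inter-chain pairs are always eligible.
    """
    residues = frame.residues()
    if len(residues) < 2:
        raise ValueError("need at least two residues for a contact map")
    labels = [key for key, _ in residues]
    coords = frame.positions
    masses = np.array([_MASSES.get(a.element.upper(), 1.0) for a in frame.atoms])
    n = len(residues)
    if method == "residue_com":
        pts = np.vstack(
            [_chain_com(coords, np.array(idx), masses) for _, idx in residues]
        )
        dmat = cdist(pts, pts)
    elif method == "min_atom":
        # contiguous residue blocks -> two reduceat passes over the atom
        # distance matrix give per-residue-pair minima
        order = [i for _, idx in residues for i in idx]
        starts = np.cumsum([0] + [len(idx) for _, idx in residues[:-1]])
        d_atoms = cdist(coords[order], coords[order])
        dmat = np.minimum.reduceat(
            np.minimum.reduceat(d_atoms, starts, axis=0), starts, axis=1
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    contacts = dmat < cutoff
    np.fill_diagonal(contacts, False)
    for i in range(n):
        ci, ri = labels[i]
        for j in range(n):
            cj, rj = labels[j]
            if ci == cj and abs(ri - rj) < min_sequence_separation:
                contacts[i, j] = False
    np.fill_diagonal(contacts, False)
    return ContactMap(labels, contacts, cutoff)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------


def _assign_hydrogens(
    frame: Structure, donor_elements: tuple[str, ...]
) -> list[tuple[int, int]]:
    """Pair each hydrogen with its covalent donor heavy atom (<1.2 Å)."""
    h_idx = [i for i, a in enumerate(frame.atoms) if a.element.upper() == "H"]
    d_idx = [
        i for i, a in enumerate(frame.atoms) if a.element.upper() in donor_elements
    ]
    if not h_idx or not d_idx:
        return []
    coords = frame.positions
    d = cdist(coords[h_idx], coords[d_idx])
    pairs = []
    for r, hi in enumerate(h_idx):
        c = int(np.argmin(d[r]))
        if d[r, c] <= 1.2:
            pairs.append((d_idx[c], hi))
    return pairs


def detect_hbonds(
    frame: Structure,
    donor_elements: tuple[str, ...] = ("N", "O"),
    acceptor_elements: tuple[str, ...] = ("N", "O"),
    max_distance: float = 3.5,
    min_angle: float = 135.0,
) -> list[HBond]:
    """Geometric hydrogen bonds: X–Y < 3.5 Å and X–H···Y angle > 135°.

    X is a donor heavy atom with a covalently bound hydrogen (assigned to
    the nearest donor-element atom within 1.2 Å), Y an acceptor heavy atom.
    Both thresholds are strict.  Raises :class:`HydrogensRequiredError`
    when the model carries no hydrogens.
    """
    donor_elements = tuple(e.upper() for e in donor_elements)
    acceptor_elements = tuple(e.upper() for e in acceptor_elements)
    if not any(a.element.upper() == "H" for a in frame.atoms):
        raise HydrogensRequiredError(
            "hydrogens required: the model contains no H atoms; "
            "add hydrogens before hydrogen-bond detection"
        )
    dh_pairs = _assign_hydrogens(frame, donor_elements)
    acc_idx = [
        i for i, a in enumerate(frame.atoms) if a.element.upper() in acceptor_elements
    ]
    coords = frame.positions
    bonds: list[HBond] = []
    if not dh_pairs or not acc_idx:
        return bonds
    acc_pos = coords[acc_idx]
    for xi, hi in dh_pairs:
        dxy = np.linalg.norm(acc_pos - coords[xi], axis=1)
        for k in np.nonzero(dxy < max_distance)[0]:
            yi = acc_idx[int(k)]
            if yi == xi or yi == hi:
                continue
            v1 = coords[xi] - coords[hi]
            v2 = coords[yi] - coords[hi]
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom == 0:
                continue
            cosang = np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)
            angle = float(np.degrees(np.arccos(cosang)))
            if angle > min_angle:
                bonds.append(
                    HBond(
                        donor_atom=frame.atoms[xi],
                        hydrogen_atom=frame.atoms[hi],
                        acceptor_atom=frame.atoms[yi],
                        distance_xy=float(dxy[k]),
                        angle_xhy=angle,
                    )
                )
    return bonds


def inter_subunit_hbonds(total: int, intra: int) -> int:
    """Inter-subunit bonds as total − intra-subunit."""
    if not 0 <= intra <= total:
        raise ValueError(f"require 0 <= intra ({intra}) <= total ({total})")
    return total - intra


# ---------------------------------------------------------------------------
# salt bridges
# ---------------------------------------------------------------------------


def list_salt_bridges(
    frame: Structure,
    criterion: SaltBridgeCriterion | None = None,
    scope: Literal["intra", "inter", "all"] = "all",
) -> list[tuple[Atom, Atom, float]]:
    """All (positive, negative) atom pairs with |r_i − r_j| − d0 ≤ 0."""
    crit = criterion or SaltBridgeCriterion()
    pos_sel = set(crit.positive_atoms)
    neg_sel = set(crit.negative_atoms)
    pos_idx = [
        i for i, a in enumerate(frame.atoms) if (a.residue_name, a.name) in pos_sel
    ]
    neg_idx = [
        i for i, a in enumerate(frame.atoms) if (a.residue_name, a.name) in neg_sel
    ]
    if not pos_idx or not neg_idx:
        return []
    coords = frame.positions
    d = cdist(coords[pos_idx], coords[neg_idx])
    out = []
    for r, pi in enumerate(pos_idx):
        for c, ni in enumerate(neg_idx):
            same_chain = frame.atoms[pi].chain_id == frame.atoms[ni].chain_id
            if scope == "intra" and not same_chain:
                continue
            if scope == "inter" and same_chain:
                continue
            if d[r, c] - crit.d0 <= 0:
                out.append((frame.atoms[pi], frame.atoms[ni], float(d[r, c])))
    return out


def count_salt_bridges(
    frame: Structure,
    criterion: SaltBridgeCriterion | None = None,
    scope: Literal["intra", "inter", "all"] = "all",
) -> int:
    """SB = Σ_{i,j} S_{i,j}, S_{i,j} = 1 iff |r_i − r_j| ≤ d0."""
    return len(list_salt_bridges(frame, criterion, scope))


# ---------------------------------------------------------------------------
# secondary structure (Kabsch–Sander energies, 3-state reduction)
# ---------------------------------------------------------------------------

_KS_Q1Q2F = 0.084 * 332.0  # kcal/mol·Å, Kabsch–Sander electrostatic constant
_KS_CUTOFF = -0.5  # kcal/mol


def _backbone_table(frame: Structure):
    """Per-residue backbone atom positions (N, CA, C, O, optional H)."""
    residues = frame.residues()
    table = []
    for (chain, rid), idx in residues:
        entry: dict[str, np.ndarray] = {}
        for i in idx:
            a = frame.atoms[i]
            if a.name in _BACKBONE_NAMES and a.name not in entry:
                entry[a.name] = a.position
            if a.element.upper() == "H" and a.name in {"H", "HN", "H1"} and "H" not in entry:
                entry["H"] = a.position
        table.append(((chain, rid), entry))
    return table


def _amide_hydrogens(table) -> list[np.ndarray | None]:
    """Explicit amide H, else reconstructed 1.0 Å from N opposite the
    C(prev)–N / CA–N bisector; None where impossible (chain start, Pro-like
    missing geometry)."""
    out: list[np.ndarray | None] = []
    for k, ((chain, rid), entry) in enumerate(table):
        if "H" in entry:
            out.append(entry["H"])
            continue
        if "N" not in entry or "CA" not in entry:
            out.append(None)
            continue
        prev = table[k - 1] if k > 0 else None
        if prev is None or prev[0][0] != chain or "C" not in prev[1]:
            out.append(None)
            continue
        n = entry["N"]
        d1 = n - prev[1]["C"]
        d2 = n - entry["CA"]
        n1, n2 = np.linalg.norm(d1), np.linalg.norm(d2)
        if n1 == 0 or n2 == 0:
            out.append(None)
            continue
        h_dir = d1 / n1 + d2 / n2
        norm = np.linalg.norm(h_dir)
        out.append(n + h_dir / norm if norm > 0 else None)
    return out


def _ks_energy(n, h, c, o) -> float:
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing geometry, not a bond
        return 0.0
    return _KS_Q1Q2F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(frame: Structure) -> list[str]:
    """Three-state secondary structure (H/E/C) per residue.

    Backbone N–H···O=C bonds are scored with the Kabsch–Sander
    electrostatic energy (bond iff E < −0.5 kcal/mol; amide H
    reconstructed when absent).  n-turns (n = 3, 4, 5) repeated on
    consecutive residues give helix; parallel/antiparallel bridge patterns
    give strand; helix takes priority over strand; everything else —
    including residues with missing backbone atoms — is coil.
    """
    table = _backbone_table(frame)
    n_res = len(table)
    labels = ["C"] * n_res
    if n_res == 0:
        return labels
    hpos = _amide_hydrogens(table)
    complete = np.array(
        [all(k in entry for k in ("N", "CA", "C", "O")) for _, entry in table]
    )
    if not complete.all():
        missing = [table[i][0] for i in np.nonzero(~complete)[0]]
        warnings.warn(
            f"{len(missing)} residue(s) missing backbone atoms assigned coil: "
            f"{missing[:5]}"
        )

    # hbond[i, j]: N-H of residue i donates to C=O of residue j
    hb = np.zeros((n_res, n_res), dtype=bool)
    chain_of = [key[0] for key, _ in table]
    idx_of = [key[1] for key, _ in table]
    for i in range(n_res):
        if hpos[i] is None or "N" not in table[i][1]:
            continue
        for j in range(n_res):
            if i == j or not complete[j]:
                continue
            if chain_of[i] == chain_of[j] and abs(idx_of[i] - idx_of[j]) <= 1:
                continue
            e = _ks_energy(table[i][1]["N"], hpos[i], table[j][1]["C"], table[j][1]["O"])
            if e < _KS_CUTOFF:
                hb[i, j] = True

    def seq(i: int, off: int) -> int | None:
        """Index i+off if it is the sequence neighbour within the chain."""
        j = i + off
        if 0 <= j < n_res and chain_of[j] == chain_of[i]:
            return j
        return None

    # helices: two consecutive n-turns (n = 4 first, then 3, 5)
    helix = np.zeros(n_res, dtype=bool)
    for turn in (4, 3, 5):
        for i in range(n_res):
            j1 = seq(i, turn)
            i2 = seq(i, 1)
            j2 = seq(i, turn + 1)
            if j1 is None or i2 is None or j2 is None:
                continue
            if hb[j1, i] and hb[j2, i2]:
                for k in range(i + 1, i + turn + 1):
                    helix[k] = True

    # bridges
    bridge = np.zeros(n_res, dtype=bool)
    for i in range(n_res):
        for j in range(n_res):
            if i == j:
                continue
            if chain_of[i] == chain_of[j] and abs(idx_of[i] - idx_of[j]) < 3:
                continue
            im1, ip1 = seq(i, -1), seq(i, 1)
            jm1, jp1 = seq(j, -1), seq(j, 1)
            par = (
                im1 is not None and ip1 is not None and hb[j, im1] and hb[ip1, j]
            ) or (
                jm1 is not None and jp1 is not None and hb[i, jm1] and hb[jp1, i]
            )
            anti = (hb[i, j] and hb[j, i]) or (
                ip1 is not None
                and im1 is not None
                and jp1 is not None
                and jm1 is not None
                and hb[jp1, im1]
                and hb[ip1, jm1]
            )
            if par or anti:
                bridge[i] = True
                bridge[j] = True

    for i in range(n_res):
        if not complete[i]:
            labels[i] = "C"
        elif helix[i]:
            labels[i] = "H"
        elif bridge[i]:
            labels[i] = "E"
    return labels


def average_ss_fractions(
    traj: Trajectory,
    window: tuple[int, int] | None = None,
    time_window: tuple[float, float] | None = None,
) -> SSAssignment:
    """Per-residue fraction of frames in H/E/C over a frame or time window.

    ``window`` is a half-open frame-index range ``(start, stop)``;
    ``time_window`` selects frames with start ≤ t ≤ stop from
    ``frame_times`` (e.g. the 200–500 ns tail of a production run).
    Defaults to every frame.  Fractions per residue sum to 1.
    """
    if time_window is not None:
        if traj.frame_times is None:
            raise ValueError("time_window requires frame_times")
        lo, hi = time_window
        frame_ids = [
            k for k, t in enumerate(traj.frame_times) if lo <= t <= hi
        ]
    else:
        start, stop = window if window is not None else (0, traj.n_frames)
        frame_ids = list(range(*slice(start, stop).indices(traj.n_frames)))
    if not frame_ids:
        raise ValueError("empty averaging window")
    labels_per_frame = []
    for k in frame_ids:
        labels_per_frame.append(assign_secondary_structure(traj.frame_structure(k)))
    arr = np.array(labels_per_frame)  # (n_window_frames, n_res)
    residue_labels = [key for key, _ in traj.topology.residues()]
    states = ("H", "E", "C")
    fractions = np.stack([(arr == s).mean(axis=0) for s in states], axis=1)
    return SSAssignment(residue_labels, arr, fractions, states)
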