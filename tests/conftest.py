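"""Shared fixtures and independent brute-force oracles.

The oracle functions re-derive the geometric criteria with plain Python
loops, independently of the vectorised implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from synucleo.structio import Atom, Structure
from synucleo import synthetic_data as sd


# ---------------------------------------------------------------------------
# brute-force oracles (plain loops, no shared code with the implementation)
# ---------------------------------------------------------------------------


def brute_contact_map(structure: Structure, cutoff: float = 6.5,
                      min_seq_sep: int = 1) -> dict[tuple, bool]:
    """All-pairs minimum atom distance, strict cutoff."""
    res: dict[tuple, list] = {}
    for a in structure.atoms:
        res.setdefault((a.chain_id, a.residue_index), []).append(a.position)
    keys = list(res)
    out = {}
    for i, ki in enumerate(keys):
        for j, kj in enumerate(keys):
            if i == j:
                out[(ki, kj)] = False
                continue
            if ki[0] == kj[0] and abs(ki[1] - kj[1]) < min_seq_sep:
                out[(ki, kj)] = False
                continue
            dmin = min(
                math.dist(p, q) for p in res[ki] for q in res[kj]
            )
            out[(ki, kj)] = dmin < cutoff
    return out


def brute_hbonds(structure: Structure, max_xy: float = 3.5,
                 min_angle: float = 135.0) -> set[tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) serial triples meeting the criterion."""
    atoms = structure.atoms
    donors = [a for a in atoms if a.element.upper() in ("N", "O")]
    out = set()
    for h in atoms:
        if h.element.upper() != "H":
            continue
        best, bestd = None, 1.2
        for x in donors:
            d = math.dist(h.position, x.position)
            if d <= bestd:
                best, bestd = x, d
        if best is None:
            continue
        x = best
        for y in donors:
            if y is x or y is h:
                continue
            if math.dist(x.position, y.position) >= max_xy:
                continue
            v1 = x.position - h.position
            v2 = y.position - h.position
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if ang > min_angle:
                out.add((x.serial, h.serial, y.serial))
    return out


def brute_salt_bridges(structure: Structure, d0: float = 4.5,
                       scope: str = "all") -> int:
    pos = [a for a in structure.atoms if (a.residue_name, a.name) == ("LYS", "NZ")]
    neg = [a for a in structure.atoms if (a.residue_name, a.name) == ("GLU", "CD")]
    n = 0
    for p in pos:
        for q in neg:
            same = p.chain_id == q.chain_id
            if scope == "intra" and not same:
                continue
            if scope == "inter" and same:
                continue
            if math.dist(p.position, q.position) - d0 <= 0:
                n += 1
    return n


def random_toy_structure(seed: int, max_atoms: int = 200) -> Structure:
    """Random structure mixing diffuse atoms with planted donor/acceptor
    clusters and Lys/Glu charged-group atoms, in a ~20 Å box."""
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    serial = 1
    n_res = rng.integers(4, 13)
    budget = max_atoms
    for r in range(1, n_res + 1):
        chain = "A" if r <= n_res // 2 else "B"
        resname = rng.choice(["ALA", "LYS", "GLU", "SER"])
        center = rng.uniform(0, 20, 3)
        n_at = int(rng.integers(2, 7))
        for k in range(min(n_at, budget)):
            elem = rng.choice(["C", "N", "O", "H"], p=[0.4, 0.2, 0.2, 0.2])
            name = {"C": "C", "N": "N", "O": "O", "H": "H"}[elem] + str(k)
            atoms.append(
                Atom(serial, name, elem, str(resname), int(r), chain,
                     center + rng.normal(0, 2.0, 3))
            )
            serial += 1
            budget -= 1
        if resname == "LYS" and budget > 0:
            atoms.append(Atom(serial, "NZ", "N", "LYS", int(r), chain,
                              center + rng.normal(0, 2.5, 3)))
            serial += 1
            budget -= 1
        if resname == "GLU" and budget > 0:
            atoms.append(Atom(serial, "CD", "C", "GLU", int(r), chain,
                              center + rng.normal(0, 2.5, 3)))
            serial += 1
            budget -= 1
        # planted donor-H...acceptor geometry to exercise the H-bond path
        if budget >= 3 and rng.random() < 0.7:
            x = rng.uniform(0, 20, 3)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            h = x + u * rng.uniform(0.9, 1.15)
            y = x + u * rng.uniform(2.0, 4.0) + rng.normal(0, 0.4, 3)
            for nm, el, p in (("ND", "N", x), ("HD", "H", h), ("OA", "O", y)):
                atoms.append(Atom(serial, nm, el, str(resname), int(r), chain, p))
                serial += 1
                budget -= 1
    return Structure(atoms)


def rigid_transform(structure: Structure, seed: int) -> Structure:
    """Random proper rotation + translation of the whole structure."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-50, 50, 3)
    return structure.with_positions(structure.positions @ q.T + t)


def make_beta_ladder(n_res: int = 6) -> Structure:
    """Two facing strands with mutual inter-chain N-H...O=C bonds per
    residue pair (the narrow antiparallel bridge pattern)."""
    atoms = []
    serial = 1
    for i in range(n_res):
        x = 7.0 * i
        for nm, el, p in [("N", "N", (x, 0, 0)), ("H", "H", (x, 1, 0)),
                          ("CA", "C", (x + 1.5, -1, 0)), ("C", "C", (x + 3, 0.6, 0)),
                          ("O", "O", (x + 3, 1.8, 0))]:
            atoms.append(Atom(serial, nm, el, "GLY", i + 1, "A", np.array(p, float)))
            serial += 1
    for i in range(n_res):
        x = 7.0 * i
        for nm, el, p in [("N", "N", (x + 3, 5, 0)), ("H", "H", (x + 3, 4, 0)),
                          ("CA", "C", (x + 1.5, 6, 0)), ("C", "C", (x, 4.4, 0)),
                          ("O", "O", (x, 3.2, 0))]:
            atoms.append(Atom(serial, nm, el, "GLY", i + 1, "B", np.array(p, float)))
            serial += 1
    return Structure(atoms)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def fibril():
    return sd.make_fibril(sd.FibrilSpec(), seed=0)


@pytest.fixture(scope="session")
def dissociation_traj(fibril):
    st, _ = fibril
    return sd.make_dissociation_trajectory(st, n_frames=10,
                                           displacement_per_frame=0.2, seed=0)
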