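"""Synthetic inputs with known ground truth for every analysis stage.

Every generator is a deterministic function of its parameters and a seed
(int or :class:`numpy.random.SeedSequence`), so each downstream operator
can be exercised against machine-readable ground truth without any
external data:

* :func:`make_fibril` — a toy stacked-β-subunit fibril (default six
  chains, 4.8 Å stacking rise) with planted inter-chain hydrogen bonds
  and Lys Nζ–Glu Cδ salt bridges whose counts are returned exactly;
* :func:`make_dissociation_trajectory` — the first subunit pulled away
  from the stack on a linear schedule (the dissociation signature);
* :func:`gen_tht_curve` — Boltzmann-sigmoid fluorescence plus noise;
* :func:`gen_particles` — three-class particle-area mixtures aligned to
  the TEM classification thresholds;
* :func:`gen_recording` — Poisson trains of biexponential postsynaptic
  currents on Gaussian baseline noise, with condition presets calibrated
  so that event rate, mean amplitude and whole-recording charge jointly
  match the printed per-condition statistics (the kernel decay is solved
  per preset from charge = rate x duration x mean event area).

The fibril is a geometric scaffold, not a chemically ideal model: atom
placements are chosen so the planted features meet the detection criteria
exactly and nothing else does.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from .agg_kinetics import BoltzmannParams, ThTCurve, boltzmann
from .ephys_analysis import Event, Recording
from .structio import Atom, Structure, Trajectory
from .tem_particles import ParticleSet

__all__ = [
    "FibrilSpec",
    "FibrilGroundTruth",
    "ConditionPreset",
    "ParticleMixSpec",
    "load_presets",
    "get_psc_preset",
    "get_particle_preset",
    "get_tht_preset",
    "make_fibril",
    "make_dissociation_trajectory",
    "gen_tht_curve",
    "gen_particles",
    "gen_recording",
]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionPreset:
    """Synaptic-recording condition: target event statistics + kinetics."""

    label: str
    event_rate_hz: float
    mean_amplitude_pa: float
    expected_charge_nc: float | None  # per reference duration; None -> default decay
    amplitude_cv: float = 0.4
    rise_ms: float = 2.0
    decay_ms: float = 10.0  # used when expected_charge_nc is None
    noise_sd_pa: float = 5.0
    sampling_rate_hz: float = 2000.0
    reference_duration_s: float = 300.0
    ttx: bool = False  # miniature (TTX) mode: metadata only

    def __post_init__(self) -> None:
        for name in ("event_rate_hz", "mean_amplitude_pa", "amplitude_cv",
                     "rise_ms", "decay_ms", "sampling_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ParticleMixSpec:
    """Three-class area mixture (monomer, dimer, trimer proportions)."""

    label: str
    proportions: tuple[float, float, float]
    n: int = 500
    # per-class area ranges (nm²) aligned to the classification thresholds
    monomer_range: tuple[float, float] = (50.0, 350.0)
    dimer_range: tuple[float, float] = (350.0, 800.0)
    trimer_range: tuple[float, float] = (800.0, 2000.0)

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")


def load_presets() -> dict:
    """Parse the packaged presets file (users may edit their own copy)."""
    text = (
        importlib.resources.files("synucleo").joinpath("data/presets.yaml").read_text()
    )
    return yaml.safe_load(text)


def get_psc_preset(name: str, kind: str | None = None) -> ConditionPreset:
    """Look up a spontaneous ('spsc') or miniature ('mpsc') PSC preset."""
    cfg = load_presets()
    kinds = [kind] if kind else ["spsc", "mpsc"]
    for k in kinds:
        if name in cfg.get(k, {}):
            entry = cfg[k][name]
            d = cfg["event_defaults"]
            return ConditionPreset(
                label=name,
                event_rate_hz=entry["event_rate_hz"],
                mean_amplitude_pa=entry["mean_amplitude_pa"],
                expected_charge_nc=entry.get("expected_charge_nc"),
                amplitude_cv=d["amplitude_cv"],
                rise_ms=d["rise_ms"],
                decay_ms=d["decay_ms"],
                noise_sd_pa=d["noise_sd_pa"],
                sampling_rate_hz=d["sampling_rate_hz"],
                reference_duration_s=d["reference_duration_s"],
                ttx=(k == "mpsc"),
            )
    raise KeyError(f"unknown PSC preset {name!r}")


def get_particle_preset(name: str, n: int = 500) -> ParticleMixSpec:
    cfg = load_presets()
    if name not in cfg.get("tem", {}):
        raise KeyError(f"unknown TEM preset {name!r}")
    return ParticleMixSpec(name, tuple(cfg["tem"][name]["proportions"]), n=n)


def get_tht_preset(name: str) -> BoltzmannParams:
    cfg = load_presets()
    if name not in cfg.get("tht", {}):
        raise KeyError(f"unknown ThT preset {name!r}")
    e = cfg["tht"][name]
    return BoltzmannParams(e["A1"], e["A2"], e["x0"], e["dx"])


# ---------------------------------------------------------------------------
# toy fibril
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FibrilSpec:
    n_subunits: int = 6
    residues_per_subunit: int = 10
    stacking_rise: float = 4.8  # Å, fixture design parameter
    # residue indices (1-based) carrying a planted Lys/Glu salt-bridge column
    salt_bridge_positions: tuple[int, ...] = (5,)
    jitter_sd: float = 0.0  # Å thermal jitter on all coordinates

    def __post_init__(self) -> None:
        if self.n_subunits < 2:
            raise ValueError("need at least two subunits")
        for p in self.salt_bridge_positions:
            if not 1 <= p <= self.residues_per_subunit:
                raise ValueError(f"salt-bridge position {p} outside 1..{self.residues_per_subunit}")


@dataclass
class FibrilGroundTruth:
    n_inter_hbonds: int
    n_intra_hbonds: int
    n_inter_salt_bridges: int
    n_intra_salt_bridges: int
    salt_bridge_distance: float  # Å between every planted Nζ–Cδ pair
    adjacent_com_distance: float  # Å between neighbouring subunit COMs
    chain_ids: list[str]


_RESIDUE_SPACING = 4.8  # Å along the strand axis; sparse enough to avoid
# accidental contacts between planted features

# per-residue backbone template, offsets from (x_i, 0, z_c):
#   N at origin, amide H pointing down the fibril axis toward the chain
#   below, carbonyl O displaced up toward the chain above so that every
#   residue of chain c+1 donates N-H...O=C to residue i of chain c with
#   X-Y = sqrt(1 + 3^2) = 3.16 Å and an X-H-Y angle of 153 deg.
_TEMPLATE = {
    "N": (0.0, 0.0, 0.0),
    "H": (0.0, 0.0, -1.0),
    "CA": (1.6, 1.2, 0.0),
    "C": (2.6, 0.6, 0.9),
    "O": (1.0, 0.0, 1.8),
}
# planted charged-group offsets: Nζ 2.0 Å above / Cδ 2.0 Å below the chain
# plane with a 3.92 Å lateral offset, giving exactly 4.0 Å between Nζ(c)
# and Cδ(c+1) while the intra-chain Nζ(c)-Cδ(c) distance stays at 5.6 Å
# (outside the 4.5 Å criterion).
_NZ_OFFSET = (0.0, 4.0, 2.0)
_CD_OFFSET = (0.0, 7.92, -2.0)


def make_fibril(
    spec: FibrilSpec | None = None, seed: int | np.random.SeedSequence = 0
) -> tuple[Structure, FibrilGroundTruth]:
    """Build a parallel in-register stacked-strand fibril with ground truth.

    Chains A, B, C, ... are exact translates along z separated by the
    stacking rise, so adjacent-chain COM distances equal the rise.  Every
    residue of chain c >= 1 donates one hydrogen bond to chain c-1
    (inter-chain bonds only), and each planted salt-bridge column yields
    one Nζ–Cδ pair at exactly 4.0 Å per adjacent chain pair.
    """
    spec = spec or FibrilSpec()
    rng = _rng(seed)
    n_res = spec.residues_per_subunit
    chains = [chr(ord("A") + c) for c in range(spec.n_subunits)]
    atoms: list[Atom] = []
    serial = 1
    for c, chain_id in enumerate(chains):
        z = c * spec.stacking_rise
        for i in range(1, n_res + 1):
            x = i * _RESIDUE_SPACING
            resname = "LYS" if i in spec.salt_bridge_positions else (
                "GLU" if i - 1 in spec.salt_bridge_positions else "ALA"
            )
            for name, (dx, dy, dz) in _TEMPLATE.items():
                element = "H" if name == "H" else name[0]
                atoms.append(
                    Atom(serial, name, element, resname, i, chain_id,
                         np.array([x + dx, dy, z + dz]))
                )
                serial += 1
            if resname == "LYS":
                atoms.append(
                    Atom(serial, "NZ", "N", resname, i, chain_id,
                         np.array([x + _NZ_OFFSET[0], _NZ_OFFSET[1], z + _NZ_OFFSET[2]]))
                )
                serial += 1
            if resname == "GLU":
                # side chain leans back over the Lys column position
                xk = (i - 1) * _RESIDUE_SPACING
                atoms.append(
                    Atom(serial, "CD", "C", resname, i, chain_id,
                         np.array([xk + _CD_OFFSET[0], _CD_OFFSET[1], z + _CD_OFFSET[2]]))
                )
                serial += 1
    structure = Structure(atoms)
    if spec.jitter_sd > 0:
        structure = structure.with_positions(
            structure.positions + rng.normal(0, spec.jitter_sd, (structure.n_atoms, 3))
        )
    truth = FibrilGroundTruth(
        n_inter_hbonds=(spec.n_subunits - 1) * n_res,
        n_intra_hbonds=0,
        n_inter_salt_bridges=(spec.n_subunits - 1) * len(spec.salt_bridge_positions),
        n_intra_salt_bridges=0,
        salt_bridge_distance=4.0,
        adjacent_com_distance=spec.stacking_rise,
        chain_ids=chains,
    )
    return structure, truth


def make_dissociation_trajectory(
    fibril: Structure,
    n_frames: int = 10,
    displacement_per_frame: float = 0.2,
    jitter_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> Trajectory:
    """Pull the first chain away from the stack on a linear schedule.

    Frame k displaces chain S1 (the first chain) by
    k x displacement_per_frame Å along -z (away from its neighbour), with
    optional Gaussian thermal jitter on all coordinates; every other chain
    stays fixed.  Frame 0 is the input conformation.
    """
    if n_frames < 2:
        raise ValueError("need at least two frames")
    rng = _rng(seed)
    first_chain = fibril.chains[0]
    mask = np.array([a.chain_id == first_chain for a in fibril.atoms])
    base = fibril.positions
    frames = []
    for k in range(n_frames):
        coords = base.copy()
        coords[mask, 2] -= k * displacement_per_frame
        if jitter_sd > 0:
            coords = coords + rng.normal(0, jitter_sd, coords.shape)
        frames.append(coords)
    return Trajectory(fibril, frames)


# ---------------------------------------------------------------------------
# ideal peptide backbones (secondary-structure test geometries)
# ---------------------------------------------------------------------------


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from A-B-C internal coordinates (natural extension)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(angle),
         bond * np.sin(angle) * np.cos(torsion),
         bond * np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# standard backbone internal coordinates (Å, degrees)
_BB = {
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231,
    "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2, "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.8, "omega": 180.0,
}


def make_ideal_backbone(
    phi: float, psi: float, n_res: int,
    chain_id: str = "A", residue_name: str = "ALA",
    start_serial: int = 1, start_residue: int = 1,
) -> Structure:
    """Poly-peptide backbone (N, CA, C, O) with uniform (φ, ψ) dihedrals.

    Standard bond lengths/angles and trans peptide bonds; e.g.
    (φ, ψ) = (−57°, −47°) builds an ideal α-helix and (−180°, 180°) a
    fully extended chain.  No hydrogens: the secondary-structure assigner
    reconstructs amide H from this geometry.
    """
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    coords: dict[tuple[int, str], np.ndarray] = {}
    coords[(0, "N")] = np.zeros(3)
    coords[(0, "CA")] = np.array([_BB["n_ca"], 0.0, 0.0])
    ang = np.radians(180.0 - _BB["ang_n_ca_c"])
    coords[(0, "C")] = coords[(0, "CA")] + _BB["ca_c"] * np.array(
        [np.cos(ang), np.sin(ang), 0.0]
    )
    for i in range(n_res):
        if i > 0:
            coords[(i, "N")] = _nerf(
                coords[(i - 1, "N")], coords[(i - 1, "CA")], coords[(i - 1, "C")],
                _BB["c_n"], _BB["ang_ca_c_n"], psi,
            )
            coords[(i, "CA")] = _nerf(
                coords[(i - 1, "CA")], coords[(i - 1, "C")], coords[(i, "N")],
                _BB["n_ca"], _BB["ang_c_n_ca"], _BB["omega"],
            )
            coords[(i, "C")] = _nerf(
                coords[(i - 1, "C")], coords[(i, "N")], coords[(i, "CA")],
                _BB["ca_c"], _BB["ang_n_ca_c"], phi,
            )
        coords[(i, "O")] = _nerf(
            coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
            _BB["c_o"], _BB["ang_ca_c_o"], psi + 180.0,
        )
    atoms: list[Atom] = []
    serial = start_serial
    for i in range(n_res):
        for name in ("N", "CA", "C", "O"):
            atoms.append(
                Atom(serial, name, name[0], residue_name, start_residue + i,
                     chain_id, coords[(i, name)])
            )
            serial += 1
    return Structure(atoms)


# ---------------------------------------------------------------------------
# ThT curves
# ---------------------------------------------------------------------------


def gen_tht_curve(
    params: BoltzmannParams,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    condition_label: str = "",
) -> ThTCurve:
    """Boltzmann-sigmoid fluorescence evaluated at ``times`` plus noise."""
    times = np.asarray(times, dtype=float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    y = boltzmann(times, *params.as_array())
    if noise_sd > 0:
        y = y + _rng(seed).normal(0, noise_sd, len(times))
    return ThTCurve(times, y, condition_label)


# ---------------------------------------------------------------------------
# particle mixtures
# ---------------------------------------------------------------------------


def gen_particles(
    spec: ParticleMixSpec, seed: int | np.random.SeedSequence = 0
) -> ParticleSet:
    """Multinomial class membership, uniform areas within each class range."""
    rng = _rng(seed)
    counts = rng.multinomial(spec.n, spec.proportions)
    ranges = (spec.monomer_range, spec.dimer_range, spec.trimer_range)
    areas = np.concatenate(
        [rng.uniform(lo, hi, c) for (lo, hi), c in zip(ranges, counts)]
    )
    rng.shuffle(areas)
    return ParticleSet(areas, spec.label)


# ---------------------------------------------------------------------------
# synaptic recordings
# ---------------------------------------------------------------------------


def _biexp_kernel(rise_ms: float, decay_ms: float, fs: float) -> np.ndarray:
    """Unit-peak biexponential (decay − rise), truncated at 8 decay times."""
    tau_r, tau_d = rise_ms * 1e-3, decay_ms * 1e-3
    t = np.arange(0, 8 * tau_d, 1.0 / fs)
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    return k / k.max()


def _kernel_area_per_pa(rise_ms: float, decay_ms: float) -> float:
    """Area (pA·s per pA of peak amplitude) of the unit-peak kernel."""
    tau_r, tau_d = rise_ms * 1e-3, decay_ms * 1e-3
    t_peak = np.log(tau_d / tau_r) * tau_d * tau_r / (tau_d - tau_r)
    peak = np.exp(-t_peak / tau_d) - np.exp(-t_peak / tau_r)
    return (tau_d - tau_r) / peak


def solve_decay_for_charge(preset: ConditionPreset) -> float:
    """Kernel decay (ms) making rate x duration x mean event area equal the
    preset's expected charge; falls back to the default decay when the
    preset prints no charge."""
    if preset.expected_charge_nc is None:
        return preset.decay_ms
    target_area = (
        preset.expected_charge_nc * 1e3  # nC -> pA·s
        / (preset.event_rate_hz * preset.reference_duration_s)
    )
    target_per_pa = target_area / preset.mean_amplitude_pa

    def f(decay_ms: float) -> float:
        return _kernel_area_per_pa(preset.rise_ms, decay_ms) - target_per_pa

    lo, hi = preset.rise_ms * 1.001 + 1e-6, 5000.0
    if f(lo) > 0:
        return lo
    return float(brentq(f, lo, hi, xtol=1e-6))


def gen_recording(
    preset: ConditionPreset,
    duration: float = 300.0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[Recording, list[Event]]:
    """Simulate one voltage-clamp recording plus its injected ground truth.

    Homogeneous Poisson event onsets at the preset rate; log-normal
    amplitudes with the preset mean and CV; unit-peak biexponential
    kernels (decay solved from the preset charge) superposed as inward
    (negative) deflections on Gaussian baseline noise.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed)
    fs = preset.sampling_rate_hz
    n = int(round(duration * fs))
    decay_ms = solve_decay_for_charge(preset)
    kernel = _biexp_kernel(preset.rise_ms, decay_ms, fs)
    area_per_pa = _kernel_area_per_pa(preset.rise_ms, decay_ms)

    n_events = rng.poisson(preset.event_rate_hz * duration)
    onsets = np.sort(rng.uniform(0, duration, n_events))
    sigma2 = np.log(1.0 + preset.amplitude_cv**2)
    mu = np.log(preset.mean_amplitude_pa) - sigma2 / 2.0
    amps = rng.lognormal(mu, np.sqrt(sigma2), n_events)

    current = np.zeros(n)
    truth: list[Event] = []
    for t0, a in zip(onsets, amps):
        i0 = int(round(t0 * fs))
        if i0 >= n:
            continue
        seg = kernel[: n - i0]
        current[i0 : i0 + len(seg)] -= a * seg
        t_peak = t0 + np.log(decay_ms / preset.rise_ms) * (
            decay_ms * preset.rise_ms / (decay_ms - preset.rise_ms)
        ) * 1e-3
        truth.append(Event(t0, max(t_peak, t0 + 0.5 / fs), float(a), float(a * area_per_pa)))
    if preset.noise_sd_pa > 0:
        current += rng.normal(0, preset.noise_sd_pa, n)
    rec = Recording(fs, current, condition_label=preset.label)
    return rec, truth
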