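"""Synthetic test systems with known ground truth.

Two generators make the whole pipeline testable without any external data:

* :func:`synth_dye_ensemble` emulates the conformational ensemble of a free
  FRET probe. A small probe chain (attachment triad N/CA/C, a four-carbon
  linker and a terminal "fluorophore" atom) is rebuilt by forward
  kinematics from sampled torsion angles: a rotameric state is drawn from
  given probabilities, wrapped Gaussian noise is added to its torsions, and
  idealized bond lengths/angles fill in the Cartesian geometry. The drawn
  state per frame is returned as ground truth.

* :func:`synth_rod_system` builds a minimal rigid poly-alanine-like system
  with two labelable residues at a controllable separation — a stand-in for
  rod-like spectroscopic-ruler peptides — optionally with a dense ball of
  obstruction atoms that guarantees steric clashes at one site in
  designated frames.

Both are pure functions of their seeded specs, so every downstream result
is exactly reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import nerf_place, wrap_deg
from .libgen import DyeEnsemble, ProbeMeta, RotamerLibrary
from .placement import ProteinEnsemble

__all__ = [
    "PROBE_ATOMS",
    "SyntheticDyeSpec",
    "SyntheticSystemSpec",
    "synth_dye_ensemble",
    "synth_rod_system",
    "single_rotamer_library",
]

# (name, element, charge); CZ plays the fluorophore central atom
PROBE_ATOMS = [
    ("N", "N", 0.0),
    ("CA", "C", 0.0),
    ("C", "C", 0.0),
    ("CB", "C", 0.0),
    ("CG", "C", 0.0),
    ("CD", "C", 0.0),
    ("CE", "C", 0.0),
    ("CZ", "C", 0.0),
]
_BOND = 1.53
_ANGLE = 111.0

PROBE_META = ProbeMeta(dipole_atoms=("CE", "CZ"), center_atom="CZ")

#: torsion definitions (atom indices) of the probe: chi1..chi3
PROBE_DIHEDRALS = [(0, 1, 3, 4), (1, 3, 4, 5), (3, 4, 5, 6)]


@dataclass
class SyntheticDyeSpec:
    """Ground-truth description of a synthetic dye ensemble.

    Defaults emulate a probe hopping between three rotameric states with
    populations 0.6/0.3/0.1, 8 degrees of angular noise and 2000 frames.
    """

    states: np.ndarray = field(
        default_factory=lambda: np.array(
            [[-60.0, 180.0, 60.0], [180.0, 60.0, -60.0], [60.0, -60.0, 180.0]]
        )
    )
    probabilities: np.ndarray = field(default_factory=lambda: np.array([0.6, 0.3, 0.1]))
    noise_sd: float = 8.0
    n_frames: int = 2000
    seed: int = 0

    def __post_init__(self):
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.states.shape[0] != self.probabilities.size:
            raise ValueError("one probability per state required")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("state probabilities must sum to 1")
        if self.states.shape[1] != len(PROBE_DIHEDRALS):
            raise ValueError(f"states must define {len(PROBE_DIHEDRALS)} torsions")


def _probe_coords(torsions: np.ndarray) -> np.ndarray:
    """Probe Cartesian coordinates from its three torsions (degrees)."""
    xyz = np.empty((len(PROBE_ATOMS), 3))
    xyz[0] = (0.0, 0.0, 0.0)  # N
    xyz[1] = (1.458, 0.0, 0.0)  # CA
    # C and CB both bond to CA with idealized geometry
    xyz[2] = nerf_place(np.array([0.0, 1.0, 1.0]), xyz[0], xyz[1], 1.52, 116.0, 122.0)
    xyz[3] = nerf_place(xyz[2], xyz[0], xyz[1], _BOND, _ANGLE, -121.0)  # CB
    for t, quad in enumerate(PROBE_DIHEDRALS):
        prev = quad[:3]
        xyz[quad[3]] = nerf_place(
            xyz[prev[0]], xyz[prev[1]], xyz[prev[2]], _BOND, _ANGLE, torsions[t]
        )
    # terminal fluorophore atom CZ, fixed anti torsion off the chain end
    xyz[7] = nerf_place(xyz[4], xyz[5], xyz[6], _BOND, _ANGLE, 180.0)
    return xyz


def synth_dye_ensemble(spec: SyntheticDyeSpec) -> tuple[DyeEnsemble, np.ndarray]:
    """Sample a dye ensemble; returns (ensemble, true state index per frame)."""
    rng = np.random.default_rng(spec.seed)
    states_idx = rng.choice(spec.states.shape[0], size=spec.n_frames, p=spec.probabilities)
    torsions = wrap_deg(
        spec.states[states_idx] + rng.normal(0.0, spec.noise_sd, size=(spec.n_frames, spec.states.shape[1]))
    )
    frames = np.stack([_probe_coords(t) for t in torsions])
    atoms = pd.DataFrame(PROBE_ATOMS, columns=["name", "element", "charge"])
    ens = DyeEnsemble(
        atoms=atoms,
        frames=frames,
        dihedral_definitions=list(PROBE_DIHEDRALS),
        probe_meta=PROBE_META,
    )
    return ens, states_idx


# idealized alanine-like residue template, CA at the origin
_RESIDUE_TEMPLATE = [
    ("N", "N", np.array([-1.458, 0.0, 0.0])),
    ("CA", "C", np.array([0.0, 0.0, 0.0])),
    ("C", "C", np.array([0.55, 1.42, 0.0])),
    ("O", "O", np.array([1.60, 1.60, 0.62])),
    ("CB", "C", np.array([0.53, -0.77, 1.20])),
]


@dataclass
class SyntheticSystemSpec:
    """A two-site rigid 'protein' with controllable inter-site distance.

    ``separation`` is the CA-CA distance (Å) between the labelable residues
    1 and 2 of chain A. ``obstruct_frames`` lists frame indices in which a
    dense carbon ball (radius ``obstruction_radius``, grid spacing 0.8 Å)
    sits on residue 2's CA, clashing with every rotamer placed there; in
    all other frames the ball is parked far away. ``jitter_sd`` adds seeded
    Gaussian coordinate noise.
    """

    separation: float = 50.0
    n_frames: int = 40
    obstruct_frames: tuple[int, ...] = ()
    obstruction_radius: float = 3.0
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        if any(not 0 <= f < self.n_frames for f in self.obstruct_frames):
            raise ValueError("obstruct_frames out of range")


def _obstruction_ball(radius: float, spacing: float = 0.8) -> np.ndarray:
    g = np.arange(-radius, radius + spacing / 2, spacing)
    pts = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
    return pts[np.linalg.norm(pts, axis=1) <= radius]


def synth_rod_system(spec: SyntheticSystemSpec) -> ProteinEnsemble:
    """Build the rod ensemble described by ``spec``."""
    rows = []
    base = []
    for resid, offset in ((1, np.zeros(3)), (2, np.array([0.0, 0.0, spec.separation]))):
        for name, element, xyz in _RESIDUE_TEMPLATE:
            rows.append((name, resid, "ALA", "A", element, 0.0))
            base.append(xyz + offset)
    ball = _obstruction_ball(spec.obstruction_radius)
    ball_center = np.array([0.0, 0.0, spec.separation])  # residue 2 CA
    parked = ball + ball_center + np.array([1000.0, 1000.0, 1000.0])
    if spec.obstruct_frames:
        for k in range(len(ball)):
            rows.append((f"X{k}", 99, "OBS", "Z", "C", 0.0))
    base = np.asarray(base)

    rng = np.random.default_rng(spec.seed)
    frames = []
    for s in range(spec.n_frames):
        xyz = base.copy()
        if spec.jitter_sd > 0:
            xyz = xyz + rng.normal(0.0, spec.jitter_sd, size=xyz.shape)
        if spec.obstruct_frames:
            ob = ball + ball_center if s in spec.obstruct_frames else parked
            xyz = np.vstack([xyz, ob])
        frames.append(xyz)
    atoms = pd.DataFrame(
        rows, columns=["name", "resid", "resname", "chain", "element", "charge"]
    )
    return ProteinEnsemble(atoms=atoms, frames=np.stack(frames))


def single_rotamer_library(
    name: str = "point-probe",
    center_offset=(0.0, 0.0, 0.0),
    dipole_direction=(1.0, 0.0, 0.0),
    weight: float = 1.0,
) -> RotamerLibrary:
    """A degenerate one-rotamer library for analytic anchor tests.

    The fluorophore central atom sits at ``center_offset`` from the
    attachment CA (in the attachment-local frame) and the transition dipole
    points along ``dipole_direction``. With the offset at the origin the
    inter-dye distance equals the inter-site CA-CA distance exactly.
    """
    center = np.asarray(center_offset, dtype=float)
    direction = np.asarray(dipole_direction, dtype=float)
    n = np.linalg.norm(direction)
    if n == 0:
        raise ValueError("dipole_direction must be non-zero")
    direction = direction / n
    # local-frame triad mirrors _probe_coords geometry: N along -x from CA
    coords = np.array(
        [
            [-1.458, 0.0, 0.0],  # N
            [0.0, 0.0, 0.0],  # CA
            [0.55, 1.42, 0.0],  # C
            list(center),  # D1 (dipole tail)
            list(center + direction),  # D2 (dipole head = central atom)
        ]
    )
    meta = ProbeMeta(dipole_atoms=("D1", "D2"), center_atom="D1")
    return RotamerLibrary(
        name=name,
        coords=coords[None, :, :],
        weights=np.array([weight]),
        atom_names=["N", "CA", "C", "D1", "D2"],
        elements=["N", "C", "C", "C", "C"],
        charges=np.zeros(5),
        meta=meta,
        cutoff_class="custom",
    )
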