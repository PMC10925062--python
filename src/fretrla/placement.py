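"""Placement of rotamer libraries on labeled protein sites.

Each library conformer is rigidly superposed (least-squares, proper rotation
only) onto the backbone triad N/CA/C of the labeled residue of every frame
of the protein ensemble. Probe-protein Lennard-Jones (optionally screened
Coulomb) energies within a cutoff then give per-rotamer Boltzmann weights
combined with the library's intrinsic populations. Donor and acceptor are
treated independently; a frame where every rotamer of either dye clashes
with the protein is non-viable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .geometry import kabsch
from .libgen import RotamerLibrary

__all__ = [
    "KB_KJ_MOL_K",
    "ProteinEnsemble",
    "LabeledSite",
    "EnergyConfig",
    "PlacementResult",
    "SiteResolutionError",
    "attach_rotamers",
    "nonbonded_energies",
    "boltzmann_weights",
    "frame_viability",
    "place_library",
    "load_nonbonded_params",
]

#: Boltzmann constant in kJ mol^-1 K^-1
KB_KJ_MOL_K = 0.008314462618
#: Coulomb prefactor e^2/(4 pi eps0) in kJ mol^-1 A e^-2
COULOMB_KJ_MOL_A = 1389.35458

#: protein atoms of the labeled residue kept in the energy environment.
#: The probe chemically replaces the side chain from CB onward (its own CB
#: superposes onto the native one), and N/CA/C are the attachment, so only
#: the backbone carbonyl/amide atoms of the labeled residue remain.
_SITE_KEEP = {"O", "H", "HA", "HN", "OXT"}


class SiteResolutionError(KeyError):
    """A labeled site does not resolve to a residue with backbone N/CA/C."""


@dataclass
class ProteinEnsemble:
    """Topology + coordinates of the system to be labeled.

    ``atoms``: DataFrame with columns name, resid, resname, chain, element,
    charge. ``frames``: (N, A, 3) ndarray in Å.
    """

    atoms: pd.DataFrame
    frames: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must have shape (N >= 1, A, 3)")
        if self.frames.shape[1] != len(self.atoms):
            raise ValueError(
                f"atom count mismatch: table has {len(self.atoms)}, "
                f"frames have {self.frames.shape[1]}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in ensemble")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def residue_mask(self, site: "LabeledSite") -> np.ndarray:
        m = self.atoms["resid"].to_numpy() == site.resid
        if site.chain is not None:
            m &= self.atoms["chain"].to_numpy() == site.chain
        return m

    def backbone_indices(self, site: "LabeledSite") -> dict[str, int]:
        """Indices of the site's N, CA, C atoms; raises if any is missing."""
        mask = self.residue_mask(site)
        names = self.atoms["name"].to_numpy()
        out = {}
        for bb in ("N", "CA", "C"):
            hits = np.flatnonzero(mask & (names == bb))
            if hits.size != 1:
                raise SiteResolutionError(
                    f"site chain={site.chain!r} resid={site.resid}: backbone atom "
                    f"{bb!r} {'missing' if hits.size == 0 else 'ambiguous'}"
                )
            out[bb] = int(hits[0])
        return out


@dataclass(frozen=True)
class LabeledSite:
    """A residue to be labeled, identified by topology residue id and chain."""

    resid: int
    chain: str | None = None


def load_nonbonded_params(path=None) -> dict[str, tuple[float, float]]:
    """Load the per-element (sigma Å, epsilon kJ/mol) table from YAML.

    Without ``path`` the packaged default table is used.
    """
    if path is None:
        text = resources.files("fretrla").joinpath("data/nonbonded.yml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {
        str(k).upper(): (float(v["sigma"]), float(v["epsilon"])) for k, v in raw.items()
    }


@dataclass
class EnergyConfig:
    """Parameters of the probe-protein interaction model.

    cutoff : float
        Pair cutoff in Å (default 10 Å = 1.0 nm).
    temperature : float
        Temperature in K used for Boltzmann weighting.
    electrostatics : bool
        Add Coulomb terms screened by a uniform relative dielectric.
    dielectric : float
        Relative dielectric constant (default 78.5, water-like).
    clash_energy : float
        Rotamers with total energy above this (kJ/mol) are treated as
        clashing (weight 0).
    clash_sigma_factor : float
        Pair distances below this fraction of the combined sigma contribute
        +inf, avoiding overflow of the r^-12 term.
    """

    cutoff: float = 10.0
    temperature: float = 298.0
    electrostatics: bool = False
    dielectric: float = 78.5
    clash_energy: float = 1.0e3
    clash_sigma_factor: float = 0.4
    params: dict[str, tuple[float, float]] = field(default_factory=load_nonbonded_params)

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class PlacementResult:
    """Per-frame, per-rotamer placement of one library on one site."""

    site: LabeledSite
    library: RotamerLibrary
    coords: np.ndarray  # (N, K, A, 3)
    energies: np.ndarray  # (N, K) kJ/mol, may contain +inf
    weights: np.ndarray  # (N, K), rows sum to 1 on viable frames, else 0
    partition: np.ndarray  # (N,) Z_s

    @property
    def viable(self) -> np.ndarray:
        return self.partition > 0.0


def attach_rotamers(
    ensemble: ProteinEnsemble,
    frame: int,
    site: LabeledSite,
    library: RotamerLibrary,
    rmsd_warn: float = 0.5,
) -> np.ndarray:
    """Rigidly transform all library conformers onto the site backbone.

    The mean attachment triad of the library (N, CA, C in the local frame)
    is superposed least-squares onto the site's backbone triad; rotation +
    translation only. Returns transformed coordinates, shape (K, A, 3).
    """
    bb = ensemble.backbone_indices(site)
    target = ensemble.frames[frame][[bb["N"], bb["CA"], bb["C"]]]
    tri = library.attachment_indices()
    source = library.coords[:, tri, :].mean(axis=0)
    R, t = kabsch(source, target)
    moved = library.coords @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((source @ R.T + t - target) ** 2, axis=-1))))
    if rmsd > rmsd_warn:
        warnings.warn(
            f"attachment superposition RMSD {rmsd:.2f} Å at site {site}: "
            "library and backbone geometries disagree",
            stacklevel=2,
        )
    return moved


def _environment_mask(ensemble: ProteinEnsemble, site: LabeledSite) -> np.ndarray:
    """Protein atoms counted in the energy: everything except the labeled
    residue's side chain beyond CB and its backbone attachment atoms."""
    site_mask = ensemble.residue_mask(site)
    names = ensemble.atoms["name"].to_numpy()
    keep_of_site = np.isin(names, sorted(_SITE_KEEP))
    return ~site_mask | (site_mask & keep_of_site)


def nonbonded_energies(
    placed: np.ndarray,
    ensemble: ProteinEnsemble,
    frame: int,
    site: LabeledSite,
    library: RotamerLibrary,
    config: EnergyConfig,
) -> np.ndarray:
    """Probe-protein nonbonded energy per rotamer, kJ/mol (+inf on overlap).

    Lennard-Jones with per-element parameters and Lorentz-Berthelot
    combination over all probe-atom/protein-atom pairs within the cutoff;
    optionally a Coulomb term screened by a uniform dielectric. The probe's
    attachment triad is excluded on the probe side (those atoms coincide
    with the protein backbone).
    """
    placed = np.asarray(placed, dtype=float)
    env_mask = _environment_mask(ensemble, site)
    env_xyz = ensemble.frames[frame][env_mask]
    env_elem = ensemble.atoms.loc[env_mask, "element"].to_numpy()
    env_q = ensemble.atoms.loc[env_mask, "charge"].to_numpy(dtype=float)
    env_names = ensemble.atoms.loc[env_mask, "name"].to_numpy()

    tri = set(library.attachment_indices())
    probe_idx = np.array([i for i in range(placed.shape[1]) if i not in tri])
    probe_xyz = placed[:, probe_idx]  # (K, P, 3)
    probe_elem = np.asarray(library.elements, dtype=object)[probe_idx]
    probe_q = np.asarray(library.charges, dtype=float)[probe_idx]

    def lj(elem_list, what):
        out = np.empty((len(elem_list), 2))
        for i, e in enumerate(elem_list):
            key = str(e).upper()
            if key not in config.params:
                raise KeyError(
                    f"no nonbonded parameters for element {key!r} ({what} atom {i})"
                )
            out[i] = config.params[key]
        return out

    p_par = lj(probe_elem, "probe")
    e_par = lj(env_elem, f"protein ({', '.join(map(str, env_names[:3]))}...)")

    # prune environment atoms that no rotamer can reach
    centers = probe_xyz.reshape(-1, 3)
    lo = centers.min(axis=0) - config.cutoff
    hi = centers.max(axis=0) + config.cutoff
    near = np.all((env_xyz >= lo) & (env_xyz <= hi), axis=1)
    env_xyz, e_par, env_q = env_xyz[near], e_par[near], env_q[near]

    K = probe_xyz.shape[0]
    U = np.zeros(K)
    if env_xyz.shape[0] == 0:
        return U
    sig = 0.5 * (p_par[:, None, 0] + e_par[None, :, 0])  # (P, E) Lorentz

    eps = np.sqrt(p_par[:, None, 1] * e_par[None, :, 1])
    for k in range(K):
        d = np.linalg.norm(probe_xyz[k][:, None, :] - env_xyz[None, :, :], axis=-1)
        within = d < config.cutoff
        if np.any(within & (d < config.clash_sigma_factor * sig)):
            U[k] = np.inf
            continue
        with np.errstate(divide="ignore"):
            sr6 = np.where(within, (sig / d) ** 6, 0.0)
        u = np.sum(4.0 * eps * (sr6**2 - sr6))
        if config.electrostatics:
            with np.errstate(divide="ignore"):
                coul = np.where(
                    within,
                    COULOMB_KJ_MOL_A * probe_q[:, None] * env_q[None, :] / (config.dielectric * d),
                    0.0,
                )
            u += coul.sum()
        U[k] = u
    U[U > config.clash_energy] = np.inf
    return U


def boltzmann_weights(
    energies: np.ndarray, intrinsic: np.ndarray, temperature: float
) -> tuple[np.ndarray, float]:
    """Combine intrinsic library populations with Boltzmann factors.

    p_i = pi_i exp(-U_i / kT) / Z with Z = sum_j pi_j exp(-U_j / kT).
    Returns (p, Z); Z = 0 (all rotamers clash) gives p = 0 everywhere and
    marks the frame non-viable.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    U = np.asarray(energies, dtype=float)
    pi = np.asarray(intrinsic, dtype=float)
    if U.shape != pi.shape:
        raise ValueError("energies and intrinsic weights differ in length")
    kt = KB_KJ_MOL_K * temperature
    with np.errstate(over="ignore"):
        factors = np.where(np.isfinite(U), np.exp(-np.clip(U / kt, -700.0, 700.0)), 0.0)
    w = pi * factors
    Z = float(w.sum())
    if Z == 0.0:
        return np.zeros_like(w), 0.0
    return w / Z, Z


def frame_viability(z_donor: np.ndarray, z_acceptor: np.ndarray) -> np.ndarray:
    """A frame is viable iff both dyes retain weight after clash masking."""
    return (np.asarray(z_donor) > 0.0) & (np.asarray(z_acceptor) > 0.0)


def place_library(
    ensemble: ProteinEnsemble,
    site: LabeledSite,
    library: RotamerLibrary,
    config: EnergyConfig,
) -> PlacementResult:
    """Attach, score and weight one library on one site for every frame."""
    N = ensemble.n_frames
    K = library.n_rotamers
    A = library.coords.shape[1]
    coords = np.empty((N, K, A, 3))
    energies = np.empty((N, K))
    weights = np.empty((N, K))
    partition = np.empty(N)
    for s in range(N):
        placed = attach_rotamers(ensemble, s, site, library)
        coords[s] = placed
        U = nonbonded_energies(placed, ensemble, s, site, library, config)
        p, Z = boltzmann_weights(U, library.weights, config.temperature)
        energies[s], weights[s], partition[s] = U, p, Z
    return PlacementResult(
        site=site,
        library=library,
        coords=coords,
        energies=energies,
        weights=weights,
        partition=partition,
    )
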