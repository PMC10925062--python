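"""Rotamer-library generation from a dye conformational ensemble.

A FRET probe (fluorophore + linker) attached to a protein explores a large
conformational space. The rotamer-library approach compresses a dye
conformational ensemble — however produced — into a small set of discrete
conformers ("rotamers") with intrinsic populations, by clustering in the
space of the linker/dye torsion angles:

1. torsions are extracted for every ensemble frame;
2. per-torsion circular histograms are scanned for peaks, and the Cartesian
   product of peak angles forms the candidate ("C1") cluster centers;
3. frames are assigned to the nearest C1 center by least-squares periodic
   angle deviation;
4. each center is refined to the circular mean of its members ("C2");
5. frames are re-assigned to the C2 centers;
6. clusters with populations below a cutoff are dropped, yielding libraries
   conventionally called *large*, *medium* and *small* for cutoffs of
   10, 20 and 30 frames.

The retained representative conformers are stored in an attachment-local
frame defined by the probe's backbone-like attachment triad (N, CA, C), so a
library can later be rigidly placed onto any labeled protein site.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    attachment_frame,
    circular_mean,
    dihedrals,
    to_local,
    wrap_deg,
)

__all__ = [
    "ProbeMeta",
    "DyeEnsemble",
    "ClusterCenter",
    "ClusteringConfig",
    "RotamerLibrary",
    "extract_dihedral_series",
    "build_c1_centers",
    "assign_to_centers",
    "refine_centers",
    "filter_by_population",
    "fluorophore_projection",
    "build_library",
    "isotropy_score",
]

#: conventional population cutoffs (frames) for the three library sizes
DEFAULT_CUTOFFS = {"large": 10, "medium": 20, "small": 30}


@dataclass(frozen=True)
class ProbeMeta:
    """Atom-name metadata describing a FRET probe.

    Attributes
    ----------
    dipole_atoms : tuple of str
        The two atoms whose difference vector defines the transition dipole.
    center_atom : str
        Central atom of the fluorophore; used as the distance-reference
        point between donor and acceptor.
    attachment_atoms : tuple of str
        The backbone-like triad (N, CA, C) used to place the probe on a
        labeled residue.
    """

    dipole_atoms: tuple[str, str]
    center_atom: str
    attachment_atoms: tuple[str, str, str] = ("N", "CA", "C")


@dataclass
class DyeEnsemble:
    """A conformational ensemble of a free dye + linker.

    ``atoms`` is a table with columns ``name``, ``element``, ``charge``;
    ``frames`` has shape (T, A, 3) in Å; ``dihedral_definitions`` is an
    ordered list of 4-tuples of atom indices defining the rotatable torsions.
    """

    atoms: pd.DataFrame
    frames: np.ndarray
    dihedral_definitions: list[tuple[int, int, int, int]]
    probe_meta: ProbeMeta | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must have shape (T >= 1, A, 3)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in ensemble")
        n_atoms = self.frames.shape[1]
        for d, quad in enumerate(self.dihedral_definitions):
            if len(set(quad)) != 4 or any(not 0 <= i < n_atoms for i in quad):
                raise ValueError(f"dihedral definition {d} is invalid: {quad}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def atom_index(self, name: str) -> int:
        hits = np.flatnonzero(self.atoms["name"].to_numpy() == name)
        if hits.size != 1:
            raise KeyError(f"atom {name!r} not uniquely present in ensemble")
        return int(hits[0])


@dataclass
class ClusterCenter:
    """A cluster center in torsion space."""

    angles: np.ndarray  # (D,) degrees, each in (-180, 180]
    population: int = 0
    rep_frame: int | None = None  # index of the representative ensemble frame
    degenerate_mean: bool = False  # circular mean was undefined; fallback used


@dataclass
class ClusteringConfig:
    """Tunables of the torsion clustering.

    ``bin_width`` (degrees) sets the circular-histogram resolution for peak
    detection; ``peak_fraction`` is the minimum occupancy of a peak bin as a
    fraction of the number of frames; ``max_candidates`` truncates the C1
    Cartesian product by descending joint empirical support. Population
    ``cutoffs`` follow the large/medium/small convention.
    """

    bin_width: float = 10.0
    peak_fraction: float = 0.02
    max_candidates: int = 2000
    cutoffs: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    seed: int | None = None  # reserved; the pipeline is deterministic

    def __post_init__(self):
        c = self.cutoffs
        if not (0 < c["large"] < c["medium"] < c["small"]):
            raise ValueError("cutoffs must be positive with large < medium < small")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


@dataclass
class RotamerLibrary:
    """A filtered set of dye conformers in the attachment-local frame.

    ``coords`` has shape (K, A, 3); ``weights`` are the intrinsic rotamer
    populations normalized to 1. Atom metadata mirrors the source ensemble.
    """

    name: str
    coords: np.ndarray
    weights: np.ndarray
    atom_names: list[str]
    elements: list[str]
    charges: np.ndarray
    meta: ProbeMeta
    cutoff_class: str = "custom"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise ValueError("library must contain at least one conformer")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("intrinsic weights must sum to 1")
        names = set(self.atom_names)
        for a in (*self.meta.dipole_atoms, self.meta.center_atom, *self.meta.attachment_atoms):
            if a not in names:
                raise ValueError(f"metadata atom {a!r} missing from conformers")

    @property
    def n_rotamers(self) -> int:
        return self.coords.shape[0]

    def atom_index(self, name: str) -> int:
        try:
            return self.atom_names.index(name)
        except ValueError:
            raise KeyError(f"atom {name!r} not in library {self.name!r}") from None

    def attachment_indices(self) -> list[int]:
        return [self.atom_index(a) for a in self.meta.attachment_atoms]


def extract_dihedral_series(ensemble: DyeEnsemble) -> np.ndarray:
    """Torsion-angle time series, shape (T, D), degrees in (-180, 180]."""
    if not ensemble.dihedral_definitions:
        raise ValueError("ensemble defines no dihedrals")
    cols = []
    for d, (i, j, k, l) in enumerate(ensemble.dihedral_definitions):
        try:
            cols.append(
                dihedrals(
                    ensemble.frames[:, i],
                    ensemble.frames[:, j],
                    ensemble.frames[:, k],
                    ensemble.frames[:, l],
                )
            )
        except ValueError as err:
            raise ValueError(f"dihedral {d} {(i, j, k, l)}: {err}") from err
    return np.column_stack(cols)


def _histogram_peaks(series: np.ndarray, config: ClusteringConfig) -> np.ndarray:
    """Peak angles of the circular histogram of one torsion series.

    A peak is a bin strictly more occupied than both circular neighbours and
    holding at least ``peak_fraction`` of the frames. The returned angle is
    the circular mean of the samples in the peak bin, so a one-point
    histogram peaks exactly at that point.
    """
    T = series.size
    nbins = max(1, int(round(360.0 / config.bin_width)))
    edges = np.linspace(-180.0, 180.0, nbins + 1)
    # map the (-180, 180] convention onto numpy's half-open bins
    shifted = np.where(series == 180.0, -180.0, series)
    counts, _ = np.histogram(shifted, bins=edges)
    threshold = max(1, int(np.ceil(config.peak_fraction * T)))
    if nbins == 1:
        is_peak = counts >= threshold
    else:
        left = np.roll(counts, 1)
        right = np.roll(counts, -1)
        is_peak = (counts > left) & (counts > right) & (counts >= threshold)
        if not np.any(is_peak):
            # plateaus (equal neighbours) still count if strictly above some bin
            is_peak = (counts >= left) & (counts >= right) & (counts >= threshold)
            if counts.max() == counts.min():
                is_peak[:] = False
    peaks = []
    which = np.digitize(shifted, edges[1:-1])
    for b in np.flatnonzero(is_peak):
        members = series[which == b]
        mean, _ = circular_mean(members)
        peaks.append(float(mean))
    if not peaks:
        raise ValueError("no histogram peak found (flat torsion distribution)")
    return np.array(sorted(peaks))


def build_c1_centers(angles: np.ndarray, config: ClusteringConfig | None = None) -> list[ClusterCenter]:
    """Candidate (C1) centers: Cartesian product of per-torsion histogram peaks.

    Candidates are ordered by descending joint empirical support (frames
    whose per-torsion nearest peak matches the combination) and truncated to
    ``config.max_candidates``.
    """
    config = config or ClusteringConfig()
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    T, D = angles.shape
    peak_lists = [_histogram_peaks(angles[:, d], config) for d in range(D)]
    # per-torsion nearest peak per frame
    nearest = np.empty((T, D), dtype=int)
    for d, peaks in enumerate(peak_lists):
        diff = np.abs(wrap_deg(angles[:, d, None] - peaks[None, :]))
        nearest[:, d] = np.argmin(diff, axis=1)
    combos = list(itertools.product(*[range(len(p)) for p in peak_lists]))
    support = {c: 0 for c in combos}
    for row in map(tuple, nearest):
        support[row] += 1
    order = sorted(range(len(combos)), key=lambda i: (-support[combos[i]], i))
    centers = []
    for i in order[: config.max_candidates]:
        combo = combos[i]
        ang = np.array([peak_lists[d][combo[d]] for d in range(D)])
        centers.append(ClusterCenter(angles=ang, population=support[combo]))
    return centers


def assign_to_centers(angles: np.ndarray, centers: list[ClusterCenter]) -> np.ndarray:
    """Assign each frame to the center minimizing the summed squared periodic
    angle deviation; ties break to the lowest center index."""
    if not centers:
        raise ValueError("need at least one center")
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    C = np.stack([c.angles for c in centers])  # (K, D)
    diff = wrap_deg(angles[:, None, :] - C[None, :, :])
    ssd = np.sum(diff**2, axis=2)
    return np.argmin(ssd, axis=1)


def _ssd_to(angles_block: np.ndarray, center: np.ndarray) -> np.ndarray:
    return np.sum(wrap_deg(angles_block - center) ** 2, axis=-1)


def refine_centers(
    angles: np.ndarray,
    labels: np.ndarray,
    c1_centers: list[ClusterCenter],
) -> list[ClusterCenter]:
    """C2 centers: circular mean of each C1 cluster's member angles.

    Empty clusters are dropped. If the circular mean of some torsion is
    undefined (mean resultant length ~ 0), the member closest to the C1
    center is used instead and the center is flagged ``degenerate_mean``.
    The representative frame is the member minimizing the squared periodic
    deviation from the C2 angles.
    """
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    labels = np.asarray(labels)
    out: list[ClusterCenter] = []
    for k, c1 in enumerate(c1_centers):
        members = np.flatnonzero(labels == k)
        if members.size == 0:
            continue
        block = angles[members]
        mean, resultant = circular_mean(block, axis=0)
        degenerate = bool(np.any(resultant < 1e-6))
        if degenerate:
            closest = members[np.argmin(_ssd_to(block, c1.angles))]
            mean = angles[closest].copy()
        rep = members[np.argmin(_ssd_to(block, mean))]
        out.append(
            ClusterCenter(
                angles=np.asarray(mean, dtype=float).reshape(-1),
                population=int(members.size),
                rep_frame=int(rep),
                degenerate_mean=degenerate,
            )
        )
    return out


def _repopulate(centers: list[ClusterCenter], angles: np.ndarray, labels: np.ndarray) -> list[ClusterCenter]:
    """Recompute populations/representatives after re-assignment, keeping angles fixed."""
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    out = []
    for k, c in enumerate(centers):
        members = np.flatnonzero(labels == k)
        if members.size == 0:
            continue
        rep = members[np.argmin(_ssd_to(angles[members], c.angles))]
        out.append(
            ClusterCenter(
                angles=c.angles.copy(),
                population=int(members.size),
                rep_frame=int(rep),
                degenerate_mean=c.degenerate_mean,
            )
        )
    return out


def filter_by_population(
    centers: list[ClusterCenter],
    cutoff: int,
    ensemble: DyeEnsemble,
    meta: ProbeMeta | None = None,
    name: str = "library",
    cutoff_class: str = "custom",
) -> RotamerLibrary:
    """Drop clusters with population < ``cutoff`` and build a library.

    Intrinsic weights are the normalized retained populations; conformer
    coordinates are the representative frames re-expressed in the
    attachment-local frame (attachment CA at the origin).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    meta = meta or ensemble.probe_meta
    if meta is None:
        raise ValueError("probe metadata required to build a library")
    kept = [c for c in centers if c.population >= cutoff]
    if not kept:
        raise ValueError(
            f"no cluster reaches the population cutoff {cutoff}; try a smaller cutoff"
        )
    pops = np.array([c.population for c in kept], dtype=float)
    idx_triad = [ensemble.atom_index(a) for a in meta.attachment_atoms]
    conformers = []
    for c in kept:
        if c.rep_frame is None:
            raise ValueError("cluster centers carry no representative frames")
        xyz = ensemble.frames[c.rep_frame]
        origin, basis = attachment_frame(xyz[idx_triad[0]], xyz[idx_triad[1]], xyz[idx_triad[2]])
        conformers.append(to_local(xyz, origin, basis))
    return RotamerLibrary(
        name=name,
        coords=np.stack(conformers),
        weights=pops / pops.sum(),
        atom_names=list(ensemble.atoms["name"]),
        elements=list(ensemble.atoms["element"]),
        charges=ensemble.atoms["charge"].to_numpy(dtype=float),
        meta=meta,
        cutoff_class=cutoff_class,
    )


def build_library(
    ensemble: DyeEnsemble,
    cutoff: int,
    config: ClusteringConfig | None = None,
    name: str = "library",
    cutoff_class: str = "custom",
) -> RotamerLibrary:
    """End-to-end library construction (torsions -> C1 -> C2 -> filter).

    Deterministic for a fixed ensemble and configuration.
    """
    config = config or ClusteringConfig()
    angles = extract_dihedral_series(ensemble)
    c1 = build_c1_centers(angles, config)
    labels1 = assign_to_centers(angles, c1)
    c2 = refine_centers(angles, labels1, c1)
    labels2 = assign_to_centers(angles, c2)
    c2 = _repopulate(c2, angles, labels2)
    return filter_by_population(
        c2, cutoff, ensemble, name=name, cutoff_class=cutoff_class
    )


def fluorophore_projection(library: RotamerLibrary) -> np.ndarray:
    """(x, y) of the fluorophore central atom per conformer, attachment CA at
    the origin — the standard anisotropy QC plot for a rotamer library."""
    ci = library.atom_index(library.meta.center_atom)
    return library.coords[:, ci, :2].copy()


def isotropy_score(projection: np.ndarray) -> float:
    """Ratio (smaller/larger) of the planar-covariance eigenvalues of a
    fluorophore projection; 1 is perfectly isotropic in the plane."""
    p = np.asarray(projection, dtype=float)
    cov = np.cov(p.T) if p.shape[0] > 1 else np.zeros((2, 2))
    ev = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))
    if ev[-1] <= 0:
        return 1.0
    return float(ev[0] / ev[-1])
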