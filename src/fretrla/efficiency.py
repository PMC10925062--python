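"""FRET efficiency: orientation factor, Förster radius and ensemble averages.

The transfer efficiency between a donor/acceptor rotamer pair at distance r
with orientation factor κ² is

    E(r, κ²) = (1 + (2 / (3 κ²)) (r / R0)^6)^-1,

where R0 is the isotropic (κ² = 2/3) Förster radius; at κ² = 2/3 this
reduces to the familiar E = R0^6 / (r^6 + R0^6). Ensemble averages over N
protein frames and all l x m donor/acceptor rotamer pairs are computed in
three regimes distinguished by the timescales of linker-distance (τ_l) and
dye-orientation (τ_k) motion relative to the fluorescence lifetime (τ_f):

* static (τ_l, τ_k >> τ_f): every (frame, rotamer pair) contributes its own
  efficiency, weighted by the independent rotamer weights p_si p_sj;
* dynamic (τ_k << τ_f << τ_l): orientations pre-average, so a single global
  ⟨κ²⟩ (weighted over all frames and pairs) enters each efficiency;
* dynamic+ (τ_l, τ_k << τ_f): the transfer *rate* is averaged within each
  frame, giving per-frame A_s = Σ (3/2) κ² (R0/r)^6 p p and E_s = A_s/(1+A_s).

Frames with steric clashes are discarded (weight 0); the remainder are
weighted equally by default, or by energy-based/user-supplied frame weights.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ForsterParams",
    "PairGrid",
    "EfficiencyResult",
    "NoViableFramesError",
    "kappa_squared",
    "forster_radius",
    "point_efficiency",
    "build_pair_grids",
    "average_static",
    "average_dynamic",
    "average_dynamic_plus",
    "regime_average",
    "kish_effective_fraction",
    "reweight_frames",
    "compute_efficiencies",
]

ISOTROPIC_KAPPA2 = 2.0 / 3.0


class NoViableFramesError(RuntimeError):
    """Every ensemble frame was discarded for steric clashes."""


def kappa_squared(mu_donor, mu_acceptor, displacement):
    """Orientation factor κ² for dipole direction vectors and the
    inter-fluorophore displacement; inputs are normalized internally and
    broadcast over leading axes.

    κ² = (μ̂_D · μ̂_A − 3 (R̂ · μ̂_A)(R̂ · μ̂_D))², bounded in [0, 4].
    """

    def unit(v, label):
        v = np.asarray(v, dtype=float)
        n = np.linalg.norm(v, axis=-1, keepdims=True)
        if np.any(n <= 0.0):
            raise ValueError(f"zero-length {label} vector")
        return v / n

    mu_d = unit(mu_donor, "donor dipole")
    mu_a = unit(mu_acceptor, "acceptor dipole")
    rh = unit(displacement, "displacement")
    dot = np.einsum("...i,...i->...", mu_d, mu_a)
    pd_ = np.einsum("...i,...i->...", rh, mu_d)
    pa = np.einsum("...i,...i->...", rh, mu_a)
    return (dot - 3.0 * pa * pd_) ** 2


def forster_radius(j, kappa2, quantum_yield, refractive_index):
    """Förster radius R0 = 0.02108 (J κ² Q_D n^-4)^(1/6).

    ``j`` is the donor-emission/acceptor-absorption spectral overlap in
    nm^4 M^-1 cm^-1, ``quantum_yield`` the donor quantum yield and
    ``refractive_index`` that of the medium. κ² = 0 gives R0 = 0.
    """
    if j <= 0 or quantum_yield <= 0 or refractive_index <= 0:
        raise ValueError("J, Q_D and n must be positive")
    k2 = np.asarray(kappa2, dtype=float)
    if np.any(k2 < 0):
        raise ValueError("kappa2 must be non-negative")
    return 0.02108 * (j * k2 * quantum_yield * refractive_index**-4) ** (1.0 / 6.0)


def point_efficiency(r, kappa2, r0):
    """E(r, κ²) with isotropic Förster radius ``r0``; κ² = 0 gives E = 0."""
    r = np.asarray(r, dtype=float)
    k2 = np.asarray(kappa2, dtype=float)
    if np.any(r <= 0) or r0 <= 0:
        raise ValueError("r and r0 must be positive")
    # (2/3)/k2 keeps E(r0, 2/3) exactly 1/2 (x/x == 1 in IEEE arithmetic)
    with np.errstate(divide="ignore"):
        term = (2.0 / 3.0) / k2 * (r / r0) ** 6
    return 1.0 / (1.0 + term)


@dataclass
class ForsterParams:
    """R0 policy: ``mode='fixed'`` with ``r0`` in Å, or ``mode='kappa'``
    with spectral parameters, in which case the isotropic radius
    R0(κ²=2/3) anchors the κ²-dependent efficiencies.

    Writing the per-pair κ²-dependent radius R0(κ²)^6 = (3/2) κ² R0_iso^6
    into (1 + (r/R0(κ²))^6)^-1 is algebraically identical to evaluating
    E(r, κ²) with R0_iso, so a single code path serves both views.
    """

    mode: str = "kappa"
    r0: float | None = None  # Å, fixed mode
    j: float | None = None  # nm^4 M^-1 cm^-1
    quantum_yield: float | None = None
    refractive_index: float | None = None

    def __post_init__(self):
        if self.mode not in ("fixed", "kappa"):
            raise ValueError("mode must be 'fixed' or 'kappa'")
        if self.mode == "fixed":
            if self.r0 is None or self.r0 <= 0:
                raise ValueError("fixed mode requires a positive r0 (Å)")
        else:
            if any(v is None for v in (self.j, self.quantum_yield, self.refractive_index)):
                raise ValueError("kappa mode requires j, quantum_yield and refractive_index")

    def r0_iso(self) -> float:
        """The isotropic Förster radius (Å) entering E(r, κ²)."""
        if self.mode == "fixed":
            return float(self.r0)
        return float(
            forster_radius(self.j, ISOTROPIC_KAPPA2, self.quantum_yield, self.refractive_index)
        )


@dataclass
class PairGrid:
    """Per-frame donor x acceptor rotamer-pair geometry and weights.

    ``r`` and ``kappa2`` have shape (N, l, m); ``w_donor`` (N, l) and
    ``w_acceptor`` (N, m) are the independent rotamer weights whose outer
    product is the joint pair weight. ``z_donor``/``z_acceptor`` are the
    per-frame partition values used for frame reweighting.
    """

    r: np.ndarray
    kappa2: np.ndarray
    w_donor: np.ndarray
    w_acceptor: np.ndarray
    z_donor: np.ndarray
    z_acceptor: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.kappa2 = np.asarray(self.kappa2, dtype=float)
        if self.r.shape != self.kappa2.shape or self.r.ndim != 3:
            raise ValueError("r and kappa2 must share shape (N, l, m)")
        if np.any(self.r <= 0):
            raise ValueError("pair distances must be positive")
        if np.any((self.kappa2 < 0) | (self.kappa2 > 4)):
            raise ValueError("kappa2 out of [0, 4]")

    @property
    def n_frames(self) -> int:
        return self.r.shape[0]

    @property
    def viable(self) -> np.ndarray:
        return (np.asarray(self.z_donor) > 0) & (np.asarray(self.z_acceptor) > 0)

    def transpose(self) -> "PairGrid":
        """Swap donor and acceptor roles (κ² is symmetric; r transposes)."""
        return PairGrid(
            r=self.r.transpose(0, 2, 1),
            kappa2=self.kappa2.transpose(0, 2, 1),
            w_donor=self.w_acceptor,
            w_acceptor=self.w_donor,
            z_donor=self.z_acceptor,
            z_acceptor=self.z_donor,
        )


def build_pair_grids(donor_placement, acceptor_placement) -> PairGrid:
    """Distances and orientation factors for all donor/acceptor rotamer pairs.

    Distances are between the fluorophore central (distance-reference)
    atoms; dipole direction vectors come from each library's dipole atom
    pair. Placements must cover the same protein frames.
    """
    dp, ap = donor_placement, acceptor_placement
    if dp.coords.shape[0] != ap.coords.shape[0]:
        raise ValueError(
            f"frame-count mismatch: donor {dp.coords.shape[0]}, acceptor {ap.coords.shape[0]}"
        )
    dlib, alib = dp.library, ap.library
    dc = dp.coords[:, :, dlib.atom_index(dlib.meta.center_atom)]  # (N, l, 3)
    ac = ap.coords[:, :, alib.atom_index(alib.meta.center_atom)]  # (N, m, 3)
    d1, d2 = (dlib.atom_index(a) for a in dlib.meta.dipole_atoms)
    a1, a2 = (alib.atom_index(a) for a in alib.meta.dipole_atoms)
    mu_d = dp.coords[:, :, d2] - dp.coords[:, :, d1]  # (N, l, 3)
    mu_a = ap.coords[:, :, a2] - ap.coords[:, :, a1]  # (N, m, 3)
    disp = ac[:, None, :, :] - dc[:, :, None, :]  # (N, l, m, 3)
    r = np.linalg.norm(disp, axis=-1)
    k2 = kappa_squared(mu_d[:, :, None, :], mu_a[:, None, :, :], disp)
    return PairGrid(
        r=r,
        kappa2=np.clip(k2, 0.0, 4.0),
        w_donor=dp.weights,
        w_acceptor=ap.weights,
        z_donor=dp.partition,
        z_acceptor=ap.partition,
    )


def _frame_weights(grid: PairGrid, frame_weights=None) -> np.ndarray:
    """Normalized frame weights; default is uniform over viable frames."""
    viable = grid.viable
    if frame_weights is None:
        w = viable.astype(float)
    else:
        w = np.asarray(frame_weights, dtype=float).copy()
        if w.shape != (grid.n_frames,):
            raise ValueError("frame weights must have one entry per frame")
        if np.any(w < 0):
            raise ValueError("frame weights must be non-negative")
        w[~viable] = 0.0
    total = w.sum()
    if total == 0.0:
        raise NoViableFramesError("no viable frames (all discarded for clashes)")
    return w / total


def average_static(grid: PairGrid, params: ForsterParams, frame_weights=None):
    """Static-regime average: every (frame, pair) keeps its own (r, κ²)."""
    w = _frame_weights(grid, frame_weights)
    E = point_efficiency(grid.r, grid.kappa2, params.r0_iso())
    per_frame = np.einsum("sij,si,sj->s", E, grid.w_donor, grid.w_acceptor)
    return float(w @ per_frame), per_frame


def average_dynamic(grid: PairGrid, params: ForsterParams, frame_weights=None):
    """Dynamic-regime average using a single global ⟨κ²⟩.

    Returns (⟨E⟩, per-frame E, ⟨κ²⟩); per-frame values already use the
    global ⟨κ²⟩.
    """
    w = _frame_weights(grid, frame_weights)
    k2_frame = np.einsum("sij,si,sj->s", grid.kappa2, grid.w_donor, grid.w_acceptor)
    k2_mean = float(w @ k2_frame)
    E = point_efficiency(grid.r, k2_mean, params.r0_iso())
    per_frame = np.einsum("sij,si,sj->s", E, grid.w_donor, grid.w_acceptor)
    return float(w @ per_frame), per_frame, k2_mean


def average_dynamic_plus(grid: PairGrid, params: ForsterParams, frame_weights=None):
    """Dynamic+ average: the rate is pre-averaged within each frame."""
    w = _frame_weights(grid, frame_weights)
    r0 = params.r0_iso()
    rate = 1.5 * grid.kappa2 * (r0 / grid.r) ** 6
    A = np.einsum("sij,si,sj->s", rate, grid.w_donor, grid.w_acceptor)
    per_frame = A / (1.0 + A)
    return float(w @ per_frame), per_frame


def regime_average(e_static: float, e_dynamic: float, e_dynamic_plus: float) -> float:
    """Unweighted mean of the three regime estimates — the recommended
    summary when the relevant timescales are unknown."""
    return (e_static + e_dynamic + e_dynamic_plus) / 3.0


def kish_effective_fraction(weights: np.ndarray) -> float:
    """Kish effective sample size of a weight vector, as a fraction of N."""
    w = np.asarray(weights, dtype=float)
    total_sq = w.sum() ** 2
    if total_sq == 0.0:
        raise ValueError("all weights are zero")
    return float(total_sq / np.sum(w**2) / w.size)


def reweight_frames(z_donor, z_acceptor, user_weights=None):
    """Energy-based frame weights w_s ∝ Z_s^D Z_s^A u_s.

    Combines the per-frame donor/acceptor partition values (small where the
    probes interact unfavourably with the protein, zero on clash) with
    optional user-supplied statistical weights. Returns the normalized
    weights and the Kish effective frame fraction.
    """
    zd = np.asarray(z_donor, dtype=float)
    za = np.asarray(z_acceptor, dtype=float)
    if user_weights is None:
        u = np.ones_like(zd)
    else:
        u = np.asarray(user_weights, dtype=float)
        if u.shape != zd.shape:
            raise ValueError("user weights must have one entry per frame")
        if np.any(u < 0):
            raise ValueError("user weights must be non-negative")
    w = zd * za * u
    total = w.sum()
    if total == 0.0:
        raise NoViableFramesError("all reweighted frame weights are zero")
    w = w / total
    return w, kish_effective_fraction(w)


@dataclass
class EfficiencyResult:
    """Ensemble FRET efficiencies under the three averaging regimes."""

    e_static: float
    e_dynamic: float
    e_dynamic_plus: float
    e_mean: float
    kappa2_mean: float
    per_frame: pd.DataFrame = field(repr=False)
    frame_weights: np.ndarray = field(repr=False, default=None)
    effective_fraction: float = 1.0

    def summary_frame(self) -> pd.DataFrame:
        n = len(self.per_frame)
        return pd.DataFrame(
            {
                "E_static": [self.e_static],
                "E_dynamic": [self.e_dynamic],
                "E_dynamic_plus": [self.e_dynamic_plus],
                "E_mean": [self.e_mean],
                "kappa2_mean": [self.kappa2_mean],
                "effective_fraction": [self.effective_fraction],
                "n_frames": [n],
                "n_viable": [int(self.per_frame["viable"].sum())],
            }
        )

    def summary(self) -> str:
        lines = [
            "FRET efficiency (rotamer-library approach)",
            f"  frames: {len(self.per_frame)} "
            f"(viable: {int(self.per_frame['viable'].sum())}, "
            f"effective fraction: {self.effective_fraction:.3f})",
            f"  <kappa^2>          : {self.kappa2_mean:.4f}",
            f"  <E> static         : {self.e_static:.4f}",
            f"  <E> dynamic        : {self.e_dynamic:.4f}",
            f"  <E> dynamic+       : {self.e_dynamic_plus:.4f}",
            f"  <E> regime average : {self.e_mean:.4f}",
        ]
        return "\n".join(lines)


def compute_efficiencies(
    grid: PairGrid, params: ForsterParams, frame_weights=None
) -> EfficiencyResult:
    """All three regime averages plus their mean for one pair grid.

    ``frame_weights`` replaces the default uniform-over-viable weighting
    (non-viable frames are always forced to zero weight).
    """
    w = _frame_weights(grid, frame_weights)
    e_s, pf_s = average_static(grid, params, frame_weights)
    e_d, pf_d, k2 = average_dynamic(grid, params, frame_weights)
    e_p, pf_p = average_dynamic_plus(grid, params, frame_weights)
    k2_frame = np.einsum("sij,si,sj->s", grid.kappa2, grid.w_donor, grid.w_acceptor)
    per_frame = pd.DataFrame(
        {
            "frame": np.arange(grid.n_frames),
            "viable": grid.viable,
            "E_static": pf_s,
            "E_dynamic": pf_d,
            "E_dynamic_plus": pf_p,
            "kappa2": k2_frame,
            "Z_donor": np.asarray(grid.z_donor, dtype=float),
            "Z_acceptor": np.asarray(grid.z_acceptor, dtype=float),
            "weight": w,
        }
    )
    viable_w = w[grid.viable]
    eff = float(viable_w.sum() ** 2 / np.sum(viable_w**2) / grid.n_frames)
    return EfficiencyResult(
        e_static=e_s,
        e_dynamic=e_d,
        e_dynamic_plus=e_p,
        e_mean=regime_average(e_s, e_d, e_p),
        kappa2_mean=k2,
        per_frame=per_frame,
        frame_weights=w,
        effective_fraction=eff,
    )
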