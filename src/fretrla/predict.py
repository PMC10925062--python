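"""End-to-end FRET efficiency prediction for a labeled pair of sites.

:class:`EfficiencyPredictor` ties the pipeline together: place the donor and
acceptor libraries independently on every frame, build the rotamer-pair
distance/orientation grids, and average the efficiencies under the three
regimes. ``run()`` optionally writes per-frame and summary CSVs plus a
cache that lets ``reweight()`` (or the ``fretrla reweight`` command)
recompute the averages under energy-based and user-supplied frame weights
without re-running placement.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from .efficiency import (
    EfficiencyResult,
    ForsterParams,
    PairGrid,
    build_pair_grids,
    compute_efficiencies,
    reweight_frames,
)
from .libgen import RotamerLibrary
from .placement import EnergyConfig, LabeledSite, ProteinEnsemble, place_library

__all__ = ["EfficiencyPredictor", "MissingCacheError", "PER_FRAME_CSV", "SUMMARY_CSV"]

log = logging.getLogger(__name__)

PER_FRAME_CSV = "per_frame.csv"
SUMMARY_CSV = "summary.csv"
REWEIGHTED_PER_FRAME_CSV = "per_frame_reweighted.csv"
REWEIGHTED_SUMMARY_CSV = "summary_reweighted.csv"
_CACHE_NPZ = "pair_grid_cache.npz"
_CACHE_JSON = "run_config.json"
_FLOAT_FMT = "%.12g"


class MissingCacheError(FileNotFoundError):
    """reweight requested but no cached run output exists."""


class EfficiencyPredictor:
    """Predict FRET efficiencies for one donor/acceptor site pair.

    Parameters
    ----------
    ensemble : ProteinEnsemble
        Protein structure(s); one frame per conformation.
    donor_site, acceptor_site : LabeledSite
        Residues to which the probes are attached (topology numbering).
    donor_library, acceptor_library : RotamerLibrary
        Pre-built rotamer libraries for the two probes.
    forster : ForsterParams
        Fixed or κ²-dependent Förster radius policy.
    energy : EnergyConfig
        Nonbonded model (cutoff, temperature, electrostatics flag, ...).
    """

    def __init__(
        self,
        ensemble: ProteinEnsemble,
        donor_site: LabeledSite,
        acceptor_site: LabeledSite,
        donor_library: RotamerLibrary,
        acceptor_library: RotamerLibrary,
        forster: ForsterParams,
        energy: EnergyConfig | None = None,
    ):
        self.ensemble = ensemble
        self.donor_site = donor_site
        self.acceptor_site = acceptor_site
        self.donor_library = donor_library
        self.acceptor_library = acceptor_library
        self.forster = forster
        self.energy = energy or EnergyConfig()
        self._grid: PairGrid | None = None

    # -- pipeline ----------------------------------------------------------

    def _compute_grid(self) -> PairGrid:
        log.info(
            "placing %s on site %s and %s on site %s over %d frame(s)",
            self.donor_library.name,
            self.donor_site,
            self.acceptor_library.name,
            self.acceptor_site,
            self.ensemble.n_frames,
        )
        dp = place_library(self.ensemble, self.donor_site, self.donor_library, self.energy)
        ap = place_library(self.ensemble, self.acceptor_site, self.acceptor_library, self.energy)
        grid = build_pair_grids(dp, ap)
        for s in np.flatnonzero(~grid.viable):
            log.warning("frame %d discarded: all rotamers clash for at least one dye", s)
        return grid

    def run(self, out_dir: str | None = None) -> EfficiencyResult:
        """Full prediction; writes CSVs and the reweighting cache if
        ``out_dir`` is given."""
        self._grid = self._compute_grid()
        result = compute_efficiencies(self._grid, self.forster)
        if out_dir is not None:
            self._write(result, out_dir, reweighted=False)
            self._write_cache(out_dir)
        return result

    def reweight(
        self, user_weights=None, out_dir: str | None = None
    ) -> EfficiencyResult:
        """Recompute the averages with frame weights ∝ Z_D Z_A u_s.

        Reuses the cached pair grids from :meth:`run`; raises
        :class:`MissingCacheError` if ``run`` has not been performed.
        """
        if self._grid is None:
            raise MissingCacheError("call run() before reweight()")
        w, eff = reweight_frames(self._grid.z_donor, self._grid.z_acceptor, user_weights)
        result = compute_efficiencies(self._grid, self.forster, frame_weights=w)
        result.effective_fraction = eff
        if out_dir is not None:
            self._write(result, out_dir, reweighted=True)
        return result

    # -- persistence -------------------------------------------------------

    @staticmethod
    def _write(result: EfficiencyResult, out_dir: str, reweighted: bool) -> None:
        os.makedirs(out_dir, exist_ok=True)
        pf = REWEIGHTED_PER_FRAME_CSV if reweighted else PER_FRAME_CSV
        sm = REWEIGHTED_SUMMARY_CSV if reweighted else SUMMARY_CSV
        result.per_frame.to_csv(os.path.join(out_dir, pf), index=False, float_format=_FLOAT_FMT)
        result.summary_frame().to_csv(os.path.join(out_dir, sm), index=False, float_format=_FLOAT_FMT)

    def _write_cache(self, out_dir: str) -> None:
        g = self._grid
        np.savez_compressed(
            os.path.join(out_dir, _CACHE_NPZ),
            r=g.r,
            kappa2=g.kappa2,
            w_donor=g.w_donor,
            w_acceptor=g.w_acceptor,
            z_donor=g.z_donor,
            z_acceptor=g.z_acceptor,
        )
        with open(os.path.join(out_dir, _CACHE_JSON), "w") as fh:
            json.dump({"forster": asdict(self.forster)}, fh, indent=1)

    @staticmethod
    def reweight_from_cache(
        out_dir: str, user_weights=None, write: bool = True
    ) -> EfficiencyResult:
        """Reweight a previous run from its on-disk cache (CLI entry)."""
        npz_path = os.path.join(out_dir, _CACHE_NPZ)
        json_path = os.path.join(out_dir, _CACHE_JSON)
        if not (os.path.exists(npz_path) and os.path.exists(json_path)):
            raise MissingCacheError(
                f"no cached run in {out_dir!r}: run the prediction first"
            )
        with np.load(npz_path) as dat:
            grid = PairGrid(
                r=dat["r"],
                kappa2=dat["kappa2"],
                w_donor=dat["w_donor"],
                w_acceptor=dat["w_acceptor"],
                z_donor=dat["z_donor"],
                z_acceptor=dat["z_acceptor"],
            )
        with open(json_path) as fh:
            forster = ForsterParams(**json.load(fh)["forster"])
        w, eff = reweight_frames(grid.z_donor, grid.z_acceptor, user_weights)
        result = compute_efficiencies(grid, forster, frame_weights=w)
        result.effective_fraction = eff
        if write:
            EfficiencyPredictor._write(result, out_dir, reweighted=True)
        return result


def read_user_weights(path: str, n_frames: int | None = None) -> np.ndarray:
    """Read per-frame user weights from a one-column (or 'weight'-column) CSV."""
    df = pd.read_csv(path)
    col = "weight" if "weight" in df.columns else df.columns[-1]
    w = df[col].to_numpy(dtype=float)
    if n_frames is not None and w.size != n_frames:
        raise ValueError(f"user weights: expected {n_frames} rows, got {w.size}")
    return w
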