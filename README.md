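# fretrla

Prediction of Förster resonance energy transfer (FRET) efficiencies from
protein structures and conformational ensembles with the **rotamer-library
approach (RLA)**.

Single-molecule FRET reports on the distance between a donor and an
acceptor fluorophore attached to a protein through flexible linkers. To
compare a structural model or a simulation ensemble against measured
efficiencies, the conformational freedom of the probes themselves must be
modelled. The RLA does this cheaply: the dye+linker ensemble is compressed
once into a discrete set of conformers ("rotamers") with intrinsic
populations; for every protein conformation the donor and acceptor
libraries are rigidly placed on the labeled residues, each rotamer is
weighted by a Boltzmann factor of its nonbonded interaction with the
protein, and the efficiency is averaged over all rotamer pairs and frames.

## The model

For a donor/acceptor rotamer pair at distance *r* with orientation factor
κ², the transfer efficiency is

    E(r, κ²) = [ 1 + (2 / 3κ²) (r / R₀)⁶ ]⁻¹ ,
    κ²       = ( μ̂_D · μ̂_A − 3 (R̂ · μ̂_A)(R̂ · μ̂_D) )² ∈ [0, 4] ,

where R₀ is the isotropic (κ² = 2/3) Förster radius,
R₀ = 0.02108 (J κ² Q_D n⁻⁴)^{1/6} with spectral overlap *J*, donor quantum
yield *Q_D* and refractive index *n*; at κ² = 2/3 the efficiency reduces
to E = R₀⁶ / (r⁶ + R₀⁶).

Ensemble averages over *N* protein frames *s* and all donor/acceptor
rotamer pairs (*i*, *j*) with independent weights *p*<sub>si</sub>,
*p*<sub>sj</sub> are computed in three regimes, distinguished by the
timescales of linker-distance and dye-orientation motion relative to the
fluorescence lifetime:

* **static** — ⟨E⟩ = (1/N) Σ_s Σ_ij E(r_sij, κ²_sij) p_si p_sj;
* **dynamic** — as static but with a single global
  ⟨κ²⟩ = (1/N) Σ_s Σ_ij κ²_sij p_si p_sj (orientations pre-average);
* **dynamic+** — the transfer *rate* pre-averages within each frame:
  A_s = Σ_ij (3/2) κ²_sij (R₀/r_sij)⁶ p_si p_sj and E_s = A_s/(1+A_s).

When the relevant timescales are unknown, the mean of the three regime
estimates is a robust summary and is reported alongside them. Frames in
which every rotamer of either dye clashes sterically with the protein are
discarded; the remainder are weighted equally, or reweighted by the
per-frame partition values (w_s ∝ Z_s^D Z_s^A u_s, with optional user
weights u_s), reporting the Kish effective frame fraction.

Rotamer libraries are built from any dye conformational ensemble by
clustering in torsion space: per-torsion circular-histogram peaks define
candidate centers (the Cartesian product, "C1"), frames are assigned by
least-squares periodic angle deviation, centers are refined to circular
means ("C2"), and clusters below a population cutoff are dropped —
cutoffs 10/20/30 frames give the conventional *large*/*medium*/*small*
libraries.

## Worked example

The package ships seeded synthetic fixtures: a three-state dye ensemble
(populations 0.6/0.3/0.1) and a rigid two-residue "rod" with a
controllable inter-site distance.

```python
import numpy as np
from fretrla import ForsterParams, build_library
from fretrla.fixtures import (SyntheticDyeSpec, SyntheticSystemSpec,
                              synth_dye_ensemble, synth_rod_system)
from fretrla.placement import LabeledSite
from fretrla.predict import EfficiencyPredictor

ens, _ = synth_dye_ensemble(SyntheticDyeSpec())           # T = 2000 frames
lib = build_library(ens, cutoff=30, name="probe small")
print("rotamers:", lib.n_rotamers, "weights:", np.round(lib.weights, 3))

rod = synth_rod_system(SyntheticSystemSpec(separation=50.0, n_frames=5))
pred = EfficiencyPredictor(rod, LabeledSite(1, "A"), LabeledSite(2, "A"),
                     lib, lib, ForsterParams(mode="fixed", r0=50.0))
print(pred.run().summary())
```

prints

```
rotamers: 3 weights: [0.604 0.296 0.1  ]
FRET efficiency (rotamer-library approach)
  frames: 5 (viable: 5, effective fraction: 1.000)
  <kappa^2>          : 0.8353
  <E> static         : 0.5363
  <E> dynamic        : 0.5543
  <E> dynamic+       : 0.5554
  <E> regime average : 0.5487
```

The library builder recovers the three seeded rotameric states with their
populations (0.604/0.296/0.100). With the inter-site distance set equal to
the fixed R₀ of 50 Å the efficiencies sit near 1/2; they exceed it
slightly because the restricted probe orientations give ⟨κ²⟩ = 0.84 > 2/3.

The same prediction from the shell (R₀ is passed in **nm** on the command
line and converted internally to Å):

```bash
fretrla run --top rod.pdb --residues 1 2 --chains A A \
    --library-index lib/libraries.yml \
    --donor-lib "probe small" --acceptor-lib "probe small" \
    --fixed-r0 5.0 --out results/
fretrla reweight --out results/            # energy-based frame weights
```

`run` writes `per_frame.csv` (per-frame efficiencies, κ² contribution,
partition values, weights, viability) and `summary.csv` (the four ⟨E⟩
values, ⟨κ²⟩, effective frame fraction); `reweight` reuses the cached
per-frame grids without re-running placement.

**Residue numbering** follows the input topology verbatim. Published RLA
examples sometimes count residues from 0; check your file's convention
before choosing `--residues`.

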