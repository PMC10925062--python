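# Methods

This note documents the model implemented in `fretrla`, the defaults it
chooses where the underlying procedure is genuinely open, what the
synthetic fixtures do and do not emulate, and the package's known
limitations.

## Efficiency model and averaging regimes

The per-pair efficiency is E(r, κ²) = [1 + (2/3κ²)(r/R₀)⁶]⁻¹ with R₀ the
*isotropic* (κ² = 2/3) Förster radius. Two R₀ policies exist:

* **fixed** — the user supplies R₀ directly (Å in the API; nm on the
  command line, converted by ×10). This is the recommended mode for
  absolute comparisons, mirroring common practice of taking R₀ for the
  actual dye pair from tabulated values.
* **κ²-dependent** — R₀ is derived from the spectral parameters via
  R₀ = 0.02108 (J κ² Q_D n⁻⁴)^{1/6}. Note that writing the per-pair
  radius R₀(κ²)⁶ = (3/2) κ² R₀(2/3)⁶ into 1/(1+(r/R₀(κ²))⁶) is
  *algebraically identical* to evaluating E(r, κ²) with the isotropic
  radius, so a single code path serves both formulations; in the dynamic
  regime the single global ⟨κ²⟩ plays that role, consistent with the
  regime's single pre-averaged orientation factor.

  **Unit caveat:** with J in nm⁴ M⁻¹ cm⁻¹ the constant 0.02108 yields a
  radius numerically in nm under the conventional form of the equation
  (typical J ≈ 10¹⁵ gives ≈ 5–6). The function follows its source
  convention and labels the output Å; supply consistent units, or prefer
  fixed R₀ when absolute distances matter. Tests assert only scale-free
  properties of this function (sixth-root scaling, κ² = 0 → 0).

The three ensemble averages (static / dynamic / dynamic+) differ only in
where the averaging over orientation (κ²) and distance happens relative to
the sums over frames and rotamer pairs; all iterate over every donor ×
acceptor rotamer combination with independent weights p_si p_sj,
implemented as vectorized einsum contractions and verified against naive
triple-loop references to 1e−10. With a single rotamer per dye the
dynamic+ frame average is algebraically a no-op, so dynamic+ = static for
any ensemble, and all three regimes coincide when the frames are
identical. The regime mean (unweighted average of the three estimates) is
reported as a convenient summary when the experimental timescales are
unknown.

Degenerate inputs: κ² = 0 gives E = 0 (the limit, not an error); r = 0 is
rejected; κ² is clipped to [0, 4] against rounding at the boundary.

## Rotamer-library generation

Clustering operates in the space of the linker/dye torsions, in degrees on
(−180, 180] with the IUPAC sign convention.

* **Peak detection** uses a circular histogram with 10° bins (matching
  rotameric-state granularity); a peak is a bin strictly above both
  circular neighbours holding at least 2% of the frames, and its angle is
  the circular mean of the samples in the bin (so a one-point histogram
  peaks exactly at that point). The 2% floor is chosen so that a rotameric
  state populated at ~10% — spread over several bins by thermal noise —
  is still detected; a flat torsion distribution raises an error rather
  than inventing centers.
* **C1 candidates** are the Cartesian product of per-torsion peak angles,
  ordered by joint empirical support (frames whose per-torsion nearest
  peaks select that combination) and truncated at 2000 candidates; useful
  libraries should stay well below ~1000 rotamers.
* **Assignment** minimizes the sum of squared periodic angle deviations;
  ties break to the lowest center index, making the pipeline fully
  deterministic.
* **C2 refinement** replaces each center by the circular mean of its
  members, in a single pass (no iteration to convergence). If the mean
  resultant length of some torsion collapses (~0, e.g. antipodal members)
  the member closest to the C1 center is used and the center is flagged.
  Representative coordinates are the *member frame* closest to the C2
  angles — averaging Cartesian coordinates across a cluster can produce
  unphysical geometry.
* **Filtering** keeps clusters with population ≥ cutoff (10/20/30 for
  large/medium/small); intrinsic weights π_i are the normalized retained
  populations. Whether real published libraries use population-based or
  uniform intrinsic weights is not universally documented; population
  weights are the natural choice for an ensemble-derived library and are
  what the generator's ground truth validates.

Conformers are stored in an attachment-local frame (origin at the
attachment CA, x along CA→N, z along (CA→N)×(CA→C)), so the
fluorophore-position projection onto the local xy-plane doubles as the
standard anisotropy QC plot.

## Placement and weighting

Each conformer is rigidly superposed onto the labeled residue's N/CA/C
triad by least-squares (SVD with reflection excluded); a superposition
RMSD above 0.5 Å warns of library/backbone geometry mismatch. Whether a
larger atom set should anchor the superposition is an open question; three
backbone atoms define the frame exactly and suffice for rigid placement.

Probe–protein energies are summed over atom pairs within 10 Å (1.0 nm):
Lennard-Jones with a small per-element (σ, ε) table and Lorentz–Berthelot
combination, optionally plus Coulomb screened by a uniform relative
dielectric of 78.5. The element table is an editable YAML
(`fretrla/data/nonbonded.yml`); it is a deliberately generic default, not
a specific published force field — electrostatics and fine parameter
choices have been reported to have little effect on prediction accuracy,
and users can override the table per run. Exclusions: on the protein side,
the labeled residue's side chain from CB onward (the probe chemically
replaces it and the probe's own CB superposes onto the native one) and the
N/CA/C attachment atoms; on the probe side, the attachment triad. A bulky
native side chain therefore cannot veto placement.

Weights are p_si = π_i exp(−U_si/k_BT) / Z_s at the configured temperature
(default 298 K), following standard RLA practice of combining intrinsic
library populations with an external Boltzmann factor. Pair distances
below 0.4 σ contribute +∞ (avoiding r⁻¹² overflow), as do rotamers whose
total energy exceeds 10³ kJ/mol (numerically irrelevant next to the
Boltzmann factor, but it keeps partition values finite). Z_s = 0 for
either dye marks the frame non-viable.

## Reweighting

By default non-viable frames are discarded and the rest weighted equally.
`reweight` instead sets w_s ∝ Z_s^donor · Z_s^acceptor · u_s (u_s optional
user weights, e.g. from Bayesian/maximum-entropy ensemble refinement),
normalized over frames. The functional form — the product of the two
independent partition values — and the Kish effective sample size
(Σw)²/Σw² as the "effective frame fraction" are this package's choices;
they are the natural estimators but other conventions exist. Reweighting
reuses the cached per-frame pair grids, so no placement is repeated; the
uniform-weight case reproduces the unweighted averages bit-for-bit because
both paths run the identical weighted contraction.

## Synthetic fixtures: what they do and do not show

The dye-ensemble generator draws a rotameric state per frame from given
probabilities, adds wrapped Gaussian angular noise (adequate below ~20°
sd; a von Mises model would matter only for larger spreads) and rebuilds
coordinates by forward kinematics with idealized bond lengths (1.53 Å) and
angles (111°). It validates the clustering pipeline exactly — state
recovery, populations, determinism — but carries no dye photophysics,
solvation or torsional energetics, so passing tests demonstrate correct
*geometry and statistics*, not force-field realism.

The rod fixture is a rigid two-residue poly-alanine-like system with an
exact CA–CA separation; with engineered one-rotamer libraries whose pair
geometry gives κ² = 2/3 and r = R₀ it pins the analytic anchor E = 1/2
through the entire pipeline. Its obstruction variant parks a dense carbon
ball (3 Å radius, 0.8 Å grid) on one site's CA in designated frames —
close enough that any attached rotamer hard-clashes — giving exact ground
truth for frame viability. Real proteins have graded, partial occlusion;
the fixture only exercises the all-or-nothing limit. Problem sizes used
throughout (T = 2000 dye frames, ≤ 40 rod frames, libraries of ~3
rotamers) keep every check exact or statistically tight while the whole
suite runs in seconds.

## Known limitations

* No probe–probe (donor–acceptor) interaction energies; the two dyes are
  weighted independently.
* No bonded/torsional energy of the probe itself and no solvent model;
  intrinsic weights carry all internal energetics.
* No time-resolved observables and no diffusion-based averaging between
  the limiting regimes.
* Library quality is bounded by the input dye ensemble; the generator
  replaces, but cannot substitute for, thorough conformational sampling
  of a real probe.
* Prediction accuracy on real systems is bounded by the accuracy of the
  input protein ensemble — the method evaluates structures, it does not
  fix them.
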