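# Per-element Lennard-Jones parameters used for probe-protein interaction
# energies: sigma in angstrom, epsilon in kJ/mol. Values are generic
# force-field-like defaults; combine with Lorentz-Berthelot rules. Edit or
# point EnergyConfig at a copy of this file to override.
H:  {sigma: 2.42, epsilon: 0.063}
C:  {sigma: 3.40, epsilon: 0.359}
N:  {sigma: 3.25, epsilon: 0.711}
O:  {sigma: 2.96, epsilon: 0.879}
S:  {sigma: 3.56, epsilon: 1.046}
P:  {sigma: 3.74, epsilon: 0.837}
F:  {sigma: 3.12, epsilon: 0.255}
CL: {sigma: 3.40, epsilon: 1.255}
BR: {sigma: 3.62, epsilon: 1.674}
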