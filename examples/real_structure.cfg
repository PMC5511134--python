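# Pipeline configuration for analysing a crystallographic structure.
# Flat key = value format; sections are organisational only.
# Every key is optional — omitted keys keep their documented defaults.

[input]
# structure = path/to/structure.pdb
# chain = A
# offset maps deposited residue numbers to mature-protein numbering
# (mature = deposited + offset); residues with insertion codes need
# explicit overrides via the library API.
offset = 0
# optional external secondary-structure table (chain first last kind):
# sse_override = path/to/sse.tsv

[force_field]
k_bond = 1000
gamma_sse = 5
c = 1e4
k_ss = 500
r_cut = 15
r_bridge = 5.5

[modes]
# mode is 1-based over all modes; leave unset for the first non-rigid
# mode (mode 7 on a generic structure)
zero_tol = 1e-12
amplitude_rmsd = 2.0
n_frames = 21

[hinge]
tau_def = 0.4
tau_fluct = 0.25
max_gap = 1

[hbond]
hbond_cutoff = 3.2

[pca]
# trajectory = path/to/multimodel.pdb
pca_components = 3

[run]
out_dir = hingescan_out
seed = 0
log_level = INFO
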