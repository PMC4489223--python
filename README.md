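# cgdock

Blind flexible docking of peptides (up to 30 residues) to protein
receptors at coarse-grained resolution, with no prior knowledge of the
binding site. The pipeline couples folding and binding in one simulation:

1. **Initialization** — random self-avoiding peptide conformers are placed
   uniformly on a sphere centred at the receptor (radius = receptor's
   longest dimension + 20 Å).
2. **Sampling** — replica-exchange Monte Carlo annealing with 10 replicas
   uniformly spread in temperature; the whole ladder shrinks as the run
   proceeds. The receptor is held near-native by a network of flat-bottom
   Cα–Cα distance restraints (pairs 5–15 Å apart with sequence separation
   ≥ 5; violations under 1 Å are free, beyond that the penalty grows
   linearly). User-marked receptor residues can be made moderately or
   fully flexible (restraint slopes halved or zeroed). Each replica emits
   a trajectory of time-stamped snapshots — 10 × 1000 = 10 000 models at
   the default 50 macrocycles.
3. **Model selection** — per-trajectory filtering drops unbound snapshots
   and keeps the 100 lowest-binding-energy models; the pooled set is
   clustered by k-medoids (k = 10, 100 restarts with different initial
   medoids) and the 10 consensus medoids become the final models.
4. **Evaluation** — ligand RMSD (peptide Cα RMSD after superimposing the
   receptors) with quality classes high (< 3 Å), medium (3–5.5 Å), low
   (> 5.5 Å), plus peptide–receptor contact maps at a user-defined cutoff.

The energy function is a documented, pluggable stand-in (two interaction
centres per residue, symmetric 20×20 contact matrix, clash penalties,
restraints, soft spherical confinement) — it reproduces the protocol's
architecture, not any published force field. All-atom reconstruction of
the final Cα-trace models is out of scope.

## CLI

```sh
# basic docking run (writes final models, trajectories, reports, log)
cgdock dock receptor.pdb HKILHRLLQDSS --seed 1 --out results_dir

# options mirroring the server surface
cgdock dock receptor.pdb PEPTIDE \
    --ss CCHHHHC --macrocycles 100 \
    --flexible A:37:moderate --flexible A:38:full \
    --exclude A:101 --contact-cutoff 6.0 --out run2

# score a finished job against a reference complex
cgdock evaluate --job results_dir --reference native_complex.pdb

# resubmit with the binding modes of final models 0 and 3 excluded
cgdock resubmit --job results_dir --exclude-models 0,3 --out run3
```

Inputs: a PDB receptor (≤ 500 residues per chain, complete N/CA/C/O
backbone per residue; non-standard residues are renamed via
`src/cgdock/data/nonstandard_residues.tsv`) and a one-letter peptide
sequence (≤ 30 residues), optionally with an H/E/C secondary-structure
string (all-coil when omitted).

The result directory is self-describing: `final_models/model_*.pdb` (+
per-model contact TSVs), `clusters.tsv`, `restraints.tsv`, per-replica
`trajectories/replica_*.pdb`, `trajectory_energies.tsv`, and `job.log`
with everything needed to reproduce the run bit-exactly.

## Synthetic fixtures

`cgdock.fixtures` generates everything needed to exercise the pipeline
offline: ideal α-helices, a two-helix groove receptor with a designed
attractive site and a known bound reference pose (a docking funnel for
end-to-end recovery tests), and compact random-coil globules.
`make_test_suite(seed, outdir)` writes the full PDB + config catalog.

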