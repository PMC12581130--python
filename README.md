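# fibrilkit

Idealized cross-β polyglutamine (polyQ) fibril construction, multi-state
native-contact parameterization, and aggregation-kinetics analysis — with a
synthetic-data generator that stands in for molecular-dynamics production
runs.

## What it does

- **`fibril_builder`** — builds idealized β-turn (BT, hairpin) and β-arc
  (BA) cross-β lattices from internal coordinates. Strand residues alternate
  between the two ssNMR-derived glutamine conformers (ψ 136°/150°,
  χ1 −65°/55°, χ2 180°); chains stack into sheets in four end-terminus
  directional arrangements (A1–A4). Turn/arc linker dihedrals are fitted
  numerically at build time so the second strand lands on its lattice slot.
  Also: minimal Q-zipper spec (6-residue strands + 4-residue turn = 16 Gln)
  and box-size/concentration helpers.
- **`structure_metrics`** — dihedral extraction with circular statistics,
  sheet/strand spacing recovery, a Kabsch–Sander hydrogen-bond secondary
  structure assigner (H/E/T/C), end-to-end EXTENDED/COMPACT classification,
  6 Å heavy-atom residue contact maps, per-residue helicity profiles with
  4-block error bars, and radius of gyration.
- **`contact_param`** — learns residue-pair contact probability maps from
  monomer / dense-phase / fibril ensembles and merges them into one
  interaction table: QCORE pairs attractive at a single ε (0.4 kJ/mol
  Q16-like, 0.325 kJ/mol H16-like defaults), flanking-domain pairs from the
  dense phase, and every flanking↔QCORE cross pair as excluded-volume
  repulsion.
- **`aggregation_kinetics`** — 10 Å Cα single-linkage chain clustering,
  largest-cluster/monomer fraction time series, t½ (monomer half-depletion),
  oligomer-order distributions before/after t½ with replicate SEM, and the
  midsize (5–13) oligomer fraction.
- **`synthetic_data`** — seeded generators: self-avoiding coil ensembles
  (optional partial helicity over a span), Gaussian-perturbed fibrils, and
  an exact-Gillespie dock-and-lock aggregation model with two docking
  channels, locking, and tunable small-oligomer stability (Q16-like vs
  H16-like presets), plus 3D coordinate realization of its snapshots and a
  dimerization-rate recovery estimator.
- **`io_core`** — PDB/GRO structure and multi-model PDB trajectory I/O
  (via biotite), the ChainTopology/Frame/Trajectory data model, domain
  annotation from config spans, and minimum-image distance utilities.

## CLI

Each stage is a subcommand (also exposed as standalone scripts); every run
writes a `manifest.json` beside its outputs and is deterministic for a fixed
config + seed.

```sh
build-fibril --model bt --arrangement a1 --sheets 4 --chains-per-sheet 4 \
             --out lattice/lattice.pdb          # PDB + JSON metadata sidecar
extract-contacts --traj traj.pdb --scope inter --cutoff 6.0 --out map.tsv
merge-params --monomer m.tsv --fibril f.tsv --dense d.tsv \
             --domains domains.yaml --eps 0.325 --out params.tsv
analyze-structure --traj x.pdb --metrics dihedrals,ss,e2e,contacts,rg \
                  --span 18:33 --out report.json
analyze-kinetics --traj r1.pdb --traj r2.pdb --cutoff 10 --window 200 \
                 --out kinetics.json
make-synthetic coil|fibril|kinetics --spec spec.yaml --seed 7 --out dir/
```

`fibrilkit --help` lists everything under one entry point.

## Notes and limitations

- Lattices are rigid idealizations: strands built from uniform dihedrals
  twist, so inter-strand registration is a fitted compromise between
  backbone hydrogen bonding and side-chain overlap. Residual side-chain
  contacts are reported as `ClashWarning`s with the offending atom pairs.
- The dock-and-lock generator encodes mechanisms as mass-action rates, not
  emergent physics; its regime presets are illustrative and non-physical by
  design. They exist to give the analysis suite a closed-form ground truth.
- The secondary-structure assigner is chain-aware; the reference
  implementation used in the tests (MDAnalysis' vendored pydssp) is not, so
  cross-validation fixtures are single-chain.
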