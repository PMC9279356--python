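# trimd

Trajectory-analysis toolkit for three-chain kinase/cyclin/inhibitor
complexes, exercisable end-to-end on synthetic trajectories with planted
ground truth. It implements the complete per-system analysis chain used to
characterise how tyrosine phosphorylation of an intrinsically disordered
inhibitor reshapes a ternary complex:

* **structure_io** — multi-model PDB trajectories, topology model, atom
  selections (`chain C and name CA`), per-atom parameter tables.
  Phospho-residues are ordinary residues named `Y2P`/`T2P` (aliases
  `PTR`/`TPO` are mapped on read).
* **superpose_rmsd** — Kabsch best-fit superposition, C-alpha RMSD series,
  equilibration trimming (default 25 ns drop; time-averaged statistics
  consume trimmed windows).
* **hbond_network** — geometric H-bond detection (donor–acceptor ≤ 3.0 Å,
  D–H–A ≥ 135°, N/O/F heavy atoms), lifetime fractions, 1 ns bound-episode
  classification, persistent intermolecular networks (fraction > 0.5).
* **secondary_structure** — DSSP-style assignment from Kabsch–Sander
  backbone H-bond energies (codes H/G/I/E/B/T/S/C) and per-residue SS
  fractions over a trajectory.
* **sasa_lcpo** — solvent-accessible surface area by linear combinations of
  pairwise overlaps, accessibility classification, Gaussian-KDE SASA
  densities.
* **collective_variables** — centre-of-mass distances, sustained-ejection
  event detection, dissociation timing, a documented kinase-activity
  decision table, k-means conformer extraction with centroid frames.
* **energy_decomposition** — per-residue receptor/ligand interaction-energy
  split (symmetric half-share; shares sum exactly to the total). The
  solvation term is a *screened molecular-mechanics model*, not a
  Poisson–Boltzmann solve; every output declares this provenance.
* **amd_toy** — accelerated-sampling boost potential
  ΔV = (E−V)²/(α+E−V), BAOAB Langevin dynamics on toy double-well
  potentials, exponential reweighting, and boost-parameter estimation from
  unbiased runs.
* **conservation** — phospho-site presence scoring across pre-built
  multiple alignments and S/T-P motif scanning.
* **synthetic_data** — the toy trimer generator: scripted H-bond on/off
  schedules, an inhibitor segment built from ideal α/3₁₀ dihedrals, a
  rigid ejection event at a known frame, and a probe residue toggling
  between a buried cage and an exposed position. Its manifest is the
  oracle for every recovery test.
* **pipeline_cli** — a YAML-driven `run-all` pipeline producing TSV report
  bundles plus a run manifest that tags each parameter `protocol` or
  `assumed`.

## CLI

```bash
trimd simulate --frames 200 --seed 1 --ejection-frame 120 --out fixture/
trimd rmsd fixture/trajectory.pdb --out rmsd.tsv
trimd hbond fixture/trajectory.pdb --threshold 0.5 --drop-ns 0 --out hb.tsv
trimd dssp fixture/trajectory.pdb --chain C --out ss.tsv
trimd sasa fixture/trajectory.pdb --chain C --resid 16 --out sasa.tsv
trimd cv fixture/trajectory.pdb --sel-a "chain C and resid 1-12" \
      --sel-b "chain A and resid 1-6" --out cv.tsv
trimd decomp fixture/trajectory.pdb --params fixture/params.tsv \
      --receptor "chain A or chain B" --ligand "chain C" --out decomp.tsv
trimd cluster fixture/trajectory.pdb --k 2 --seed 0 --out clusters.tsv
trimd amd --potential double_well --barrier 6 --steps 100000 --boost --out amd.tsv
trimd conserve aln.fasta --ref-id human --site Y88:88:Y --out cons.tsv
trimd run-all --config config.yaml --out report/
```

`trimd run-all` consumes a YAML config; see
`trimd.pipeline_cli.AnalysisConfig` for the schema. Reruns with the same
config and seed are byte-identical.

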