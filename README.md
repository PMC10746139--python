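# dockeval

Evaluation toolkit for ligand-docking benchmarks: given experimental
protein–ligand complexes and predicted receptor structures (deep-learning or
template-based models), it measures how accurate the models' binding pockets
are and how well docking to them reproduces known ligand poses.

It is aimed at structural bioinformaticians running cross-docking studies —
the setting where a ligand is docked into a structure of its target that was
determined (or predicted) *without* that ligand bound, and the predicted pose
is compared with the experimentally determined one.

## What it computes

**Structural metrics** (all heavy-atom, after closed-form Kabsch
superposition, reflections excluded):

- *Binding-pocket RMSD* — the pocket is the set of residues with any heavy
  atom within 5 Å of the reference-bound ligand; alignment and RMSD use the
  same pocket atom set (all-heavy or backbone-only N/CA/C/O).
- *Full-structure RMSD* over all mapped heavy atoms.
- *Ligand pose RMSD* — protein frames are aligned on residues within 15 Å of
  the reference ligand, the transform is applied to the predicted pose, and
  the ligand heavy-atom RMSD is computed with no further fitting, minimized
  over graph automorphisms of the ligand (symmetry correction).
- *Per-residue divergence* — after one global pocket alignment per candidate
  structure, each pocket residue's RMSD, reduced by max across candidates and
  ranked (which residues a model gets most wrong).

**Ligand similarity** — the size of the maximum common substructure (largest
connected common subgraph under exact element and bond-order matching,
found by exact branch-and-bound) divided by the heavy-atom count of the
smaller molecule; pairs with ratio < 0.5 are flagged "very different".

**Success statistics** — a predicted pose is *correct* iff its RMSD ≤ 2.0 Å
(inclusive). Records are weighted so every ligand–protein pair counts
equally (weight 1/M within each pair × receptor-kind group of M records):

    accuracy = Σᵢ wᵢ·[rmsdᵢ ≤ 2 Å] / Σᵢ wᵢ  =  mean over pairs of per-pair success

with 90% percentile bootstrap CIs (resampling unit = the ligand–protein
pair, 9999 resamples by default) and two-sided paired t-tests on per-pair
success fractions between receptor kinds. Self-docking (docking a ligand
back into its own reference structure) is excluded by default, and
experimental receptors whose bound ligand is similar to the docked one can
be excluded too.

**Smoothed accuracy curves** — Nadaraya–Watson kernel regression of the
binary outcomes on binding-pocket RMSD with an Epanechnikov kernel
K(u) = 0.75·(1 − u²) on |u| ≤ 1 and bandwidth h = 0.25 Å, evaluated only
between the smallest and largest observed pocket RMSD, with pair-level
bootstrap bands and a per-grid-point bootstrap test for the difference
between two curves.

**Synthetic studies** — `generate_study` builds desk-scale pseudo-receptors
with a central ligand-bearing cavity, perturbs them to hit target pocket
RMSDs drawn per receptor kind from Gamma distributions, and draws pose
correctness from a logistic link P(correct | pocket RMSD r) = expit(a + b·r),
so the whole pipeline can be validated against a known ground truth.

## Worked example

```python
import dockeval as dv

cfg = dv.StudyConfig(n_proteins=6, ligands_per_protein=3, seed=42)
study = dv.generate_study(cfg)                  # simulate + measure via the pipeline
model = dv.DockingAccuracyModel(study.manifest) # self-docking excluded by default
res = model.fit(level=0.90, n_resamples=1999, seed=42)
print(res.summary())
```

prints

```
Docking pose-prediction accuracy (pair-equal weighting)
  correctness criterion: pose RMSD <= 2.0 A
  records used: 90  (excluded: 18 self-dock, 0 similar-ligand)
  bootstrap: 90% percentile CI, 1999 resamples, pair-level blocks

  receptor kind  accuracy   ci lo   ci hi  pairs  records
  af2               0.333   0.167   0.500     18       18
  experimental      0.528   0.361   0.667     18       36
  traditional       0.139   0.056   0.222     18       36

  paired t-tests on per-pair success fractions:
    af2 vs experimental: p = 0.2987
    af2 vs traditional: p = 0.13
    experimental vs traditional: p = 0.002744
```

Each row is one receptor kind: the pair-weighted fraction of correctly
docked poses, its 90% bootstrap CI, and the number of ligand–protein pairs
and records behind it. Here the simulated "experimental" receptors (most
accurate pockets by construction) dock best and the "traditional" models
worst; the difference between experimental structures and traditional models
is significant while af2-vs-experimental is not at this sample size.
Smoothed curves come from the same results object:

```python
curve = res.smooth("af2", band=True, n_resamples=999, seed=42)
print(curve.to_frame().iloc[::40].round(3))      # x, estimate, n_effective, lo, hi
cmp_ = res.compare_curves("experimental", "af2") # per-grid-point p-values
```

The command line mirrors the library: `dockeval simulate`, `aggregate`,
`smooth`, `similarity`, `pocket-rmsd`, `full-rmsd`, `pose-rmsd`,
`residue-divergence` (see `dockeval --help`).

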