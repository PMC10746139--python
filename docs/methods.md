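# Methods

This note documents the models, estimators and numerical choices behind
dockeval, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Structural comparison model

All RMSDs are computed over non-hydrogen atoms; hydrogens are discarded at
parse time because every metric here is defined on heavy atoms and hydrogen
placement is preparation-dependent. Structures are first *cleaned*: only the
ligand-bearing chain is kept, waters are removed, and alternate locations
are resolved deterministically (highest occupancy; ties toward altloc 'A').
Determinism of this rule matters more than its chemistry — it makes every
downstream number reproducible from the input file alone.

Residue correspondence between a model and a reference is established by
global sequence alignment (Biopython `PairwiseAligner`; match +1,
mismatch −1, gap open −2, extend −0.5) of the one-letter sequences, never by
raw author numbering. A residue pair enters an RMSD sum only if both
positions are aligned and the residue names agree, and only atom names
present in both members contribute. Residues present in a model but
unresolved in the reference (or vice versa) are therefore excluded; the
mapping coverage is checked and an error is raised below 30% of the shorter
sequence. This is the main free choice in the structural pipeline: an
alternative would be to penalize missing atoms, which would conflate
coverage with geometric error.

Superposition is the closed-form SVD Kabsch solution with the reflection
correction (det(R) = +1 enforced), the canonical least-squares rigid fit.
No outlier rejection is performed by default; an optional `cycles` parameter
(discard atoms beyond 2× the current RMSD, at most 5 rounds, RMSD still
reported over the full atom set) is available for sensitivity analysis,
since some interactive alignment tools reject outliers silently and this
changes reported pocket RMSDs.

Metric definitions:

- **Pocket** — residues of the reference with any heavy atom within 5.0 Å of
  the reference-bound ligand (the cutoff is a parameter; 5 Å is the field's
  operational definition of a binding pocket). Alignment and scoring use the
  same pocket atom set; the backbone variant restricts to N/CA/C/O.
- **Pose RMSD** — the protein frames are aligned on mapped residues within
  15 Å of the reference ligand (membership computed in the reference frame),
  the transform is applied to the predicted ligand pose, and the RMSD over
  ligand heavy atoms is computed with **no further fitting**. With symmetry
  correction on (the default) the RMSD is minimized over graph automorphisms
  of the ligand's chemical graph (element- and bond-order-preserving),
  enumerated with networkx and capped at 10,000; beyond the cap the identity
  correspondence is used with a warning. Both symmetric and plain values can
  be obtained via the flag.
- **Per-residue divergence** — one global pocket alignment per candidate
  (not per-residue re-fitting), then per-pocket-residue heavy-atom RMSD,
  reduced by max across candidates and sorted. Re-fitting per residue would
  hide exactly the local displacements this ranking is meant to expose.

Protein atom correspondence is by identical atom name within mapped
residues. Chemically equivalent side-chain atom pairs (e.g. aromatic
CD1/CD2) are *not* swap-minimized; this can bias per-residue RMSDs upward
for symmetric side chains and is a documented limitation.

## Ligand similarity

Similarity of two ligands is `|MCS| / min(|a|, |b|)` in heavy atoms, where
the MCS is the largest **connected** common subgraph under exact element
match and exact bond-order match (aromatic matches only aromatic; SMILES
aromaticity is taken as written, never re-perceived, so a Kekulé-written
ring and a lowercase-aromatic ring are deliberately different graphs).
Pairs with ratio strictly below 0.5 are "very different". The search is an
exact branch-and-bound growing a partial atom mapping through edges present
in both molecules, pruned by an element-multiset bound and a visited-state
table; it is deterministic, and because only the size is consumed,
tie-breaking among equally large substructures is irrelevant. An 80-atom cap
guards against pathological inputs; an `engine` hook accepts an external MCS
implementation for cross-checks. Connected, bond-order-strict matching is
the most common convention; disconnected or order-relaxed MCS variants would
give systematically larger ratios and are out of scope.

## Success statistics

A pose is **correct** iff RMSD ≤ 2.0 Å — inclusive, and the threshold is a
parameter. Aggregation weights every ligand–protein pair equally: within
each (protein, ligand, receptor-kind) group of M records each record gets
weight 1/M, so the weighted accuracy for one receptor kind equals the
unweighted mean of per-pair success fractions, and duplicating a pair's
records changes nothing. Self-docking records are excluded from headline
accuracy by default (they answer a different, much easier question); an
optional filter also drops experimental receptors whose bound ligand has
similarity ≥ 0.5 to the docked ligand.

Uncertainty: percentile bootstrap at level 0.90 with 9999 resamples by
default. The resampling unit is the **ligand–protein pair** — a pair's full
record set moves as a block — because pairs are the declared unit of equal
representation and records within a pair are strongly dependent. BCa or
studentized intervals were not used; the percentile interval is the common
default and its small-sample behavior is quantified directly (the
acceptance suite measures ~90% empirical coverage at 40 pairs). With a
single pair the interval degenerates to the point estimate with a warning.

Receptor kinds are compared with a two-sided paired t-test on per-pair
success fractions (pairs missing in either kind are dropped and counted).
All-zero differences give p = 1 by convention; zero-variance non-zero
differences give p = 0, both with warnings, since the t statistic is
undefined there.

## Kernel-smoothed accuracy curves

The success-vs-pocket-RMSD curve is a Nadaraya–Watson locally weighted mean
of the binary outcomes with the Epanechnikov kernel 0.75·(1 − u²) on
|u| ≤ 1. "Width 0.25 Å" is interpreted as the bandwidth h in K((x − xᵢ)/h),
i.e. support ±0.25 Å; the alternative reading (full support 0.25 Å,
h = 0.125) is available by passing `bandwidth=0.125`. The evaluation grid
(step 0.01 Å, a presentation choice) is restricted to the closed interval
between the smallest and largest observed pocket RMSD — the boundary rule
that avoids extrapolation artifacts at the ends. Grid points with zero
kernel mass are omitted. Pair-equal weights are carried into the kernel sums
by default so the curves are consistent with the aggregate accuracies; a
flag disables weighting.

Bands are pair-level percentile bootstrap bands: each resampled curve is
re-clipped to its own resample's data range, and a band value is reported
only where ≥95% of resamples could be evaluated. The two-curve test
resamples pairs independently within each group and reports, per grid
point, p(x) = 2·min(frac(Δ* ≤ 0), frac(Δ* ≥ 0)) with a +1/(n+1) continuity
correction, evaluated only where both curves exist. Grid-point-wise testing
is the chosen operationalization of "per-interval" significance; neighboring
grid points share data and are therefore strongly correlated, so the
fraction of significant points in a single study is itself a noisy quantity
— calibration statements in the test suite average over repeated studies.
For identical inputs Δ ≡ 0 and the p-values concentrate near (but, by the
nature of independent resampling, not identically at) 1.

## Synthetic studies: what is and is not emulated

The generator produces a pseudo-receptor whose backbone (N, CA, C, O per
residue) follows a coiled path of radius 9 Å around a central cavity, with
2–4 inward-pointing side-chain pseudo-atoms per residue, and a rigid ligand
(aromatic 5- or 6-ring plus a 3–8-atom heteroatom chain, 8–14 heavy atoms)
in the cavity. The construction guarantees a non-empty 5 Å pocket (≥8
residues), no interatomic distance below 1 Å, and byte-identical PDB output
for a fixed seed. It emulates the *statistical* structure the analysis
assumes — per-kind pocket-error distributions, a monotone link from pocket
error to docking success, pair/receptor grouping — and none of the physics:
no realistic protein geometry, rotamers, energetics, or docking-score
distributions. Passing tests therefore validate the measurement and
inference machinery, not any claim about real receptors.

Model error is i.i.d. zero-mean Gaussian per coordinate, with side-chain
atoms given twice the backbone sigma (binding-pocket side chains are the
least constrained part of real models). To realize a target pocket RMSD the
generator scales a single noise realization by secant iteration on the
measured (Kabsch-aligned) pocket RMSD until within 10% of target; the
manifest records both target and achieved values. Per-kind Gamma
distributions of target pocket RMSD default to means of ≈0.9 Å
(re-determined experimental structures), ≈1.3 Å (deep-learning-like models)
and ≈3.3 Å (template-based-like models) — the qualitative ordering such
benchmarks report, used here only as plausible study conditions.

Pose correctness is drawn from P(correct | r) = expit(a + b·r) with default
(a, b) = (4, −4): near-certain success for a perfect pocket, ≈12% at 2 Å
pocket error, non-increasing in r (enforced unless explicitly overridden;
per-kind overrides may be logistic parameters or an arbitrary callable).
Correct poses are the reference plus Gaussian jitter (σ = 0.35 Å), accepted
when their in-frame RMSD is ≤1.5 Å; incorrect poses get a ≥90° rotation, a
4 Å displacement and jitter, accepted at ≥3.0 Å. The margins (1.5/3.0
rather than the bare 2.0 Å criterion) keep the intended class stable under
the small additional error the downstream 15 Å-shell frame alignment
introduces; the rejection loops make the class guarantees exact, and a loop
exhausting 100 tries raises rather than silently mislabeling.

All randomness flows from one root seed through named substreams (receptor,
ligand, perturbation, pose, bernoulli, bootstrap), so each stage is
independently reproducible and study generation is deterministic per seed.

The manifest emitted by `generate_study` contains *pipeline-measured*
pocket and pose RMSDs — the generator calls the same public superposition
functions users do — alongside the generator's truth columns (`true_*`),
so parameter-recovery tests close the full loop.

## Problem sizes and tolerances

The test suite and acceptance script use study sizes chosen to make the
statistical assertions sharp at desk scale: link recovery uses ≥3000
records (max absolute error of the smoothed curve vs the true link ≤0.07 on
the 10th–90th percentile interior, where kernel bias ≈ ½f″σ²_K h² ≲ 0.01
and the pointwise standard error ≈ 0.03); bootstrap coverage uses 40 pairs
× 500 replications (±4 percentage points around 90%); null calibration of
the curve-difference test averages 25 studies of 30 pairs per kind, where
the pair-block bootstrap is close to nominal (at ≲16 pairs it is visibly
anti-conservative — a known small-cluster bootstrap effect and a documented
limitation). Kabsch is checked against a zoomed axis-angle grid search to
1e-3 Å on 50 instances; the exact MCS is checked against exhaustive
connected-subgraph enumeration on 100 random ≤8-atom pairs.

## Known limitations

- No mmCIF input; no protonation, charge assignment or energy minimization.
- Atom-name-based correspondence can overstate RMSDs for symmetric side
  chains (no CD1/CD2-style swap minimization).
- The smoother is not boundary-corrected (no local-linear estimator) and the
  bandwidth is fixed, not cross-validated.
- The pair-block bootstrap is anti-conservative below ~20 pairs.
- The synthetic geometry is schematic; conclusions about real structures
  require real structures.
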