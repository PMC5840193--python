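# abflex

Rigidity-theory and B-factor flexibility analysis of antibody CDR-H3 loops.

## The scientific problem

Affinity maturation is widely believed to rigidify the antigen-binding site
of antibodies, and in particular the third heavy-chain complementarity
determining region (CDR-H3), the most diverse and antigen-contacting loop of
the Fv. Testing that hypothesis at repertoire scale needs a flexibility
measure that is cheap enough to evaluate on hundreds to thousands of
structures. `abflex` implements the full analysis stack for that question:

* **Pebble-game rigidity analysis.** An Fv structure is converted into a
  molecular constraint network: every atom is a rigid body with 6 degrees of
  freedom (DOF), rotatable covalent bonds contribute 5 bars, dihedral-locked
  bonds 6 bars, hydrogen bonds 5 bars (with a Mayo-style geometry-dependent
  energy), and hydrophobic tethers 2 bars. The (6,6) body-bar pebble game
  absorbs independent constraints; the free pebbles that can be gathered on
  the loop's backbone atoms (N, C&alpha;, C) count its conformational DOFs.
* **Hydrogen-bond dilution.** The DOF count is swept over the hydrogen-bond
  energy cutoff grid 0.00, &minus;0.01, ..., &minus;7.00 kcal/mol: weak
  bonds break first, and the DOF rises from its fully-bonded value toward
  the theoretical maximum `2L + 6` (two backbone torsions &phi;/&psi; per
  residue plus 6 rigid-body DOFs for a loop of `L` residues). The scaled
  DOF `sDOF = DOF / (2L + 6)` makes loops of different length comparable,
  and the signed area under the sDOF-vs-cutoff curve (AUC, negative by the
  descending-cutoff convention) summarizes a whole profile in one number.
* **B-factor z-scores.** Per chain, C&alpha; temperature factors of the
  heavy-chain variable domain (Chothia 1&ndash;112) are normalized to
  `z = (x - mu) / sigma`; the mean z over CDR-H3 (Chothia H 95&ndash;102) is
  a crystallographic flexibility score comparable across resolutions.
* **Cohort statistics.** Naive vs mature (or bound vs unbound) cohorts are
  compared with a two-sample Kolmogorov&ndash;Smirnov test and with a
  pooled-permutation randomization test on the difference of group means
  (10,000 re-splits, repeated 10 times for an SD on the Monte-Carlo
  fraction).
* **Ensemble measures.** Kabsch superposition, region RMSD, the
  distance-based RMSF (SD over frames of each residue's C&alpha; distance
  to the reference after whole-Fv superposition) and k-medoids selection of
  representative conformers from trajectory-like multi-model ensembles.
* **Germline comparison.** Somatic mutations are counted from a local
  BLOSUM50 alignment of heavy/light variable sequences to their germline
  V-genes; an antibody with at least one mutation in either chain is labeled
  mature, otherwise naive.

A synthetic-data module generates every input class with known ground truth
(ideal-geometry loops with programmable hydrogen-bond networks, B-factor
cohorts with a controllable naive/mature shift, jittered coordinate
ensembles), so the whole pipeline is testable without downloading any
structures.

## Worked example

```python
import numpy as np
from abflex import ToyLoopSpec, make_toy_loop, sweep_dof, make_bfactor_cohort
from abflex import bfactor_zscores, ks_two_sample, randomization_test

# a length-10 loop with one engineered backbone hydrogen bond at -4 kcal/mol
spec = ToyLoopSpec(loop_length=10, hbond_plan=((5, 1, -4.0),), seed=0)
loop, truth = make_toy_loop(spec)
profile = sweep_dof(loop)
print(f"loop length L = {truth.loop_len}, theoretical max DOF = {truth.max_dof}")
print(f"DOF at cutoff 0.00: {profile.dof[0]}   at -7.00: {profile.dof[-1]}")
steps = profile.cutoffs[1:][np.diff(profile.dof) != 0]
print(f"profile steps at cutoff: {steps}")
print(f"AUC of the scaled-DOF curve: {profile.auc(scaled=True):.3f}")

# a B-factor cohort with a one-sigma loop shift, 23 naive vs 897 mature
manifest, structures = make_bfactor_cohort(n_naive=23, n_mature=897, shift=1.0, seed=1)
naive, mature = [], []
for rec in manifest.to_dict("records"):
    z = bfactor_zscores(structures[rec["id"]]).cdrh3_mean_z
    (naive if rec["maturity"] == "naive" else mature).append(z)
D, p = ks_two_sample(naive, mature)
res = randomization_test(naive, mature, n_iter=10_000, n_repeat=10, seed=1)
print(f"KS: D = {D:.3f}, p = {p:.2e}")
print(f"randomization: {res.fraction_ge:.3f} +/- {res.fraction_sd:.3f} % of splits "
      f">= observed diff {res.observed_diff:.3f}")
```

prints

```
loop length L = 10, theoretical max DOF = 26
DOF at cutoff 0.00: 21   at -7.00: 26
profile steps at cutoff: [-4.]
AUC of the scaled-DOF curve: -6.232
KS: D = 0.884, p = 5.21e-21
randomization: 0.000 +/- 0.000 % of splits >= observed diff 0.898
```

Reading the output: with its one hydrogen bond intact the loop loses 5 of its
26 possible DOFs (21 at cutoff 0); the bond breaks exactly when the dilution
cutoff passes its &minus;4.0 kcal/mol energy, restoring the full 26; and the
AUC is correspondingly less negative than the &minus;7.0 of a bond-free loop.
In the cohort comparison the planted one-sigma loop shift is decisively
detected: no random re-split of the pooled scores reproduces the observed
mean difference, and the KS test agrees.

## Command line

The library is also exposed as a thin `flex` CLI:

```bash
flex synth loop --length 10 --bond 5:1:-4.0 --out loop.pdb
flex sweep   --manifest cohort/manifest.tsv --region H3 --out results/
flex bfactor --manifest cohort/manifest.tsv --stratify maturity --out results/
flex ensemble --traj frames.pdb --ref ref.pdb --fit FR_H --measure H3
flex germline --query EVQLV... --germ EVQLV...
```

All tabular outputs are tab-separated text with a header comment recording
the run configuration.

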