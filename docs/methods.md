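# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `abflex`, in the package's own terms.

## Constraint network model

Atoms are modeled as rigid bodies with six degrees of freedom each;
interactions become bars between bodies. The bar multiplicities follow the
standard body-bar convention for molecular frameworks:

| interaction | bars | notes |
|---|---|---|
| rotatable covalent single bond | 5 | leaves the bond torsion free |
| dihedral-locked covalent bond | 6 | peptide &omega;, carbonyl and other double bonds, sp2 ring bonds, proline ring, bonds to hydrogen |
| hydrogen bond | 5 | present iff its energy &le; the dilution cutoff |
| hydrophobic tether | 2 | C/S pair contact |

Covalent topology comes from per-residue heavy-atom templates for the 20
standard amino acids plus inter-residue peptide links (C&ndash;N below
2.0 &Aring;) and disulfides (SG&ndash;SG below 2.5 &Aring;, rotatable).
Hydrogens are attached to their nearest heavy atom within 1.3 &Aring; by
name-independent distance matching, which tolerates the many protonation
naming schemes in the wild. Bonds to hydrogen are locked (6 bars): a
point-like hydrogen has no meaningful spin degree of freedom, and the choice
leaves loop-backbone DOF counts unchanged while keeping whole-network counts
clean. Alternate side-chain locations keep the highest-occupancy conformer.

**Hydrogen-bond energy.** A Mayo-style function
`E = V0 [5 (R0/R_DA)^12 - 6 (R0/R_DA)^10] * F` with `V0 = 8` kcal/mol and
`R0 = 2.8` &Aring;. The angular factor is
`F = cos^2(theta_DHA) * cos^2(phi - phi0)`, clamped to [0, 1], where `phi`
is the hydrogen&ndash;acceptor&ndash;base angle and `phi0` the acceptor
hybridization ideal (120&deg; sp2, 109.47&deg; sp3). Detection screens:
donor&ndash;acceptor &le; 3.6 &Aring;, hydrogen&ndash;acceptor &le;
2.6 &Aring;, donor-H-acceptor angle &ge; 110&deg;, donor and acceptor more
than three covalent bonds apart, and negative energy. Salt bridges between
Lys/Arg/His nitrogens and Asp/Glu carboxylate oxygens are assigned a flat
&minus;10 kcal/mol. Structures without hydrogens either raise an error or,
with the fallback enabled, get backbone amide hydrogens placed in the
peptide plane (1.01 &Aring; from N, trans to the carbonyl oxygen);
side-chain protonation is not attempted.

**Tethers.** C/S atom pairs from different residues within the van der
Waals sum plus 0.25 &Aring; (vdW C 1.70, S 1.80 &Aring;), excluding pairs
within three covalent bonds. The graph-distance exclusion is essential:
without it, adjacent-residue backbone carbons (~2.4 &Aring; apart) would
tether and destroy the &phi;/&psi; torsions the analysis counts.

## The (6,6) pebble game

Each body starts with six pebbles; a bar between `u` and `v` is independent
iff seven pebbles can be gathered on `{u, v}` by depth-first searches along
absorbed-bar orientations with path reversal. Absorbed bars consume one
pebble; redundant bars are counted but change nothing. By Tay's theorem the
absorbed count equals the rank of the generic body-bar rigidity matrix, a
fact the test suite exploits: on random multigraphs the free-pebble total is
checked against `6|V| - rank` of a matrix with random bar attachments, and
subset collections against the dimension of the null space projected onto
the subset's coordinates (numerical rank with a relative 1e-8 singular-value
cutoff; generic spectra have O(1) gaps at the rank boundary).

The loop DOF count is the maximum number of free pebbles simultaneously
placeable on the backbone (N, C&alpha;, C) bodies of the CDR-H3 residues.
This includes the six trivial rigid-body pebbles: the scaling denominator
`2L + 6` counts them too, so a fully liberated loop scales to exactly 1.
Collection queries run on a copy of the game state and are side-effect
free. Rigid-cluster decomposition pins six pebbles on a seed body and
assigns every body whose pebble search then fails (together with the whole
pebble-free visited set of that failed search) to the seed's cluster,
avoiding quadratic pair testing.

## Dilution sweep

Cutoffs run from 0.00 to &minus;7.00 kcal/mol in steps of 0.01, both
endpoints included (701 points). A bond is retained iff its energy is &le;
the cutoff ("equal is not weaker"). The sweep is incremental: the game is
played once with the covalent + tether skeleton and the bonds stronger than
&minus;7, then bonds are added weakest-cutoff-first as the cutoff rises
toward zero, re-collecting pebbles only when the bond set changed. Because
the pebble-game rank is a matroid rank, the result is independent of
insertion order; the suite verifies bit-identity against a
rebuild-from-scratch at every grid point.

AUC uses the rectangle-plus-triangle sum
`sum (x_i - x_{i-1}) y_{i-1} + (x_i - x_{i-1})(y_i - y_{i-1})/2`, which is
algebraically the trapezoid rule; with descending cutoffs and positive
ordinates it is negative (a flat sDOF = 1 profile integrates to exactly
&minus;7). For mixed-length cohorts the scaled-DOF curve is integrated; for
fixed-length comparisons the raw DOF curve is available. Cohort summaries
report the across-antibody sample SD of per-antibody AUCs (the per-antibody
integral is the default; integrating the cohort-mean curve gives the same
mean by linearity but no SD).

## B-factor statistics

z-scores use the arithmetic mean and *sample* SD (n&minus;1) of all V_H
C&alpha; B-factors; the per-antibody score is the mean z over the CDR-H3
C&alpha; atoms. Chains whose C&alpha; B-factors are all identical are
excluded (their z-scores would be identically zero by construction), and
the pipeline counts such exclusions in its bookkeeping.

The randomization test pools both samples and re-splits them without
replacement into the observed group sizes, `n_iter = 10,000` times,
reporting the percentage of splits whose mean difference meets or exceeds
the observed one (&ge; by default; a `strict` flag gives >). The whole
estimate is repeated `n_repeat = 10` times with sub-seeds spawned from one
seed to attach an SD. The comparison is oriented so the observed difference
is non-negative, which is how such fractions are quoted in cohort reports;
because that direction is chosen after seeing the data, the null
distribution of the fraction is uniform on (0, 50%], not (0, 100%].
`orient=False` keeps the fixed direction `mean(a) - mean(b)` and has an
exactly uniform null; the calibration suites use it. A tiny (1e-12)
tolerance absorbs floating-point ties in the &ge; comparison so the
fraction is invariant under adding a constant to both samples.

The KS test computes D from the two empirical CDFs and the p-value from
Smirnov's asymptotic two-sided distribution at the effective sample size
`mn/(m+n)` &mdash; the same approximation scipy's two-sample test uses in
asymptotic mode, which the suite cross-checks to 1e-8. Per-cutoff KS
curves over the 701-point grid are reported raw, without multiple-testing
correction, with 0.05 as a reference line.

## Ensemble analysis

Superposition is Kabsch (SVD with determinant correction); fits with fewer
than three atoms or nearly collinear fit geometry are rejected. Region RMSD
fits each frame on the heavy-chain framework C&alpha; atoms and measures
C&alpha; RMSD over CDR-H3, averaged over frames. RMSF is distance-based:
after whole-Fv C&alpha; superposition, the fluctuation of residue *i* is
the SD over frames of `|Ca_i(t) - Ca_i(ref)|`, with population (1/F)
variance for the time average; the conventional per-coordinate RMSF is
available behind a flag. For isotropic Gaussian jitter of scale &sigma; the
distance to the reference is a Maxwell variable, so the expected RMSF is
`sigma * sqrt(3 - 8/pi)`, which the tests recover.

Representative selection clusters frames by k-medoids on the pairwise
C&alpha;+C&beta; RMSD matrix (20 clusters by default), with deterministic
seeding: the global medoid first, then farthest-first; Voronoi
reassignment iterates to a fixed point. The medoids of the 10 largest
non-empty clusters are returned, ordered by cluster size, ties to the lower
frame index.

## Germline comparison

Local alignment (Smith&ndash;Waterman via Biopython's PairwiseAligner)
under BLOSUM50 with gap open 10 and extend 1; mismatches are aligned
residue pairs that differ, gap columns are not counted. An antibody is
mature iff heavy + light mismatches &ge; 1. Only V-gene mutations are
counted; CDR-H3/D/J mutations are outside the comparison by construction.

## Synthetic data

`make_toy_loop` builds an ideal-geometry backbone (fixed bond lengths and
angles, trans peptides) from &phi;/&psi; torsions, Chothia-numbered
H 95&ndash;102 with insertion codes after residue 100 for loops longer than
8, preceded by a short extended scaffold segment (2 residues by default).
Scaffold rigidity is deliberately not engineered: scaffold internal motions
either move the loop rigidly (projecting into the six trivial DOFs the
collection already counts) or not at all, so the `2L + 6` contract holds
regardless &mdash; the acceptance suite verifies sDOF &equiv; 1 for
bond-free loops of length 8&ndash;16. Residues are alanine, with glycine at
engineered-bond sites to keep side-chain tethers away from the bond
geometry.

Planned hydrogen bonds (donor residue's amide N-H to acceptor residue's
carbonyl O) are realized by bending the torsions between the two residues
with a Levenberg-Marquardt fit whose residuals drive the Mayo energy to the
planned value while keeping the geometry inside the detection screens and
every *unplanned* polar pair and loop carbon pair outside detection/tether
range. Multi-bond plans are fitted one bond at a time over disjoint
residue windows (overlapping windows raise the infeasible-plan error);
weak bonds, which need off-ideal angles, are retried from bent-geometry
starts. The achieved energies land within ~1e-4 kcal/mol of the plan but
may fall on either side of it, so profile step positions are exact only to
one grid step (0.01 kcal/mol). The generator verifies itself by running
the actual detectors and refuses to emit a structure whose bond set or
energies disagree with the plan.

`make_bfactor_cohort` emits minimal C&alpha;-only V_H chains (residues
1&ndash;112) with i.i.d. normal B-factors (baseline 20 &Aring;&sup2;, SD 5)
and shifts the CDR-H3 residues of the naive group upward by a chosen number
of chain SDs. The default comparison sizes used in the acceptance run are
23 naive vs 897 mature, the realistic imbalance for crystallographic
cohorts. Because the shifted loop inflates the chain SD slightly, the
recovered mean z under-reports the planted shift by a few percent; tests
account for that. `make_ensemble` adds isotropic Gaussian jitter with
per-region scales, or cycles through well-separated rigid CDR-H3
displacements for ground-truth clustering labels. All generators are
deterministic given their seed; identical spec + seed reproduce
byte-identical PDB text.

## What the synthetic data does and does not show

The generators reproduce the *statistical structure* of the analysis inputs
(known bond energies and step positions, known group shifts, known
fluctuation scales), not the physics of real antibodies: loops are
polyalanine/glycine with no side-chain packing, B-factors are i.i.d. rather
than spatially autocorrelated, and ensembles have no kinetic correlation
between frames. Passing tests therefore demonstrate the correctness of the
machinery (constraint counting, dilution bookkeeping, statistics), not any
biological conclusion about affinity maturation.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale inputs chosen to exercise every
code path: 50 random multigraphs (&le; 12 bodies, &le; 40 bars) for the
rigidity oracle, chains up to 50 bodies, five engineered loops for the
sweep-equivalence check over all 701 grid points, 2,000-frame ensembles for
RMSF recovery, and 40 replicate null cohorts for calibration. Degenerate
inputs fail loudly: empty pebble target sets, sub-3-atom or collinear
superposition fits, all-equal B-factors, out-of-reach or overlapping bond
plans, unknown residue templates, positive cutoffs and malformed PDB lines
all raise informative errors. Ties in representative selection resolve to
the lower frame index; redundant-bar identity in the pebble game depends on
input order (only the counts are contract-stable, as a matroid has a unique
rank but not a unique basis).

## Known limitations

* Input structures must already carry Chothia numbering; no renumbering.
* No electrostatics beyond the flat salt-bridge energy; no pi-stacking
  constraints; no ligand parameterization; waters and hetero groups are
  dropped at Fv truncation.
* Trajectories are consumed as multi-model PDB only.
* The distance-based RMSF is not the conventional per-coordinate RMSF
  (which is available behind a flag) and the two differ for anisotropic
  motion.
* The maturity label depends on the germline sequences supplied in the
  manifest; V-gene assignment itself is out of scope.
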