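# Methods

## Model and assumptions

`coilmrf` labels each residue of a protein sequence with one of 127 hidden
states: a single non-coil state, plus 63 states per oligomer class (dimer,
trimer) indexed by heptad letter a–g and a location label 1–9.  Locations
1–7 mark the first seven residues of a coil, 8 any middle residue, 9 the
last.  The labeling is a chain Markov random field: singleton potentials
score a residue under each state from its local sequence context (the
residue itself and up to seven predecessors), and the pairwise potential is
a 0/1 indicator of allowed transitions.

The transition graph encodes the model's structural assumptions:

* the heptad register advances cyclically (a→b→…→g→a) with no skips or
  stutters;
* a coil runs 1,…,7, then any number of 8s, then 9, so every coil spans at
  least nine residues;
* the oligomer class is constant within a coil;
* coils start only from the non-coil state (at any register phase) and end
  only into it, so consecutive coils are separated by at least one non-coil
  residue;
* a sequence may begin in the non-coil state or at coil location 1, and end
  in the non-coil state or at location 9.  Coils truncated by the sequence
  boundary are therefore unrepresentable — a deliberate strict reading that
  forces predicted coils to be complete (known limitation).

Antiparallel orientation, tetramers and higher oligomers, and register
discontinuities are out of scope.

## Features and potentials

Eight features summarize a register-assigned segment: the summed log
probability of its residues under per-heptad dimer tables, per-heptad
trimer tables and a heptad-free background table (f1–f3); pairwise
correlation log-odds summed over distances k = 1..7 for pairs inside the
segment, under each table set (f4–f6); and the summed Eisenberg consensus
hydrophobicity of a-position and d-position residues (f7, f8).  The
correlation statistic is the log of the joint pair probability over the
product of the single-residue marginals, the form used throughout the
pair-frequency lineage of coiled-coil predictors.  Pair tables are indexed
by the heptad of the downstream residue; the upstream heptad is implied by
the distance modulo 7, which is exact for contiguous register-continuous
coils.

Every feature decomposes into per-position summands.  The location label
gates the correlation terms: a residue at location p has exactly
min(p−1, 7) in-coil predecessors, so distance k contributes iff k < p
(all seven distances at locations 8 and 9).  Summing the per-position
vectors along a coil's forced state path reproduces the segment features
exactly (tested to 1e−10), which is what lets the regression score factor
into MRF singleton potentials: a dimer state's log-potential is
`alpha · contribution`, a trimer state's `beta · contribution`, the class
constant is added only at location 1, and the non-coil state is the
reference with log-potential 0.

For positions i < 7, a state whose location would reference a predecessor
before the sequence start is unreachable by any valid path (location p > k
implies i ≥ k), so out-of-range correlation terms are skipped without any
padding convention; their potentials never influence a posterior.

## Frequency tables and smoothing

Single tables count annotated coil residues per class and heptad; pair
tables count ordered in-coil residue pairs at distances 1..7 (pairs never
straddle disjoint annotations); background tables count residues and pairs
in negative sequences without register.  All tables keep raw counts, so
tallies merge additively before smoothing.

Smoothing is additive with one knob, `pseudocount` (default 1), interpreted
as the total prior mass per distribution divided by 20: each 20-cell single
column receives `pseudocount` per cell, and each 20×20 pair slice receives
`pseudocount/20` per cell so its total prior mass matches.  Giving every
pair cell a full pseudocount would place 400 pseudo-observations against
the few hundred real pair counts available per slice at desk scale, which
measurably biases the correlation log-odds on background segments
(~+0.2–0.5 per pair) and adds enough noise that random negative segments
can outscore the coil-bias offset.  With matched total mass the correlation
features stay centred and the false-coil mass on negatives collapses (see
Limitations for the measured effect).

The residue X (and all non-standard codes, which normalize to X) is never
counted; on lookup it receives the average probability of its table slice,
keeping all potentials finite without inventing counts.

## Regression and the coil-bias offset

The three-class weighted multinomial logistic regression uses the non-coil
class as reference: scores `alpha·f + c_d` and `beta·f + c_t`, 16
coefficients and 2 constants.  Class weights normalize totals to 1 (dimer),
1 (trimer) and 1000 (negative); the likelihood is divided by the total
weight, making the optimum invariant to rescaling all weights, and a small
L2 ridge (default 1e−6, coefficients only) guarantees convergence under
perfect separation.  The optimizer is L-BFGS with analytic gradients; an
intercept-only fit recovers the weighted class frequencies
(1/1002, 1/1002, 1000/1002) to 1e−6.

Negative training windows follow the stated sampling law: per negative
sequence, a length L uniform on 0–249 (the whole sequence if shorter), a
uniformly drawn starting heptad, and a continuous register.  Windows
shorter than nine residues cannot host a valid coil path and are resampled.

Summing over hidden-state paths biases the model toward coil calls — many
paths put a residue in a coil, one keeps it out — so a fixed offset
(default 20, configurable) is subtracted from both constants after
fitting.  Pointwise in each residue, raising the offset can only lower coil
posteriors when the sequence hosts at most one coil segment (length < 19);
with multiple possible segments, paths carrying several constants shift
relative mass and individual residues may move non-monotonically, which is
why the package's monotonicity guarantees are stated for the single-coil
regime.

## Inference

Forward–backward recursions run entirely in log space with log-sum-exp
(no scaling-factor variant), over the fixed state ordering (non-coil,
dimer a1..g9, trimer a1..g9) so matrices are bit-for-bit reproducible.  The
forward and backward log-normalizers agree to 1e−9 by construction and are
asserted at run time.  Per-residue dimer/trimer probabilities are posterior
mass sums over each class's 63 states; the displayed register is the
arg-max coil state's heptad when total coil probability exceeds 0.5
(display only — the probabilities are the contract).  A brute-force
posterior by explicit path enumeration (guarded at 14 residues) serves as
an independent oracle; forward–backward matches it to 1e−9 on randomized
models.

## Evaluation protocol

Dimer-vs-trimer classification of a known coil: per coil residue the dimer
ratio p_dimer/(p_dimer+p_trimer) (residues with zero coil posterior are
skipped), summed into dimer and trimer scores; the score ratio is compared
to a threshold (default 1; ties call dimer).  Detection: a residue is a
coil call when total coil probability strictly exceeds a cutoff (default
0.5); a positive sequence is detected only if every annotated coil residue
exceeds the cutoff; a negative is a false positive only if some 28-residue
window lies entirely above it (sequences shorter than 28 are trivially true
negatives).  ROC curves sweep the pooled unique scores plus ±infinity.

Cross-validation is leave-family-out with the nested table scheme: families
with fewer than five sequences are pooled into one miscellaneous family;
for each held-out family, the regression features of every training family
come from tables over the other n−2 training families, the regression is
fitted on those features plus negative windows (scored with tables over all
n−1 training families), and the held-out family is predicted with the n−1
tables.  Fold provenance (the record identifiers entering every table and
regression) is recorded so leakage is auditable.  Detection specificity is
measured by scoring the negative pool under a model trained on all
families, mirroring the protocol of training on everything before scoring
an external negative set.  When a fold's table or training set happens to
lack one coil class entirely (possible in tiny family collections), the
harness falls back to prior-only columns for the missing class instead of
aborting the fold.

## Synthetic study conditions

The generator emulates a curated coil corpus: per class, 6 families of 8
sequences, each with one coil of 30–90 residues (long-coil–dominated, as
curated coil sets are) with a continuous register starting at a random
phase, embedded in 10–40-residue flanks; 100 negative sequences of 60–200
residues.  Dimer coils are Leu-heavy at a/d and trimer coils Ile-heavy,
echoing the beta-branched core preference of trimers but chosen only to
make the classes separable, not to claim real coil statistics.  Families
within a class are small Dirichlet perturbations (concentration 300) of the
class composition; the background is uniform.  An optional coupling plants
correlations at a chosen distance k by copying the residue k positions
upstream with a given probability, so the correlation features can be
exercised; strength 0 recovers independence.

What passing tests show — and do not show.  The synthetic data have
independent residues (unless coupled), a uniform background, exactly one
coil per record, and family structure that is compositional jitter rather
than phylogeny.  Recovery there demonstrates the correctness of the
machinery (tallying, feature construction, regression, decoding, the
nested protocol), not the accuracy achievable on real proteins, whose
negatives contain hydrophobic stretches and whose families share deep
homology.  Statistical-consistency tests run at 504,000 coil residues per
class (6,000 coils of length 84), where the multinomial standard error
(~0.002) sits well inside the 0.01 tolerance.

## Numerical choices and degenerate inputs

* Tolerances: posterior normalization 1e−9; oracle equivalence 1e−9;
  feature factorization 1e−10; regression gradient norm < 1e−5 at
  convergence (L-BFGS ftol 1e−12).
* Empty sequences, empty FASTA, duplicate ids, register/sequence length
  mismatches and register discontinuities are hard errors; a family file's
  line count must be a multiple of four.
* A classification interval with no coil posterior mass raises an
  undefined-statistic error rather than returning a silent default; a zero
  trimer score maps the statistic to +infinity (dimer at any finite
  threshold).
* Probabilities print with six decimals; the table reader checks
  p_coil = p_dimer + p_trimer within the two columns' rounding error.

## Limitations

* Coils truncated by the sequence boundary cannot be represented, so
  posteriors near the edges of a sequence understate coil probability for
  coils running off the ends.
* The offset (20) is inherited as a fixed configuration default; the
  package does not re-derive an operating point from a specificity target.
* With the default desk-scale dataset the regression separates the classes
  perfectly, so the coefficient scale is set by the ridge rather than by
  the data — calibrated probabilities on overlapping real data would
  require no change to the machinery but would behave differently.
* Per-residue oligomer evaluation scores only residues inside annotated
  coils; unannotated flanks are not claimed as negatives for that purpose.
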