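# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `mdstab`, and what the synthetic fixtures do and do not
demonstrate.

## Input model and assumptions

A variant is a `StructureEnsemble`: a bonded topology plus N ≥ 1
coordinate frames in Å, optionally concatenated from several replicate
trajectories (boundaries recorded, all frames weighted equally in every
average).  The portable interchange format is multi-model PDB with
CONECT records; binary trajectories (XTC/DCD) are read through
MDAnalysis.  Assumptions, stated loudly:

* **No periodic-boundary imaging.**  Inputs must be whole molecules;
  trajectories wrapped across a box will produce nonsense distances.
* **Explicit hydrogens are required** on every protonated donor.  The
  package contains no protonation engine; protonate before simulating.
* Topology residue numbering is authoritative and never re-indexed.
  Mutations are written `CHAIN:WposM` (e.g. `A:N92K`) and validated
  against both the wild-type and mutant topologies.

## Selection granularities

Metrics are evaluated for the mutated residue, its surrounding, and
optionally the whole protein.  The surrounding is every protein residue
with ≥ 1 atom within 8 Å (default; `surrounding_radius`) of any atom of
the mutated residue.  Membership is **recomputed per frame** for
per-frame quantities (hydrogen-bond totals, unsatisfied counts), which
matches the per-frame averaging of those metrics; inherently
cross-frame quantities (RMSF, benchmark scores, mean hydrophobic SASA)
use the frame-0 surrounding so each residue contributes one trajectory
statistic.  Whole-protein evaluation of fluctuating metrics is opt-in
(`include_whole_protein`) because it converges much more slowly than
the local selections on sub-nanosecond trajectories; salt bridges are
the exception and are always counted protein-wide, being too rare to
appear reliably in a local selection.  Waters never enter selections —
they participate only through water bridges.

## Hydrogen-bond model

Detection is deliberately lenient (donor–acceptor ≤ 3.5 Å,
D–H···A ≥ 100°, donors/acceptors N, O, S) and the realism burden is
moved to an approximate bond energy that needs no charges:
E = 25 · S_HA · S_DHA · S_HAX kJ/mol with the three saturated ramps
given in the README.  Numerical conventions:

* The 3.5 Å detection cutoff is a donor–acceptor distance (the ramp
  then acts on the hydrogen–acceptor distance).
* Bonds with E ≤ 6.25 kJ/mol are discarded (strict: the boundary value
  itself is discarded).
* **Bifurcation capping** keys on the *hydrogen* and the *acceptor*: an
  atom's strongest retained bond keeps its energy and every further
  bond sharing that hydrogen or acceptor is capped at 15 kJ/mol.  A
  donor heavy atom serving two acceptors through two different
  hydrogens (a water, an -NH2) is not bifurcated.  Ties between equal
  energies are broken by (donor, hydrogen, acceptor) index order.
* A water in ≥ 2 retained protein bonds forms one water bridge with
  energy Σ(members) − 32.2 kJ/mol; negative bridge energies are floored
  at 0 (the desolvation penalty cannot make a bridge actively
  destabilizing in this bookkeeping).  Water–water bonds are ignored.
* Unsatisfied counting uses the broad partner set — N, O, S atoms plus
  hydrogens bound to them — and an atom engaged only through a water
  bridge counts as satisfied.  The narrower alternative (all O, plus N
  without bound H) is available as `partner_mode="methods"`.

## Flexibility and exposure

Backbone RMSF: all frames are least-squares superposed onto frame 0 on
all Cα atoms (scipy Kabsch), then RMSF is the RMS deviation from the
mean position.  Note the superposition absorbs 6 rigid degrees of
freedom, shrinking apparent fluctuation by ≈ √(1 − 2/N_Cα); tests
recovering the jitter closed form a·√3 use a 60-residue chain to keep
this below 2 %.

Sidechain RMSF aligns on the heavy backbone atoms of residues i−1..i+1
(truncated at chain ends) before measuring the residue's non-backbone
atoms, so backbone drift does not masquerade as sidechain mobility.
Glycine has no sidechain: it returns 0, is flagged in sample
collection, gets no RMSF benchmark curve, and is skipped when averaging
sidechain scores over a selection.

SASA is Shrake–Rupley (biotite), probe 1.4 Å, published single-atom vdW
radii so explicit hydrogens contribute, 100 sphere points per atom by
default (configurable; rotation sensitivity is ≈ 4 % at 100 points and
< 1 % at 1000).  Burial classes come from the trajectory-mean residue
SASA divided by a reference free-residue SASA: buried = 0 %, partial
(0, 20] %, exposed > 20 %.  The mean (rather than per-frame classes) is
used for category stability.  The shipped reference table is a
published theoretical maximum-accessibility set; any 20-residue CSV can
be substituted (`reference_sasa.csv` format: `amino_acid,sasa`).

## Benchmark curves

Per category — (amino acid × burial class) for sidechain RMSF (≤ 60
curves), amino acid for hydrophobic SASA (≤ 20) — samples from a
reference ensemble collection are fitted with a Gaussian KDE using
Silverman's rule h = 0.9·min(sd, IQR/1.34)·n^(−1/5), evaluated on a
512-point uniform grid over [0, max + 3h], scaled to max 1, and made
monotone non-increasing with a suffix-maximum envelope (each grid value
becomes the max of itself and everything to its right).  The grid and
range are a package choice — curves ship with their grids in the CSV
(`category,x,y`), so scoring is self-consistent regardless of how the
curves were produced.  Scoring interpolates linearly and clamps to the
endpoint values outside the grid.  Categories with < 2 distinct samples
are omitted and listed in the build manifest; they fail loudly at
scoring time rather than silently returning a default.

## Structural checks

Helices are assigned on frame 1 only, with the Kabsch–Sander
electrostatic criterion E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH −
1/r_CN) kcal/mol, bond if E < −0.5; α-helices are runs of i→i+4 bonded
turns (two consecutive turns make residues i..i+3 helical; runs ≥ 4
become segments).  Helix propensity uses a shipped experimental scale
in kJ/mol (Ala = 0, Pro = 13.22) and is only charged for sites ≥ 5
residues from both helix termini, keeping it independent of capping.
The capping check flags mutations within 5 residues of a helix terminus
whose wild-type residue fills a capping role (N-cap: Asn/Asp/Ser/Thr/
Gly; C-cap: Gly) that the mutant does not preserve.  The motif table is
a documented approximation of the richer capping-motif literature and
is swappable via the function's arguments.  Disulfides count explicit
SG–SG bonds, falling back to a 2.3 Å frame-1 distance criterion.  Salt
bridges are Asp/Glu carboxylate O within < 4 Å (strict) of Lys NZ,
Arg NE/NH1/NH2, or His ring N — His only when both ring nitrogens are
protonated in the topology — counted once per residue pair per frame
and frame-averaged.

## Scaling, composite, ranking

Columns are divided by their population SD (ddof = 0) across the
mutation set — population rather than sample SD because the set is the
entire universe being ranked — and multiplied by a fixed polarity
(+1: H-bond energy, sidechain and exposure scores, salt bridges,
disulfides; −1: unsatisfied count, backbone RMSF, helix propensity,
capping flag).  No mean-centering, so 0 remains the wild-type anchor.
The binary capping flag bypasses SD division and enters as 0/−1.
Zero-SD columns are dropped from the composite with a logged warning.
Each (metric × selection) pair is a separate composite column (rather
than first averaging a metric across selections).  The composite is the
arithmetic mean; ranking sorts descending with lexicographic
tie-breaks on the mutation id.  A primary predictor's numeric score can
be appended as one more column, normalized identically (default
polarity −1 for ΔΔG-style scores).

## Evaluation toolkit

Stabilizing means ΔTm strictly > 0 °C (configurable threshold); neutral
mutations count as failures.  ROC curves process score ties as blocks
(diagonal segments) and integrate by trapezoid.  The stability-weighted
ROC gives positive i a TPR step of ΔTm_i/ΣΔTm while negatives keep
uniform 1/N_neg steps; with equal ΔTm it reduces exactly to the
unweighted curve.  The unweighted implementation is cross-checked in
tests against both a Mann–Whitney pair-counting oracle and
scikit-learn's `roc_curve`.  For sets with untested mutations, AUC
bounds flip the k best-ranked (upper) or k worst-ranked (lower)
untested entries to positive for k = 0..U, untested-not-flipped
counting as negative; the fraction sweep instead averages the AUC over
seeded random placements of round(f·U) hidden positives (1000
repetitions by default).

## ML harness

Repeated stratified k-fold (4 splits × 10 repeats); per repeat the test
folds' predictions are pooled into one ranking and scored, and the
AUCs are averaged across repeats.  Classifiers rank by positive-class
probability, regressors by predicted ΔTm; regression rows are
stratified by their binary stabilizing bin, since continuous targets
have no natural strata.  Fold assignment depends only on labels, seed,
and the split geometry.  Grid search is exhaustive, objective
(AUC + weighted AUC)/2, first-in-grid tie-break.  Estimators come from
scikit-learn behind a fit/predict(_proba) contract; the stock set is
SVC, k-NN, random forest (classification) and SVR, ridge, random
forest (regression), with no claim that these defaults match any
particular published hyperparameters.

## Synthetic fixtures: what they show and what they don't

The fixtures module builds ideal-geometry peptides (NeRF chain
extension; helix φ = −57°, ψ = −47°; per-residue dihedrals supported),
seeded Gaussian-jitter "trajectories", exact-geometry hydrogen-bond /
bifurcation / water-bridge / salt-bridge toys, and seeded log-normal
benchmark sample tables.  Sidechains beyond Cβ use generic idealized
geometry that preserves the bonded graph and PDB atom names but is not
physically relaxed; jitter frames have no force field behind them.
Consequently the test suite demonstrates *algorithmic* correctness —
exact reproduction of the analytic constants, property invariants,
closed-form parameter recovery — and the package's behavior on real MD
output inherits the usual caveats of short-trajectory sampling, force
field accuracy, and mutant-structure quality.  Scoring runs on real
data at roughly the cost of the per-frame hydrogen-bond detection and
SASA, which dominate.

Problem sizes used by the default test run and the acceptance script
are small by design: toy systems of 4–21 residues, jitter ensembles of
6–2000 frames, evaluation instances of n ≤ 50, and an ML matrix of
n = 200 × 5 — enough for every stated tolerance while keeping the whole
suite under a minute of CPU.

## Known limitations

* No charge model: hydrogen-bond energies are geometric estimates; very
  short or strained bonds are clamped to the ideal plateau.
* His protonation is read from the topology, not predicted.
* The capping-motif catalogue is minimal (N-cap/C-cap role residues).
* Benchmark curves are only as representative as the ensemble
  collection they were fitted from; the package ships none and expects
  users to fit their own (`mdstab benchmark`) or supply compatible CSVs.
* Static single-frame input is accepted, but RMSF-based metrics are
  then undefined and omitted from the table.
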