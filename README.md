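# mdstab

Secondary filtering and ranking of candidate stabilizing point mutations
from molecular-dynamics structure ensembles.

## The problem

Thermostability predictors (empirical force fields, ML models) are good
at rejecting destabilizing mutations but rank the remaining, nominally
stabilizing candidates poorly — experimental success rates for
"predicted stabilizing" sets hover around 30 %.  Engineering pipelines
therefore add a second filter: short MD simulations of each candidate
mutant, traditionally judged by expert visual inspection.  `mdstab`
formalizes that inspection into a reproducible, automated score.  Its
users are protein engineers who already have a primary predictor's
shortlist and per-variant MD snapshots (even very short runs, e.g.
5 × 50 ps) and want an objective ranking of which mutants to take to the
bench.

## The method

For each mutation *m* with ensemble *E_m* and wild-type ensemble *E_wt*,
every metric *x* is frame-averaged per variant and reported as a delta

Δx(m) = ⟨x⟩_{E_m} − ⟨x⟩_{E_wt},

evaluated at up to three granularities: the mutated residue itself, its
8 Å surrounding, and (opt-in) the whole protein.  The metrics:

* **Hydrogen-bond energy.**  Candidates are all N/O/S donor–acceptor
  pairs with donor–acceptor distance ≤ 3.5 Å and D–H···A angle ≥ 100°.
  Each bond is scored without charge information as

  E = 25 · S_HA · S_DHA · S_HAX  (kJ/mol),

  with saturated ramps S_HA = clamp((2.6 − max(d_HA, 2.1))/0.5),
  S_DHA = clamp((min(θ_DHA, 165°) − 100°)/65°), and S_HAX the minimum
  over acceptor neighbours X of clamp((θ_HAX − 85°)/10°) (heavy X) or
  clamp((θ_HAH − 75°)/10°) (hydrogen X).  Bonds at ≤ 6.25 kJ/mol are
  discarded; bifurcated bonds beyond an atom's strongest are capped at
  15 kJ/mol.  Waters hydrogen-bonded to ≥ 2 protein atoms form water
  bridges worth the member-bond sum minus a 32.2 kJ/mol entropic
  penalty.
* **Unsatisfied donors/acceptors.**  Polar atoms (N/O/S and their bound
  hydrogens) engaged in no retained bond.
* **Flexibility.**  Cα RMSF after global superposition (backbone), and
  per-residue sidechain RMSF after local ±1-residue alignment, mapped to
  a [0, 1] score through benchmark curves per (amino acid × burial
  class) — 60 categories.
* **Hydrophobic exposure.**  Shrake–Rupley SASA of C and C-bound H
  atoms, scored through 20 per-amino-acid benchmark curves.
* **Structural checks.**  Salt bridges (acidic O — basic N < 4 Å,
  counted per residue pair, frame-averaged, always whole-protein),
  disulfide counts, helix-propensity penalties (Ala = 0, Pro =
  13.22 kJ/mol) for mid-helix sites, and helix-capping disruption flags.

Each delta column is divided by its population SD across the mutation
set (zero stays the wild-type reference), sign-adjusted so positive
means stabilizing, and the **composite score** — the plain mean of the
scaled columns — ranks the mutations.  Benchmark curves are Gaussian
KDEs (Silverman bandwidth) scaled to max 1 and made monotone
non-increasing with a suffix-maximum envelope; a `benchmark` command
fits them from any ensemble collection.

For evaluation against measured ΔTm the package provides ROC/AUC, a
stability-weighted ROC (each positive's TPR step ∝ its share of total
ΔTm), combinatorial AUC upper/lower bounds for partially untested sets,
a randomized fraction sweep, and a repeated stratified 4×10
cross-validation harness for re-ranking with scikit-learn estimators.

## Worked example

Everything below is generated in-process by the synthetic-fixtures
module — a 16-residue helix "wild type" plus three mutant jitter
ensembles (10 frames each), benchmark curves fitted from a seeded
synthetic sample table:

```python
from mdstab import Mutation, ScoringConfig, build_benchmark, score_mutations
from mdstab.synthetic import (FixtureSpec, build_benchmark_samples,
                              build_ideal_peptide, jitter_trajectory)

seq = "ADKLSNQERTVYFAMW"
make = lambda s, seed: jitter_trajectory(
    build_ideal_peptide(s), FixtureSpec(s, n_frames=10, jitter=0.12, seed=seed))
wt = make(seq, 0)
mutants = {
    Mutation("A", 5, "S", "R"): make("ADKLRNQERTVYFAMW", 15),
    Mutation("A", 7, "Q", "K"): make("ADKLSNKERTVYFAMW", 17),
    Mutation("A", 12, "Y", "A"): make("ADKLSNQERTVAFAMW", 22),
}
rmsf_curves, sasa_curves, _ = build_benchmark(build_benchmark_samples(seed=3))
table = score_mutations(wt, mutants,
                        ScoringConfig(rmsf_curves=rmsf_curves, sasa_curves=sasa_curves))
print(table[["raw:hbond_energy[surrounding]", "raw:unsatisfied[surrounding]",
             "composite", "rank"]].round(3))
```

```
          raw:hbond_energy[surrounding]  raw:unsatisfied[surrounding]  composite  rank
mutation
A:Y12A                           -8.155                          -1.8      0.465     1
A:Q7K                            -0.391                           0.2      0.402     2
A:S5R                             5.084                           5.7      0.007     3
```

Raw columns are mutant-minus-wild-type deltas in physical units
(kJ/mol for hydrogen-bond energy, counts for unsatisfied partners).
The composite is the mean of the SD-scaled, sign-adjusted columns
across *all* metrics and selections: A:S5R gains hydrogen-bond energy
(+5.1 kJ/mol) but also 5.7 new unsatisfied polar atoms, which cancels
it down to ~0, while A:Y12A's reduced unsatisfied count, lower local
RMSF, and better exposure score outweigh its bond-energy loss in this
toy set.  Columns with zero spread across the set (here e.g. salt
bridges — none of these mutations touches one) are dropped from the
composite with a logged warning.

The same pipeline is available from the shell:

```bash
mdstab fixtures --out-dir fx --seed 1
mdstab run --wt fx/wt.pdb --mutant A:S5R fx/mutant.pdb --out scores.tsv
mdstab evaluate --scores labeled.csv --bounds --sweep 0.1,0.3 --out report.json
```

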