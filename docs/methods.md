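# Methods

This note documents the models implemented in `smoothdescent`, the
assumptions behind them, the defaults and why they were chosen, and what
the simulation-based tests do and do not demonstrate.

## Inheritance model and naive IBD

An F1 offspring of parents with even ploidies p₁ and p₂ inherits p₁/2
homologues from parent 1 and p₂/2 from parent 2. We assume strict bivalent
pairing and no double reduction, so within a parent the transmitted
homologues are distinct and every choice is a priori equally likely. The
resulting configuration space has C(p₁,p₁/2)·C(p₂,p₂/2) elements (4, 36
and 400 for diploid, tetraploid and hexaploid crosses). Double-reduction
gametes (two copies of one homologue, at most two) are counted by
`count_configurations_with_double_reduction` as a combinatorial
cross-check — 100 for a tetraploid cross — but are excluded from all
probability calculations: double reduction is rare in practice and
including it would make every dosage explicable by some configuration,
weakening the phase-impossibility signal.

Naive IBD conditions only on the single-marker dosage: the probability of
homologue h is the fraction of dosage-compatible configurations containing
h. Two consequences worth knowing:

- Per parent, the probabilities of an informative cell always sum to the
  number of transmitted homologues (p/2) — the implementation is tested
  against an independent enumeration oracle on this.
- Because conditioning is on the *total* dosage, a truly inherited
  homologue of a weakly heterozygous parent can receive less probability
  than a non-inherited homologue of a highly heterozygous one. The
  familiar "truth outranks non-truth within a parent" intuition is a
  theorem only for diploids; for higher ploidies only positivity is
  guaranteed (an inherited homologue never gets probability zero on
  error-free data). The tests encode exactly these two scopes.

Dosages that match no configuration (phase-impossible) are treated as
missing for IBD purposes and pre-flagged for correction. Missing dosages
are simply uninformative: excluded from smoothing, never flagged.

## Smoothed IBD prediction

The prediction at marker m is a weighted average of observed IBD at the
markers within *l* of m, per homologue and individual, with weights
proportional to the no-recombination probability 1−ρ(d) of the separating
distance. Defaults and choices:

- **l = 10 cM.** Wide enough to hold ~20 markers at the simulated density
  of 2 markers/cM, narrow enough that within-window recombination is
  uncommon (ρ(10 cM) ≈ 0.09).
- **Map function: Haldane** (no interference), matching the meiosis model
  used for simulation and mapping; Morgan and Kosambi are available.
  Note the weight profile is *not* invariant to a uniform rescaling of
  distances (normalising 1−cρ changes with c); weights simply decrease
  with distance under every map function.
- **Informative band [0.3, 0.7], inclusive at both ends.** Observed values
  in this band indicate uncertain inheritance; averaged in, they pull
  predictions toward 0.5 and mask true disagreements, so they are removed
  from every window. Inclusive endpoints are a convention choice; the
  measure-zero boundary makes it immaterial in practice.
- **The centre marker is excluded from its own window**, so a cell's
  prediction is independent of the value under test — otherwise each error
  would partially vouch for itself.
- Cells with an empty window (isolated markers, or all neighbours
  uninformative) get no prediction and can never be flagged.
- **Physical-position mode** accepts bp coordinates and a bp window
  (e.g. 1 Mbp); since bp separations carry no absolute recombination
  scale, weights fall off linearly with distance within the window. Order
  is taken as given and never re-estimated in this mode.

## Error calling, imputation, iteration

A cell is called an error when any homologue shows |observed − predicted|
> δ with an informative observation and a non-missing prediction. δ starts
at 0.9 and decreases linearly to 0.7 over the requested iterations (a
single iteration uses 0.9): early rounds, working on the least reliable
map, only act on the most flagrant disagreements. Flagged cells are
replaced by the dosage of the configuration with the highest product of
predicted homologue probabilities over *all* configurations — the observed
genotype is presumed wrong, so it does not constrain the search. Ties are
resolved at dosage level: if all near-maximal configurations agree on the
dosage it is used, otherwise the cell is set missing. Previously corrected
cells may be re-flagged in later rounds; idempotence is not assumed.

Default **5 iterations**: in our simulations (as in the method's published
behaviour) the largest improvements come in the first rounds and the
metrics plateau well before round 5.

## Two-point mapping

Recombination fractions are estimated per marker pair by maximum
likelihood under exactly the meiosis model that generates the data:
homologues pair uniformly at random into bivalents, each bivalent
transmits one strand starting on either partner with probability ½ and
switching with probability r between the loci. The parental joint
contribution distribution is averaged over all (p−1)!! pairings and
convolved across parents to give P(g₁,g₂ | H, r); per-individual counts
enter a grid search (step 0.005 on [0, 0.5]) refined by a parabolic step,
with LOD = log₁₀ L(r̂) − log₁₀ L(0.5). Zero-probability genotype pairs
(true errors) are floored at 10⁻¹² so they depress rather than void the
likelihood — errors therefore inflate r̂, which is precisely the pathology
the correction loop repairs. Tables depend only on the phase rows, so they
are cached per pattern pair and reused across all iterations of a run;
this caching is what keeps hexaploid populations at ~15 s per full run
instead of minutes.

Ordering follows the weighted-MDS convention: distances are the Haldane
transform of r̂ (capped at r = 0.49), weights LOD², a 2-D weighted SMACOF
embedding (initialised by classical MDS) is parameterised by a principal
curve (running-mean smoothing, nearest-point projection), and **positions
are arc length along that curve**. Arc length — rather than summing
adjacent-pair Haldane distances — is the deliberate choice here: with 200
markers on 100 cM, adjacent r̂ under 10% genotyping error is dominated by
the error signal, and cumulative adjacent distances would produce maps an
order of magnitude too long, whereas the weighted embedding pools every
informative within-window pair. Orientation is fixed by correlating with
the previous iteration's positions (input order for the first map), which
keeps maps stable across rounds; a disconnected LOD graph raises an error
naming the components. Linkage-group assignment is out of scope: inputs
are assumed to be one chromosome.

## Best-iteration selection and evaluation

Each mapped round is scored by the R² of the least-squares fit
d = a + br + cr² over marker pairs within 20 cM on that round's map (plus
all map-adjacent pairs). Restricting the pair set matters: distant pairs
saturate at r = 0.5 and would dilute the signal. The round with the
highest R² wins, ties to the earliest; with fewer than three usable pairs
the last round is returned with a warning.

Simulation-mode evaluation reports the three study metrics: genotyping
error (fraction of cells differing from truth, missing counted as
different), position correlation (absolute Pearson, since maps have
arbitrary orientation) and map length (cM span).

## The simulator

`simulate` generates the study conditions used throughout the tests: one
chromosome of 100 cM carrying 200 biallelic segregating markers at
variable density (Dirichlet-distributed spacings), 100 F1 individuals,
ploidies 2/4/6. Parent haplotypes are Bernoulli(½) with
monomorphic-in-cross rows resampled. Meioses use uniform bivalent pairing,
no interference (Haldane interval probabilities), no double reduction, and
pairing is resampled independently per meiosis. Errors replace a cell's
dosage with a uniform draw over the other valid dosages, under a uniform
rate, per-individual rates (special case A: 80 individuals at 0.02, 20 at
0.3) or a positional cubic-spline profile (special case B: rates
0.02/0.1/0.3/0.02/0.1 at quarter-chromosome knots, clipped to [0, 1]).

What the simulator does *not* emulate: crossover interference,
double reduction or multivalent pairing, preferential pairing, segregation
distortion, depth-dependent dosage uncertainty (errors are uniform
replacements, not read-count noise) and phasing mistakes in the parents
(the phase given to the algorithm is exact). Passing simulation tests
therefore demonstrates the machinery under its own generative assumptions;
on real data, phasing quality and non-uniform error processes are the
practically limiting factors.

## Numerical and degenerate-input choices

- Probabilities are exact rationals realised in floating point; the
  enumeration tests assert 1e-12 agreement with a brute-force oracle.
- Imputation ties use a 1e-9 relative tolerance on configuration scores.
- The likelihood floor (1e-12), rf grid step (0.005) and the r-cap for
  distance transforms (0.49) bound all logs and distances.
- Single-marker maps have length 0; i = j pairs have r = 0 by definition;
  pairs with fewer than 10 doubly genotyped individuals return (0.5, 0).
- SMACOF runs at most 300 iterations or to a 1e-7 relative stress
  improvement; the principal curve uses a running-mean window of ~12% of
  the markers and at most 8 projection rounds.

## Known limitations

- Dosage calls are taken at face value (no genotype likelihoods); an
  extension point exists for HMM-based IBD prediction but only the
  weighted-average predictor is implemented.
- Naive IBD treats configurations as equiprobable, ignoring linkage
  between adjacent markers within the same calculation; this is what makes
  it cheap and error-sensitive, by design.
- Ordering quality degrades when the preliminary map is poor (hexaploids
  at high error rates); the iteration loop recovers much, but not all, of
  the true order — measured behaviour is reported by the acceptance
  script rather than asserted as exact values.
- Diploid correction in this implementation is somewhat stronger than the
  figures published for the original R implementation of the method
  (final error ~2–3% rather than ~5% at 10% injected error); the
  correction mathematics is the same, and the difference is consistent
  with the model-matched mapper producing cleaner maps, hence fewer wrong
  imputations. The acceptance script reports what this code computes.
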