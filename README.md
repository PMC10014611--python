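# smoothdescent

Ploidy-aware detection and correction of genotyping errors in F1 mapping
populations, built around identity-by-descent (IBD) probabilities.

High-throughput genotyping (GBS, skim sequencing) delivers dense marker
sets with error rates that routinely reach 5–20%. Linkage-map construction
is notoriously sensitive to such errors: every wrong dosage looks like a
double recombination, inflating two-point recombination-fraction estimates,
scrambling marker orders and stretching maps well past their true length.
The problem is worse in autopolyploids (potato, rose, sweet potato), where
polysomic segregation already makes linkage estimation harder. This package
implements **Smooth Descent**, an iterative correction scheme for F1
populations of any even ploidy (including mixed-ploidy crosses) that uses
phased parental haplotypes to detect and re-impute erroneous offspring
dosages while re-estimating the linkage map each round. A polysomic
meiosis simulator is included so the method's behaviour can be measured
against a known truth.

## The method

Given the phased parental homologue matrix **H** (markers × p homologues,
entries 0/1) and offspring dosages **G** (markers × individuals):

1. **Naive (observed) IBD.** At each marker an offspring carries one of the
   inheritance *configurations* c — a choice of p₁/2 homologues from parent
   1 and p₂/2 from parent 2 (no double reduction; C(p₁,p₁/2)·C(p₂,p₂/2)
   configurations: 4 diploid, 36 tetraploid, 400 hexaploid). Each
   configuration implies a dosage d(c) = Σ_{h∈c} H[m,h]. With all
   configurations a priori equally likely,

   p(H_h | g) = #{c ∈ C_g : h ∈ c} / |C_g|,   C_g = {c : d(c) = g}.

   These probabilities are deliberately error-sensitive: one wrong dosage
   flips them completely.

2. **Predicted (smoothed) IBD.** For marker m_i the local set L_i holds the
   markers within *l* cM (default 10) whose observed IBD is *informative*
   (outside the [0.3, 0.7] band). The prediction is the convex combination

   î_i = Σ_{j∈L_i} w_j · i_j,  w_j ∝ 1 − ρ(d_ij),

   where ρ is an inverse mapping function (Morgan, Haldane or Kosambi) of
   the map distance — the weight is the no-recombination probability of the
   interval. The centre marker is excluded from its own window.

3. **Error calling and imputation.** A cell is an error when some homologue
   has |i − î| > δ, with δ = 0.9 in the first iteration easing linearly to
   0.7 in the last. Genotypes whose dosage is impossible under the parental
   phase are always flagged. Flagged cells are re-imputed with the dosage
   of the configuration maximising Π_{h∈c} î_h (ties across distinct
   dosages → missing).

4. **Re-mapping and iteration.** After each round the linkage map is
   re-estimated: two-point recombination fractions by maximum likelihood
   under the same bivalent-pairing meiosis model the simulator uses, then
   marker ordering by LOD²-weighted multidimensional scaling with a
   principal-curve parameterisation that yields cM positions. Each
   iteration is scored by the R² of the quadratic fit d = a + br + cr²
   between inter-marker distance and recombination fraction over close
   pairs; the round with the highest R² is the final answer.

## Worked example

The three-marker diploid cross with phased parents

```python
import numpy as np
import smoothdescent as sd

H = sd.HomologueMatrix([[1, 0, 0, 0],
                        [0, 1, 1, 0],
                        [0, 0, 0, 1]], ploidy_p1=2, ploidy_p2=2)
G = sd.DosageMatrix(np.array([[1.0], [0.0], [1.0]]))  # one offspring
I0 = sd.naive_ibd_population(H, G)
print(I0.probs[:, :, 0])
```

prints the observed IBD matrix of that individual:

```
[[1.  0.  0.5 0.5]
 [1.  0.  0.  1. ]
 [0.5 0.5 0.  1. ]]
```

Row 1: genotype 1 with H-row (1,0,0,0) is only explained by configurations
{H1,H3} and {H1,H4}, so H1 is certainly inherited (p=1) while H3 and H4
split the remaining probability (0.5 each).

A full correction run on simulated tetraploid data:

```python
cfg = sd.SimConfig(ploidy_p1=4, ploidy_p2=4, n_individuals=100,
                   n_markers=200, seed=42)
bundle = sd.simulate_experiment(cfg, sd.ErrorProfile.uniform(0.10), seed=42)
results = sd.run_smooth_descent(bundle.G_observed, bundle.H,
                                sd.SmoothDescentConfig(verbose=True))
best = sd.best_iteration(results)
for label, res in (("preliminary", results[0]), (f"iteration {best}", results[best])):
    m = sd.evaluate(res, bundle.G_true, bundle.positions)
    print(f"{label}: error {100*m.genotyping_error:.2f}%  "
          f"position corr {m.position_correlation:.3f}  map {m.map_length:.1f} cM")
```

```
[iter 0] preliminary map length=207.2 cM R2=0.0296
[iter 1] delta=0.90 flags=1107 map length=160.2 cM R2=0.0591
...
[iter 5] delta=0.70 flags=368 map length=93.8 cM R2=0.2157
preliminary: error 10.06%  position corr 0.750  map 207.2 cM
iteration 5: error 5.81%  position corr 0.984  map 93.8 cM
```

Starting from 10% corrupted dosages, five rounds nearly halve the
genotyping error, lift the truth/estimate position correlation from 0.75
to 0.98 and bring the error-inflated 207 cM map back to the true ~100 cM
scale.

The same pipeline is available from the shell:

```bash
smoothdescent simulate --ploidy 4 --n-ind 100 --n-markers 200 \
    --error-rate 0.1 --seed 42 --out pop/
smoothdescent run --genotypes pop/dosage.tsv --phase pop/phase.tsv \
    --ploidy1 4 --ploidy2 4 --iterations 5 --out run/
smoothdescent evaluate --run run/ --truth pop/
```

`--special-case A|B` simulates heterogeneous error rates (per individual /
along the chromosome), and `run --physical positions.tsv` performs a
single order-preserving pass for marker sets with known physical positions.

## Layout

| module | contents |
| --- | --- |
| `smoothdescent.simulate` | polysomic meiosis simulator, error injection |
| `smoothdescent.ibd` | configurations, naive IBD probabilities |
| `smoothdescent.smoothing` | map functions, informativeness filter, windowed prediction |
| `smoothdescent.correct` | error calling, δ schedule, imputation |
| `smoothdescent.mapping` | two-point ML recombination fractions, weighted-MDS ordering |
| `smoothdescent.engine` | iteration loop, best-round selection, evaluation metrics |
| `smoothdescent.io` / `smoothdescent.cli` | TSV/YAML artifacts, `smoothdescent` command |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
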