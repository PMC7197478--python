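# cyclephase

Continuous cell-cycle phase from paired FUCCI fluorescence imaging and
single-cell RNA-seq.

## The problem

Single-cell studies usually handle the cell cycle by binning cells into
discrete stages (G1, S, G2/M) from a handful of markers and arbitrary
gates. But cell-cycle progression is a continuous process, and most cells
in an unsynchronized culture sit between the canonical stages. `cyclephase`
treats progression as an angle theta on the unit circle and provides the
full workflow for measuring it, characterizing its transcriptional
signature, and predicting it from expression alone:

1. **FUCCI quantification** — detect nuclei in DAPI well images and score
   each channel as log10 of the background-corrected summed intensity in a
   fixed 100x100 px cell area.
2. **Phase inference** — remove plate effects with a linear model
   (`score ~ plate + individual`, keeping individual effects), then map
   each cell's centered (EGFP, mCherry) score pair to an angle
   `theta = atan2(EGFP_c, mCherry_c)`; PAM (k-medoids, k = 3) supplies
   discrete G1/S/G2M labels when comparisons need them.
3. **Cyclic trends** — for each gene, estimate f_g(theta), the smooth
   periodic expression trend, by quadratic trend filtering

       min_beta (1/2)||y - beta||^2 + lambda ||D^(3) beta||_1

   on the phase-ordered, thrice-concatenated series (middle third kept, so
   the fit closes at 0/2pi). The penalty is chosen by ordered 5-fold CV
   with the 1-SE rule; fit quality is the proportion of variance explained
   (PVE), and significance comes from a permutation null built from a
   well-detected template gene.
4. **Phase prediction (naive Bayes on a grid)** — store (f_g, sigma_g) for
   a ranked marker panel (default: CDK1, UBE2C, TOP2A, H4C5, H4C3); for a
   new cell with normalized expression y, evaluate

       log L(k) = sum_g log N(y_g | f_g(theta_k), sigma_g^2)

   on K = 100 equally spaced candidate phases and report the argmax.
   Accuracy is the circular error min(|d|, 2pi - |d|)/2pi (max 0.5; random
   guessing averages 0.25), assessed by leave-one-individual-out
   cross-validation.
5. **Benchmark adapters** — translate other tools' cyclic orderings and
   discrete phase scores into comparable angles and misclassification
   rates.
6. **Synthetic data** — a seeded generator for phases, cyclic expression
   (normalized and count scale, with library-size variation and dropout),
   quadrature FUCCI scores with batch structure, and channel images, so
   the whole pipeline is testable without any downloads.

The trend-filter solver is written in-house (log-barrier interior point on
the exact dual box-QP, banded O(n) Newton steps, numba-compiled) and is
cross-checked in the tests against an independent convex solve.

## Worked example

`examples/` holds one short script per capability. Training and prediction
(`examples/04_train_and_predict.py`):

```text
per-gene residual scales: {'CDK1': 0.28, 'UBE2C': 0.279, 'TOP2A': 0.296,
                           'H4C5': 0.304, 'H4C3': 0.331}
mean prediction error: 2.7% of the cycle (random guessing would give 25%)
K = 100 candidate phases evaluated per cell
```

Five cosine marker genes with noise SD 0.3 are fit on 300 labeled cells;
the residual scales recover the planted noise level, and 100 held-out
cells are placed on the cycle to within ~3% of a full revolution. Cyclic
gene discovery (`examples/03_cyclic_genes.py`):

```text
 gene_id      pve  empirical_p  rank
gene0003 0.871080     0.009901     1
...
6 genes at the minimum attainable p = 1/101
enrichment in the planted cyclic set: OR = 637.0, exact p = 1.68e-06
```

All six planted cyclic genes hit the permutation floor (p = 1/(B+1) with
B = 100) while null genes spread over larger p-values.

A `cyclephase` CLI wraps the same library for shell pipelines
(`cyclephase simulate | qc | fucci-phase | cyclic-genes | train | predict |
crossval | benchmark-adapt`); every run writes a JSON provenance record
with seeds and parameters.

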