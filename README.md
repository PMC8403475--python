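# dietquant

Quantitative diet analysis from DNA metabarcoding feeding trials.

DNA metabarcoding of faecal samples can, in principle, do more than list
what an animal ate: if the number of sequence reads scales with ingested
biomass, the *relative read abundance* (RRA) of each food taxon estimates
its share of the diet. Whether that quantitative relationship holds is
system-specific — marker copy number, PCR efficiency and digestion all
distort it — so it has to be validated with feeding trials in which
animals eat mixtures of known biomass composition. `dietquant` is a
toolkit for designing, simulating and analysing such trials. It targets
the classic small-herbivore setting (a few plant taxa fed in rotating
biomass proportions, faecal pellets amplified in several PCR replicates)
but nothing in the code is specific to voles or plants.

The package has three parts:

1. **Trial simulator** (`dietquant.synthetic`) — generates MOTU × PCR
   replicate read-count tables with known ground truth: rotation designs
   (e.g. 60/30/10% biomass), taxon-specific amplification and digestion
   bias, Dirichlet-multinomial replicate noise, log-normal sequencing
   depth, low-level contaminant MOTUs and occasional aberrant replicates.
2. **Filtering cascade** (`dietquant.filtering`) — the standard
   metabarcoding cleanup from replicate counts to per-sample RRA:
   artefact-flag removal, iterative PCR-replicate outlier removal by
   Euclidean distance, replicate averaging, a 1% within-sample
   relative-frequency filter, an 85% reference-identity filter, taxon
   merging/dropping, and normalisation — with a per-stage audit trail.
3. **Compositional regression** (`dietquant.regression`) — a
   transformation-free linear model between compositions,

   *E*[*y<sub>i</sub>*] = *x<sub>i</sub>* **B**,

   where both the predictor *x* (expected biomass fractions) and outcome
   *y* (RRA) lie on the unit simplex and **B** is a row-stochastic
   *transition matrix*: entries in [0, 1], unit row sums. **B** is fitted
   by minimising the Kullback–Leibler divergence
   Σ<sub>ik</sub> *y<sub>ik</sub>* log(*y<sub>ik</sub>*/*μ<sub>ik</sub>*)
   with monotone EM-style multiplicative updates, so predictions stay on
   the simplex without log-ratio transforms and each coefficient
   *B<sub>jk</sub>* reads directly as "the share of predictor component
   *j* that shows up as outcome component *k*". A diagonal near 1 means
   reads mirror biomass. Inference is nonparametric: permutation tests
   for overall linear dependence, percentile bootstrap intervals and
   leave-one-out cross-validation.

`dietquant.pipeline.run_study` ties the three together; the `dietquant`
command-line tool exposes `simulate`, `filter`, `fit`, `report` and
`run-study` subcommands.

## Worked example

Simulate the vole-style trial (3 plant taxa, 60/30/10 rotations, 9
animals, 3 PCR replicates, ~18k reads per replicate) with one taxon
amplifying at 5% efficiency, then run the full analysis:

```python
import dietquant as dq

design = dq.build_design(("Trifolium", "Salix", "Avenella"))
bias = dq.BiasModel(amplification_factor={"Trifolium": 0.05})
table, truth = dq.simulate_trial(design, bias, seed=11)

cfg = dq.PipelineConfig(n_perm=1000, n_boot=1000, seed=11)
report = dq.run_study(table, design, cfg)

print(report.faeces.fit.B.round(2))
print("permutation p:", round(report.faeces.permutation.p_value, 4))
print("LOOCV RMSE:", round(report.faeces.cv.rmse, 4))
```

prints

```
           Trifolium  Salix  Avenella
Trifolium        0.1   0.55      0.35
Salix            0.0   1.00      0.00
Avenella         0.0   0.00      1.00
permutation p: 0.001
LOOCV RMSE: 0.0728
```

Read the B matrix row-wise: of the biomass share fed as *Trifolium*, only
10% shows up as *Trifolium* reads in faeces — the rest is re-attributed
to the two taxa that amplify normally — while *Salix* and *Avenella*
diagonals of 1.00 mean their read shares track their biomass shares. The
permutation test still finds a strong overall linear dependence
(p = 0.001), and the LOOCV RMSE of 0.073 summarises out-of-sample
prediction error per composition cell. The same run reports bootstrap
intervals per coefficient (e.g. [0.08, 0.11] for the *Trifolium*
diagonal, [0.99, 1.00] for *Salix*): systematic under-amplification is
clearly distinguishable from noise. With the bias removed, both
regressions return near-identity B (diagonals ≥ 0.95).

The same analysis from the shell:

```sh
dietquant simulate --seed 11 --out trial.tsv
dietquant run-study --table trial.tsv --seed 11 --outdir study/
```

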