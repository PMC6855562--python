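# radnet

Network-based nomination of radioresistance driver genes from paired
radioresistant/radiosensitive omics profiles, with transfer of the
nominated drivers to patient relapse data.

## The problem

When a cancer cell line acquires radioresistance it typically carries
hundreds to thousands of DNA copy-number alterations, and broad
deletions or amplifications drag along many passenger genes. With a
single resistant/sensitive pair per cell line, standard per-gene
statistics cannot separate drivers from passengers. `radnet` implements
a network strategy for this situation:

1. **Copy-number calling** — segmented aCGH log2-ratio profiles are
   mapped onto genes (overlap-weighted means) and trinarized at
   |log2-ratio| > 0.1.
2. **Differential expression** — quantile-normalized replicate arrays
   are collapsed to a chromosomally ordered average log2-ratio profile
   and segmented by a three-state Gaussian HMM (underexpressed /
   unchanged / overexpressed, initial means −1.25 / 0 / +1.25), with
   per-gene states assigned by posterior decoding. Genes altered in the
   same direction on both layers are the *direct candidates*.
3. **Network inference** — on a patient cohort, each gene's expression
   x_g is modeled as x_g = β₀ + β_cn·c_g + Σ_{j≠g} β_j·x_j by lasso
   regression with the penalty at minimum 10-fold CV error; predictors
   are kept when the covariance test for the lasso path gives
   p below the selection cutoff, local regulators are pruned, and the
   per-gene models form a signed directed network whose per-gene
   predictive power is scored on independent data.
4. **Propagation impact** — each candidate's expression log2-ratio is
   propagated along all network paths up to length 5 (edge coefficients
   × predictive-power node weights); its mean absolute impact on known
   radioresistance marker genes is compared against 10 degree-preserving
   network permutations (one-sided t-test, Benjamini–Hochberg q < 0.01).
5. **Patient transfer** — drivers with sign-consistent expression/relapse
   correlations in irradiated patients are screened as relapse markers by
   optimal-cutoff Kaplan–Meier splitting constrained to ≥ 8 patients per
   group, with asymptotic and exact permutational log-rank p-values,
   conservative (BH) and liberal (Storey) FDR estimates, random-gene
   baselines, and covariate-adjusted Cox models.

A synthetic-data generator (`radnet.synthetic`) supplies every input
with a recoverable planted truth — network edges, driver genes, marker
genes, and hazard links — so the full pipeline is exercisable and
testable with no downloads. See `docs/methods.md` for the models,
assumptions, and design choices.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
synthetic inputs (about four minutes total on one CPU):

```sh
python analysis/01_simulate_inputs.py        # writes results/bundle/
python analysis/02_copy_number_calls.py
python analysis/03_differential_expression.py
python analysis/04_network_inference.py
python analysis/05_impact_scoring.py
python analysis/06_patient_transfer.py
```

The default run (seed 11) prints, step by step:

```
planted drivers: {"G0098": "up", "G0006": "down", "G0092": "down", "G0185": "up"}
41 of 300 genes reduced (13.7%), 14 increased (4.7%)            # step 02
72 underexpressed, 16 overexpressed of 300 genes                # step 03
52 same-direction direct candidates
planted drivers among candidates: 4 of 4
inferred 828 edges from 400 patients                            # step 04
mean predictive correlation on the validation cohort: 0.739
skeleton precision 0.96, recall 0.90 against the planted truth
8 candidates significant at q < 0.01                            # step 05
planted drivers among significant: 3 of 4
consistency filter on 32 relapsed irradiated patients: 4 of 8 kept
3 markers split the 60 irradiated patients into early/late relapse
planted drivers recovered in the final marker table: 3 of 4     # step 06
random-gene baseline: 1.45 genes with p < 0.05 per draw (95% CI 0.97-1.93)
```

and for the top marker (G0092, approximate log-rank p = 1.4e-9, exact
permutational p = 1e-5) the Cox model shows the expression-group term
(p < 1e-4) dominating age, T-stage, Gleason and PSA. Interpretation: of
four planted drivers, the copy-number × expression intersection keeps
all four; the propagation test against the degree-preserving permutation
null keeps the three whose outgoing edges the cohort supports; and all
three split irradiated patients into early and late relapse groups at
p < 0.05 under the ≥ 8-patients-per-group constraint, while random gene
sets of the same size yield ~1.5 such splits by chance.

The same pipeline is scriptable through the CLI (`radnet simulate`,
`radnet cna`, `radnet de`, `radnet infer-net`, `radnet impact`,
`radnet transfer`, `radnet run-all --config cfg.yaml --seed 11
--out-dir out/`), where the YAML config echoes every stage parameter
into the run log and a fixed seed makes the whole bundle byte-identical
across reruns.

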