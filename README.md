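# molfc

Molecular-enriched functional connectivity analysis: a two-step
dual-regression GLM that projects resting-state BOLD fMRI onto
neurotransmitter density templates (DAT, NET, SERT, µ-opioid, ...),
followed by permutation-based group inference with max-cluster-size FWE
correction and frequentist/Bayesian treatment-response statistics.

The package ships a synthetic-data generator with full ground truth, so
every stage — template preparation, BOLD preprocessing, the enrichment
regression, cluster inference and clinical statistics — is testable
end-to-end without any external dataset.

## Layout

| module | what it does |
|---|---|
| `molfc.synth` | synthetic templates, BOLD cohorts and clinical outcomes with known ground truth |
| `molfc.templates` | template preparation: reference-region masking, grey-matter masking, min-max normalization, resampling, analysis-mask construction |
| `molfc.preprocess` | WM/CSF mean-signal regression, 0.005 Hz DCT high-pass, 6 mm FWHM Gaussian smoothing |
| `molfc.dualreg` | the two-step regression: spatial GLM (volumes ~ templates) then temporal GLM (voxels ~ system time series), beta and z-scale FC maps |
| `molfc.inference` | voxelwise t/F permutation inference, Freedman–Lane nuisance handling, max-cluster-size FWE, Bonferroni, cluster-mean extraction |
| `molfc.clinical` | responder classification (≥ 20% analgesia), covariate-adjusted group tests, JZS and stretched-beta Bayes factors by quadrature, bootstrap correlations, Tukey-corrected simple effects, Levene's test |

## CLI

```bash
# generate a synthetic cohort (BIDS-like layout, with ground truth)
molfc simulate --spec spec.yaml --out data/ --seed 1

# prepare molecular density templates
molfc prep-templates --config templates.yaml --out prep/

# preprocess one subject's BOLD series
molfc preprocess --bold sub-01_bold.nii.gz --wm wm.nii.gz --csf csf.nii.gz \
    --tr 2.5 --out sub-01_preproc.nii.gz

# subject-level enrichment regression (one FC map per system)
molfc react --bold sub-01_preproc.nii.gz --templates templates_prepared.yaml \
    --tr 2.5 --out react/

# group inference with permutation cluster FWE
molfc group-stats --maps maps.tsv --design participants.tsv \
    --contrast "OA>HC" --nperm 5000 --cft-p 0.01 --seed 1 --out stats/

# ROI-level clinical statistics
molfc clinical-stats --table participants.tsv --values cluster_means.tsv \
    --analysis case-control --out results.json
```

`simulate` reads a small YAML spec (grid shape, number of systems,
group sizes, effect size/system, VAS coupling); see
`tests/test_cli.py` for a working example.

## Conventions worth knowing

- Standardization uses the population SD (divide by N).
- Step-1 demeaning is across voxels per time point; step-2 demeaning is
  across time per voxel. Reference-region voxels excluded from step 1
  are included in step 2.
- High-pass filtering projects out a discrete-cosine basis below the
  cut-off (removes the mean exactly); smoothing uses reflective
  boundaries so the global mean is preserved on small grids.
- Cluster-forming threshold defaults to the parametric one-sided
  p < 0.01 quantile at the model's residual df and is configurable
  (`--cft-p`); p_FWE = (1 + #{null ≥ observed}) / (1 + n_perm), or the
  exact enumeration fraction when all relabelings are enumerable.
- Bayes factor priors: Cauchy scale 0.707 (t-tests), stretched beta
  width 1 (correlations); BF01 > 1 favours the null. Evidence bands
  follow the standard classification, regularized to a partition.
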