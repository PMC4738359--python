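# multifun

Does soil microbial diversity sustain the simultaneous provision of
multiple ecosystem functions?  `multifun` is a Python toolkit for that
question: it takes OTU tables, site covariates and ecosystem-function
measurements from large-scale soil surveys and carries them through the
full diversity–multifunctionality analysis chain, with a ground-truthed
synthetic landscape generator so every stage can be validated end to
end.  It is aimed at microbial ecologists and biogeographers working
with survey-style data (tens to hundreds of sites, amplicon-based
community tables, a handful of measured functions).

## What it computes

* **Diversity** from rarefied OTU tables: Shannon index
  H = −Σ pᵢ log₂ pᵢ (bits), richness, and Faith's phylogenetic
  diversity (total branch length of the subtree spanning a sample's
  taxa) from a newick tree.
* **Averaging multifunctionality** M: each function is normalized
  (log-transform when it tames strong skew), Z-scored across sites and
  averaged, with optional microsite cover-weighting and bulk-density
  correction upstream.
* **Multiple-threshold multifunctionality**: functions are rescaled by
  their top-5% maxima; for every threshold t ∈ 1..99% the number of
  functions exceeding t is regressed on diversity, giving a
  slope-versus-threshold curve with 95% bands.
* **Spatial regression**: OLS and maximum-likelihood SAR error models
  (y = Xβ + u, u = λWu + ε) over k-nearest-neighbour weights, compared
  by AICc.
* **Random-forest importance**: %IncMSE from out-of-bag permutation,
  with response-permutation significance for each predictor and a
  cross-validated-R² model test.
* **Path analysis**: recursive standardized path models with composite
  variables, χ²/RMSEA fit statistics, bootstrap coefficient p-values,
  the Bollen–Stine bootstrap, and standardized direct/indirect/total
  effects.

## Worked example

```python
from multifun import SimulationConfig
from multifun.pipeline import RunManifest, run_all

manifest = RunManifest(
    seed=3,
    outdir="demo_run",
    simulation=SimulationConfig(seed=3, n_sites=60, n_taxa=150, read_depth=1000),
    rf_trees=200, rf_permutations=99, path_bootstrap=199,
)
summary = run_all(manifest)
print(summary["stages"]["regression"])
print(summary["stages"]["rf_importance"]["ranking"][:3])
print(summary["stages"]["path_model"])
```

which prints (numbers from this exact run):

```
{'ols_diversity_slope': 0.5311419331736785, 'ols_p': 1.2161443698968403e-10,
 'ols_r2': 0.5133815456701729, 'ols_aicc': 74.51296938806134,
 'sar_diversity_slope': 0.5663728924595964, 'sar_lambda': -0.766619439607484,
 'sar_r2': 0.5133815456701729, 'sar_aicc': 72.30248589322301}
['microbial_diversity', 'altitude', 'MAT']
{'direct_diversity_effect': 0.6611251479850587,
 'diversity_total_effect': 0.6611251479850587,
 'r2_multifunctionality': 0.5714963532105917,
 'chi2': 0.9142991155095954, 'rmsea': 0.0,
 'bollen_stine_p': 0.6231155778894473}
```

Reading this: Shannon diversity (bits, from the rarefied synthetic OTU
table) has a positive slope on the averaging multifunctionality index
under both OLS and the spatially-explicit SAR model; the random forest
ranks microbial diversity first among the six predictors; and the path
model finds a positive direct diversity → multifunctionality path
(standardized coefficient 0.66) with good fit (low χ², RMSEA 0,
Bollen–Stine p ≫ 0.10).  That is the qualitative signature the package
is built to detect, here recovered from a landscape simulated with a
known positive diversity effect.  `demo_run/` contains every
intermediate artifact (diversity CSV, index, threshold curve,
regression and path-model JSON, run log).

The same stages are available on the command line:

```bash
multifun simulate --seed 3 --outdir demo
multifun diversity --otu-table demo/otu_table.tsv --tree demo/tree.nwk --out demo/div.csv
multifun mfi --functions demo/functions.csv --out demo/mfi.csv
multifun run-all --manifest manifest.yaml
```

## Layout

```
src/multifun/
  synthetic.py    ground-truthed landscape / OTU / phylogeny generator
  diversity.py    OTU table IO, rarefaction, Shannon, richness, Faith PD
  mfi.py          averaging multifunctionality index
  thresholds.py   multiple-threshold slope curves
  regression.py   OLS, SAR error model, spatial weights, AICc
  rf.py           random-forest OOB importance + permutation significance
  pathmodel.py    recursive path models, composites, bootstraps
  pipeline.py     manifest-driven orchestration
  cli.py          command-line interface
docs/methods.md   models, defaults, numerical choices, limitations
```
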