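# maxsdm

Presence-only maximum-entropy species distribution modelling (SDM) with
AICc-based model tuning, multi-metric evaluation, and Markov-chain land-cover
simulation for projecting habitat-suitability change under combined climate
and land-cover scenarios.

The package is aimed at spatial ecologists who want the full analysis chain
behind an invasive-species risk map — from raw occurrence records and
predictor rasters to binary range-change percentages per scenario — as a
tested, scriptable pipeline rather than a GUI workflow. Every stage can also
be exercised end-to-end on fully synthetic landscapes with known generating
truth, so the statistical machinery is verifiable without any external data.

## The model

Given presence cells and background cells with feature vector f(x) ∈ [0,1]^k
(linear, quadratic, product, threshold and hinge transforms of the
predictors, plus class indicators for categorical layers), the habitat model
is the Gibbs distribution

    q_λ(x) = exp(λ·f(x)) / Z_λ,   Z_λ = Σ_background exp(λ·f(x)),

fitted by maximizing the L1-penalized log-likelihood

    Σ_presence log q_λ(x_i) − Σ_j β_j |λ_j|,

with per-feature penalties β_j = (regularization multiplier) × (feature-class
default) × sd_j/√n. Optimization is coordinate-wise sequential ascent with
safeguarded proximal Newton steps; it stops at first-order optimality
(max penalty-adjusted gradient ≤ 10⁻⁶ by default). The logistic suitability
output is c·q/(1+c·q) with c = exp(H), H the entropy of the background
distribution, so a "typical" presence site scores 0.5.

Around the model, the pipeline implements:

* occurrence cleaning and spatial rarefaction (one record per grid cell),
  uniform background sampling, and a greedy Pearson |r| ≤ 0.85 collinearity
  filter over the predictor stack;
* model tuning: all non-empty feature-class subsets × a regularization grid,
  scored by AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) with k the number of nonzero
  weights and lnL computed from landscape-standardized raw probabilities;
* evaluation: rank (Mann–Whitney) AUC with qualitative bands, the Continuous
  Boyce Index (Spearman correlation of windowed predicted-to-expected
  presence ratios against suitability), jackknife variable importance, and
  percent variable contribution from the fit's gain credits;
* replicated calibration (default 20 seeded 75/25 splits), mean suitability
  maps, 10-percentile training-presence threshold binarization, and percent
  range change per scenario;
* land-cover change simulation: cross-tabulated Markov transition matrix,
  fractional matrix powers for horizon scaling, per-source-class MLP
  transition potentials on driver rasters, and highest-potential change
  allocation;
* a synthetic-data module generating correlated random-field predictors, a
  categorical land-cover layer, presences from a known log-linear truth, and
  land-cover map pairs from a known transition matrix.

Rasters are read and written as ESRI ASCII grids; occurrences and all tables
as CSV; configuration as YAML.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from maxsdm import PipelineConfig, run_pipeline

config = PipelineConfig(
    seed=7,
    output_dir="demo_run",
    grid_rows=40, grid_cols=40,
    n_presences=250, n_background=800, n_replicates=5,
    scenarios=[{"label": "warm_rcp85", "offsets": {"env1": 0.8}}],
)
manifest = run_pipeline(config)
state = manifest["_state"]
rep = state["report"]
print(f"selected model : {''.join(state['best'].feature_classes)} @ beta={state['best'].reg_multiplier:g}")
print(f"AUC train/test : {rep.auc_train:.3f} / {rep.auc_test:.3f} ({rep.band})")
print(f"CBI            : {rep.cbi:.3f}")
print(f"tau10 threshold: {state['tau10']:.3f}")
print(f"suitable cells : {state['current_thr'].suitable_count} of {len(state['reps'].mean_map)}")
for r in state["scenario_results"]:
    print(f"scenario {r.label}: suitable {r.thresholded.suitable_count}, change {r.percent_change:+.2f}%")
```

prints

```
selected model : L @ beta=2
AUC train/test : 0.663 / 0.667 (Poor)
CBI            : 0.965
tau10 threshold: 0.325
suitable cells : 1206 of 1600
scenario warm_rcp85: suitable 1473, change +22.14%
```

Reading the output: AICc tuning selected a linear-features model at
regularization multiplier 2. The presence/background AUC of ~0.66 reflects
the deliberately broad niche simulated here (presences and background
overlap heavily on a 40×40 landscape, which caps attainable AUC), while the
Boyce index of 0.97 shows the suitability ranking tracks the presence
density almost perfectly. The 10-percentile threshold 0.325 marks 1206 of
1600 cells currently suitable; under a scenario that warms `env1` (a
predictor with positive fitted weight) by +0.8 and swaps in the simulated
future land cover, the suitable area grows by 22%. Directions reverse for
negative shifts — on synthetic landscapes the sign and size of the change
follow the known truth. The run directory holds every intermediate artifact
(layers, filter report, selection table, evaluation JSON, response curves,
suitability/binary maps, scenario table) plus `manifest.json` with the
per-stage seeds needed to reproduce the run bit-identically.

The same pipeline is scriptable from the shell:

```bash
maxsdm run -c config.yml          # end to end
maxsdm simulate -c config.yml     # or stage by stage:
maxsdm landcover -c config.yml    # simulate | landcover | prepare | tune
maxsdm evaluate -c config.yml     #   | evaluate | project | report
```

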