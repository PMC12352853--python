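# allomflow

Toolkit for evaluating scaling models of tree-branch allometry on internode
measurement tables. It bundles:

- **`allomflow.simulate`** — a seeded branching-network generator producing
  internode tables (CSV) with area-preserving bifurcations, mean-one
  radius-dependent area-ratio noise, exponentially distributed internode
  lengths, and an optional power-law length–diameter coupling
  `L = c·D^α` whose exponent can blend smoothly toward 2/3 for large radii.
- **`allomflow.geometry`** — cylinder-derived surface area and volume,
  bifurcation extraction, and the daughter/parent cross-sectional area-ratio
  test of area-preserving ("DaVinci") branching, including raw (Pearson)
  kurtosis and variance binned against parent radius.
- **`allomflow.sma`** — standardized major axis (SMA) regression on
  log10–log10 axes with F-based slope confidence intervals, analytic exponent
  predictions for the six variable pairs (length, diameter, surface area,
  volume) as closed-form functions of the length–diameter exponent α
  (`CFS`: α = 2, `WBE`: α = 2/3), and slope-vs-prediction scoring
  (single-fit absolute deviation plus an expanding-window `running_rmse`).
- **`allomflow.curvature`** — concave/convex classification of each log-log
  relationship by the sign of a least-squares quadratic.
- **`allomflow.distfit`** — maximum-likelihood fits of shifted-exponential
  and continuous power-law (Pareto) models with AICc competition and relative
  likelihoods (reported raw and in log10 to survive underflow).
- **`allomflow.pipeline`** — end-to-end orchestration: CSV reading with
  topology validation, the field truncation filter (drop rows under 100 mm
  length or 1.5 mm diameter, inclusive thresholds), per-tree and pooled
  analyses, and CSV/JSON report output.

All dimensions are millimetres (surface area mm², volume mm³).

## CLI

```sh
# generate a synthetic internode table
allomflow simulate --config sim.yaml --out net.csv [--seed 7]

# run the full analysis (writes sma.csv, curvature.csv, area_ratio_*.csv,
# distfit.csv and report.json into the configured output directory)
allomflow analyze --config analysis.yaml [--input net.csv] [--out-dir out/]

# re-render the tables of an existing report
allomflow report --dir out/
```

Config files are YAML or JSON mirroring the `SimulationConfig` /
`AnalysisConfig` field names, e.g.

```yaml
# sim.yaml
mode: branching_cascade     # or allometric_coupling
base_radius: 40.0           # mm
radius_floor: 1.2           # mm, lineage termination
length_scale_mu: 450.0      # mm, mean internode length
ratio_noise_sd0: 0.2        # area-ratio noise sd at the base radius
ratio_noise_radius_exp: 0.3 # noise growth as radius shrinks
seed: 1
n_trees: 4
```

```yaml
# analysis.yaml
input_path: net.csv
output_dir: out
length_min: 100.0    # mm, truncation threshold (inclusive keep)
diameter_min: 1.5    # mm
prune_subtrees: true # drop whole subtrees rooted at truncated internodes
```

Internode tables are CSV with header
`tree_id,internode_id,parent_id,length_mm,diameter_mm`; a blank `parent_id`
marks a root.

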