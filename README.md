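# badgermove

Two-timescale analysis of animal GPS telemetry, built around European
badger (*Meles meles*) collar studies: fast-scale movement is quantified
by an isotropic diffusion constant estimated per animal and month, and
slow-scale territorial structure is detected as metastable states of a
data-driven Koopman operator.

## The model

Positions follow a stochastic differential equation

```
dX_t = b(X_t) dt + σ(X_t) dW_t,      σ(x) = c I,
```

with drift `b` (slow territorial attraction) and isotropic diffusion
`c` (fast nightly foraging movement, units m·min^-1/2).

**Fast scale.** From `m` fixes `(x_i, y_i)` at times `t_i`, the
Kramers–Moyal second-moment estimator gives

```
c² ≈ 1/(2(m−1)) Σ_i [ (x_{i+1}−x_i)² + (y_{i+1}−y_i)² ] / Δt_i .
```

Per-animal-month estimates (log-normally distributed, which the package
checks with a Shapiro–Wilk test on log c) feed a log-scale mixed-effects
model with month and sex fixed effects, a random intercept for animals
within sites, and optional correlated per-site random slopes for capture
year. A log-scale coefficient β maps to a rate multiplier exp(β):
exp(0.106) = 1.112 is an 11.2% increase, exp(−0.152) = 0.859 a 14.1%
decrease.

**Slow scale.** Cleaned tracks are resampled to a uniform step τ and
turned into snapshot pairs `(x_k, y_k)` with `y_k` one step after `x_k`.
With a dictionary of indicator functions on a ~100 m box grid, the EDMD
least-squares solution `K^T = Ψ_Y' Ψ_Y^+` is exactly Ulam's method — a
Markov state model over boxes. Eigenvalues near 1 mark metastable
(rarely-left) regions; the first spectral gap `|λ_i − λ_{i+1}| > δ`
selects the number `N` of metastable states, and k-means on the first
`N` eigenfunctions partitions boxes into clusters. Convex hulls of
cluster fixes are compared with convex hulls of observed social-group
ranges.

Because real badger telemetry is confidential, the package ships a
ground-truthed generator: multi-well SDE movement (one inverted-Gaussian
well per social group), nightly fix schedules (20-min, 35-min with its
midnight-boundary 30-min interval, or hourly), fix-time jitter, dropout,
ring outliers, poor-quality fixes, and culling-like mid-study removals.

## Worked example

```python
from badgermove.pipeline import RunConfig, run_pipeline

cfg = RunConfig(out_dir="runs/demo", seed=3, n_groups=4,
                badgers_per_group=2, months=1, n_sites=2)
manifest = run_pipeline(cfg)
```

This simulates a two-site study (two social groups per site), cleans it
(quality, 26.2 m·min⁻¹ speed and 1500 m lone-spike filters, time
snapping, period splitting, per-site origin shift), estimates per-month
diffusion, fits the mixed model, runs the EDMD analysis per site, and
writes `territory_summary.csv`:

```
site subset  n_groups  n_clusters  group_area_mean  group_area_sd  cluster_area_mean  cluster_area_sd  n_fixes
  S1  Total         2           2         0.029537       0.022452           0.029537         0.022452     2846
  S2  Total         2           2         0.014941       0.005773           0.014941         0.005773     2870
```

At each site the spectral gap finds two metastable clusters matching the
two simulated social groups, and the mean convex-hull areas (km²) of
clusters and groups coincide because every animal stays in its own
territory. The same pipeline is available from the shell:
`badgermove all --seed 3 --out-dir runs/demo` (stage-wise subcommands
`simulate`, `clean`, `diffusion`, `glmm`, `koopman`, `report` also
exist).

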