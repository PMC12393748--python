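# Methods

## Movement model and synthetic studies

Animals move by `dX_t = b(X_t) dt + c dW_t` in the plane. The drift is
the negative gradient of a sum of inverted Gaussian wells,

```
U(x) = − Σ_k d_k exp(−|x − m_k|² / (2 w_k²)),
```

one well per social group (centre `m_k`, depth `d_k`, width `w_k` in
metres). This form was chosen because it is smooth, its drift is bounded
and total (no blow-up anywhere in the plane), and its metastability is
tunable: within a well the dynamics are locally Ornstein–Uhlenbeck with
stiffness θ = d/w², stationary per-coordinate spread c/√(2θ), and an
escape probability controlled by the ratio of well depth to the noise
temperature c²/2. Because the drift vanishes far from all wells, an
animal whose depth-to-c²/2 ratio is small will occasionally escape and
wander freely — realistic extra-territorial excursions, but a property
to keep in mind when choosing parameters. Defaults (depth 1500, width
150 m, spacing 1200 m, base c ≈ 8–10 m·min^-1/2, individual log-scale
SD 0.2 in pipeline runs) give strong metastability with rare
excursions; at these values an animal sits ~25–50 m RMS from its well
centre and inter-well hops are observed on the order of once per study.

Integration is Euler–Maruyama at `sim_dt` = 5 min (drift step ≪ well
width, so the scheme is stable and the discretisation bias in the
estimated c is ≲ θ·dt/2 ≈ 2%). A zero-depth field short-circuits to
exact Brownian increments. Each animal draws from its own random stream
keyed by (seed, animal id), so removing one individual never perturbs
the others — required for clean culling-emulation comparisons.

Per-month diffusion for animal i in calendar month m is
`c_im = base_c · exp(sex·1[female] + month_m + b_i)`, b_i ~ N(0, σ_ind²).
The default month profile (February +0.106 … November −0.442, January
reference), sex contrast (−0.152) and individual SD (√0.229 ≈ 0.479)
mirror the magnitudes reported for UK badger populations, so synthetic
studies exercise the estimators at realistic effect sizes.

The observation layer emulates GPS collars: fixes only inside a nightly
window (default 20:00–04:00 every 20 min; a 35-min variant re-anchors
at midnight, producing the characteristic 30-min interval between 23:30
and 00:00; an hourly variant emulates sparser schedules), recording
times jittered by U(0, jitter_max) minutes with the position read at
the nearest trajectory sample (collars log late while acquiring
satellites), independent dropout, gross outliers placed uniformly in a
ring 2–5 km out (so the speed and jump filters can catch them), and a
small fraction of poor-quality fixes (3 satellites or dilution of
precision > 4).

What the generator does **not** emulate: habitat or landscape geometry,
social interaction forces, state-switching behaviour (resting vs
foraging), positional measurement noise on ordinary fixes, or
autocorrelated fix failure. Tests passing on this generator therefore
demonstrate correctness of the estimators under the model's own
assumptions, not robustness to every artefact of field data.

## Cleaning rules

Fixed order: quality → speed → jump → snap → split → shift →
interpolate, with per-stage removal counts logged as JSON lines.

- Quality: fewer than 4 satellites or DOP > 4 removed; fixes lacking
  both fields pass. Thresholds inclusive (4 satellites, DOP = 4 kept).
- Speed: implied speed above 26.2 m·min⁻¹ (the fastest recorded badger
  travel speed) drops the *later* fix of the pair, rescanning from the
  surviving predecessor. Dropping the later fix is a design choice —
  the rule needs an orientation to be idempotent and deterministic.
- Jump: a lone spike — out-and-back exceeding 1500 m over two
  consecutive steps with the flanking fixes nearly coincident (|AC| <
  0.25(|AB|+|BC|)) — removes the middle fix. This operationalises
  "biologically unrealistic single points" as a concrete geometric test.
- Snap: timestamps move to the nearest programmed slot; displacement
  beyond 3 min (configurable) discards the fix; slot collisions keep
  the first; exact midpoints round down.
- Split: gaps above 7 days (no threshold is canonical; a week
  distinguishes collar failure from ordinary fix loss) start a new
  monitoring period with a fresh period id.
- Shift: per-site translation to a (0, 0) base — an exact isometry.
  Because each site gets its own base, all slow-scale analysis is
  per-site.
- Interpolate: linear, within nights only (the daytime gap, when
  badgers are in their setts, is never bridged and contributes no
  estimator pairs). Each inter-fix interval must be an integer multiple
  of dt; the one exception is half-interval mode (dt = native/2, the
  17.5-min case for 35-min collars), where every interval gets
  midpoints — including the 30-min midnight interval, whose halves are
  15 min. The output is then uniform except at that boundary, the same
  compromise the sampling design itself forces.

## Diffusion estimation and the mixed model

`estimate_c` implements the Kramers–Moyal second-moment estimator with
unequal Δt support. Estimates aggregate per (animal, calendar month) —
the observational unit of the mixed model — and a pair spanning two
months counts toward the month of its earlier fix. Animal-months with
ten or fewer fixes are dropped as too sparse.

Known estimator biases, documented and tested rather than corrected:
sampling an Euler chain at its own step with strong drift inflates c by
~θ·dt/2; sampling a confined (OU-like) process at coarse Δt deflates it
by (1−e^(−θΔt))/(θΔt). Both vanish as Δt → 0. The deflation factor
depends only on θ and Δt, not on c, so log-scale covariate contrasts
survive coarse sampling unbiased.

The model for log c has fixed effects month (reference January) and sex
(reference male), a random intercept for animals within sites, and
optionally correlated per-site random slopes for capture year. Fitting
delegates to statsmodels' linear mixed-effects machinery on log c (the
log-normal formulation of a log-link normal model), by maximum
likelihood so AIC/BIC are comparable across specifications. Exact
numerical agreement with any particular penalised-likelihood solver is
explicitly not a contract; the module is validated by parameter
recovery on synthetic truth (95% CI coverage at the nominal rate).
p-values and CIs use the normal reference distribution, which is
mildly anti-conservative for small animal counts; recovery tests
therefore use ~200 animals, where the effect is negligible. Degenerate
designs (one site, one year) drop the year slopes with a warning;
singular variance estimates are flagged, never silenced.

## Koopman/EDMD analysis

Snapshot pairs are consecutive positions of uniformly resampled
within-night segments; no pair bridges tracks or the daytime gap, so
every pair has lag exactly τ (= the interpolation step: 20 min default,
17.5 nominal for 35-min collars). The grid covers the pair cloud with
edge lengths ≈ 100 m (integer box counts, exact edge = span/count).

`estimate_koopman` solves the EDMD least-squares problem
`K^T = Ψ_Y' Ψ_Y^+` in Gram/stiffness form, accumulated in chunks. With
indicator dictionaries this equals the row-normalised transition-count
matrix; `transition_count_oracle` computes that matrix by direct
counting and serves as the module's independent cross-check (entrywise
agreement to 1e-8 is asserted property-style over random pair sets).
The dictionary spans boxes occupied by any pair endpoint; a box seen
only as a destination yields a zero row (transient bookkeeping state).

Two finite-sampling artifacts are handled explicitly:

- **Sparse states.** Boxes supported by fewer than `min_count` = 5
  endpoint visits cannot support a transition-probability estimate
  (a single excursion writes rows estimated from one sample); pairs
  touching them are removed before estimation, iterating to stability.
- **Spurious absorbing states.** A box whose only recorded exits fell
  across night boundaries becomes absorbing with eigenvalue exactly 1.
  Terminal strongly-connected classes smaller than 2 boxes are removed
  and rows renormalised.

Eigenvalues are sorted by descending real part (near-reversible
dynamics give near-real spectra; imaginary magnitudes are exposed).
The metastable count is the first i with Re λ_i − Re λ_{i+1} > δ
(default δ = 0.05); if no difference exceeds δ, the largest successive
difference is used instead, with a warning, ties breaking to the
earliest index. k-means (k = N, seeded, 10 restarts) runs on the real
parts of the first N eigenfunctions, including the trivial constant one
(configurable); each box is weighted by its visit count, which — since
eigenfunctions are piecewise constant on boxes — is exactly k-means
over individual fixes and prevents a few rarely-visited boxes from
capturing a centroid.

## Territory summaries

Cluster and group outlines are convex hulls (vertices a subset of the
member fixes; area via exact polygon area, reported in km²). A group's
range is the hull of all its members' fixes in the subset — the same
construction as for clusters, making the two families comparable.
Degenerate point sets (< 3 distinct non-collinear fixes) are reported
with zero area rather than dropped. Comparison tables list cluster and
group counts and mean (SD) hull areas per subset and pooled; pooled
rows use all fixes in one grid. Hull families serialise to GeoJSON
(planar metre coordinates, role property `cluster`/`group`).

## Pipeline and problem sizes

`run_pipeline` executes simulate → clean → diffusion → glmm → koopman →
report, the last two per site, writing every intermediate artifact and
a manifest of seeds, record counts, timings and checksums; identical
configuration and seed reproduce identical bytes.

Default validation problem sizes: four-group studies of 12 animals over
two months (~17k fixes, ~30–40 occupied boxes) for metastable recovery;
5×10⁴-step zero-drift chains for diffusion recovery; 2×10⁵-step
exactly-sampled OU chains on ~60 boxes for the spectral closed-form
check; twenty replicate 200-animal drift-free studies for mixed-model
coverage. These sizes put Monte-Carlo error comfortably inside the
asserted tolerances while keeping the full suite fast.

## Known limitations

- Non-uniform fix series are handled by interpolation, not by filtering
  approaches designed for irregular sampling (e.g. Kalman smoothing).
- The half-interval (17.5-min) mode leaves 15-min spacings at the
  midnight boundary; pairs there have a slightly shorter lag.
- Anisotropic or state-dependent diffusion is out of scope; the
  estimator reports a single isotropic c per animal-month.
- Coordinate reference systems are not handled; inputs must already be
  metric planar coordinates.
- The manual exclusion of spatially isolated individuals is exposed
  only as an explicit exclusion list, not detected automatically.
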