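# Methods

## The model

The unit of observation is an eye. For each eye the macular map supplies a
thickness (µm) for each of 7 segmented retinal layers (RNFL, GCL, IPL, INL,
OPL, ONL, RPE) in each of 9 ETDRS sectors (central subfield; inner ring
1–3 mm: IS, II, IN, IT; outer ring 3–6 mm: OS, OI, ON, OT), giving 63
measurements. Derived quantities are the ring averages (`Avg_I`, `Avg_O`:
arithmetic means of the four inner/outer sectors) and the composite layers
IR, OR and TRT, defined as sums of primary layers under a configurable
scheme. The composite boundaries are not anatomically standardised across
reports, so the scheme is explicit configuration; the default is
IR = RNFL+GCL+IPL+INL, OR = OPL+ONL+RPE, TRT = all seven, and the scheme in
force is echoed into every run report.

### Structural covariance network

For one group, each node's thicknesses across eyes are residualised on age
by OLS with intercept, and the edge weight between nodes *i*, *j* is
|Pearson r| of the residuals (zero diagonal). Residualise-then-correlate on
a single shared covariate is algebraically identical to the first-order
partial correlation r(i,j | age); the test suite asserts that identity to
1e-10. Negative raw correlations are kept as absolute values rather than
zeroed — a signed edge influences graph measures even when the meaning of
its direction is unclear — and their pre-absolute share is retained as
`negative_fraction`, with a warning at ≥ 5%. Matrices stay dense: at 63
nodes nothing is gained by sparsification, and thresholding would add a free
parameter the analysis does not need.

Eyes are the sampling unit, so correlations mix within- and between-subject
variation when both eyes of a subject are enrolled.
`CohortTable.average_by_subject()` provides the conservative alternative
(one averaged record per subject); it is off by default to mirror the
eye-level design the group sizes imply.

### Modularity and Louvain

Quality function: Newman–Girvan modularity with resolution γ on the weighted
graph, doubled-sum convention —

    Q = (1/2m) Σ_ij ( A_ij − γ k_i k_j / 2m ) δ(c_i, c_j),

both orientations of every pair counted, i = j included in the null term,
k the node strengths, 2m the total doubled weight. Under this convention
the all-in-one partition scores exactly 1 − γ (0 at γ = 1), and Q values are
comparable across implementations. The general multilayer form of this
quality function adds an inter-layer coupling ω; with one network per group
the coupling term vanishes, which is the case implemented (no ω parameter is
exposed).

The optimizer is the standard two-phase Louvain heuristic, written from
scratch: seeded random sweep over nodes, each node moved to the community
with the largest positive modularity gain (gain > 1e-12, guarding against
floating-point livelock on plateaus; ties resolved to the lowest community
index, so a run is a pure function of its seed), followed by graph
aggregation with self-loops carrying internal weight, iterated to a fixed
point. The returned Q is always recomputed from the definition on the
original graph. An exhaustive-enumeration oracle (`brute_force_optimal`,
restricted-growth-string generation of all set partitions, ≤ 10 nodes)
provides exact optima for validation; best-of-50 Louvain attains the exact
optimum on ≥ 95/100 random 7-node weighted graphs in the acceptance suite.

### Ensemble, consensus and the group comparison

Each network gets `n_runs = 50` Louvain runs with per-run seeds drawn from
the ensemble seed. Because community ids are arbitrary per run, the
per-node mode is only defined after alignment: every run is relabelled
against the highest-Q run by maximum-overlap assignment on the community
contingency table (Hungarian algorithm; communities left unmatched, or
matched with zero overlap, get fresh labels). The consensus is the per-node
mode of aligned labels, ties resolved toward the best run's label. The
ensemble modularity is the arithmetic mean of run-level Q.

Two groups are compared by a two-sample t-test on the two sets of 50
run-level Q values (Welch by default; pooled by flag). This reproduces the
published procedure, with an important caveat stated plainly: the samples
are optimizer restarts around two fixed group-level networks, not data
resamples, so the p-value quantifies restart variability, not cohort
sampling variability. On well-converged 63-node problems the restart
distribution can collapse to a point per group, in which case the statistic
degenerates (t → ±∞, p → 0 for any mean difference; t = 0, p = 1 when the
constants are equal) — the implementation reports these limits rather than
masking them. A subject-resampling alternative would be the statistically
defensible extension; it is out of scope here.

### Age trajectories

Per group and per layer × region (default family: 10 layers × {C, Avg_I,
Avg_O} = 30 cells), thickness is regressed on age by OLS; the age
association is reported as Pearson r with the two-sided p from the t
distribution on n − 2 df. Groups are compared by Fisher's r-to-z,
z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3)), with eye counts as n —
the only sample sizes the design reports. The whole table is one FDR family
by default, corrected with hand-implemented Benjamini–Hochberg step-up
(validated against both a rejection-threshold oracle and statsmodels).
Comparing correlations is not the same contrast as comparing slopes when
group variances differ; `slope_difference_test` (normal theory on b₁ − b₂
with OLS standard errors) is provided for sensitivity analysis.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the published design size: 156 HC-like and 78 DWOR-like eyes (two eyes per
subject, independent), ages normal with mean ± SD 46.06 ± 13.06 (HC) and
50.8 ± 8.6 (DWOR), truncated at 18 years by rejection sampling.

Thickness is a latent-factor model per group:

    x = baseline + offset + slope·(age − mean age) + λ_g·G + λ_b·F_block + ε

with standard-normal global factor G, one factor F per planted block, and
Gaussian noise ε. Loadings are solved so that the age-residualised
correlation is exactly `rho_within` inside a block and `rho_between`
elsewhere (λ_g² = ρ_b·V, λ_b² = (ρ_w − ρ_b)·V, ε² = (1 − ρ_w)·V with total
variance V = noise_sd²/(1 − ρ_w)); a Monte-Carlo test at 2000 eyes confirms
calibration to ±0.05. This construction is positive semi-definite by design
and never materialises a 63 × 63 covariance matrix. Values are floored at
0.5 µm to respect the physical range (touched by ≪ 0.1% of cells at the
default noise level).

Defaults, and why:

| parameter | default | rationale |
|---|---|---|
| n_eyes | HC 156 / DWOR 78 | the published cohort sizes |
| blocks | HC 5 / DWOR 4 | the published community counts; consecutive near-equal runs of the layer-major node order |
| rho_within | HC 0.5 / DWOR 0.7 | tighter DWOR covariance ⇒ higher planted modularity, matching the published direction Q_DWOR > Q_HC; magnitudes are free parameters |
| rho_between | 0.25 | keeps between-block *sample* correlations almost surely positive at these n (P(r̂<0) ≈ Φ(−atanh ρ_b·√(n−3)) ≈ 0.1–1.4%), matching the observed rarity (< 5%) of negative covariance entries, while leaving a within−between contrast > 0.2 |
| noise_sd | 1.7 µm | total node SD = noise_sd/√(1−ρ_w) ≈ 2.4 (HC) / 3.1 (DWOR) µm, bracketing published per-group SDs (e.g. RNFL central 2.48/2.23 µm) |
| group offsets | RNFL_C +0.69, INL inner +1.0, ONL_C −1.2, ONL inner −0.9 µm (DWOR) | published group differences in sign and size; the ONL offsets carry the outer-retina thinning so the default OR composite reproduces the printed OR means |
| age slopes | HC-only central thickening, 0.014–0.055 µm/yr | reproduces the published pattern (age-related central thickening in controls, absent in DWOR) at r ≈ 0.1–0.25 |
| baselines | per layer × ring | the four published sector means exactly; remaining cells are plausible adult macular values chosen once |

What the generator does **not** emulate: inter-eye correlation within a
subject, missing data, segmentation error, non-Gaussian tails, spatially
graded (rather than block-constant) covariance, or the full per-sector mean
tables (not all published). Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes when that structure is present at
realistic strength — not that real retinas have block-constant covariance.

## Numerical choices and degenerate inputs

- Residualisation falls back to mean-centering (with a warning) when all
  ages are identical; zero-residual-variance nodes are an error naming the
  node.
- Louvain gain tolerance 1e-12; `modularity()` agrees with a naive
  triple-loop evaluation to 1e-12.
- Zero-total-weight graphs raise an undefined-modularity error.
- Equal-constant Q ensembles give t = 0, p = 1; both-singleton ensembles are
  a degrees-of-freedom error.
- Cohort and matrix I/O round-trip to full precision
  (`float_precision="round_trip"` on read).
- All seeds are integers < 2³¹; every stage's randomness derives from the
  master seed through named substreams.

## Known limitations and honest margins

- **Recovery is probabilistic at the default contrast.** With ρ_w = 0.5 vs
  ρ_b = 0.25 and n = 156, about one default replicate in eight yields an
  HC-like network whose *true* modularity optimum merges two planted blocks
  (verified against the ensemble: the merged partition scores strictly
  higher Q than the planted one). That is a property of sampling noise at
  this design size, not of the optimizer. Raising the contrast would make
  recovery certain but would reintroduce negative sample correlations beyond
  the observed < 5% share; the defaults sit where both properties hold with
  margin in expectation.
- The restart-level t-test inherits the published design's interpretive
  weakness (see above).
- Printed z-values for the r-to-z comparisons in the source clinical report
  are not reproducible from the standard formula with eye-level n; no test
  asserts them.
- Analyses are cross-sectional; age "trajectories" are between-subject
  gradients, not longitudinal change.

## Problem sizes

Defaults throughout: 234 eyes, 63 nodes, 2 × 50 Louvain runs (< 1 s
end-to-end). Validation uses 100 seeded 7-node graphs against the exact
oracle, 20 replicate cohorts for recovery, and 200 replicate null cohorts
for FDR control — sizes at which the Monte-Carlo error of each check is
small relative to its acceptance margin.
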