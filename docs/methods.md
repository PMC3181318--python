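# Methods

This note documents the statistical model behind `ratepath`, the choices
made where the design was genuinely open, what the synthetic-data generator
does and does not emulate, and the problem sizes used by the test suite and
the acceptance script.

## Rates of change along a transition

An environmental transition is an ordered series of sites connected by a
moving water mass, with cumulative transit times t₀ = 0 < t₁ < … < t_k
(hours). For each multivariate category the raw site-date × variable table
is (optionally) log10-transformed per variable, z-scored per variable
(sample SD, n−1) over **all site-dates pooled** — one global z-space, so
that dissimilarities are comparable across transitions — and converted to a
Euclidean distance matrix. The rate of change of a category along one
transition on one date is the OLS slope of the dissimilarity between the
head site and each downstream site against transit time, in
dissimilarity·h⁻¹. Abundance (BA) uses the raw difference to the head
instead of a dissimilarity; ΔH′ (Shannon diversity of band relative
intensities, natural log, 0·ln 0 = 0) and ΔBANDS (count of bands present in
exactly one of head and site, presence threshold 0 by default) are computed
the same way but never enter the path models.

**The head anchor.** Difference-to-head series begin at the structural
point (0, 0). Anchoring the fit there biases the slope upward under pure
noise: every downstream dissimilarity sits a positive "nugget" above an
exact zero, so the line through the anchor tilts up even when nothing
changes systematically. The default fit therefore uses the downstream
pairs only, with a free intercept that absorbs the nugget; under a null
gradient the expected rate is then zero. Two-site transitions keep the
head pair (the fit degenerates to the finite difference d/t₁, as it
should), and `include_head=True` restores the anchored variant for
comparison. An origin-forced fit is also available.

Negative slopes on noisy dissimilarities are legitimate estimates and are
kept on their signed scale; the pipeline logs their frequency. The
log-log cross-rate regressions (ΔBCM on ΔRES etc.) exclude rows with a
non-positive rate in either column and report the exclusion count, since
those rows have no logarithm. Rates entering the path models are used on
their raw signed scale; the SEM stage standardizes internally, so upstream
scaling (including the cell-count scale of ΔBA) cannot dominate.

## Recursive path models

A candidate causal structure is a DAG over the six rate variables with
ΔRES as the exogenous root and ΔBCM as the terminal response. The model is
the linear-Gaussian recursive system x = Bx + ε with strictly triangular
(in topological order) coefficient matrix B and independent errors,
implying Σ(θ) = (I−B)⁻¹ Ψ (I−B)⁻ᵀ with Ψ diagonal. Because the Gaussian
likelihood of such a system factorizes over nodes, the ML estimates are
the equation-wise OLS estimates computed from the sample correlation
matrix S: β_v = S_PP⁻¹ S_Pv and ψ_v = 1 − R²_v per endogenous node. The
engine verifies this numerically (BFGS on F_ml with analytic gradient,
started from perturbed values, agrees with the closed form to better than
1e-6 in every parameter).

Fit is judged by the ML discrepancy F_ml = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p,
scaled to T = (n−1)·F_ml and referred to a chi-square distribution with
df = p(p+1)/2 − (p + E): p = 6 variance parameters plus E path
coefficients, with exogenous variables assumed mutually uncorrelated.
Under this convention both 7-edge library structures (A-DAG4, B-DAG4) have
df = 8. A structure is *retained* ("significant" in path-analysis usage)
when T does not exceed the critical value — a small p-value rejects the
structure. α defaults to 0.05 and is always reported alongside p. The
alternative convention in which exogenous covariances are free parameters
(df reduced by one per exogenous pair) is available via `exog_free_cov`.

Because the model family is closed under diagonal rescaling, fitting the
correlation matrix is equivalent to fitting the covariance matrix; the
reported coefficients are standardized path coefficients (SD change in the
child per SD change in the parent) and r² per endogenous node is 1 minus
its standardized residual variance. Per-coefficient standard errors, t and
p come from the per-equation OLS with n − k − 1 residual df.

The printed reference statistics this machinery reproduces analytically
(the df = 8 bookkeeping for 6-node/7-edge models) are exact; note that a
chi-square(8) reference assigns p ≈ 0.02 to T = 17.9, so published
path-analysis p-values obtained under other statistic conventions (e.g.
d-separation tests or resampling) will not match the chi-square p reported
here. This engine reports the standard ML chi-square p only.

**Model library.** The nine candidate DAGs ship as JSON
(`src/ratepath/data/model_library.json`) rather than code, so edge sets
can be curated without touching the engine. Replacement-scenario models
(A-DAG1..4) all contain ΔRES→ΔBCC; adjustment-scenario models (B-DAG1..5)
all contain ΔRES→ΔSCC. In B-DAG4 and B-DAG5 composition is a second
exogenous root whose paths feed physiological structure and metabolism
directly. The prose sources describing these structures are not fully
explicit about every edge; the JSON encodes the edge sets consistent with
the stated constraints (7 edges and df = 8 for both DAG4 variants, root
and sink roles, the ΔBCC→ΔPS / ΔBCC→ΔBCM / ΔBA→ΔBCM content of B-DAG4),
and any alternative encoding can be supplied via `--library`.

**Subset screenings.** `by_date` refits the library per sampling date;
`by_intensity_median_split` ranks rows by ΔRES and splits them into
equal-sized low/high groups (odd row counts give the high group the extra
row); `single_resource` substitutes a one-variable resource rate (e.g.
ΔDOC, computed as |z_i − z_j| on the standardized single column) for ΔRES.
Subsets below 10 rows are skipped with a warning: with p = 6 variables a
correlation matrix needs n ≥ 8 to be non-singular, and the (n−1)·F_ml
statistic is meaningless at smaller n anyway.

## Synthetic data

Two generators provide causal ground truth.

`sample_rate_sem` draws rate-table rows directly from the linear-Gaussian
system: exogenous nodes standard normal, endogenous nodes parent-sum plus
N(0, sd²) noise, in topological order. It is the reference sampler for
calibration (data really drawn from the model) and power experiments.

`simulate_transition_dataset` emulates the study design one level below
the rates: 13 transitions × 3 dates by default, 4 sites per transition at
transit times (0, 6, 18, 36) h, per-transition gradient intensities
geometrically spaced over 0.25–4 (an order-of-magnitude spread), modulated
per date by factors (0.7, 1.0, 1.3) as a stand-in for seasonal variation.
Along a transition the resource score rises linearly with transit time at
the gradient's rate; downstream node scores propagate through the
generating DAG (default coefficient 0.7 per edge); exogenous non-resource
nodes (composition in the two-root adjustment structures) drift with their
own random slope, uncorrelated with resources. Each measured variable is
its category score times a fixed loading plus N(0, noise_sd²) noise
(noise_sd 0.3 by default); abundance and the metabolism variables are
exponentiated to stay positive (metabolism is log10-normalized again on
the way in, closing the loop). Composition is emitted as a band table:
12 active bands per transition from a 40-band pool, lane intensities from
a softmax of base logits plus gradient-driven drift (total lane intensity
100). The *adjustment* scenario changes only these relative intensities —
band identity sets are constant, so head-to-site turnover is exactly zero.
The *replacement* scenario swaps band identities: among the top-5 dominant
bands (by head-lane intensity), a fraction that grows linearly with
transit time up to `turnover_fraction` is replaced by reserve bands unique
to the transition; at turnover 1 no dominant band is shared between head
and terminal site. All randomness descends from one integer seed through
`SeedSequence` spawning (one stream per transition for band structure, one
per transition × date for scores and noise), so a fixed seed reproduces
every table byte-for-byte.

What the generator does **not** emulate: real limnological chemistry,
spatial autocorrelation between transitions, gel artefacts (band
co-migration, lane saturation), taxon dynamics, or nonlinear responses.
Passing tests therefore demonstrate that the statistical machinery is
correct and calibrated under the linear-Gaussian assumptions the analysis
itself makes — not that those assumptions hold in any particular field
dataset. One consequence is visible at study scale: pushing community-level
data through dissimilarities is a nonlinear transformation, so the
rate-level covariance only approximates the generating DAG's, and with 39
rows the true structure is retained in roughly half of replicate studies
(a wrong structure essentially never wins). Recovery is near-certain when
rates are sampled from the system directly at large n.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use: 50 random recursive models
(6 nodes, 3–10 edges, n = 300) for the OLS/ML equivalence at 1e-6;
chi-square calibration from each of the 9 library models at n = 500
(1500 replicates per model in the tests, 500 in the script) against the
band 0.032–0.071 around the nominal 0.05; scenario recovery and power at
coefficient 0.7 and n = 2000 over 200 replicates; 100 gradient-free
replicate datasets (5 transitions × 1 date) for the null-rate check; and
20 replicate full studies for the study-scale retention frequency. Matrix
discrepancies are guarded by Cholesky positive-definiteness checks;
residual variances are optimized on the log scale in the numerical ML;
tiny negative F_ml round-off at the optimum is clamped to zero; saturated
models (df = 0) report p = 1 by convention. Ranking of retained models is
by descending p, ties broken by fewer edges then library order.

## Known limitations

No latent variables, feedback loops, fit indices beyond chi-square/p, or
d-separation (C-statistic) tests; single-date categories and missing rows
are dropped rather than imputed; the Euclidean metric is the only distance
offered; transit times are taken as given inputs, with no hydrological
modeling.
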