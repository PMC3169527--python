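# Methods

## The imprinting model

The simulator formalizes a verbal mechanism — co-transcriptional imprinting
of transcripts by Rpb4/7 and a limited cytoplasmic decay-machinery pool —
as a deterministic ODE system over mean copy numbers.  Per gene *i* two
pools evolve, imprinted `I_i` and non-imprinted `U_i`:

    dI_i/dt = q_i(t) β_i(t) − k_U I_i − min(D s_i, λ_max I_i)
    dU_i/dt = (1 − q_i(t)) β_i(t) − k_U U_i

* `q_i(t) = clip(p(t) · a_i · ρ_i, 0, 1)` — probability that a newly made
  transcript is exported imprinted.  `p(t)` jumps from `p_basal = 0.3` to
  `p_stress = 0.8` at stress onset; `a_i ∈ [0,1]` is a per-gene affinity;
  `ρ_i` is 1 in wild type and < 1 in a recruitment-impaired mutant.
* `β_i(t) = β_i · φ_i(t)` — transcription; `φ` is a stress profile
  (transient pulse or sustained step).
* `k_U` — basal first-order decay acting on every molecule (1/min).
* machinery flux — the pool `D` (molecules/min) is shared in proportion to
  imprinted-copy fractions, `s_i = f_i/Σf_j`, `f_i = I_i/(I_i+U_i)`, with a
  per-molecule cap `λ_max` so an almost-empty imprinted pool cannot absorb
  an arbitrary flux.  Unused capacity is not redistributed.

Assumptions: machinery acts only on imprinted molecules (the non-imprinted
pool decays at `k_U` alone); affinities are constant through stress; export
is instantaneous; the system is deterministic (the argument is at the level
of copy-number fractions, and determinism keeps tests exact).  Integration
is explicit Euler, `dt = 0.05` min, pools clipped at zero with a warning;
halving `dt` tenfold changes trajectories by < 0.5%.

Three scenarios mirror the experimental design: `reference_decay` (arrest
at t = 0, no stress), `stress_decay` (stress at t = 0, arrest 7 min later,
sampling clock restarting at the arrest; samples 0,5,10,20,30,40,50 min),
and `stress_abundance` (stress only; samples 0,5,10,15,25,35,45 min).  The
ground-truth "effective half-life" of a (generally non-exponential)
trajectory is defined exactly as the estimator defines it: ln 2 over the
least-squares slope of log copies against the sampled times.

## Default parameters and why

| parameter | default | rationale |
|---|---|---|
| `p_basal → p_stress` | 0.3 → 0.8 | the probabilities the mechanism posits for basal vs stress export |
| `k_U` | 0.02 /min | puts reference half-lives at ~20–30 min, typical of a yeast transcriptome |
| `D` | 120 molecules/min | machinery consumes most of the imprinted production of a 1000-gene genome while staying capacity-limited; scale with genome size |
| `λ_max` | 0.35 /min | numerical guard; rarely binding at the defaults |
| genome | 300 induced / 400 neutral / 300 repressed | class proportions of a strong environmental-stress response |
| `β` | 2^N(1, 0.8); induced × 0.25 | log-normal expression; stress-induced genes are lowly expressed before induction |
| affinity | U(0.35, 1.0) | broad heterogeneity in Rpb4/7 clientship |
| stress multipliers | 8× (induced), 0.125× (repressed), each × 2^N(0, 0.8) | median 8-fold induction/repression with the wide per-gene spread real responses show |
| stress profile | pulse, τ_on = 2 min, τ_off = 15 min (25 min for repression) | oxidative-stress-like transient transcription drive |
| noise | 0.15 log2 units multiplicative, per-array scale sd 0.2 log2 | intensity-array measurement error and global array distortions |
| spike-in | summary over 100 control probes | an array's internal-standard value aggregates many control features, so its error is far below a single probe's |
| mutant | ρ = 0.4, basal abundance 0.7× wild type | strongly reduced recruitment plus a production defect |

These constants were fixed once, by forward exploration of the model,
to sit in the regime the mechanism describes — machinery capacity-limited,
wild-type counter-action strong, mutant attenuated — and were not revisited
afterwards.

The mutant's production defect deserves a note.  It is specified as the
*realized* median basal abundance ratio (0.7), imposed by a fixed-point
calibration of per-gene transcription rates: a raw β multiplier is not the
same thing as an abundance ratio because the mutant's altered decay feeds
back on abundance.  The defect is also coupled to imprinting affinity
(genes that rely most on Rpb4/7 lose the most production,
`attenuation_affinity_coupling = 0.6`), reflecting that the real mutation
impairs synthesis and decay through the same subunits; with a purely
uniform defect the model predicts a *positive* association between basal
abundance change and basal stability change, the opposite of what the
coupled defect produces.  Both knobs are exposed on `MutantDesign`.

## Estimation choices

* **Reference-profile scaling.** Transcription-arrest courses cannot use
  spike-ins (the arrest drug is polymerase-unspecific), so each array is
  rescaled to make the genome-mean intensity follow a prescribed reference
  decay profile.  The scaling is per-column and monotone: within-array
  ranks are untouched, and applying it twice is a no-op.  The default
  reference is a 20-min-half-life exponential; any two-column TSV can be
  supplied.  Forcing both conditions (or both strains) onto one reference
  centers *global* stability differences on zero — relative statements
  (correlations, ranks, enrichment) survive, absolute ones do not.
* **Log-space OLS with free intercept.**  First-order decay is exactly
  linear in log space, the fit is deterministic, and the free intercept
  absorbs t0 measurement noise.  A nonlinear least-squares variant on the
  linear ratios is available (`method="nls"`) for sensitivity analysis;
  on exact data the two agree.
* **Strict thresholds.** `R² > 0.9` (a gene at exactly 0.9 is dropped) and
  responsiveness at a linear fold change strictly above 1.75, applied
  symmetrically to induction and repression.
* **Spline maximum.** The maximal fold change is located on a cubic spline
  through the log2 profile with not-a-knot boundary conditions (so
  polynomial profiles are reproduced exactly); candidates are interior
  derivative roots plus both endpoints, ties broken by earliest time.
* **Cluster count.** The concatenated-profile tree is cut to `k` clusters
  (default 3) deterministically rather than by eye; labels are renumbered
  by first appearance so the partition is independent of input order.
  In the per-cluster stability fits the mutant is the response and the wild
  type the regressor, so a slope below 1 (95% CI below 1) reads as impaired
  mutant stability modulation.

## What the synthetic study does and does not emulate

The generator reproduces the *structure* of the real design — two strains,
reference/stress decay and stress abundance courses at the real sampling
times, multiplicative intensity noise, per-array global distortions, an
internal-standard control, and known ground truth.  It does not emulate
probe-level effects (RMA residuals, saturation, background), biological
replicate variability, cross-hybridization, or secondary regulation
(stress-activated RNA-binding proteins, translation effects).  Passing
tests therefore demonstrate that the estimators recover what this
observation model distorts, and that the analysis chain detects the
coupling pattern the ODE produces — not that the mechanism is what operates
in real cells.

Two quantitative limits of the formalization itself are worth recording,
because they bound what any parameter choice can show:

1. **Flux balance bounds the effect sizes.**  At steady state the machinery
   flux into gene *i* cannot exceed its imprinted production `q_i β_i`, so
   the machinery share of basal decay is at most `q/(1−q)` ≈ 0.35 `k_U` at
   `p_basal = 0.3`.  Stabilization of repressed genes during stress
   (machinery withdrawal) is therefore capped near +0.1 log2 in
   arrest-measured half-lives — the sign is robust, the magnitude modest —
   and induced-gene destabilization bottoms out near −0.7 log2.  Cells of
   the fold-enrichment table defined by stability-ratio cuts of 1.5–2 are
   consequently sparsely populated on the stabilized side.
2. **A residual null coupling is intrinsic.**  With machinery active, the
   standing imprinted fraction sits below the production fraction `q`, so a
   pure transcription burst (no change in `p`) still shifts a gene's
   imprinted fraction upward and transiently attracts machinery.  A
   constant-probability control run therefore shows a small negative
   correlation between abundance change and stability change (|r| ≈ 0.1–0.15
   through the noisy pipeline at the defaults) rather than exactly zero;
   it vanishes only in the limit of negligible machinery, where the
   stress-driven coupling vanishes with it.

## Numerical details

Steady states are found by damped integration to a 1e-10 relative drift
per minute, with the machinery-free closed form as the starting point, and
are cached per model.  Division by empty pools defines `f_i = 0`; shares
sum to 1 or to 0 (empty genome).  Genes with non-positive intensities are
dropped (never imputed) before log transforms, with logged counts.
Reported p-values are floored at 1e-300 before `−log10`.  All randomness
flows from explicit seeds; regenerating any bundle with the same seed is
bitwise reproducible.

## Known limitations

* The ODE is a mean-field caricature: no transcriptional bursting, no
  export delay, no machinery saturation kinetics beyond the `min` flux.
* The reference decay profile is an input; when it is wrong in *shape*
  (not just scale) the absolute half-lives are biased, though ranks and
  between-condition contrasts survive.
* The transience index compares only the endpoint to the extremum; it does
  not distinguish fast-relaxing from oscillatory profiles.
* With fewer than four time points the spline maximum falls back to the
  discrete extremum.
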