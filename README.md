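# decaycoupling

Genome-wide coupling between mRNA production and mRNA degradation, studied
through transcription-arrest decay experiments and a mechanistic simulator of
co-transcriptional imprinting.

## The scientific problem

When yeast cells meet a stress, hundreds of genes are transcriptionally
induced and hundreds repressed — yet the abundance response is often *spiked
and transient* rather than a slow approach to a new steady state.  One
proposed explanation is **counter-action coupling**: the same genes that are
transcriptionally induced are simultaneously *destabilized* (their mRNA
half-life drops), while repressed genes are *stabilized*.  Mechanistically
this can arise from co-transcriptional **imprinting**: each new transcript is
exported either associated with the Pol II subunits Rpb4/7 (probability `p`)
or not, imprinted molecules recruit the limited cytoplasmic decay machinery,
and the machinery pool is distributed across genes in proportion to each
gene's imprinted-copy fraction.  Raising `p` genome-wide at stress onset
then redistributes degradation capacity toward induced genes with no
gene-specific regulation at all.

This package is for computational biologists who want to (a) estimate mRNA
half-lives from transcription-shutoff time courses with the bespoke
normalizations those experiments need, (b) quantify the coupling between
abundance change and stability change, and (c) explore the imprinting model
as an explicit dynamical system.

## What is inside

**Simulation** (`imprinting`, `simulate`) — a deterministic ODE model per
gene *i*, with imprinted (`I`) and non-imprinted (`U`) copy pools:

```
dI_i/dt = q_i(t) β_i(t) − k_U I_i − min(D s_i, λ_max I_i)
dU_i/dt = (1 − q_i(t)) β_i(t) − k_U U_i
```

where `q_i = p(t)·affinity_i·ρ_i` is the effective imprinting probability
(`ρ < 1` models a recruitment-impaired mutant), `s_i = f_i / Σ_j f_j` is the
machinery share given imprinted fractions `f_i = I_i/(I_i+U_i)`, `D` the
total machinery capacity and `k_U` basal decay.  `generate_study` simulates
the full two-strain experimental design — reference decay, stress decay
(transcription arrested 7 min after stress), and stress abundance courses —
and observes it with multiplicative array noise, per-array scale distortions
and a spike-in control.

**Estimation** (`normalize`, `halflife`) — reference-profile scaling for
arrest courses (spike-ins are unusable when the arrest drug inhibits all
polymerases), zero transform, first-order fits `m(t) = m₀e^(−kt)` by OLS in
log space (`t½ = ln2/k`), a strict `R² > 0.9` filter, and stability changes
`Δ = log2(t½,stress / t½,reference)`.

**Statistics** (`response`, `coupling`, `cluster`) — responsive-gene calling
(fold change strictly above 1.75), spline-located maximal fold change and a
transience index, OLS coupling fits with 95% CIs, fold-enrichment tables
against an independence null, spike-in-normalized basal strain comparison,
and Spearman/average-linkage clustering of concatenated two-strain profiles
with per-cluster stability-modulation slopes.

**Orchestration** (`pipeline`, `cli`) — `run_all` goes from a YAML config
(simulation block or input TSV paths) to the full set of tables, JSON
summaries and a provenance manifest; the `decaycoupling` command exposes
`simulate`, `normalize`, `fit-halflives`, `respond`, `couple`, `cluster` and
`run-all`.

## Worked example

```python
from decaycoupling.pipeline import PipelineConfig, run_all

cfg = PipelineConfig(outdir="demo", seed=1, hl_threshold=1.25, simulate={})
res = run_all(cfg)
print(res.coupling["wild_type"]["all"].summary())
print(res.enrichment["wild_type"].summary())
```

prints (default 1000-gene study: 300 induced / 400 neutral / 300 repressed,
imprinting probability 0.3 → 0.8 at stress):

```
Coupling fit (stability change ~ maximal fold change)
  n genes:      1000
  Pearson r:    -0.5216   -log10(p) = 70.12
  fitted line:  y = -0.0911x + -0.0728
  slope 95% CI:     (-0.1003, -0.0818)
  intercept 95% CI: (-0.0823, -0.0633)
Fold enrichment (observed / expected under independence)
  n genes: 1000
    induced & stabilized   obs    0  exp    2.06  enrichment 0.00  p = 1
    induced & destabilized obs   47  exp   12.15  enrichment 3.87  p = 7.41e-24
  repressed & stabilized   obs    7  exp    4.22  enrichment 1.66  p = 0.072
  repressed & destabilized obs    3  exp   24.90  enrichment 0.12  p = 1
```

Read: across the genome, stability change is negatively correlated with the
transcriptional response (induced genes are destabilized — Pearson r ≈
−0.52), and the discretized view shows the two counter-acting cells
(induced∧destabilized, repressed∧stabilized) enriched above independence
while the co-acting cells are depleted.  Rerunning the same genome with the
recruitment mutant (`ρ = 0.4`) collapses the correlation to r ≈ −0.02 and
flags every induced cluster's wild-type-vs-mutant stability slope far below
1 — the mutant barely modulates stability, and its induced genes relax more
slowly (mean transience 0.03 vs 0.42 in wild type).

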