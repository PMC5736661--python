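# Methods

## Study design emulated by the synthetic generators

All generators share one design: four exposure conditions (Control,
TiO2NPs, UV, UV+TiO2NPs) with three biological replicates for the omics
tables. A single global seed drives independent per-generator
substreams (`numpy.random.SeedSequence` spawn keys), so an identical
configuration is byte-identical on disk and adding a generator never
perturbs another's draws.

**Expression.** Per-gene baseline log2 intensities are drawn once from
Normal(7, 1.5) — arbitrary but typical of microarray log intensities;
only relative effects matter downstream. Each condition replicate is
baseline + planted log2 effect (zero off-plan) + additive
Normal(0, `noise_sd_log2`) noise, default SD 0.25 on the log2 scale,
matching how fold changes and t-tests are computed. The generator does
not emulate probe-level summarization, between-array normalization
artifacts, intensity-dependent variance, or correlated genes; passing
recovery tests therefore demonstrates correctness of the selection
arithmetic and thresholds under the assumed model, not robustness to
raw-chip preprocessing.

**Pathways.** `n_pathways` (default 12) gene sets with sizes uniform on
`pathway_size_range` (default 5–40) sampled from a 200-gene universe,
without replacement within a pathway and freely across pathways, so
overlaps — the source of shared-pathway links — arise naturally; a
guaranteed overlap is enforced when two or more pathways exist.

**Mortality.** Deaths at positive dose d are
Binomial(n, Φ((log10 d − log10 LC50)/σ)) with defaults LC50 = 7.9 mg/L
and σ = 0.176 on the log10 scale; the zero dose produces zero deaths
(no natural-mortality parameter, consistent with UV alone showing no
lethal effect in the emulated design).

**Reproduction.** Offspring counts are truncated-at-zero rounded
Normal(mean, CV·mean) draws, 8 worms per condition, CV 0.1. Group means
are calibrated so the relative decreases of UV+TiO2NPs against
Control / TiO2NPs / UV are 37.9% / 29.5% / 24.3%, with the Control mean
fixed at 230 offspring (a typical 72-h wild-type brood; only ratios
matter). A normal-with-CV generator was chosen over a negative binomial
because the quantities consumed downstream are group means and
significance only. The variance of real brood counts is not part of the
calibration; CV 0.1 is a stated default, and the percent-decrease
estimator consequently carries ≈3-point sampling SD per 8-worm table —
recovery checks therefore average over replicate tables.

**qPCR / metabolites.** The housekeeping gene (*pmp-3*) has constant Ct
by construction; target Ct is a per-gene baseline − log2(planted
relative expression) + noise, so noiseless tables round-trip exactly
through ΔΔCt. Metabolite concentrations are baseline × planted fold ×
log-normal noise. Default panels plant oxidative-stress-like responses
(e.g. gst-4 up under UV+TiO2NPs) and an energy-metabolism signature
(succinate accumulation, pyruvate depletion).

## DEG selection

Welch's two-sample t-test on log2 intensities is used for per-gene p
(the robust default for n = 3 groups); fold change is the difference of
mean log2 values, i.e. a geometric-mean ratio, not a ratio of linear
means. The compound rule |FC| > 2 AND raw p < 0.01 uses strict
inequalities on both thresholds; boundary genes are excluded. No
multiple-testing correction is applied — the compound threshold is the
procedure — and a notice is logged. Degenerate zero-variance cases are
defined explicitly: equal means give p = 1, unequal means give the
smallest positive float.

## Network scoring

The graph is a *simple* graph with per-edge pathway-label sets rather
than a multigraph with one edge per shared pathway, so geodesic lengths
are pathway-independent. Unit edge weights reduce Dijkstra to BFS; a
predecessor DAG per source enumerates all geodesics. During scoring the
DAG backtrack prunes at any non-DEG node, since every node of a
qualifying path must be a DEG — this enumerates exactly the DEG-only
geodesics of the *full* network (a geodesic of the DEG-induced subgraph
that is longer than the full-network distance does not qualify).

Pathway increment rule: each qualifying geodesic adds one per pathway
per traversed link carrying it (a 2-link path with both links labeled P
adds 2 to P), because links are the carriers of pathways in this
construction. The alternative — at most one per path per pathway — is
available as `pathway_increment="per_path"`. Unordered pairs are
counted once, self-pairs are excluded, and disconnected pairs
contribute nothing. Both the pair-edge count and the (pair, pathway)
incidence count are reported, as either can be meant by a "number of
links".

A `path_cap` (default 10^6 enumerated geodesics per scoring run) aborts
with guidance rather than silently truncating scores; per-pair
enumeration via `all_shortest_paths` instead flags a capped result
non-exhaustive.

## Permutation null and p-values

Null replicates draw node sets of the mapped-DEG size uniformly without
replacement **from network nodes**, not the full gene universe, and are
scored identically. The empirical p uses the add-one pseudocount
(1 + b)/(1 + n_perm), which is super-uniform under the null and cannot
reach zero; its floor is 1/(n_perm + 1). Because reported pathway
p-values in this kind of analysis sometimes lie below that floor, an
optional `null_model="gaussian"` computes a one-sided normal tail from
the null mean/SD; it is a smooth approximation, not an exact test, and
the empirical mode is the default. Result rows sort by ascending p with
pathway ID as a deterministic tie-break.

## Toxicology endpoints

Probit regression is on log10 dose (toxicology convention; an
LC10/50/90 triplet like 4.7/7.9/13.2 mg/L is self-consistent under
log-normal tolerance since 7.9/4.7 ≈ 13.2/7.9). The fit is a binomial
GLM with probit link (IRLS, parameter tolerance 1e-8); μ = −a/b,
σ = 1/b from the intercept/slope. Zero-dose rows are dropped. A
non-positive fitted slope (flat or decreasing response) raises a
non-identifiability error; non-monotone but rising data fit with a
warning flag. LCp = 10^(μ + σ·Φ⁻¹(p)).

Group tests use one-way ANOVA with Tukey HSD, or two-tailed Welch t
per pair; all two-sample tests in the package are the Welch variant for
consistency. ΔΔCt assumes amplification efficiency 2 (100%); the
control condition maps to exactly 1 because its ΔΔCt is identically
zero. Total-area normalization scales each sample column to unit sum.
The metabolite filter is two-sided (ratio > 1.5 or < 1/1.5, strict)
with Welch p < 0.05, labeling direction as accumulation or depletion.

## Numerical and scale choices

- Empirical p-values and all probabilities are clamped away from zero
  at the smallest positive double; p ∈ (0, 1] throughout.
- Writers emit 6-significant-digit floats and deterministic column
  order for diffable outputs; the run manifest records a configuration
  hash and per-output SHA-256 checksums.
- Test and recovery problem sizes (200-gene/12-pathway networks,
  n_perm 200–500, 50–200 replicates) are desk-scale choices that keep
  the full suite fast while leaving Monte-Carlo error well inside the
  asserted tolerances.

## Known limitations

- The scoring is direction-agnostic: up- and down-regulated DEGs are
  pooled. Per-direction scoring is a trivial re-invocation with a
  filtered DEG set.
- No gene-identifier mapping between expression platforms and pathway
  annotations is provided; inputs must share a namespace.
- Probit confidence intervals (Fieller/fiducial) are out of scope;
  only point estimates are computed.
- The pipeline orchestrator drives the simulated study; on real data
  the individual CLI subcommands are composed instead.
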