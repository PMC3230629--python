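# Methods

## Model and assumptions

The core object is a parallel reaction network in which `n` competitors
reversibly bind a shared target and each target–competitor complex
carries an irreversible production flux. At steady state the flux
through competitor `i` is proportional to the complex amount `tc_i`, and
the conserved totals obey `T = t + Σ_j tc_j` and `C_i = c_i + tc_i`
(moiety conservation). Three assumptions underlie the closed-form
response coefficients:

1. binding is reversible mass action;
2. production is irreversible mass action (first order in the complex);
3. the substrate of the production step is constant and subsumed into an
   apparent rate constant.

Under these, the response of each steady-state flux to the conserved
totals depends *only* on `(T, C_i, tc_i)` — the formulas in the README —
and not on any rate constant. The package treats the amounts as
unit-agnostic: `T`, `C` and `tc` must share one unit (molecules/cell or
concentration) and are never converted. Input tables are validated with
a relative slack of `1e-9` to absorb rounding in published tables.

Two algebraically exact consequences are used as internal checks
throughout the test suite:

* row identity: `R_i^T + Σ_k R_i^{C_k} = 1 + R_i^T · t/T`;
* ultrasensitivity: `R_i^T > 1 ⇔ Σ_j tc_j s_j > s_i T`. The threshold
  reported to users is the equivalent free-target bound
  `t < Σ_{j≠i} tc_j (ρ_ij − 1)` with `ρ_ij = s_j/s_i`; the predicate
  itself is evaluated in the division-free form so competitors with
  `s_i = 0` need no special-casing (their threshold is `+inf` whenever
  any other competitor holds target).

The denominator of the target response is implemented as
`1 − Σ_j (tc_j/T)(tc_j/C_j)`. This is the unique form consistent with
the verbal description of the theory (numerator = free-competitor
fraction, symmetric saturation-weighted denominator) and it reproduces
every entry of the published sigma-factor table at printed precision;
likewise the self response is fixed as `1 − R_i^T · tc_i/T`.

## Translation: multiple identical targets

An mRNA of `N` codons accommodates at most `N/L` ribosomes of footprint
`L` (default 12 codons). The closed-form coefficients carry over with
`s_i = P_i L/N_i` and `f_i = C_i P_i/T`, where `P_i` is the mean number
of ribosomes bound per transcript. The derivation additionally assumes
all-or-nothing binding of the average load and no steric interference —
the translation-specific error sources probed by the traffic simulator.

`P` resolution precedence when building a state from a table: an
explicit `P` column wins; otherwise `occupancy × polysome_size`, with
missing occupancies filled by a default of 0.75 (the mean of the
compiled measurements the default emulates); otherwise a ribosome
density. Densities are expressed in ribosomes per 100 codons — the only
unit in which the physical cap equals `100/L = 8.33` for `L = 12`; a
converter from ribosomes per 1000 nucleotides (× 0.3) is provided.
Densities above the cap are measurement artefacts and are clamped to
`cap − ε` with `ε = 0.005` density units by default (configurable);
the clamp count is reported.

## Mass-action simulator (oracle for the single-binding formulas)

State variables are the complexes, with
`d tc_i/dt = k_f_i t c_i − (k_r_i + k_cat_i) tc_i` and the free pools
substituted through the conservation relations. Fluxes are
`J_i = k_cat_i tc_i`.

* Closed-form steady state: `tc_i = K_i t C_i/(1 + K_i t)` with
  `K_i = k_f_i/(k_r_i + k_cat_i)`; the free target is the unique root of
  the strictly increasing function `t + Σ_i tc_i(t) − T` on `[0, T]`,
  found by Brent bracketing to near machine precision.
* Integrated steady state: LSODA (stiff-capable, required because rate
  constants may span four orders of magnitude) from `tc = 0` in doubling
  time chunks until `max|d tc/dt| ≤ 1e-10 · max(tc)`; the steady state
  of this model class is unique, so the initial condition is immaterial.
  Cross-solver agreement is asserted at `1e-6` relative.
* Numerical response: forward log-difference
  `[ln J(p(1+δ)) − ln J(p)]/ln(1+δ)` with `δ = 0.01` by default; a
  central variant (`p(1±δ)` symmetric in log space) is available and is
  one order more accurate in `δ`, which the tight-tolerance oracle tests
  use.

The bundled three-competitor example (`sigma_network_params`) uses
binding constants 24/8/11, unbinding 3/6/30, production 5 (per minute)
with totals 700/370/110 — a parameter set whose steady state at
`T = 700` falls in the regime of the measured sigma-factor state. The
rate constants only ever enter oracle comparisons between the formulas
and finite perturbations *on the simulated state*, so their calibration
looseness is immaterial to those tests.

## Ribosome-traffic simulator (oracle for the multi-site formulas)

Mean-field ODEs for the per-codon occupancy `p_j` of each mRNA species
(fraction of molecules with a ribosome front at codon `j`), with a
shared free pool `r_free = T − Σ_s C_s Σ_j p_{s,j}`:

* initiation `k_init · r_free · (1 − Σ_{j≤L} p_j)`;
* elongation `k_elong · p_j · (1 − Σ_{m=j+1}^{j+L} p_m)/(1 − Σ_{m=j+1}^{j+L−1} p_m)`
  — the conditional probability that the codon ahead is free given the
  hard-body exclusion, the classical closure for traffic of extended
  particles; both window sums are truncated at the last codon, codons
  beyond the stop being treated as free;
* termination `k_term · p_n`, giving the species flux
  `J = C · k_term · p_n`.

Whether the conditional-probability denominator should span `L − 1` or
`L` downstream codons is ambiguous in verbal descriptions of such
models; this implementation fixes `L − 1`, the form that reduces to the
standard point-particle expression `k p_j (1 − p_{j+1})` at `L = 1`.

Steady states are found by a Newton-type fixed-point solve (hybrid
Powell), warm-started from a nearby solution when scanning, with
feasibility checks (occupancies in `[0,1]`, every `L`-window sum ≤ 1,
non-negative free pool); if the fixed-point solve fails, the ODEs are
relaxed by LSODA in doubling chunks (`rtol 1e-8`) until
`max|dp/dt| ≤ 1e-9` and then polished. Flux balance
(initiation = termination throughput) holds at `~1e-14` relative at the
returned states.

A structural property of this model worth knowing when interpreting
oracle comparisons: under strong initiation the coverage `P L/N` of an
mRNA does not approach 1 but the maximal-current density of the
exclusion process, `√L/(1+√L) ≈ 0.776` for `L = 12` (verified by a unit
test). Near this jamming regime the closed formulas — which assume no
steric interference — overestimate the residual sensitivity of jammed
fluxes, and the acceptance-level comparison of formulas against finite
perturbations documents exactly where the agreement degrades. At low
and moderate coverage the two agree closely.

## Synthetic transcriptome generator

The generator emulates the statistical structure of compiled yeast
translation datasets; its defaults are the study conditions, not tuning
knobs:

| quantity | distribution | default | unit |
|---|---|---|---|
| genes | — | 4621 | — |
| ribosome pool `T` | — | 79 | µM |
| footprint `L` | — | 12 | codons |
| ORF length | log-normal, clipped to `[L, 5000]` | median 400, σ_log 0.55 | codons |
| abundance | log-normal | median 0.0026, σ_log 1.0 | µM |
| density | log-normal, capped at 8.33 | median 0.8, σ_log 0.8 | rib./100 codons |
| occupancy | Beta(6, 2) | mean 0.75 | — |
| missing occupancy | Bernoulli | 2% | — |

The density tail is chosen so a default-sized draw produces a handful of
physically impossible densities (of order ten in 4621), exercising the
clamping rule the way real compiled tables do; the abundance scale is
chosen so a draw commits roughly the whole ribosome pool, as measured
data do (most ribosomes engaged). When a draw demands more bound
ribosomes than the pool holds, all `P` are rescaled by one common factor
to leave 5% of the pool free (configurable); real datasets already
satisfy the constraint, so this step is a feasibility guard for
synthetic draws only. Generation is reproducible: one seed, one table.

What the generator does **not** emulate: correlations between abundance,
length and density present in real data; per-codon elongation
heterogeneity; measurement error structure; paralog structure or any
gene identity (ids are synthetic). Tests passing on these tables
therefore demonstrate the correctness and the qualitative genome-scale
behaviour of the formulas (majority of transcripts ultrasensitive when
the pool is nearly fully committed; occupancy = 1 variant shifting the
distribution; deterministic 5% tail binning at `floor(0.05 n)` = 231 of
4621 genes with ties broken by gene id), not quantitative claims about
any particular organism.

## Numerical choices and degenerate inputs

* Response denominator ≤ 0 (all target bound to fully saturated
  competitors) raises a degenerate-state error naming the offending
  competitors.
* Ratio relations with zero reference quantities raise undefined-ratio
  errors rather than returning infinities.
* Exact identities (row identity, ratio relations, predicate
  equivalence) are asserted at `1e-12` relative on randomized states;
  equivalence between the analytic formulas and `δ = 1e-4`
  finite perturbations of the mass-action model at `1e-3` relative.
* The traffic-model right-hand side clips the conditional weight's
  denominator at `1e-12` to tolerate transient overshoot of the
  exclusion boundary during relaxation; returned steady states are
  always checked against the exact feasibility conditions.
* Tail binning uses `floor(fraction · n)` per bin; with all-equal
  coefficients the bins are the lexicographically first and last ids
  (documented determinism).

## Scale of the validation runs

Oracle scans use 20 target levels for the mass-action comparison and an
8-point logarithmic grid over 0.1–220 µM for the two-mRNA traffic
comparison with full-length 240-codon ORFs; unit tests of the traffic
mechanics use shorter ORFs (36–48 codons). These sizes keep the whole
suite in the tens of seconds while covering the first-order, transition
and saturated regimes of both simulators.

## Known limitations

* The closed formulas assume the production step is far from substrate
  limitation; substrate dynamics are out of scope.
* The traffic model is mean field: it neglects correlations between
  ribosome positions, which a discrete stochastic exclusion process
  would capture.
* Cross-talk conclusions at genome scale concern single-competitor
  perturbations; co-regulated groups of mRNAs changing together compound
  their (individually small) effects, which the per-gene coefficients
  quantify only additively to first order.
* Annotation enrichment of the exported tail bins requires external
  databases and is deliberately not part of the package; the pipeline
  stops at ranked gene lists.
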