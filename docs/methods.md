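# Methods

## The analysis

`gshflux` implements a transcriptome-constrained ensemble analysis of a
kinetic model of glutathione metabolism. The question it answers: given
replicate gene-expression measurements for a patient and a control, and a
kinetic (ODE) model of the pathway, what does the expression change imply
for the *fluxes* through the pathway — and where does the flux change
fail to track the expression change?

The chain of computations:

1. **Expression → Vmax ranges.** The working assumption is that a change
   in mRNA abundance maps one-to-one onto a change in the enzyme's maximal
   rate. For gene *g* mapped to reaction *r*, each replicate hybridization
   *i* of subject *s* yields

   `Vmax_r,i(s) = Vmax_r,ref · ( x_g,i(s) / mean_i x_g,i(control) )`

   and the replicate values are collapsed to the interval
   `[min_i Vmax_r,i, max_i Vmax_r,i]`. The control subject gets an interval
   from its own replicate spread, so control ensembles carry measurement
   uncertainty too. Where several genes map to one lumped reaction (the
   GST isoforms), per-replicate ratios are combined by geometric mean —
   symmetric between up- and down-regulation on the log scale. The
   mRNA→Vmax exponent is configurable (`proportionality`, default 1;
   0 switches expression scaling off for sensitivity analysis).

2. **Monte-Carlo steady-state ensemble.** Each sample draws one Vmax per
   reaction, independently and uniformly within its interval, and solves
   the steady state. Means and SDs of every flux and concentration are
   accumulated in a single pass (Welford). The uniform choice is the
   minimal assumption for "a value within the range"; the distribution id
   is a config field so alternatives can be added without interface
   changes. The reference ensemble size for the full-scale analysis is
   500,000 samples; the library default is a desk-scale 10,000, which
   resolves flux means to well under 1% relative Monte-Carlo error on the
   bundled models (standard error of the mean ≈ SD/√n).

3. **Condition comparison.** For each reaction,
   `flux_ratio = mean flux(case) / mean flux(control)`,
   `vmax_ratio = midpoint(case range) / midpoint(control range)`, and
   `agreement = log flux_ratio − log vmax_ratio`.
   Agreement 0 means the flux follows the enzyme-capacity change
   one-to-one; strongly negative agreement is the signature of a
   supply-/demand-limited step whose flux ignores its own Vmax. The
   "effect" flag marks `|Δmean| > SD_case + SD_control` — a separation
   heuristic over the parameter-uncertainty distributions. It is **not** a
   hypothesis test: the ensemble SDs quantify propagated parameter
   uncertainty, not sampling error of an estimator, so no p-values are
   attached anywhere.

## The kinetic model layer

Models are species + reactions + rate laws with a stoichiometric matrix
N; time evolution is `dc/dt = N·v(c)` with boundary (clamped) species
rows forced to zero. Three rate-law forms are supported:

- irreversible Michaelis–Menten, `v = Vmax · Π_i S_i/(Km_i + S_i)` (one
  saturation factor per substrate);
- reversible Michaelis–Menten (one substrate, one product),
  `v = (Vmax/Kms)(S − P/Keq) / (1 + S/Kms + P/Kmp)`, which vanishes
  exactly at the equilibrium mass-action ratio;
- mass action `v = k·ΠS_i`, including zeroth-order constant inputs.

Units are fixed: mM, hours, fluxes in mM/h. SBML unit definitions are
read but not converted (documented limitation). Exchange is SBML L3V1
(L2 is read); kinetic-law parameters use the local-parameter convention
`Vmax`, `Km_<species>`, `Keq`, `k`, and the maximal-rate parameter of
arbitrary models is located by a configurable id-pattern list
(default `Vmax`, `Vmax_<rid>`, `V<rid>`, `Vf`).

### The surrogate glutathione network

The published reference model's equations are not redistributable here,
so the package bundles a surrogate with the same scope: methionine cycle
(with the DNA-methyltransferase step labelled `v11`), glutathione
synthesis (gamma-glutamylcysteine synthetase → glutathione synthetase),
detoxification (glutathione peroxidase GSH→GSSG, reductase, GSSG export,
GST conjugation drain), and the gamma-glutamyl cycle (lumped
transpeptidase/cyclotransferase, 5-oxoprolinase labelled `v27`, a slow
non-enzymatic 5-oxoproline leak, dipeptidase salvage). 13 species (4
boundary), 16 reactions. Reference Vmax/Km values are surrogate choices
verified to give a unique positive steady state (GSH ≈ 0.85 mM at
reference); they are not measured constants, and any conclusions about
real subjects require supplying the real model via `--model`. The
surrogate has no conserved moiety — every internal pool exchanges with a
boundary — so steady states are unique rather than dependent on initial
totals.

## Steady-state solver

Strategy: integrate the ODEs (LSODA) in expanding time chunks toward
stationarity, then polish with a damped Newton iteration on the algebraic
system; if Newton fails, the integration result alone decides. Defaults:
absolute tolerance 1e-9 mM/h per dynamic species, horizon 1e6 h of model
time. Convergence requires max |dc/dt| ≤ tolerance **and** non-negative
concentrations; anything else returns `converged=False` (never an
exception) so ensembles can count failures — trajectories exceeding 1e9
mM are cut off as unbounded (e.g. a drain Vmax below a constant input).

Conserved moieties are detected exactly as the rational left null space
of the dynamic stoichiometric matrix; one ODE row per moiety (the one
with the largest coefficient) is replaced by the conservation relation
anchored at the starting concentrations, which removes the Jacobian
singularity before Newton.

Ensemble solves are warm-started: the range-midpoint steady state is
solved once, its Newton Jacobian LU-factored, and each sample runs a
chord-Newton iteration (fixed factorization, fresh residuals). This
converges for draws near the reference because the Jacobian varies slowly
inside the sampled box; failures fall back to a full Newton from the
reference and then to integrate+polish. A test asserts the chord path
agrees with the full path to 1e-7. Typical cost ≈ 1 ms/sample on the
surrogate. Per-sample random substreams derive from `(seed, sample
index)`, so summaries are independent of execution order; identical
configs give bit-identical summaries.

The monostability assumption (solution independent of the starting
point) is asserted on the fixtures, not proven; bifurcation and
oscillatory regimes are out of scope.

## Synthetic data

`gen_expression` emulates normalized bead-summary microarray intensities:

`intensity = base · fold_change · exp(ε)`, `ε ~ N(0, σ)`,
`σ = sqrt(log(1 + CV²))`,

so the multiplicative CV equals `noise_cv` exactly and intensities are
strictly positive. Defaults: base 1000 (typical normalized bead scale),
CV 0.05 (a realistic residual replicate CV after normalization), two
replicates per subject, matching the study design the pipeline serves
(one control, two patients, duplicate hybridizations). It models
*residual post-normalization noise only*: no probe effects, background,
batch structure, or correlation between genes. Passing tests on this
generator therefore demonstrate pipeline correctness (ratios, ranges,
propagation), not robustness to raw-array artefacts.

The bundled study-shaped scenario programs the reported expression
contrasts: H0008 with 5-oxoprolinase (OPLAH) up 1.86× and glutathione
synthetase (GSS) up 1.26×; H0007 with DNA methyltransferase (DNMT1) down
2.33× and GSS down 1.2×; both patients with GPX4 up 1.3× (a
representative modest value — only the direction is reported for the
peroxidase).

### Toy fixtures and their closed forms

- **chain**: constant input k1 → S → MM drain (Vmax, Km). Steady flux =
  k1; S* = Km·k1/(Vmax−k1), requires Vmax > k1. The flux is input-limited:
  scaling the drain Vmax moves S*, not the flux.
- **branch**: input k1 split between two MM drains with a shared Km:
  J_i = V_i·k1/(V1+V2); S* = Km·k1/(V1+V2−k1).
- **redox**: closed 2·RED→OX / OX→2·RED couple; RED + 2·OX conserved —
  the moiety-handling and conservation-drift fixture.
- **supply**: clamped substrate S0 → MM input → S → high-capacity drain.
  J = V_in·S0/(Km+S0) exactly proportional to V_in — the
  flux-follows-Vmax counterpart to the chain.

The chain and supply fixtures together realize the central qualitative
phenomenon: the same two-fold enzyme up-regulation yields flux_ratio ≈ 2
(supply) or flux_ratio ≈ 1 with agreement ≈ −log 2 (chain), i.e. a good
flux/Vmax correlation is a property of network position, not of the
expression change.

## Numerical and design choices

- Newton: forward-difference Jacobian (step 1e-7 scaled), Armijo-style
  backtracking with non-negativity projection, ≤ 60 iterations.
- Range construction is min/max over replicates (not mean ± k·SD) —
  the ranges are replicate envelopes, not confidence intervals.
- Ratios use the control *mean* in the denominator (per-replicate
  denominators would double-count control spread).
- Degenerate ranges (single replicate equal to control mean, or unmapped
  reactions) sample as constants and consume no RNG draws.
- Non-converged samples are excluded from summaries and counted; a
  warning fires above 1% failures; an all-failed box raises with the box
  printed.
- Agreement-table ordering: |agreement| descending, ties broken by
  reaction id for stable output.
- CSV outputs use pandas defaults (UTF-8, '.' decimal, full repr floats),
  which makes the byte-identical determinism contract testable.

## Problem sizes used in tests and the acceptance script

Quadrature and law-of-large-numbers checks run at n = 10⁴ samples;
the SD-of-mean scaling law uses 10 independent ensembles at each of
n ∈ {10², 10³, 10⁴} on the surrogate (slope −0.5 ± 0.1 on log–log axes);
end-to-end recovery uses n = 2000 per ensemble. These sizes put
Monte-Carlo error well inside the asserted tolerances (3 standard
errors where a statistic is compared to a closed form).

## Known limitations

- The surrogate model's parameters are illustrative; quantitative flux
  predictions for the study subjects require the external reference model
  (SBML) and its Vmax range table, which the pipeline accepts but does
  not bundle.
- One steady state per draw is assumed (monostable regime).
- Reversible MM is restricted to uni-uni reactions.
- No microarray preprocessing, differential-expression testing, or
  multiple-testing control — inputs are normalized intensities and the
  outputs are descriptive ratios with propagated parameter uncertainty.
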