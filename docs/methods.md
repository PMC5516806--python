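# Methods

All concentrations are micromolar (μM) and all times minutes; no
compartment volumes are modelled. "Steady state" always means the state at
which the largest relative rate of change, max_i |dy_i/dt| / max(|y_i|,
10⁻⁶ μM), falls below 10⁻⁹ per minute.

## Occupancy profiling

Occupancy is the single-site binding isotherm C/(K_d + C) evaluated at the
mean unbound plasma concentration at steady state, which is taken to
equilibrate with the intracellular free drug. Censored affinities ("no
measurable binding") are mapped to occupancy 0 rather than dropped, so two
drugs' profiles always cover the same kinase universe and differences are
well defined. Differential shortlisting keeps kinases with occupancy ≥
`min_occ_a` (default 0.5) for the drug of interest and ≤ `max_occ_b`
(default 0.1) for the comparator, ranked by occupancy difference with
lexicographic tie-breaks for deterministic output. The thresholds are
package defaults, not a reconstruction of any published cut-off: half
occupancy is the natural "substantially engaged" boundary for a binding
isotherm, and 0.1 leaves a 5-fold margin to call the comparator essentially
unengaged.

## IC50 fitting

Inhibition curves are fitted with the four-parameter logistic
`bottom + (top − bottom)/(1 + (c/IC50)^h)` by unweighted nonlinear least
squares. The contract is the minimised residual sum of squares, not a
specific optimiser; the implementation uses a bounded trust-region
least-squares solver over (top, bottom, log IC50, h) with multi-start over
a log-spaced grid of IC50 initial values, which makes the fit insensitive
to the starting point. The Hill slope may be clamped (`fix_hill=1` for
pure one-site competition) or fitted freely (default, bounds 0.05–10).
Curves whose responses are flat carry no concentration information and
raise a non-identifiability error instead of returning an arbitrary IC50.
A fitted IC50 outside the spanned concentration range is flagged
`extrapolated`.

## Glycogen-phosphorylase cascade

Species: active/inactive glycogen phosphorylase (GPa/GPb) and glycogen
synthase (GSa/GSb), glycogen (glucosyl units) and G6P. PHK phosphorylates
GPb with Michaelis–Menten kinetics and competitive inhibition by drug,

    v_PHK = Vmax · GPb / (Km·(1 + I/K_i) + GPb),    K_i = 5.5 μM default,

and the same kinase activity (scaled to [0,1) as v_PHK/Vmax) inactivates
GSa with first-order rate `k_gs_inact`. Protein phosphatase 1 reverses
both with shared Michaelis–Menten kinetics. Glycogenolysis is
`vmax_gp·GPa·gly/(km+gly)`; synthesis is `vmax_gs·GSa·g6p/(km+g6p)` with a
capacity factor (1 − gly/gly_cap) that is far from active at baseline
(baseline stores ≈ 10% of capacity) and merely prevents unbounded
accumulation. G6P has a constant lumped hexokinase supply and a
first-order drain to glycolysis.

The competitive term is written with respect to the protein substrate.
The measured affinity is for the ATP site, but the algebraic form of
competitive inhibition is identical under reinterpretation of the
substrate, so the dose–response shape — the quantity of interest — is
unaffected.

A first-order non-phosphorolytic glycogen turnover `k_gly_loss` (lumping
lysosomal/debranching routes whose products do not return to the G6P pool)
is included deliberately: without it, the glycogen balance forces
synthesis = phosphorolysis at steady state and steady-state G6P becomes
independent of drug. With the loss term, steady-state synthesis exceeds
phosphorolysis by `k_gly_loss·gly`, so drug-induced glycogen accumulation
drains G6P — the coupling the tandem chain propagates. Reference values
put half the G6P supply through this route at baseline (gly ≈ 5000 μM,
loss ≈ 5 μM/min against a 10 μM/min supply), giving G6P a 49.7 → 11.4 μM
dynamic range over drug 0–100 μM.

Reference kinetics were designed, not fitted: PP1 capacity is set at twice
PHK's Vmax so the resting cascade sits mostly off (GP activity ≈ 0.22,
GS activity ≈ 0.20), and a 100 μM dose drives GP activity below 0.03 and
GS activity above 0.7. The drug-free steady state (the documented
reference initial condition) is obtained by root-solving the right-hand
side, not hard-coded.

The endpoint of a simulation reports the PHK *flux* recomputed from the
final state; the cascade's "PHK content" is not a state variable here, so
activity (flux) is the reported quantity.

## Oxidative pentose-phosphate pathway

G6PD and 6PGD are bi-substrate Michaelis–Menten rates
`Vmax·(A/(Km_A+A))·(NADP/(Km_N+NADP))`; a first-order drain (lumped
biosynthetic and antioxidant demand) returns NADPH to NADP+, closing the
pyridine pool. G6P is a *clamped supply*: it relaxes toward the supplied
level `g6p_initial` at rate `k_g6p_refresh`, so the steady state — and the
NADPH/NADP+ ratio it defines — depends on the supplied G6P level, which is
what the upstream interface scales. A depleting (no-refresh) variant is
available via `clamped=False` for transient studies; the clamped mode is
default because a steady ratio is what the downstream model consumes.
Ribulose-5-phosphate is a terminal sink (the non-oxidative branch is out
of scope); it is reported as cumulative production and excluded from
steadiness checks, since it grows without bound whenever flux is nonzero.
Reference values give a baseline NADPH/NADP+ ratio of 2.87 at
g6p_initial = 100 μM, falling monotonically to 0 as the supply is removed.

A caveat discovered in robustness sweeps: if G6PD flux exceeds the maximal
6PGD capacity, 6-phosphogluconate accumulates without bound and no steady
state exists. The integrator's convergence flag reports this honestly;
robustness sweeps therefore draw jittered parameter sets from the model's
validity domain, screened by that flag (never by any downstream
comparison).

## Glutathione redox cycle

GPx consumes 2 GSH per H2O2; GR regenerates GSH from GSSG using NADPH;
both are bi-substrate Michaelis–Menten. NADPH is resupplied at flux
`k_nadph_supply · (NADP/NADP_total)` — proportional to the oxidised
fraction so the pyridine pool stays bounded — and `k_nadph_supply` is the
handle the tandem interface scales to impose an upstream NADPH deficit.
Optional zero-order GSH synthesis and first-order GSSG efflux open the
glutathione moiety; both default to 0, conserving GSH + 2·GSSG exactly
(3000 μM total, a physiological low-millimolar pool; NADP pool 50 μM).
A steady state exists only while the NADPH supply exceeds the H2O2 load
(2 μM/min reference production against a 10 μM/min reference supply);
below that the pool oxidises and H2O2 escapes control, which the
convergence flag again reports.

Vitamin E is a non-depleting pool quenching H2O2 at second-order rate
`k_vite_quench·vite·H2O2` (tocopherol radicals are assumed regenerated by
other cellular reductants; a depleting-pool variant sits behind the
`depleting_vite` flag). Quenching substitutes for GPx flux, so under a
halved NADPH supply (steady GSH at 62% of the unstressed 3000 μM) raising
the vitamin-E load monotonically restores GSH; when the quench flux
carries ≥ 99.9% of the H2O2 production, GSH returns to within 5% of the
unstressed steady state. The reference quench constant (1 /μM/min) places
the rescue's half-effect within a 10²–10³ μM load range.

## Tandem coupling

The chain runs the glycogen model to steady state at each dose, scales the
pentose-phosphate model's `g6p_initial` by the G6P fold-change, and scales
the glutathione model's `k_nadph_supply` by the NADPH/NADP+ *ratio*
fold-change (a supply-scaling reading — the glutathione model's own NADPH
is dynamic, so overwriting it directly would be inconsistent). Coupling is
multiplicative (fold-change) by default because only the degree of change
is transferable between independently scaled models; an absolute mode
exists for models that genuinely share units. Fold-changes are therefore
invariant to rescaling any single model's concentration units, dose 0
reproduces each model's standalone baseline exactly, and no information
flows backwards. Per-dose failures (e.g. a non-convergent stage) are
recorded in the scan's `status` column without aborting the grid.

## Numerical choices

- Integration: LSODA (stiffness-switching), rtol 10⁻⁸ / atol 10⁻¹⁰ μM.
  Conserved pools are linear invariants of the right-hand side and are
  preserved to rounding by the multistep integrator (observed drift
  ≤ 10⁻¹⁵ relative; the contract is ≤ 10⁻⁶).
- Steady states: chunked relaxation (doubling chunks from 500–2000 min, cap
  2×10⁶ min) to the 10⁻⁹/min criterion, cross-checked against an
  independent algebraic root of the right-hand side. The root solver works
  in log-coordinates on reduced variables (conserved pools eliminated via
  an odds parameterization that keeps iterates inside their bounds) with a
  deterministic multi-start; agreement is ≤ 0.1% (observed ~10⁻⁷).
- Negative excursions beyond 10⁻⁶ of the state scale abort integration;
  smaller ones are clipped to zero.
- CSV output uses 9 significant digits, so repeated runs are
  byte-identical.

## Synthetic data

The kinome generator emulates the *structure* of a two-drug selectivity
panel, not any real kinome: 50 kinases, 3 shared primaries (K_d 0.001–0.05
μM, near-saturated for both drugs at the 1 μM exposures), 4 drug-A-only
off-targets (K_d 0.1–0.9 μM, censored for drug B), the rest weak
background (10–10⁴ μM, 30% censored). The off-target K_d ceiling is kept
below the exposure so every planted off-target exceeds the 0.5 occupancy
threshold — the generator guarantees its planted truth is recoverable in
the noise-free limit, which is what makes exact-recovery tests meaningful.
Assay curves are 4PL responses (true IC50 5.5 μM by default) on a
zero-anchored 8-point log grid with multiplicative Gaussian noise of
stated CV. Parameter jitter multiplies each positive parameter by a
log-normal factor of given CV. All generators are pure functions of their
scenario (seed included); none touches global random state.

What passing these tests does *not* show: real kinome panels have
correlated affinities across gene families, real assay noise is not purely
multiplicative, and the three pathway models are minimal mechanisms whose
parameters are designed stand-ins — the package's claims about real data
are directional (signs and orderings of responses), not quantitative.

## Known limitations

- The pathway models reproduce directional behaviour; absolute
  concentrations and time constants are not calibrated to any tissue.
- No calcium/hormonal activation of PHK, no insulin signalling, no
  non-oxidative pentose-phosphate branch, no catalase/peroxiredoxin
  competition for H2O2, no γ-glutamyl cycle detail.
- SBML import/export is not provided; parameter sets are YAML.
- The tandem chain is feed-forward only, by design; systems with genuine
  feedback between these pathways need a merged model.
- Problem sizes used throughout (50-kinase panels, 10-point dose grids,
  10–20-set jitter sweeps) are the package's reference study conditions;
  all scale linearly if enlarged.
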