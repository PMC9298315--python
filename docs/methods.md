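# Methods

## Blending model

A working medium is a map item → (target concentration, unit family) plus a
fill volume.  Unit families are **closed**: `g_per_L`, `v_v_percent` and
`fold` never convert into one another, and a fold concentration is anchored
to the name of the reference premix it scales ("1x YNB" and "1x MEM amino
acids" are unrelated).  This is safe because the volume computation only
ever needs the dimensionless ratio target/stock within one family.

Item resolution precedence is: exact stock-name match (the stock must be
single-component, otherwise the target is ambiguous), then unique
registered stock containing the item as a component; multiple suppliers or
no supplier raise explicit errors rather than guessing.

The solver computes the ideal volume `C_target/C_stock · V_fill` per item,
rounds it to the pipette resolution (default 0.1 µl, a typical
small-pipette step), and tops up with water by difference, water always
last so worklists are deterministic.  Feasibility rules:

* every per-item volume ≥ `min_transfer` (default 1 µl — sub-microliter
  dispenses are unreliable on small liquid handlers); the error reports the
  smallest stock dilution that would fix the offending item;
* summed stock volumes ≤ fill volume;
* transfers above `max_single_dispense` (default 300 µl) are split into
  equal sub-steps, equal rather than max-first so every sub-step stays
  comfortably above the minimum.

Because rounding shifts the realised concentration, the plan reports the
**achieved** concentration per item next to the target instead of silently
compensating; a >1% shift is flagged.

`water_fraction` and `max_fold_concentration = 1/(1 − water_fraction)`
quantify the headroom of a formulation: a medium that is 69% water can be
prepared at up to 3x working strength from the same stocks.

## Plate planning

24-well plates are 4×6 (rows A–D), filled row-major by default; randomized
layouts are a seeded permutation of the slot sequence, so a seed reproduces
the layout exactly.  Worklists are grouped by source stock (water last)
because serving every destination from one source before switching is how
liquid handlers minimise tip and labware changes.  Deck requirements are
`(1 + safety_margin) · Σ demand + dead_volume` per stock, margin 10% by
default, with slots assigned in demand-descending order.  Dead volume is a
property of the source labware and therefore lives on the stock, applied
only at deck aggregation.

## Response-surface statistics

`fit_quadratic` builds candidate terms — intercept, linear per factor, all
pairwise interactions, quadratic for numeric factors with ≥ 3 levels —
with numeric factors coded to [−1, 1] (conditioning; standard RSM
practice) and categorical factors effect-coded.  Backward elimination is
strictly sequential: fit OLS, compute per-term p-values (t for
single-column terms, F for effect-coded groups), adjust across the current
non-intercept terms (Benjamini–Hochberg by default; Holm and none are
options), drop the single worst term above α (default 0.01), refit.
Model hierarchy is *not* enforced by default — elimination is purely by
p-value order — but a flag can protect linear terms whose factor appears
in a surviving higher-order term.

Numerically perfect fits (noiseless data) make every t statistic 0/0; the
implementation takes the well-defined limit instead: when SSR ≤ 1e−12 ·
max(TSS, 1), a term with coefficient norm above 1e−8 of the coefficient
scale gets p = 0 and an exactly-zero term gets p = 1.  This is what makes
noiseless oracle surfaces behave correctly (zero terms eliminated, true
terms retained).

Coefficients over numeric factors are reported in natural units by
re-expanding the coded polynomial; with categorical factors the
effect-coded coefficients are reported as fitted.

`optimum_on_surface` maximises the fitted surface on a box with a dense
grid of ≥ 201 points per axis (full mesh up to 3 factors; above that,
coordinate-ascent sweeps over 201-point axis lines, since a full 201⁴ mesh
is ~10⁹ points), refined analytically for a pure one-dimensional parabola
(vertex −b/2c).  A maximum on the box boundary is flagged, not treated as
an error, because a monotone fitted surface is a legitimate outcome.

`screen_vs_control` works inside a one-way-ANOVA frame: the per-condition
contrast against the control uses the pooled within-group variance across
*all* conditions (df = N − k), which is exact under homoscedasticity and
gives far better power at n = 3 per arm than isolated two-sample tests;
p-values are BH-adjusted across conditions, and the omnibus F is reported
alongside.  Growth-type endpoints should be screened on the log scale
(`transform="log"`), where multiplicative noise is homoscedastic; titers
on the identity scale.  Which adjustment real screening software applies
is rarely documented, so the method is an explicit config option.

`welch_one_tailed` uses the Welch statistic with Welch–Satterthwaite
degrees of freedom; zero-variance degenerate samples (which arise in
noise-free simulation) resolve by direct mean comparison (p ∈ {0, 0.5, 1}).

## Greedy optimization loop

Each round: supplement screen → combination screen (singles + all
unordered pairs of the beneficial set, ranked by mean) → concentration
optimization.  The audit-trail discipline is strict: every evaluation is
recorded in the audit log, and acceptance is an explicit statistical rule
rather than an informal choice — the top combination is accepted when a
one-tailed Welch test against the incumbent passes (α = 0.05 default)
*and* its mean exceeds the incumbent's recorded best mean.  The second
condition also makes the accepted-mean trajectory monotone non-decreasing
by construction, even when the stage-local control arm draws low.
Concentration changes are accepted on a strict mean improvement at a level
different from the current one; re-selecting the current level counts as
no change so the no-gain stopping rule can fire.

Detrimental supplements are excluded from later rounds by default
(`rescreen_all` restores full re-screening).  Screening concentrations
come from the library file, never inferred.  Stopping reasons:
`spec_met`, `library_exhausted`, `no_gain`, `max_rounds`.

`tune_items` lists base components (e.g. the carbon source) to include in
every concentration stage; which base components deserve scanning is a
judgement call in practice, so it is explicit configuration here.

## Phenotype simulator

The simulator composes per-component effect multipliers on a positive
baseline: `essential` (Monod saturation, zero without the component),
`boost` (1 + (f_max−1)·c/(K+c): fine without the supplement, saturating
benefit with it), `peaked` (f_max·(c/c_opt)·e^(1−c/c_opt), unimodal with
maximum f_max at c_opt), `inhibitory` (1/(1+slope·c)) and `inert`.  The
`boost` shape exists because a screening library needs supplements whose
absence leaves the control viable — an essential shape would zero the
control and trivialise every screen.  `boost_effect(c_screen, effect)`
calibrates K and f_max so the multiplier equals `effect` exactly at the
screening concentration (90% saturation there by default).

Synergies are pairwise multipliers γ applied when both components are
present, matching the pairwise combination screens the optimizer runs.
Replicate noise is multiplicative log-normal with σ = √ln(1 + cv²), so
the replicate CV equals `noise_cv`, values stay positive, and log-scale
variance is concentration-independent.  Noise streams are keyed by (truth
seed, replicate seed, CRC32 of the medium name, replicate index):
deterministic per call, different across replicates and media.  Unknown
medium items are treated as inert with a warning so libraries may exceed
the truth's scope.

What the simulator does **not** model: growth dynamics over time, pH
drift, precipitation, flocculation, or any mechanistic coupling between
components beyond the pairwise γ.  Passing tests therefore demonstrate
that the algorithms recover what was planted under proportional plate
noise — not that any specific real medium will behave likewise.

## Benchmark study sizes

The bundled studies use 1000 random media for the solver oracle, 200
seeded replicates per arm for the screen operating characteristics
(16 supplements, 5 beneficial at +50%, 10% CV, n = 3, α = 0.02 BH on the
log scale), and 50 seeded runs of the full optimization loop on a planted
landscape (two +50% supplements with a 1.2x pairwise synergy and a peaked
carbon source with optimum at 22.5 g/L inside the scanned range, 5% CV,
n = 3, up to 3 rounds).  The default replicate CV of 0.10 is a fixture
choice representative of small-scale plate screens, not a measured value.

## Known limitations

* The optimizer is greedy; on non-separable landscapes it finds local
  optima by design.
* The combination stage is pairwise-only by default; higher-order synergy
  requires a config change and cost grows combinatorially.
* No chemical feasibility model: solubility limits are metadata for
  stockability checks, not constraints the solver enforces per blend.
* Worklist schemas are self-defined (documented CSV), not claimed to be
  drop-in for any particular robot vendor.
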