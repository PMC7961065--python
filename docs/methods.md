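# Methods

## Model

Three state variables are tracked over the 14-day injury-repair window:
osteoblast abundance `OB(t)` and osteoclast abundance `OC(t)` (cells per
reference marrow volume) and bone volume `B(t)` (mm³). The constant-rate
("initial") model is

```
dOB/dt = H_OB + γ_OB·OB·1[0 ≤ t ≤ T_anab] − δ_OB·OB
dOC/dt = −Inhib_OC·OC·1[t ≤ T_antiCatab] + R_OC·1[t ≥ T_Catab] − δ_clear·OC
dB/dt  = −δ_B·OC·B + Π_B·OB
```

The injury is encoded purely through the sharp indicator windows: a transient
osteoblast expansion of duration `T_anab`, an osteoclast suppression phase of
duration `T_antiCatab`, and osteoclast replenishment starting at `T_Catab`.
Resorption is proportional to bone volume (less bone means less substrate to
resorb); formation is proportional to osteoblast number only.

Three closures pin the homeostatic state `(OB₀, OC₀, B₀)` as an exact fixed
point: `H_OB = δ_OB·OB₀`, `δ_clear = R_OC/OC₀`, and — in the
closure-constrained workflows — `Π_B = δ_B·OC₀·B₀/OB₀`. The osteoclast
clearance term is kept active at all times (including during suppression);
`T_Catab = 0` means the replenishment source is never interrupted.

The myeloid-modulated ("expanded") model replaces the bone equation by

```
dB/dt = −δ_B·(1 + α·P(t))·OC·B + Π_B·(1 + β·A(t))·OB
```

where `P(t)` is the combined pro-inflammatory monocyte + macrophage signal
and `A(t)` the anti-inflammatory macrophage signal, both expressed as
*excess* fold change over homeostasis (0 at day 0 and as t → ∞). The
multiplicative `(1 + α·P)` coupling guarantees exact reduction to the base
model when α = β = 0 or the drivers vanish, and a well-defined homeostatic
limit. Anti-inflammatory monocytes are not coupled (they stay at
consistently low levels); the mono/mac combination weights default to (1, 1)
but are configurable because the split is not constrained by the data.

The piecewise variant replaces `δ_B` (or `Π_B`) by an explicit continuous
piecewise-linear function of time with breakpoints on a uniform grid,
constant extrapolation beyond the end breakpoints, and hard bounds
`[10⁻⁸, 5·10⁻⁵] mm³ cell⁻¹ day⁻¹` taken from published osteoclast resorption
measurements. Evaluation never clamps silently: bound violations are exposed
to the calibration penalty and can be made to raise.

## Driver curves

Myeloid populations are imposed, not mechanistically modeled. Each
population is a sum of asymmetric log-normal pulses
`a·exp(−ln((t−t₀)/r)²/d)` (zero before the onset `t₀`, peak `a` at `t₀ + r`,
width set by `d`). Any smooth non-negative unimodal kernel through the
observed error bars would be equally consistent; this parametric choice
makes otherwise manual fits reproducible. Driver fitting minimizes the
weighted SSE Σ(curve(tᵢ)−meanᵢ)²/σᵢ² with onsets initialized at the largest
local maxima of the mean series, plus a ~10⁻⁶-scale amplitude shrinkage that
breaks ties between exact fits (a pulse hidden outside the observation
window fits all-zero data as well as no pulse; the shrinkage selects the
zero-amplitude solution without measurably biasing data-driven fits).

## Calibration

The objective is the minimax weighted least squares
`LS = max_j Σ_i (f_j(t_i) − D_ij)²/σ_i²`, taken over the fitted variables so
no variable is sacrificed to another. `D_ij` are replicate means; `σ_i` is
the standard error of the mean of the (default 5) replicates, floored at 5%
of the variable's baseline magnitude so noise-free data never produce an
undefined objective. Model comparison uses `AIC = 2p + LS`.

Minimization is Nelder–Mead with a quadratic penalty on normalized bound
violations (scale 10⁶ — large enough to dominate any plausible LS, smooth
enough for the simplex), multi-start with seeded jitter (default 5 starts),
and up to three "polish" restarts of the simplex from its own best point,
which reliably recovers from premature stalls in narrow valleys. Searches
run in a space scaled by the magnitude of the start point; rate parameters
spanning decades (δ_B, Π_B) are optimized in log₁₀ space. Everything is
deterministic given the seed; repeated runs are bitwise identical.

Fitting is staged: (1) cell dynamics (`γ_OB, T_anab, Inhib_OC, T_antiCatab,
R_OC` free; `δ_OB = 0.19 day⁻¹` fixed from literature, `T_Catab = 2 d`
imposed) against OB and OC only; (2) the bone equation with cells frozen,
via one of four workflows — a log-uniform scan of constant `δ_B` with `Π_B`
closure-constrained, a free joint `(δ_B, Π_B)` fit reporting the terminal
bone deficit `B(T)/B₀ − 1`, the modulation fit of `(δ_B, α, β)` with `Π_B`
closure-pinned and a penalty keeping `δ_B(1+αP(t))` inside the published
range, and the piecewise-rate fit (initial rate plus one slope per segment,
randomized slope initializations). The piecewise workflow anchors the
complementary constant rate by the homeostasis closure evaluated at the
fitted initial rate, so every candidate model starts at a fixed point.

### Numerics

`simulate` integrates with adaptive RK45 (default rtol 10⁻⁸ / atol 10⁻¹⁰),
restarted at every indicator switch time and piecewise breakpoint so
discontinuities never straddle a step. The cell subsystem is linear with
piecewise-constant coefficients and is also available in closed form
(piecewise-exponential); the two routes agree to < 10⁻⁶ relative and are
cross-checked in the tests. Bone-stage fits exploit the staging: with cells
frozen the bone equation is scalar and linear, and is integrated by an
exponential-midpoint scheme on a fixed grid (dt = 0.01 d), which is exact
for locally constant coefficients, unconditionally stable for any candidate
rate the optimizer proposes, and O(dt²) accurate (~10⁻⁵ relative here) at
~0.5 ms per evaluation.

### Standard errors

The original estimation procedure reports parameter SEs without stating the
method; this package provides a replicate-resampling bootstrap as a
substitute, not a reproduction. Replicates are resampled with replacement
independently at each (variable, time point), σ recomputed, and the workflow
refitted from cold starts — warm-starting refits from the point estimate
was found to shrink bootstrap SEs several-fold below the Monte-Carlo
sampling spread and is deliberately avoided. With zero bootstrap draws the
SEs are reported as unavailable, never as zero; more than 20% refit
failures invalidates them.

## Synthetic data

The generator emulates the study design: six variables (OB, OC, B and the
three informative myeloid subsets) at days {0, 1, 2, 3, 7, 14}, five
replicates per time point, multiplicative Gaussian noise with CV = 10%
truncated at zero (counts and volumes are positive; a CV is more plausible
than additive noise across variables spanning orders of magnitude). Myeloid
variables are emitted as excess fold change over homeostasis, matching how
the driver curves are defined. The generating truth is always serialized
with the dataset because parameter recovery is the pipeline's primary
validation mode.

The packaged fixture uses the published cell-dynamics estimates
(γ_OB = 0.873, Inhib_OC = 1.2186, R_OC = 6774.8, T_anab = 6.6924,
T_antiCatab = 2, T_Catab = 2, δ_OB = 0.19). Baselines are arbitrary but
chosen for identifiability and consistency with the published activity
values: OC₀ = 30000 cells (so R_OC/OC₀ ≈ 0.23 day⁻¹, an osteoclast recovery
timescale resolvable by the day-3/7/14 samples), B₀ = 0.5 mm³, and OB₀ set
so the closure formation rate equals the reported osteoblast-activity floor
1.21·10⁻⁶ mm³/cell/day. In the expanded fixture δ_B is the reported
osteoclast-activity floor 4.26·10⁻⁷ and (α, β) are defined so the modulated
activities span exactly the reported ranges [4.26·10⁻⁷, 7.28·10⁻⁶] and
[1.21·10⁻⁶, 2.63·10⁻⁶] — hence the ≈17-fold resorption and ≈2-fold
formation excursions. Driver pulses place the main pro-inflammatory wave
inside the first 48 h, a smaller monocyte wave around days 6–8, and the
anti-inflammatory infiltration after day 1, which yields the observed
biphasic bone course (dip by day 2, overshoot after day 2–7).

What the fixture does *not* emulate: the true observation-noise structure of
the experiments (figures only; CV = 10% is a convention), flow-cytometry
gating or histology counting artifacts, any feedback from bone state onto
myeloid dynamics, and absolute population scales (all acceptance-facing
quantities are ratios or relative errors so the baseline choice is
immaterial). Passing recovery tests therefore demonstrate that the
*machinery* identifies parameters under the study's sampling design and
noise level — not that the biological estimates themselves are correct.

## Test problem sizes

Recovery tests for the piecewise rate and driver curves use daily sampling
(15 time points): with only five post-baseline bone observations a
9-parameter rate function is under-determined and truth-recovery assertions
would be meaningless. All acceptance-facing runs keep the 6-time-point,
5-replicate study design. The long-horizon homeostasis-return check uses a
fast-turnover parameter set (δ_B·OC₀ = 0.05 day⁻¹): the property belongs to
the closure algebra, and with the published slow rates the bone relaxation
time (1/(δ_B·OC₀) ≈ 10³–10⁴ d) simply exceeds any reasonable horizon.
Bootstrap checks use 12–20 draws; the suite completes in a few minutes on
one CPU.

## Known limitations

- With the published expansion parameters the osteoblast excursion is large
  (≈95-fold), so closure-constrained bone trajectories overshoot baseline
  substantially before relaxing; the fixture's turnover scale keeps this
  within a physically sensible range but day-14 bone volume sits above
  baseline rather than back at it.
- `Inhib_OC` and `T_antiCatab` are weakly identified by the 6-point design
  (sampling SDs of ~25–30% at CV = 10%); the bootstrap SEs reflect this.
- The piecewise workflow's breakpoints are fixed (uniform); only the initial
  rate and slopes are estimated.
- No reciprocal coupling from bone state back onto myeloid dynamics, and no
  spatial structure.
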