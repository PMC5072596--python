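# Methods

## The behavioral-state model

A homogeneous population of `N` predators forages on a patchy landscape.
Population fractions occupy four behavioral states: lone search `s`,
harvesting a self-found patch `h`, moving toward a caller `m`, and bound
co-feeding at the caller's patch `b`. The per-capita fluxes are

| flux | rate | meaning |
|---|---|---|
| s → h | `1/τ_s` | a lone searcher finds a patch |
| s → m | `N λ s / τ_s` | a searcher receives a broadcast; proportional to the number of searchers about to discover (`N s`) times the tie strength `λ` |
| m → b | `1/τ_d` | the traveller reaches the called patch |
| h, m, b → s | `W_L = 1/τ_l + n_p/τ_h` | the patch is lost — it moved (hazard `1/τ_l`) or `n_p` co-feeders depleted it (hazard `n_p/τ_h`), combined as independent Poisson hazards |

At stationarity the in- and out-fluxes of every state balance. Using the
normalization `s + h + m + b = 1`, the system reduces to one scalar
equation in `s`:

    (N λ s² + s)/τ_s = (1 − s) · W_L(s),

with `h = (s/τ_s)/W_L`, `m = (Nλs²/τ_s)/(W_L + 1/τ_d)`, `b = m/(τ_d W_L)`.
Foraging efficiency is the feeding fraction `H/H* = h + b`; `H*` is the
consumption rate on an encountered patch, so `H/H* = 1` would mean feeding
without interruption. For `λ = 0` the model is exactly the Type II response
`1/(1 + τ_s/τ_h)`.

Two flux-consistent forms of the efficiency circulate: the per-state
balance value `h + b` used here, and a closed form whose sharing term drops
a `1/τ_s` factor relative to the balance equations. We report the
flux-balance value (it is the definition of the feeding fraction and is
internally consistent with the reduced equation for `s`); both values are
available from `functional_response(..., debug=True)` and coincide at
`τ_s = 1`.

### The co-feeding closure `n_p`

`n_p` — the expected number of predators consuming the same patch — is the
only carrier of spatial/temporal correlation. Its exact form is intricate;
two limits are transparent: a fully communicating group moves as one pack
(`n_p → N` as `λ → 1`), and under rare sharing the finder hosts on average
the bound-to-harvesting ratio (`n_p → 1 + b/h`, assuming a patch is not
independently discovered twice). The shipped closure interpolates linearly:

    n_p = (1 − λ)(1 + b/h) + λ N,   clipped to [1, N].

Because `b/h = Nλs / (1 + τ_d W_L)` and `W_L` depends on `n_p`, the closure
is a quadratic in `n_p` solved in closed form at each `s` (the positive
root; this is the exact fixed point of the blend, found algebraically
rather than by iteration). The closure is pluggable: `occupancy_np` is the
public estimator and the solver's result is verified self-consistent
against it.

### Numerical scheme

The scalar residual in `s` is negative as `s → 0+` (return flux `W_L > 0`
since `n_p ≥ 1`) and positive at `s = 1`, so a root always exists in
`(0, 1]`. The solver brackets sign changes on a 512-point uniform grid and
polishes with Brent's method to machine tolerance; if several roots exist
the largest `s` is returned with a warning (none has been observed across
10⁵ random parameter draws). Degenerate inputs: `τ_l = ∞` is handled as an
exact zero hazard, never a sentinel; `n_p` for `h = 0` with `λ < 1` is a
degenerate-state error.

**Single predator.** The printed s → m rate `Nλs/τ_s` is nonzero at
`N = 1`, i.e. a lone predator would call itself. The solver suppresses the
communication coupling when `N = 1` (no partner exists), so `λ` is inert
there and the group-size curve's `k = 1` point equals the lone Type II
efficiency exactly. `transition_rates` still reports the textbook formula.

## The agent-based simulator

A 2D square domain of side `X` with periodic boundaries carries `N_s`
circular patches (radius `σ`, initial prey `N_i`) and `N` predators.
Dynamics advance by a fixed increment `dt`; rates `r` become per-step
probabilities `r·dt`. Each step applies, in order:

1. **Landscape change** — each patch vanishes w.p. `r_l·dt` and is replaced
   at a uniform random location with full prey (coverage is conserved;
   patch "movement" is disappearance plus replacement). Predators whose
   target vanished revert to search.
2. **Consumption** — every harvesting/bound predator drains its patch by
   `r_q·dt` (scramble competition is additive; if less prey remains than
   demanded, the remainder is split pro rata). Depleted patches are
   replaced; their consumers revert to search.
3. **Calls** — predators that discovered a patch in the previous movement
   phase, and still hold it, broadcast once. Each *searching* neighbor
   independently receives w.p. the tie strength; a receiver heads for the
   nearest caller's patch (ties to the lowest index). Harvesting, bound and
   travelling predators ignore calls; there are no repeat broadcasts.
4. **Movement** — searchers travel ballistically at speed `v`, or with
   probability `r_p·dt` pause for one step and sense: a patch whose center
   lies within `σ_s + σ` is detected (sensing the patch edge counts), the
   predator locks onto the nearest such patch and moves to its center;
   otherwise it draws a fresh uniform heading. Travellers advance straight
   toward the called patch (shortest periodic path) and become bound on
   entering the patch radius. Communication range is the whole landscape.

Prey within a patch are a continuous scalar (their spatial arrangement
plays no role in any rule). Two searchers may discover one patch in the
same step; both harvest. A traveller whose target vanishes or is depleted
mid-journey reverts immediately. Sensing happens only at pauses, not during
ballistic flight, which inflates the measured `τ_s` slightly relative to
continuous sensing; since `τ_s` is always *measured*, not derived, this
costs nothing downstream. Encounters are logged separately as self-found
discoveries and called arrivals; the headline encounter rate is their sum.

Replicate worlds advance as one vectorized batch from a single seeded
generator, so identical `(config, seed, n_replicates)` reproduce metrics
bit for bit, and Monte-Carlo standard errors come from replicate spread.

### Timescale estimators

`τ_l = 1/r_l` and `τ_h = N_i/r_q` are exact. `τ_s` is the mean of repeated
single-predator first passages (no ties, consumption disabled, fresh random
initial conditions, the configured landscape dynamics active); censored
trials warn and bias the estimate low. `τ_d` is the Monte-Carlo mean travel
time between two uniform random points under the periodic metric
(≈ `0.3826 X/v` on the square torus), or a configured constant. The turning
rate used in experiments is the empirical arg-min of `τ_s(r_p)` on a
log-spaced grid with common random numbers, capped at `0.1/dt` so per-step
probabilities respect the discretization guard.

## Validation studies and their parameters

The validation base setting (chosen once): unit domain, 4 patches of radius
0.04 (≈ 2% coverage), speed 1, `dt = 0.01`, `r_q = 10`, sensing radius 0.06
(yielding `τ_s ≈ 2`, i.e. ≈ 200 steps and ≈ 5 travel times per search).
Handling time is varied through the integer prey count `N_i` at fixed `r_q`
— not through `r_q` — so the per-step drain never exceeds the 0.1
discretization guard. The sharing study uses the ratio grid
`τ_h/τ_s, τ_l/τ_s ∈ {0.5, 1.5, 4.5}` (bracketing 1, clear of the extreme
prey-mobility regime), two predators, `λ ∈ {0, 1}`, 30 replicates per cell
and ≈ 60 search-plus-handling cycles per run; these sizes resolve
efficiencies to ≈ 1% while keeping the full suite to minutes on one CPU.
The environment grid is *constructed* against the static-landscape search
time, but each cell's analytic prediction uses that cell's own
in-environment first-passage time: patch relocation genuinely contributes
encounters, and feeding that to `1/τ_s` is what the estimator measures.

Analytic sweep grids hold the normalizer at 5 travel times by default. This
matters: with the normalizer equal to `τ_d`, reaching a caller costs as
much as searching and sharing can never pay, so the value-of-information
map would be negative everywhere. Five travel times reflects the
simulator's own regime (`τ_s/τ_d ≈ 5.5` at the base setting).

## What passing tests do and do not show

The simulator *is* the synthetic data source; its defaults emulate a
patchy, re-shuffling prey field with intermittent searchers. Passing
validation shows that the four-state model with the blended closure
predicts simulated consumption within 20% across the studied grid, that the
timescales are sufficient statistics there, and that the qualitative
structure (value-of-information signs, convex/concave group-size regimes,
near-coincidence of their zero contours) is robust. It does not show that
real foraging systems satisfy the closure, that prey demography can be
neglected (prey abundance is stationary by construction), or that the
degree-one moments used here capture heterogeneous networks.

## Known limitations

* **Depletion is deterministic in the simulator but an exponential hazard
  in the model.** A lone feeding bout on a full patch lasts exactly `τ_h`
  in the ABM, while the Poisson combination in `W_L` treats it as
  memoryless; near `τ_h ≈ τ_l` this lengthens real bouts by up to ≈ 25%
  relative to `1/W_L` and is the main contributor to the residual
  efficiency gap.
* **The value-of-information zero contour is shifted between engines.** The
  simulator's fractional change sits systematically ≈ +0.05..0.08 above the
  blended-closure prediction, so cells within that band of the analytic
  zero contour can disagree in sign even when both efficiencies agree
  within 15%. A refined occupancy closure would be needed to align the
  contours; the strategy interface of `occupancy_np` is the intended
  extension point.
* Groups in the partition analysis are treated as non-interacting
  populations (patch replacement keeps coverage constant); cross-group
  competition is absent by construction.
* No interference or cooperative handling (`n_p` enters `W_L` linearly), no
  prey demographic feedback, no finite communication radius, no asymmetric
  networks, and no evolutionary dynamics on `λ` — the payoffs computed here
  are the inputs such analyses would need.
* Results should be `dt`-robust: halving `dt` at the base setting changes
  the efficiency by an amount indistinguishable from sampling noise (within
  three replicate standard errors, checked in the test suite); per-step
  event probabilities warn above 0.1.
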