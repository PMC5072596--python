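# forageshare

Models of **social foraging with information sharing**: when should a
predator broadcast the location of the prey it has found?

Lions on a savanna, hyenas converging on a kill, honey bees dancing, fishing
vessels radioing a school's position — in all these systems an individual
that finds a prey aggregation can tell others. The tip-off raises everyone's
encounter rate, but the recruits also eat from the same patch, so it
depletes faster. Whether sharing pays depends on the spatial temperament of
the system: how hard prey are to find, how long a patch lasts once found,
and how quickly the landscape itself reshuffles.

The package provides twin models of this trade-off, for quantitative
ecologists and modelers of social-ecological systems:

1. **A spatially implicit behavioral-state model** (`forageshare.behavioral`).
   Each of `N` predators is searching alone (`s`), harvesting a self-found
   patch (`h`), moving toward a caller (`m`) or bound co-feeding at the
   caller's patch (`b`). Space enters only through three timescales — the
   lone-search first-passage time `τ_s`, the lone handling time `τ_h`, the
   patch lifetime `τ_l` — plus the inter-predator travel time `τ_d`, and
   social behavior through the communication propensity `λ ∈ [0, 1]`.
   Stationary flux balance reduces to one scalar equation for `s`,

       (N λ s² + s) / τ_s = (1 − s) · W_L,    W_L = 1/τ_l + n_p/τ_h,

   where `n_p`, the expected number of co-feeders on a patch, carries all
   spatial correlation and is closed self-consistently by
   `n_p = (1 − λ)(1 + b/h) + λN`. Foraging efficiency is the feeding
   fraction `H/H* = h + b` — a *generalized functional response* that
   collapses to the Type II form `1/(1 + τ_s/τ_h)` when `λ = 0`.

2. **A spatially explicit agent-based simulator** (`forageshare.abm`).
   Predators perform intermittent search (ballistic runs at speed `v`,
   pauses at rate `r_p` sensing within radius `σ_s`) on a periodic square
   landscape with `N_s` circular prey patches that are drained at `r_q` per
   consumer (scramble competition) and relocate at rate `r_l`. Discoveries
   are broadcast over a symmetric social-tie matrix. Estimators map the
   simulator onto the analytic timescales (`τ_l = 1/r_l`, `τ_h = N_i/r_q`,
   empirical `τ_s` and `τ_d`), which is what lets the four-state model
   predict the simulator's measured consumption rates.

On top of these, `forageshare.experiments` reproduces the headline analyses:
**value-of-information maps** (two predators, fractional change of
consumption between full and no sharing, with its zero contour) and
**optimal group size** for a 30-predator population partitioned into
all-sharing groups, summarized by the curvature of efficiency vs. group
size.

## Worked example

```python
from forageshare import Timescales, SocialConfig, functional_response

# patches are rich (tau_h = 4 tau_s) but fleeting (tau_l = 0.4 tau_s);
# timescales are in units of the travel time tau_d
ts = Timescales(tau_s=5.0, tau_h=20.0, tau_l=2.0, tau_d=1.0)
lone = functional_response(ts, SocialConfig(8, 0.0))
pack = functional_response(ts, SocialConfig(8, 1.0))
print(lone.efficiency, pack.efficiency)
```

prints `0.2667 0.3236`: a lone forager feeds 26.7% of the time (exactly the
Type II value `1/(1+5/20)`), while a member of a fully communicating group
of eight feeds 32.4% of the time — a **+21% value of information**, because
tips are valuable when search is slow and a hoarded patch would soon vanish
anyway. In a persistent landscape (`tau_l = 200`) the loner feeds 78.4% of
the time and the pack member only 51.3%: the same call then *costs* 35%,
because seven recruits strip a patch the finder could have kept.

Each `examples/*.py` script is a runnable narrative of one capability:
`functional_response.py` (the sweep over `λ` above), `abm_quickstart.py`
(simulate a named scenario), `timescale_mapping.py` (measure `τ_s`, `τ_d`
and check the simulator against Type II theory), `value_of_information.py`
(the sign map and its zero contour) and `optimal_group_size.py` (convex vs
concave group-size curves).

A thin CLI wraps the same functions:

```bash
forageshare simulate --preset S4 --replicates 8
forageshare analytic --tau-s 5 --tau-h 20 --tau-l 2 --n 8 --lam 1
forageshare voi-map --resolution 21 --out voi.csv --heatmap voi.png
forageshare group-size --tau-s 5 --tau-h 60 --tau-l 4.2 --n-total 30
```

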