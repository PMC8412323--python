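# Methods

This note records the models implemented by `epilock`, the conventions
chosen where the underlying model family is ambiguous, the defaults of
every tunable parameter, and what the synthetic study conditions do and
do not establish.

## 1. Cell-state jump process

The population is a continuous-time Markov jump process on integer
counts `n_i` over the states Q, G-Tp, G-Tr, GS-Tp, GS-Tr and, once drug
is present, the absorbing resistant states G-R, GS-R (or, in the hybrid
model, G-Tp-MGMT / GS-Tp-MGMT). Event channels and rates (coefficients
in day⁻¹, time in days):

- birth of state *i*: `c_b(i,t)·n_i` — 2 for G/GS states, 0 for Q
  (quiescent cells never divide);
- death of state *i*: `c_d(i,t)·n_i` — 1 before drug, 2.2 after, for all
  sensitive states including Q; resistant states die at
  `2.2·n_i·exp(−(t−t_drug)/d)` with decay divisor `d = 20` by default
  (10 and 100 in the sensitivity presets), reflecting progressively
  acquired resistance;
- transition *i → j*: `c_t(i,t)·n_i` for each admissible destination
  *j*. Sensitive states are fully connected bidirectionally; each G/GS
  state additionally has a one-way channel into its resistant
  counterpart after drug onset. Resistant states have no outgoing
  transitions.

Drug arrives at `t_drug = 2` d; simulations run to at most
`t_max = 20` d (the ensemble statistics below use day 6).
Initial condition: Q=80, G-Tp=G-Tr=7, GS-Tp=GS-Tr=3 (100 cells).

**Transition-rate apportionment.** The scenario tables give one
transition coefficient per state, while a state has several
destinations. Two readings are implemented: *per destination* (each
admissible channel fires at `c_t·n`; the default) and *total outflow*
(`c_t·n` split evenly over destinations). The default was selected
because it reproduces all three reported ensemble statistics of the
model family simultaneously (reductions of ≈35%, ≈60% and >90%, see §6)
and matches the statement that transition rates are proportional to the
source-state occupancy; the alternative remains available as
`ScenarioRates(apportionment="total")`.

**Rescue constraint.** Whenever a *sensitive* state holds fewer than 10
cells (strict inequality), its death rate and its channel into the
resistant states are set to zero; births and lateral transitions are
untouched. The rule is active at all times, not only after drug. It is
deliberately nonlinear; properties that require linearity (moment
equations, scale invariance) are stated and tested with the rescue
disabled.

**Instability, single-step form.** In the unstable scenario every
state's transition outflow is multiplied by an independent
Uniform(0, 1) draw at each propensity evaluation (mean 0.5). Uniform is
the minimal one-parameter-free choice for a random multiplier confined
to [0, 1].

## 2. Stochastic simulation

Trajectories are sampled with the Gillespie direct method: waiting time
Exponential(Λ) with Λ the propensity sum, event chosen with probability
rate/Λ. The decaying resistant death rate (and the per-event instability
draws) makes propensities time-dependent; they are held constant between
events (quasi-static approximation). Inter-event times at the
populations simulated are O(10⁻³ d), three orders below the 20-day decay
timescale, so the induced bias is negligible against the Monte-Carlo
noise that the acceptance statistics tolerate.

Determinism: one integer seed fixes a trajectory bit-for-bit; ensembles
derive one sub-stream per replicate from a master seed via
`numpy.random.SeedSequence`, so any replicate can be re-run in
isolation. Degenerate cases are explicit statuses: total extinction ends
a run; a frozen state (zero total propensity with cells remaining, e.g.
an all-rescued population with no active channels) advances the clock to
the horizon unchanged and is flagged; event-count overruns are flagged
as truncated. The inner event loops are numba-compiled; a pure-Python
propensity implementation is kept as the reference and the two are
cross-checked in the tests.

## 3. Multi-step lock-in ladder

Conversion to resistance requires three independent binary switches to
be simultaneously on. Each firing of a sensitive→resistant channel
performs one switch flip: with probability `p_off` (and at least one
switch on) an on-switch turns off, otherwise one off-switch turns on
(`p_on = 1 − p_off`); when the third switch turns on, one cell converts.
`p_off = 0` is forward lock-in.

**Ladder scope.** By default the ladder belongs to the *transition
pathway* (one ladder per sensitive→resistant pair): switch progress
persists through birth/death/lateral turnover of the source population
and resets after each completed conversion. The alternative — every
cell carries its own ladder, losing progress when it dies or moves —
is available as `SwitchChain(scope="per_cell")`. The pathway scope is
the default because the per-cell variant makes lock-in essentially
unreachable under the standard coefficients (per-cell exit rate ≈ 3/d
versus switch rate ≈ 0.2/d, so forward lock-in yields ≈0.5 resistant
cells at day 6), while the pathway ladder's embedded random walk gives
3, 9 and 51 expected firings per conversion at `p_off` = 0, 0.5, 0.8 —
the graded reductions the model family is built around.

The ladder in isolation is an exactly solvable 4-level Markov chain;
`SwitchChain.absorption_probability(m)` returns the probability of
lock-in within `m` firings via matrix power of the embedded chain, and
the SSA switch mechanics are tested against it at 3 standard errors.
(The unconditional absorption probability is 1 for every `p_off` < 1, so
the finite-firing-window form is the meaningful oracle.)

## 4. TMZ pharmacokinetics and MGMT

Hours time base; concentrations in model units with one 150 mg/m² dose
defining unit blood concentration. Doses are instantaneous jumps of the
blood compartment. The cascade is linear first-order:

    blood →(k_bi) interstitial →(k_ic) intracellular →(k_act) cation →(k_conv) ·
    with eliminations k_eb, k_ei, k_eic from the transit compartments;
    a fraction f_ad of converted cation forms O6mG.

The pH-dependent chemical activation of TMZ is collapsed to the fixed
constant `k_act` (constant intracellular pH). MGMT follows a two-stage
gene-expression model gated by the epigenetic state of the population
(`gate` ∈ [0, 1]):

    mRNA'    = k_tx·gate·(1 + f_fb·complex) − k_dm·mRNA
    protein' = k_tl·mRNA − k_dp·protein − k_rep·protein·O6mG
    complex' = k_rep·protein·O6mG − k_dc·complex
    O6mG'    = f_ad·k_conv·cation − k_rep·protein·O6mG

Suicide repair is the bilinear `k_rep·protein·O6mG` term: one protein is
consumed per adduct removed, and the degraded complex feeds back
positively on transcription (multiplicative `1 + f_fb·complex`; `f_fb=0`
recovers the plain two-stage model). Runs start at the closed-form
pre-dose steady state `mRNA* = k_tx·gate/k_dm`,
`protein* = k_tl·mRNA*/k_dp`.

**Defaults (assumptions of this package, not literature values):**
`k_bi=0.4, k_eb=0.3, k_ic=1.0, k_ei=0.2, k_act=0.4, k_eic=0.1,
k_conv=2.0` h⁻¹, `f_ad=0.1`; `k_tx=1.0` units/h, `k_dm=0.0866` h⁻¹
(8-h mRNA half-life), `k_tl=1.0` h⁻¹, `k_dp=0.0289` h⁻¹ (24-h protein
half-life), `k_rep=0.05` (conc·h)⁻¹, `k_dc=0.35` h⁻¹, `f_fb=0.5`.
They were chosen once to give TMZ-like kinetics (blood half-life ≈ 1 h
overall, minutes-scale cation lifetime, O6mG a ~10% minority adduct) and
slow protein turnover. Because absolute concentrations in this model are
not anchored to data, all conclusions drawn from it are *orderings and
dynamical shapes* (dose-driven oscillations, gate monotonicity,
instability orderings), never absolute levels — and the tests assert
exactly those. The stiff-capable LSODA integrator is restarted at every
dose event; outputs are clipped at zero within solver tolerance.

## 5. Hybrid coupling

Operator splitting with synchronization window `Δt = 1 h` (horizon
144 h): (1) the SSA advances cell counts for one window with death
coefficients computed from the O6mG level frozen at the window start;
(2) the ODE advances with the transcription gate fixed at the MGMT-state
fraction of all G/GS cells (Q excluded; a thresholded binary gate is
available). Cell coefficients are the multi-step model's, re-expressed
per hour; lock-in channels toward the MGMT states open with the first
dose. Inside the compiled window loop the ODE uses fixed-step RK4
(`0.02 h`); agreement with the scipy route and with the pure multi-step
model at zero dose is tested.

Death mapping: `c_d = base + gain·O6mG` per day (optionally saturating),
with `base = 1` (the pre-drug coefficient). The gain is calibrated once
per configuration so that the repair-free mean post-dose O6mG maps to
2.2/d — the drug-phase death coefficient of the pure cell-state models —
making the hybrid's drug pressure commensurate with theirs. MGMT-state
cells feel only a fraction (default 0.2) of the O6mG kill term; their
protection is otherwise double-counted, since repair already lowers the
shared O6mG field. Which states the adduct-driven death should apply to
is genuinely open; the fraction is a config field.

**Splitting-error control.** Halving Δt changes ensemble-mean terminal
MGMT protein (both instability regimes) and terminal O6mG (forward
regime) by under 5% — observed <1% at replicate counts chosen so the
Monte-Carlo standard error sits well inside the band (2000 forward /
6000 at `p_off=0.8`). Terminal O6mG at high instability is too
heavy-tailed across replicates (CV ≈ 7: most runs lock in enough MGMT
to clear adducts, a few do not) for a 5% mean comparison at any feasible
replicate count, so the control is asserted on the measurable terminals.

## 6. Ensemble statistics and oracles

The headline statistic is the percent reduction
`100·(mean_baseline − mean_treated)/mean_baseline` of the summed
resistant states (G-R + GS-R) at day 6, over 2000 independent
replicates per condition. At these study conditions the package
computes: single-step stable vs unstable ≈ 31%; multi-step forward vs
`p_off=0.5` ≈ 59%; vs `p_off=0.8` ≈ 92% — reproduced from scratch by
`scripts/acceptance.py` and asserted (with the instability-sweep
monotonicity across p_off ∈ {0, 0.2, 0.4, 0.5, 0.6, 0.8}) in
`tests/test_acceptance.py`.

Two independent oracles guard the simulator:

- **Mean-field.** For linear propensities (rescue disabled) the first
  moments obey `dE[n]/dt = A(t)·E[n]`; the control-scenario SSA ensemble
  mean of every state must match the solve_ivp solution of this system
  within 3 SE at days 1–6 (2000 replicates). In the unstable mode the
  mean-field uses `E[u] = 0.5`; this neglects the covariance between the
  random multiplier and the waiting time and is therefore only used as
  an oracle in the no-instability configuration.
- **Ladder chain.** Empirical lock-in frequencies of a frozen single
  cell against the matrix-power solve (§3).

## 7. What the synthetic conditions do and do not show

All inputs are self-generated: the scenario tables, the 100-cell
initial population and the dosing schedule *are* the study conditions,
and every reported number is conditional on them. Passing tests
establish internal correctness (exact-method sampling, moment
agreement, conservation laws, reproducibility) and the qualitative
claims (instability reduces lock-in, graded by p_off; MGMT/O6mG
orderings). They do not establish anything about real tumors: there is
no spatial structure or microenvironment, no patient PK variability, no
data-anchored concentrations, cell-state granularity is coarse (7
states), and the rescue constraint is a modeling device rather than a
biological mechanism. The reduction percentages are descriptive
ensemble statistics; no inferential claims are attached to them.

## 8. Numerical and design choices (summary)

- Direct SSA with quasi-static time-dependent rates; no tau-leaping
  (populations stay ≤ ~10⁴ at the day-6 horizon).
- Per-destination transition apportionment by default; total-outflow
  mode retained (§1).
- Pathway-scoped lock-in ladder by default; per-cell variant retained
  (§3).
- Instability multiplier Uniform(0,1), drawn per state per event.
- Rescue threshold 10, strict, all phases, sensitive states only.
- Report-time statistics by last-value interpolation of jump paths;
  day-6 report grid; reductions are grid-resolution invariant.
- Replicate seeding via SeedSequence sub-streams (reproducible,
  embarrassingly parallel); all kernel seeds < 2³¹.
- LSODA with dose-event restarts for the standalone PK/PD module; RK4
  (0.02 h) inside the compiled hybrid window loop; both start from the
  closed-form steady state.
- Mean ± SD reported per state and time; median/IQR available on the
  raw replicate matrix kept inside `EnsembleSummary`.
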