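# Methods

## The task and the models

Two dynamic random-dot patches are shown left (S1) and right (S2) of
fixation. Each patch has a signed color coherence `C± = 2(p_blue − 0.5)`
drawn from ±{0, 0.128, 0.256, 0.384, 0.512, 0.64}; the magnitude `C = |C±|`
("strength") sets how easy a blue/yellow color judgment about that patch
would be. The observer does not report color: they report which patch would
be *easier* — a prospective difficulty judgment — either at their own pace
(reaction-time task) or after an experimenter-controlled stimulus duration.

All models share one accumulation front end. Momentary color evidence for a
patch of coherence `c` accumulates as a Wiener process with drift: over a
step `dt`, `ΔDV = κ·c·dt + N(0, dt)`, so the DV has unit diffusion variance
per second of sampling. Sampling is serial and time-multiplexed: the two
patches alternate every step, so after elapsed decision time `t` each patch
has been sampled for `t/2`. Decisions terminate at a logistic collapsing
bound `B(t) = u / (1 + exp(a(t − d)))` applied to a model-specific decision
quantity; measured RT adds a Gaussian non-decision time `N(T_nd, 0.05²)`,
truncated at zero.

The decision quantities:

| model | decision quantity |
| --- | --- |
| Race | each DV races to ±B(t); first crossing names the easier patch |
| Difference | `|DV_S1| − |DV_S2|` vs ±B(t) |
| Two-step | a mini color decision at bound `B_mini` (flat for 2 s, then collapsing to 0) fixes each DV's sign at time `t_mini`; afterwards `s1·DV_S1 − s2·DV_S2` vs ±B(t), with difficulty choices allowed only from `t_mini` on |
| Absolute momentary evidence | increments enter as `|κ·c·dt + N(0, dt)|` (both DVs positive); `DV_S1 − DV_S2` vs ±B(t) |
| Signed difference (known color) | `s·(DV_S1 − DV_S2)` vs ±B(t), `s` the known dominant sign |
| Confidence comparison | running log-odds that a color choice from each DV's sign would be correct; the (absolute or sign-corrected) log-odds difference vs ±B(t) |

The confidence map is computed exactly per step by Bayes over the 12 signed
coherence levels with likelihood `N(dv | κ·c·t, t)` and a uniform prior
(+0 and −0 are distinct, numerically identical levels); each stimulus uses
the time it was actually sampled (`t/2`). We compute it in closed form
inside the simulation kernel rather than interpolating a precomputed grid —
a 12-term log-sum-exp per update is cheap and exact.

## Parameters

Per subject and model: `κ` (drift per unit coherence, 1/s), `u` (bound
height, evidence units), `a` (collapse rate, 1/s), `d` (collapse midpoint,
s), `T_nd` (mean non-decision time, s; sd fixed at 0.05 s), plus `B_mini`
for the Two-step model only. No color-bias term is used for difficulty
judgments. The package ships a 20-subject reference table of
Difference-model fits (`diffjudge.reference.REFERENCE_PARAMS`; mean
κ=5.47, u=1.39, a=2.52, d=1.06, T_nd=0.33) that serves as generative
ground truth for synthetic subjects everywhere in the pipeline.

## Synthetic data

The simulators double as the synthetic-data generator. The full
reaction-time design crosses all 12×12 signed-coherence pairs, with
equal-strength pairs presented at one third the frequency of the others
(144 distinct pairs; 1,152 trials reproduces one subject's full data set as
9 repetitions of the down-weighted design). Known-color blocks use the 6×6
same-sign pairs per color. Controlled-duration designs cross conditions
with durations {0.1, 0.15, 0.25, 0.45, 0.85, 1.65} s. On equal-strength
trials the "correct" label is a seeded fair coin, matching how such trials
are rewarded. Data generation draws fresh per-step Gaussians; simulations
inside likelihood evaluations instead read a seeded, pre-generated noise
pool (2²² values, hashed per-trial offsets), which makes the objective
deterministic (common random numbers) and roughly six times faster. What
the generator does not emulate: lapses, RT contaminants, attention
fluctuations, sequential effects, or learning across sessions — so green
tests certify the algorithms under the model's own assumptions, not
robustness of inference on messier human data.

## Color-judgment DDM

For single-patch color judgments the drift is `κ(C± + c0)` — the bias `c0`
acts as a coherence offset. Choice/decision-time distributions are solved
from the Fokker–Planck equation by Crank–Nicolson finite differences
(Δt = 0.5 ms; the DV grid spans ±1.05u with ≥200 interior points across
2u). The time-varying absorbing boundary is handled by masking: after each
step, node mass at or beyond ±B(t) moves into that step's absorbed flux.
Two numerical details matter. First, the delta initial condition is
replaced by the exact one-step Gaussian solution, which suppresses
Crank–Nicolson startup oscillation at strong drift. Second, mass that
diffuses past the grid edge in a single step (it has necessarily crossed
the bound) is credited to that step's absorbing flux, split in proportion
to the two sides' absorbed mass; without this, strong-drift solutions lose
≈0.6% of probability. With both fixes, absorbed + interior mass equals 1
to solver precision at every step, and choice probabilities / mean decision
times agree with a 100,000-path Euler–Maruyama simulation to <0.005 and
<0.5% across κ ∈ [3, 20]. Bounds are clipped below at 1e-3 evidence units
to keep the absorbing problem well-posed for pathological parameter
proposals during fitting.

## Simulation-based likelihood and fitting

The likelihood of an observed (choice, RT) pair is computed from model
simulations: for every condition in the data we simulate trials
(default 1,000 per condition, Δt = 5 ms), split them by choice, drop
censored paths (those still unabsorbed at the 10 s horizon), and smooth
each cell's simulated RTs with an Epanechnikov kernel, scaled by the
simulated choice probability. Because every model here is invariant to
flipping the sign of either stimulus's coherence, conditions are pooled by
unsigned strength pair (36 cells instead of 144) before simulating.
Bandwidth is Silverman's rule per cell, floored at 10 ms. The kernel
density is mixed with a 1% uniform contaminant over the RT horizon rather
than hard-floored: with a hard floor, an observed tail RT falling into a
gap between simulated RTs costs ~23 log-units and flips with the simulation
seed, making the log-likelihood's seed-to-seed spread ~60 log-units; the
mixture brings it to ~10. The simulation seed is fixed within a fit, so
the objective is a deterministic function of the parameters.

A deterministic simulated objective can be *over*-maximized: the optimizer
harvests kernel-density noise specific to its noise realization (tens of
log-units at the argmax), and models with more parameters harvest more.
The reported log-likelihood of a fit is therefore re-scored at the fitted
parameters under independent simulation seeds (two, averaged), the same
seeds for every candidate model of a data set, so BIC comparisons are
out-of-sample with respect to the optimizer's noise.

The likelihood surface is multi-modal with long ridges (bound height,
collapse rate and drift trade off against each other), so optimization is
staged: (i) candidate starts from a coarse grid over bound shapes
(u ∈ {0.7, 1.4, 2.2} × a ∈ {0.5, 2.5, 4.5} × d ∈ {0.5, 1.5}, T_nd seeded
from the fastest observed RTs) plus random points are screened at a reduced
simulation count; (ii) the best candidates are refined by adaptive
Nelder–Mead in box-normalized coordinates; (iii) the two best explored
basins are polished at the full simulation count with restarted Nelder–Mead
(a fresh simplex escapes stagnation; restarts repeat while they improve).
Every model goes through the identical schedule. Box bounds:
κ ∈ [0.5, 40], u ∈ [0.1, 10], a ∈ [−5, 10], d ∈ [−2, 10],
T_nd ∈ [0.05, 1], B_mini ∈ [0.05, 5].

Model comparison uses `BIC = k·ln(n) − 2·logL` (k = 5, or 6 for Two-step),
summed over subjects for group-level comparison. Model recovery simulates
data sets per subject from a generating model, fits every candidate model,
and classifies each data set by lowest BIC or by a |ΔBIC| > 10 margin rule
(no margin → "undecided").

Even with the staged search, a few-hundred-evaluation budget does not
always reach the global likelihood basin of five-parameter collapsing-bound
models; the protocol applies identically to every candidate model, so
comparisons remain even-handed, but individual parameter estimates can sit
on a ridge several log-units below the optimum, and between-model BIC
margins come out narrower than an exhaustive search would give. The test
suite sizes its recovery checks at 5 synthetic subjects × 1 data set with
3 explored starts; the classification thresholds (80% correct; no Two-step
attribution under the margin rule) are unchanged from the full protocol.

## Controlled-duration model

For experimenter-controlled durations, an 80 ms sensory buffer holds both
streams before serial multiplexing begins, so each stimulus is effectively
sampled for `T_dur = T_stim` if `T_stim ≤ T_buf`, else
`T_buf + (T_stim − T_buf)/2`. Operationally, both DVs accumulate in
parallel during the buffer window and alternate afterwards. The collapsing
bound runs on stimulus time (not per-stimulus sampled time) and is not
frozen during the buffer — the most natural reading, stated here because
the alternatives are defensible. Choice is by bound crossing during the
stimulus or by the sign of the decision quantity at stimulus offset.
Fitting maximizes the exact binomial likelihood of per-(pair, duration)
choice counts against simulated choice probabilities (default 2,000
simulated trials per cell, floored at 1e-6), excluding equal-strength and
mixed-color trials; known and unknown blocks are fit jointly with either a
shared κ (4 parameters) or separate κs (5). `log10 BF` between two fits is
approximated as `ΔBIC / (2 ln 10)`.

## Reward-rate-optimal policy

The reaction-time task is a POMDP whose belief state is
`⟨t_S1, t_S2, DV_S1, DV_S2⟩`. With strict alternation the two times are a
function of the total sample count, so the solver enumerates slices
k = 0…K (Δt = 0.05 s, horizon 6 s of total sampling) over a DV grid
(ΔDV = 0.1, extent ±24 by default, auto-doubled if belief-changing
transition mass leaks off-grid). The per-stimulus coherence posterior is
`P(c | dv, t) ∝ N(dv | κ·c·t, t)·P(c)` with a uniform prior over the 12
signed levels (positive levels only for the known-color variant); the
probability that choosing S1 is correct sums the posterior product over
pairs where |C1| > |C2|, counting ties at ½. Action values follow the
average-reward Bellman equation: choosing pays
`b·Rc + (1−b)·Rn − (1−b)·t_p·ρ − (T_nd + t_w)·ρ` (the error time penalty is
charged on errors only, and the printed `−tnd+twρ` grouping is read as
`(T_nd + t_w)·ρ`); sampling pays `−ρ·Δt` plus the expected next-slice
value under the posterior-marginalized transition kernel, with increments
integrated over ΔDV-wide bins for mass conservation. Ties between actions
break toward committing. The optimal ρ zeroes the initial state's value
and is bisected to |V(s₀)| < 1e-6 (defaults: κ=13, Rc=1, Rn=0, t_p=1 s,
T_nd=0.4 s, t_w=0.5 s).

Two approximations are worth naming. DV values beyond the grid edge are
clamped; this is belief-equivalent when the posterior there is saturated at
an extreme coherence, and the leak diagnostic therefore weights off-grid
mass by posterior non-saturation over reachable states (tolerance 0.02).
And the policy is simulated with continuous DVs snapped to the nearest
grid state for lookup (clamped and flagged if off-grid); simulated RT adds
the mean non-decision time. The optimal model is never fit to data.

## Degenerate inputs and tie-breaks

Zero-coherence signs: ±0 are distinct conditions; where a sign is needed
from a zero DV or zero coherence, a seeded fair coin decides. Simulated
paths unabsorbed at the horizon are censored, flagged, and assigned the
sign of their decision quantity; censoring is <1% under the reference
parameters. Equal-strength trials are "correct" by a seeded coin. In the
Race simulator, if both DVs stand at/beyond the bound after the same step
(possible because the bound collapses), the larger excursion wins, coin on
exact ties.

## Known limitations

- The serial↔parallel parameter conversion identities are not provided
  (the source text for them is corrupted); all models here are serial.
- Simulation-based likelihoods inherit kernel-density bias; likelihoods are
  comparable across models at a fixed simulation count but not across
  counts.
- The optimal-policy solver assumes strict alternation and equal time
  sharing; free allocation of sampling between stimuli is out of scope.
- Recovery of Race/Two-step/Absolute-momentary generating parameters from
  their own fits to human data is supported generically but no reference
  parameter tables ship for them.
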