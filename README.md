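# diffjudge

Sequential-sampling models of **prospective difficulty judgments**: given
two noisy perceptual decisions one *could* make, how do people decide which
one would be easier — before, and without, making either?

The package targets the two-patch random-dot color paradigm. Each patch has
a signed color coherence `C± = 2(p_blue − 0.5)` with strength
`C = |C±| ∈ {0, 0.128, …, 0.64}`; observers report which patch would be
easier to classify as blue- or yellow-dominant, either at their own pace
(reaction-time task) or at an experimenter-controlled viewing duration. It
is written for computational cognitive scientists who want to simulate,
fit, and compare mechanistic accounts of such judgments.

## What's inside

Every model accumulates momentary color evidence for each patch into a
decision variable (`ΔDV = κ·C±·dt + N(0, dt)`; serial, time-multiplexed
sampling, so each patch gets half of elapsed time) and terminates at a
logistic collapsing bound `B(t) = u/(1 + e^{a(t−d)})`:

- **Race** — first color decision to hit its bound names the easier patch;
- **Difference** — bounds `|DV_S1| − |DV_S2|`;
- **Two-step** — a mini color decision fixes each DV's sign, then the
  sign-weighted difference is bounded;
- **Absolute momentary evidence** — accumulates `|momentary evidence|`;
- **Confidence comparison** — bounds the difference in the log-odds that
  each color choice would be correct;
- **Signed difference** — the known-color variant, plus a buffer-limited
  controlled-duration model (80 ms parallel buffer, then multiplexing);
- a **reward-rate-optimal policy** for the same task, solved as a
  belief-state MDP by backward induction with reward rate found by
  root-finding.

Fitting is by simulation-based maximum likelihood (Epanechnikov-smoothed
choice-conditional RT densities; exact binomial likelihood for
controlled-duration choices), with BIC model comparison, group-level BIC
sums, and generate–fit–classify model recovery. Estimators follow
scikit-learn conventions (`DifficultyModel(...).fit(trials)` with fitted
`params_`, `loglik_`, `bic_` attributes). A 20-subject reference parameter
table ships as generative ground truth for synthetic subjects.

## Worked example

```python
from diffjudge import Condition, MEAN_PARAMS, make_design, simulate_difference
from diffjudge.fitting import DifficultyModel

# the RT signature in three extreme cells
cells = [Condition("difficulty_rt_unknown", a, b)
         for a, b in [(0.0, 0.0), (0.64, 0.64), (0.64, 0.0)]]
demo = simulate_difference(MEAN_PARAMS, cells, n=2000, seed=7)
for a, b in [(0.0, 0.0), (0.64, 0.64), (0.64, 0.0)]:
    cell = demo[(demo.c1_signed == a) & (demo.c2_signed == b)]
    print(f"RT({a}:{b}) = {cell.rt.mean():.2f} s")

# one synthetic subject: full 12x12 design, equal-strength pairs at 1/3 rate
design = make_design("difficulty_rt_unknown", reps=9,
                     equal_strength_frequency=1/3)   # 1,152 trials
trials = simulate_difference(MEAN_PARAMS, design, n=1, seed=7)
fit = DifficultyModel(model="difference", n_starts=2, max_evals=100,
                      random_state=0).fit(trials)
print(f"kappa = {fit.params_.kappa:.2f}, BIC = {fit.bic_:.1f}")
```

```
RT(0.0:0.0) = 1.45 s
RT(0.64:0.64) = 1.22 s
RT(0.64:0.0) = 1.08 s
kappa = 6.32, BIC = 1716.9
```

The printed RTs show the signature criss-cross: the hard–hard comparison is
slowest, the easy–easy comparison is slower than easy–hard (it is the
*difference* in accumulated evidence that must reach the bound, not the
evidence itself), and the fitted drift coefficient recovers the generating
κ = 5.47 to within sampling error.

The command line mirrors the library:

```bash
diffjudge simulate --model difference --params params.json \
    --design design.yaml --n 1 --seed 7 --out trials.csv
diffjudge fit --model difference --trials trials.csv --out fit.json
diffjudge recover --gen-model difference --scale 0.2 --seed 1 --out rec.json
diffjudge optimal solve --out policy.npz
diffjudge exp1 --scale 0.05   # simulate -> fit 4 models -> compare BICs
```

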