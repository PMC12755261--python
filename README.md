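# cascade-chronos

Timing precision of bursty gene-activation cascades: simulation,
small-noise theory, and activation-threshold design.

Many cellular events are scheduled by a molecular timer: a gene is switched
on, its protein accumulates, and the event fires when the concentration
first crosses a threshold. Flagellar assembly, phage lysis, cyclin-driven
cell-cycle transitions and MAP-kinase signaling all chain several such
steps into a *cascade* — gene *i* activates gene *i+1* once its product
x_i reaches the threshold X_i, and the quantity of interest is the total
first-passage time (FPT) until the last product x_N crosses X_N.

`cascade-chronos` implements a burst–dilution hybrid stochastic model of
this process and answers the design questions it raises. Each protein is a
continuous concentration produced in random bursts (a compound Poisson
process at rate k_i, burst sizes b_i with moments ⟨b_i⟩, ⟨b_i²⟩) and
diluted exponentially at the shared cell-growth rate γ; downstream
activation is a step function of the upstream level. The package provides:

- **an exact event-driven simulator** of the piecewise-deterministic
  process (decay between bursts is analytic, so there is no time step),
  with per-stage and total FPT ensembles, full trajectory logs, and a
  coupled global-clock mode used to cross-validate the stage decomposition;
- **moment dynamics**: closed-form transient mean and variance
  ⟨x⟩(t) = x̄(1−e^{−γt}), σ²(t) = (⟨b²⟩/2⟨b⟩) x̄ (1−e^{−2γt}) with
  x̄ = k⟨b⟩/γ, plus a numerical integrator for verification;
- **small-noise FPT theory**: with relative thresholds α_i = X_i/x̄_i and
  intrinsic noise CV_i² = ⟨b_i²⟩/(2⟨b_i⟩x̄_i),

      γ⟨T⟩  = Σ_i ln 1/(1−α_i)
      CV_T² = (γ⟨T⟩)^{-2} Σ_i CV_i² α_i(2−α_i)/(1−α_i)²

- **threshold optimization** at fixed mean FPT: closed-form optima
  α_n* = 1 − e^{−γ⟨T⟩/N}·CV_n/GM(CV), the three two-gene regimes (use
  gene 1 only / couple both / use gene 2 only, set by whether CV₂/CV₁
  lies inside (e^{−γ⟨T⟩}, e^{γ⟨T⟩})), an inclusion criterion telling
  whether adding a gene can improve precision, and the identical-gene
  results: the optimal relative time solves (1−x)e^{2x} = 1 (x* ≈ 0.797
  per stage) and the noise floor is ≈ 6.18·CV₁²/N.

## Worked example

Design a three-gene cascade with intrinsic noises
CV² = (0.0045, 0.018, 0.001125) — the levels produced by geometric bursts
of mean 4, 17.5 and 0.625 at steady state 1000 — for a mean FPT of 40 min
at γ = 0.05 min⁻¹ (γ⟨T⟩ = 2):

```python
import json
import cascade_chronos as cc

res = cc.optimal_thresholds_general([0.0045, 0.018, 0.001125], gammaT=2.0)
print(json.dumps(res.to_dict(), indent=2))
```

```json
{
  "regime": "some_excluded",
  "alphas_opt": [0.47973990497711105, 0.0, 0.7398699524885555],
  "cv2_T_opt": 0.006906438111296981,
  "gammaT": 2.0,
  "excluded_genes": [1]
}
```

The middle gene is too noisy relative to the geometric mean of the set
(its optimal threshold would be negative), so it is excluded; the
remaining pair splits the 40 minutes with the quieter gene holding the
higher threshold, and the best achievable timing noise is
CV_T² ≈ 0.0069 — a standard deviation of about 8% of the mean.

Simulation confirms the theory. One gene with threshold at
α = 1−e^{−2} of steady state (mean FPT 40 min):

```python
spec = cc.CascadeSpec(
    genes=(cc.GeneSpec.from_steady_state(
        1000, cc.BurstModel("geometric", 4), 0.05,
        relative_threshold=1 - 2.718281828**-2),),
    dilution_rate=0.05)
print(cc.sample_fpt_ensemble(spec, 100_000, seed=1).summary)
```

```
{'n': 100000, 'seed': 1, 'mean_T': 38.64, 'var_T': 68.65,
 'cv2_T': 0.0460, 'sem_cv2': 0.00025}
```

against a small-noise prediction of CV_T² = 0.060 (the approximation
overestimates noise for thresholds this close to steady state). Five
identical stages at the same 40-minute total mean push the simulated
noise down to ≈ 0.0068, the 1/N suppression that makes long cascades
good clocks.

The same operations are available from a shell:

```bash
cascade-chronos simulate --config cascade.yaml --replicates 100000 --seed 1 --out out/
cascade-chronos optimize --config cascade.yaml --mean-fpt 40
cascade-chronos design --cvs 0.06,0.05,0.2 --gammat 1.5
cascade-chronos reproduce --experiment fig5 --seed 1 --out out/fig5
```

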