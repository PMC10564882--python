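# rhibayes

Bayesian hierarchical ordered-probit analysis of rubber-hand-illusion (RHI)
ownership ratings, for researchers studying the link between body ownership
and interoception. The package answers one question: **how much of the
between-person variation in illusion susceptibility is explained by cardiac
interoceptive accuracy (CIA)?**

## The model

Participants rate the ownership statement ("it seemed like the fake hand
was my hand") once after synchronous and once after asynchronous stroking,
on a K-point Likert item. The rating is modeled as an ordered-probit
response: a latent normal ownership intensity

```
IHO*ᵢ = (β₁ + rᵢ)·cond + β₂·CIAᵢ + β₃·cond·CIAᵢ + e,   rᵢ ~ N(0, σᵣ²),  e ~ N(0, 1)
```

is cut into K categories by K−1 free ordered cutpoints (`cond`: 0 =
asynchronous, 1 = synchronous; there is no intercept — location lives in
the cutpoints). Participant *i*'s **illusion susceptibility** is
β₁ + β₃·CIAᵢ + rᵢ, so β₃ is the slope of susceptibility on CIA. CIA is
scored from the heartbeat tracking task as the mean over three trials of
1 − |HB_rec − HB_rep|/HB_rec.

Inference is by MCMC (built-in self-contained adaptive sampler; 4 chains ×
4000 iterations, warmup 2000, R̂ ≤ 1.1 gate) under weakly informative
priors — Normal(0, 2.5) coefficients, half-Cauchy(0, 2.5) on σᵣ. Reported
quantities: posterior medians with 95% credible intervals for β₁, β₂, β₃,
σᵣ; per-participant susceptibility intervals classified by whether they
include 0; the Cohen-d-like **standardized β₃** (= β₃/σᵣ per draw); and the
**Bayesian R²** = Var(β₃·CIAᵢ)/(Var(β₃·CIAᵢ) + σᵣ²) per draw, summarized
with a 95% HPDI. See `docs/methods.md` for derivations and numerical
details.

## Worked example

```python
import rhibayes as rb

# a synthetic study drawn from the model itself: 50 participants,
# weak average induction effect, large between-person spread
data, truth = rb.simulate_dataset(rb.GeneratorConfig(n_participants=50, seed=11))

draws = rb.sample_posterior(data, config=rb.McmcConfig(seed=3))
report = rb.make_report(draws, data)
print(report.parameters.round(2).to_string(index=False))
n_incl, n_excl, n = report.counts
print(f"{n_incl}/{n} susceptibility intervals include 0")
```

prints

```
parameter  median  lower  upper interval_type
    beta1    0.32  -1.72   2.41  equal_tailed
  sigma_r    2.73   1.68   3.96  equal_tailed
    beta2    0.33  -1.03   1.86  equal_tailed
    beta3    0.53  -2.49   3.96  equal_tailed
31/50 susceptibility intervals include 0
```

At this sample size the condition effect (β₁) and its modulation by CIA
(β₃) are both highly uncertain — the 95% interval for β₃ spans roughly
−2.5 to +4 latent-SD units around a small median, so the data cannot
distinguish "CIA strongly dampens the illusion" from "no modulation at
all"; most individual susceptibility intervals straddle 0. That is exactly the high-uncertainty
regime the generator's defaults emulate. The same pipeline runs on real
data via the CSV readers (`read_ratings`, `read_heartbeat_trials`,
`assemble_dataset`) or the CLI:

```sh
rhibayes simulate --n 50 --seed 11            # writes ratings.csv + cia.csv (categories 1..7)
rhibayes fit ratings.csv cia.csv draws.csv --scale-min 1 --scale-max 7 --seed 3
rhibayes summarize draws.csv ratings.csv cia.csv results/ --scale-min 1 --scale-max 7 --plot
```

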