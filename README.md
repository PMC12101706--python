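# coxprior

Data-driven Normal priors for Bayesian Cox regression, and a sequential
Bayes-factor engine that uses them.

Biomedical time-to-event studies are routinely analyzed with two-arm Cox
proportional-hazards regression, λ(t|x) = λ₀(t)·exp(xβ), where HR = e^β is
the hazard ratio between arms. Testing H₀: β = 0 against H₁: β ~ f(φ) with a
Bayes factor

    BF₁₀ = ∫ L(β) f(β) dβ / L(0)

lets researchers quantify evidence *for* either hypothesis and monitor
results as patients accrue, stopping when BF₁₀ exits a decision interval
such as (1/20, 20). The catch is the prior f on the log hazard ratio.
`coxprior` builds that prior from the published record: it mines hazard
ratios and their confidence intervals from abstract corpora, screens them,
converts each to a log-HR and standard error, and pools them — sign-
symmetrized, so the prior is centered at 0 — into a per-subfield Normal
prior

    μ_p = 0,    σ_p = sqrt( ((n−1) Σ SE_i² + n Σ b_i²) / (N n − 1) ),

with an assumed common per-study size n = 200. The package ships pooled
summaries for nine biomedical subfields (anesthesiology/pain through
pulmonary medicine); their prior scales all fall between 0.915 and 1.079,
so N(0, 1) is a sensible compromise default. The Bayes factor itself uses
the Cox partial likelihood (Efron ties) and adaptive quadrature in log
space; one-sided hypotheses truncate the prior at 0.

For whom: biostatisticians and trialists who want an informed default prior
for a Bayesian Cox analysis, and anyone who wants the full pipeline —
mining, screening, pooling, sensitivity analysis, sequential monitoring —
reproducible end to end on synthetic data.

## Worked example

Pool the bundled immunology-and-allergy corpus summary into a prior, then
monitor a simulated trial (true log-HR 0.7, 500 patients per arm,
exponential event and censoring times) with one-sided positive evidence and
thresholds (1/20, 20):

```python
from coxprior import default_prior, gen_survival, TrialConfig, sequential_bf

prior = default_prior("immunology and allergy")
print(f"prior: N(mu={prior.mu:.0f}, sigma={prior.sigma:.3f})")

trial = gen_survival(TrialConfig(n_per_arm=500, true_beta=0.7, seed=7))
traj = sequential_bf(trial, prior, side="positive",
                     thresholds=(1/20, 20), step=10)
for k, bf in traj.steps:
    print(f"n={k:4d}  BF10={bf:8.3f}")
print("decision:", traj.decision)
```

which prints

```
prior: N(mu=0, sigma=1.023)
n=  10  BF10=   0.499
n=  20  BF10=   0.797
n=  30  BF10=   0.992
n=  40  BF10=   1.908
n=  50  BF10=   1.444
n=  60  BF10=   2.788
n=  70  BF10=   3.921
n=  80  BF10=  12.327
n=  90  BF10=  97.429
decision: accept_h1
```

The prior scale 1.023 is the pooled σ_p of the immunology corpus (N = 833
screened studies). The Bayes factor hovers near 1 while evidence is thin,
then climbs as events accrue and crosses the upper threshold of 20 at the
ninth interim look — the trial stops after 90 of the 1,000 available
patients, with the data ~97 times more likely under H₁ than under H₀.

The same machinery is scriptable from the shell:

```bash
coxprior simulate trial --seed 7 --out trial.csv
coxprior mine --articles articles.csv --journals journals.csv --out effects.csv
coxprior pool --effects effects.csv --n 200 --out priors.txt
coxprior pool --effects effects.csv --subfield "synthetic oncology" --out prior.txt
coxprior monitor --data trial.csv --prior prior.txt --out trajectory.csv
```

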