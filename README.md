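# seqbf

Sequential Bayes-factor analysis of binary-outcome cohorts, built for the
statistical pipeline of a large multi-lab "retroactive avoidance"
replication study — and for anyone who needs a numerically robust one-sided
Bayesian one-sample t-test evaluated sequentially over thousands of
participants, with Monte-Carlo calibration of how its evidence trajectory
fluctuates over time.

## The problem

In the underlying experimental design each participant completes 60 binary
trials; a trial shows a negative or a neutral masked picture depending on
the XOR of two random bits (one pre-stored, one generated live after the
response).  Under the null hypothesis the per-participant count of negative
pictures is Binomial(60, ½) with chance level 30; the directional
alternative — unconscious *avoidance* of negative pictures — predicts
counts below 30.  Evidence is accumulated with a sequential Bayesian
one-sample t-test: after each participant the Bayes factor

```
BF10 = m1(t) / m0(t),     m0: central-t density (df = n − 1),
m1(t) = ∫ f_nct(t; df, δ√n) π(δ) dδ,   π: Cauchy(0, r) truncated to δ < 0, doubled
```

is recomputed on the cumulative sample (prior scale r = 0.1; data collection
would stop at BF ≥ 10 or ≤ 1/10).  Beyond the final Bayes factor the package
computes three *temporal-anomaly* statistics of the resulting evidence curve
— its maximum, its "energy" Σ(BFₙ − 1), and the sum of its one-sided FFT
amplitudes — and calibrates them against simulated null cohorts, plus
per-lab Bayes factors and a DerSimonian–Laird random-effects meta-analysis
across labs.

A note on numerics: the noncentral-t density is evaluated by an in-package
log-space routine (Laplace-recentred Gauss–Legendre quadrature of the
chi-mixture integral) because library implementations overflow at the large
degrees of freedom (df > 1000) this analysis requires.  Bulk evaluation for
simulations runs through an interpolated log-BF surface over (t, n),
accurate to ~1e-5 relative and validated against the exact quadrature.

## Worked example

The headline numbers of the replication analysis, recomputed from the
published summary statistics (N = 2004, M = 29.97, SD = 3.92, chance 30):

```python
>>> import math
>>> from seqbf import bf10
>>> t = (29.97 - 30) / (3.92 / math.sqrt(2004))   # -0.3426
>>> bf10(t, 2004, prior_scale=0.1, direction="less")
0.22613597269307908
>>> 1 / _
4.4221181976971025
```

BF10 ≈ 0.23 (BF01 ≈ 4.4): the data favour the null about four-fold — the
avoidance effect did not replicate.  The per-lab picture and its
random-effects pooling:

```python
>>> from seqbf.meta import LabMeta
>>> from seqbf.datasets import five_lab_summaries
>>> print(LabMeta(five_lab_summaries()).fit().summary())
Random-effects meta-analysis (DerSimonian-Laird)
==================================================
lab            n    mean     sd        d     BF10
Germany     1413   30.00   3.88   0.0000    0.200
Italy        235   30.12   4.10  -0.0293    0.311
Russia       154   29.49   3.83   0.1332    1.965
France       103   29.52   4.27   0.1124    1.179
Sweden        99   30.20   3.80  -0.0526    0.401
--------------------------------------------------
pooled ES 0.0123 (SE 0.0253)
tau^2 0.000293  I^2 6.55%  Q(4) = 4.280, p = 0.369
```

No lab reaches strong evidence in either direction and the labs are
statistically homogeneous (Q(4) ≈ 4.3, p ≈ .37).  A full synthetic run —
cohort generation, sequential curve, robustness sweep, meta-analysis and a
null-calibrated anomaly report — from the shell:

```
seqbf simulate --seed 42 --out cohort.csv                 # five-lab null cohort, N = 2004
seqbf run-all --input cohort.csv --outdir out --seed 7 --n-sims 1000
```

or in Python via the model objects:

```python
from seqbf import SequentialBF
res = SequentialBF.from_csv("cohort.csv").fit()
res.bf10, res.bf01            # final evidence
res.stopping(threshold=10)    # optional-stopping status
res.robustness()              # BF10 under r = 0.1, 0.707, 1.0, 1.414
res.anomaly()                 # max BF, curve energy, FFT amplitude sum
```

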