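# qeeg

Non-extensive (Tsallis) q-statistics complexity analysis of EEG-like
signals.

## The problem

Commonly used complexity measures for neural signals (sample entropy,
Lempel–Ziv, Lyapunov exponents) rest on Shannon/Boltzmann–Gibbs
entropy, which assumes statistically independent components. Brain
dynamics are long-range correlated — *non-extensive* — and Tsallis'
generalization of statistical mechanics indexes exactly that property
with a single scalar, the entropic index **q**. `qeeg` implements the
EEG-oriented estimation pipeline for q:

1. **Events** — in each channel, find negative amplitude events
   exceeding 1 SD below the mean of the signal's negative part
   (maximal sub-threshold runs, stamped at the downward crossing).
2. **Intervals** — collect the inter-event intervals (ms), pooled
   across channels.
3. **Distribution** — bin them into an empirical probability
   distribution (default 500 equal classes on 0–1000 ms).
4. **Fit** — fit the q-exponential density by bounded multi-start
   least squares,

       f(x) = a x^c (1 + (q−1) b x^h)^(−1/(q−1)),

   with the normalization `a` slaved analytically to `(b, c, h, q)`
   through an incomplete-beta closed form, against the
   Boltzmann–Gibbs null `f_BG(x) = a x^c exp(−b x^h)` (the q → 1
   limit, expected for purely chaotic dynamics).

`q > 1` quantifies non-extensive complexity; `q → 1` indicates
BG-like (uncorrelated) dynamics. Tsallis entropies
(`S_q = k/(q−1)(1 − Σ p_i^q)`, `S_BG = −k Σ p ln p`), a logistic-map
chaos generator, an exact q-exponential interval sampler and an
EEG-like surrogate-signal generator with planted ground truth are
included. Intended users: computational-neuroscience and biosignal
researchers studying complexity measures.

## Worked example

Recover the published worked-example parameters from the distribution
they imply (a noiseless round trip):

```python
from qeeg import (QExpParams, IntervalDistribution, HistogramSpec,
                  FitConfig, fit_qexp)

truth = QExpParams(b=0.14, c=2.24, h=1.07, q=1.22)
dist = IntervalDistribution.from_model(truth, HistogramSpec(n_bins=500))
print(fit_qexp(dist, FitConfig(seed=0)).summary())
```

```
q-exponential interval model
==============================================
 parameter     estimate      std err
----------------------------------------------
         b         0.14     4.12e-16
         c         2.24      1.4e-15
         h         1.07     5.28e-16
         q         1.22     1.98e-16
a (analytic)  0.000193026
----------------------------------------------
SSE 2.67109e-33    R^2 1    bins 500    converged True
```

The fit returns exactly the four parameters that generated the
distribution (SSE at machine precision; the tiny standard errors
reflect the noiseless input).

End-to-end on a surrogate signal with a planted interval law —
synthesize, detect events, bin, fit:

```python
from qeeg import (SurrogateSpec, synthesize_signal, RunConfig,
                  run_pipeline)

spec = SurrogateSpec(interval_params=truth, n_events=10_000,
                     noise_sd=0.5, seed=42)
report = run_pipeline(RunConfig(inputs=("surrogate",), seed=42),
                      signal=synthesize_signal(spec))
print(report.pooled_q)
```

prints `1.223` (planted q = 1.22; 9999 events detected, 113 intervals
beyond the 1000-ms window discarded; the q-exponential is preferred
over the BG null). At 10^4 intervals the estimator's sampling sd is
≈ 0.05 — see `docs/methods.md` for what single-run recovery can and
cannot promise.

The same pipeline from the shell:

```bash
qeeg simulate --out surr.csv --q 1.22 --n-events 10000 --seed 42
qeeg fit surr.csv --out report.json
qeeg events surr.csv --out events.json
qeeg entropy dist.tsv --q 1.5
```

`qeeg fit` accepts delimited text (with a JSON sidecar or `--fs` for
the sampling rate) or EDF, and writes a JSON report embedding the full
configuration, seed and software version.

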