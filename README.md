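# clonedyn

Clonal dynamics of DNA-barcoded tumors under immune checkpoint blockade
(ICB).

When every cell of a transplanted tumor carries a heritable DNA barcode,
the barcode frequencies in the harvested tumor record the fate of each
founder clone. Experiments of this design ask a sharp question: does a
tumor with a *fixed* genetic background respond to anti-PD-1 / anti-CTLA-4
stereotypically, or does the host decide? Answering it requires machinery
that this package provides as a tested Python library:

- **`simulate`** — a generative model of the whole experiment: barcode
  library, engraftment bottleneck, latent clone growth-pattern clusters
  with treatment-specific selection, per-mouse host effects shared by two
  flank tumors, multinomial sequencing; plus a matched expression-matrix
  generator.
- **`barcodes`** — ClonTracer-style (WS)^15 barcode extraction from FASTQ,
  greedy Hamming-distance error collapse, count-to-frequency conversion.
- **`stats`** — clonality (1 − normalized Shannon entropy), barcode
  distribution correlations, within- vs between-mouse host-effect tests,
  per-barcode ANOVA enrichment screens with Benjamini-Hochberg correction,
  tumor-size variance F tests, hierarchical sample clustering.
- **`response`** — responder / non-responder calls from end-of-treatment
  size versus the control cohort (thresholds `10^(M−0.5)`, `10^(M−0.1)`
  around the log10 median control size M) and a fold-change alternative.
- **`dynamics`** — the core model: clone fitness advantage
  `x_k = [ln(f_end/(1−f_end)) + ln(1/f_start)] / ((b_p−d_p) t)` from the
  exponential-selection forward model, and a **grouped finite mixture of
  Gaussian linear regressions** on log barcode frequency (covariates:
  treatment indicators, log tumor size) in which all observations of one
  barcode share a latent component — fitted by EM with restarts and
  BIC-based selection of the component count.
- **`signatures`** — cancer-cell-intrinsic resistance signature scoring:
  per-gene mean-centering, Pearson correlation of a tumor's expression
  with a log2 fold-change reference signature, GZMA/PRF1 cytolytic
  activity, group association, robustness grids.

There is no command-line interface; the importable API is the product, and
`examples/` holds one short narrative script per capability.

## Worked example

```python
import clonedyn as cd

sim   = cd.simulate_experiment(seed=1)                       # 70 tumors, 3 arms
freqs = cd.counts_to_frequencies(sim.counts, min_reads=10)
obs   = cd.build_observations(freqs, sim.meta)               # y = ln f + covariates
fit   = cd.fit_mixture(obs, K=6, n_restarts=10, seed=11)
print(fit.loglik, fit.bic, fit.converged)
```

Running `examples/05_fit_growth_patterns.py` (which continues this
pipeline) prints:

```
fitness advantage x under anti-PD-1: estimated for 1950 clones, correlation with generating truth r=0.67

K=6 grouped mixture: loglik=-30914, BIC=62180, converged=True
assignment purity vs generating clusters: 85%
component ICB enrichment (treated / control cumulative frequency):
cluster
3    0.13
1    0.21
6    0.33
5    0.58
2    1.41
4    5.38

cumulative frequency of the two most ICB-resistant components:
  responder: 0.852
  non_responder: 0.315
```

Reading: clone-level fitness estimates track the generating truth
(r = 0.67 — the estimates pool over hosts whose immune pressure varies,
so per-clone values are noisy while the ranking is preserved); the six
mixture components span strongly ICB-depleted
(enrichment 0.13) to strongly ICB-enriched (5.38) clones; and the
ICB-resistant components make up 85% of responder tumors but only 32% of
non-responders — responders are the tumors whose hosts eliminated the
sensitive clones, leaving the pre-existing resistant minority enriched.
That inversion (resistance signatures *high* in on-treatment responders)
is the package's central, clinically relevant observation, echoed on the
expression side by `examples/06_signature_scoring.py`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch (~10 min): **t1** — the modal number of
growth-pattern clusters selected by BIC over K = 2..10 (10 restarts)
across five default-configuration simulated experiments; **t2** — the mean
percentage of library barcodes absent from an engrafted tumor across ten
simulated tumors (2,000 barcodes, 250,000 transplanted cells, engraftment
probability 0.0013). Results are written as JSON keyed by target id.

See `docs/methods.md` for the model, its assumptions, the simulator's
stated world, and known limitations.
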