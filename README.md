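# switchscope

Single-cell analysis of stochastic **white–opaque switching** in *Candida
albicans*.  White and opaque are two heritable transcriptional states whose
interconversion is rare, stochastic, and governed by the master regulator
**Wor1** (~40-fold higher in opaque cells, positively autoregulating its own
control region).  `switchscope` implements the quantitative pipeline used to
establish that switching requires **two stochastic events** — a heritable
predisposition followed by activation — and that Wor1 autoregulation is
**ultrasensitive**:

- **Imaging** — registration of 24 h / 12-min-cadence microfluidic trap
  movies (translation by phase cross-correlation), morphological cell
  segmentation (top-hat + bottom-hat borders, property-based selection),
  the top-300-pixel Wor1-GFP metric, and cell-length morphometrics.
- **Lineage** — dotted-name pedigrees (`"2.1"` is the first daughter of
  `"2"`), LOESS trace smoothing, switch calling with a geometric-mean
  threshold, and grouping of synchronously activating mother–daughter
  pairs into direct, four-cell, and mixed-fate patterns.
- **Event statistics** — per-trap event counts under three dependence
  schemes, the Poisson zero-class null λ = −ln(n₀/N), and χ² goodness of
  fit with Monte-Carlo p-values (2,000 multinomial replicates).
- **Flow fitting** — two-gate event filtering, forward-scatter
  normalization, and robust 4-parameter log-logistic (Hill) fits of the
  Wor1 transcriptional response,

      log10(reporter) = c + (d − c) / (1 + exp(−h·(ln x − log K))),

  with replicate aggregation and half-max-ratio comparison between the
  monomeric (Wor1-mGFP) and dimerizing (Wor1-GFP) fusions.
- **Synthetic data** — a ground-truthed generator for trap movies,
  pedigrees, and flow plates that reproduces the study's statistical
  structure (two-step switching, 3 h reporter rise, birth-to-max
  9.9 ± 3.2 h, 134/168 zero-event traps, Hill coefficients 3.2 / 4.3 with
  a 5-fold half-max ratio), so the whole pipeline is testable end to end
  without any downloads.

## Worked example

```python
import switchscope as ss
from switchscope.pipeline import classify_pedigrees, run_event_statistics

# Hill quantification of Wor1 autoregulation from one synthetic plate
fcfg = ss.FlowModelConfig()
plate = ss.simulate_strain_day("Wor1-mGFP", fcfg, seed=42)
gated, report = ss.gate_events(plate.events)
norm, _ = ss.normalize_events(gated)
fit = ss.fit_hill(norm.gfp_n.to_numpy(), norm.mcherry_n.to_numpy())
print(f"events kept by gating: {report.n_out}/{report.n_in}")
print(f"Hill coefficient h = {fit.h:.2f}, half-max K = {fit.K:.3g} "
      f"(normalized GFP units), asymptotes c = {fit.c:.2f}, d = {fit.d:.2f}")

# switching-event statistics for a 168-trap experiment
rc = ss.RunConfig(seed=11)
peds, truth = ss.simulate_pedigrees(rc.switch, seed=rc.stage_seed("simulate"))
calls, groups = classify_pedigrees(peds, rc)
stats = run_event_statistics(groups, rc)
s3, s2 = stats["schemes"]["3"], stats["schemes"]["2"]
print(f"zero-event traps: {s3['n_zero']}/168, lambda = {s3['lambda']:.3f}")
print(f"scheme 3: chi2 = {s3['chi2']:.2f}, p = {s3['p']:.3f}")
print(f"scheme 2: chi2 = {s2['chi2']:.2f}, p = {s2['p']:.4f}")
```

prints

```
events kept by gating: 42690/50000
Hill coefficient h = 3.19, half-max K = 0.0015 (normalized GFP units), asymptotes c = -3.00, d = -1.00
zero-event traps: 142/168, lambda = 0.168
scheme 3: chi2 = 2.31, p = 0.402
scheme 2: chi2 = 203.17, p = 0.0050
```

Reading the output: gating removed the simulated debris/aggregate events
(~15%); the fitted Hill coefficient h ≈ 3.2 (h > 1 means cooperative,
switch-like activation of the Wor1 enhancer; levels are relative, so c and
d are log10 of FSC-normalized units).  In the trap experiment, counting
every mixed-fate pedigree as **one** event (scheme 3) matches the Poisson
expectation built from the zero-event class (p = 0.40), while counting its
switching groups as independent events (scheme 2) is firmly rejected
(p = 0.005): related switching events cluster in lineages, the signature
of a heritable predisposing first event.

A thin CLI wraps the same stages:

```bash
switchscope run-all --seed 11 --out runs/demo        # simulate→segment→call→stats→flow
switchscope eventstats --seed 11 --out runs/demo     # just the trap statistics
```

## Layout

```
src/switchscope/
  config.py      # dataclass configs, seed derivation, error types
  synth.py       # ground-truthed generator (pedigrees, movies, flow plates)
  imaging.py     # registration, segmentation, top-k metric, lengths
  lineage.py     # pedigree model, LOESS smoothing, switch calls, grouping
  eventstats.py  # counting schemes, zero-class Poisson null, MC-GOF
  flowfit.py     # gating, FSC normalization, robust 4PL fits, summaries
  pipeline.py    # orchestration + JSON run report
  cli.py         # click CLI (`switchscope ...`)
docs/methods.md  # model assumptions, parameter defaults, numerical choices
```
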