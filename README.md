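# exvivopharm

Analysis pipeline for ex vivo tumor-slice pharmacology studies. It covers
the computational chain from raw assay readouts to study-level calls:

- **ihc** — immunostaining quantification: percent-positive scores, the
  two-score (percent × intensity, 0–300) composite, baseline (T0)
  normalization and the Ki-67/cleaved-caspase-3 growth index.
- **classify** — Responder / Non-Responder calling from the final
  drug-arm Ki-67 relative to vehicle control (Responder iff ≤ 50% of
  control), plus group association statistics: classical unpaired t tests
  and an exact-enumeration two-sided Fisher test. Ships a packaged
  33-case clinicopathology fixture.
- **expression** — multi-target qPCR card workflow: relative quantities
  anchored at the best-expressed sample, reference-gene stability (M)
  values, geometric-mean normalization factors, median-centered log2
  matrices, per-gene t + Benjamini–Hochberg differential ranking, and
  single-reference `2^-ΔCt` quantification.
- **bliss** — two-drug 7×7 dose-matrix analysis: control-normalized
  fractional growth inhibition, Bliss independence expectation
  `E = A + B − A·B`, excess-over-Bliss grids and plate-level
  synergy/additive/antagonism calls.
- **synthetic** — seeded generators for cohorts (two latent response
  classes with disjoint relative-Ki-67 ranges and class-restricted
  caspase-3 induction), duplicate-well gene-card Ct tables with planted
  log-fold effects, and Hill-response plates with optional planted
  interactions. Planted truth sits behind explicit `reveal_*` accessors.
- **pipeline / cli** — a reproducible end-to-end runner with a single
  YAML config, per-stage seed derivation and a manifest per run.

## CLI

```sh
# everything, defaults, fixed seed
exvivopharm all --seed 1 --outdir run_out

# individual stages (prerequisites run automatically; --no-deps skips them)
exvivopharm simulate --seed 1 --outdir run_out
exvivopharm synergy  --no-deps --outdir run_out

# config file + flat overrides
exvivopharm all --config my.yaml --set cohort.n_cases=50 --set plate.interaction=independent
```

Every run writes `manifest.json` echoing the fully resolved
configuration; all tables are comma-separated UTF-8 with header rows.
Unknown config keys are rejected with every offending key listed.

## Notes

- Composite scores of exactly 0 are floored to 0.5 before ratios and
  baseline normalization (configurable) so growth indices stay defined.
- Raw fractional inhibitions may leave [0, 1] under noise; a clamped
  copy feeds the Bliss formula and the clamp count is logged; raw values
  are kept in the output grid.
- The 92-target gene roster in `exvivopharm/data/apoptosis_panel.csv`
  marks all but the reported differential genes as placeholders.
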