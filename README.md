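# porestep

Simulation and kinetic analysis of stepwise **co-translocational protein
unfolding** in single-molecule nanopore recordings.

When a protein--DNA complex is pulled through an α-hemolysin pore by an
applied voltage, the pore is too narrow for the folded protein, and the
ionic current steps through a reproducible ladder of partially blocked
levels — one per unfolding intermediate — before the pore reopens.  The
motivating system is the relaxase domain of the conjugative protein TrwC
(plasmid R388) covalently bound to a 30-mer ssDNA leader through one of
its two catalytic tyrosines (Y18 or Y26): each construct shows a strictly
sequential seven-level pattern, and the two differ sharply in the
kinetics of levels 2 and 3, so single molecules in a mixed (wild-type)
sample can be assigned to a population event by event.

`porestep` is for biophysicists analysing such recordings (or building
analysis methods for them).  It provides:

- **`kinetic_scheme`** — the seven-step sequential model per construct
  and voltage: step rates *k<sub>i</sub>* (s⁻¹), level residual currents
  *I*<sub>RES</sub>(%) = 100·*I*<sub>RES</sub>/*I*<sub>O</sub>, the
  wild-type two-population mixture, hypoexponential whole-event
  durations, and sliding-window net-charge analysis of a protein
  sequence.  Ships with the published +120 mV rate/residual tables as a
  YAML registry.
- **`synthetic_data`** — ground-truth-bearing trace simulation: Poisson
  captures, exponential dwells, Gaussian noise, an optional 5 kHz
  Bessel-filter emulation (20 kHz sampling, ~230 pA open pore in
  2 M KCl), and a denaturant ("GdnHCl") mode with an irregular
  post-level-4 tail.
- **`segmentation`** — event detection and level idealization by binary
  change-point segmentation with a Schwarz-type penalty, sub-resolution
  merging, template-based level assignment and canonical-pattern
  flagging.
- **`dwell_kinetics`** — dwell-time fitting on the natural-log axis with
  pdf(*x*) = *A·k·*exp(*x* − *k·e<sup>x</sup>*) (*x* = ln *t*), mono- and
  double-exponential, BIC model choice, bootstrap confidence intervals,
  and the exact 1/mean maximum-likelihood oracle.
- **`population`** — k-means (k = 2) classification of events on
  standardized (log₁₀ *t*₂, log₁₀ *t*₃) features and per-population
  duration summaries.
- **`voltage_analysis`** — Pearson trends of rate against voltage and
  capture-frequency statistics across the +100…+140 mV range.
- **`io` / `pipeline` / `cli`** — text-based trace and table formats, an
  end-to-end seeded driver, and a `porestep` command-line umbrella
  (`simulate`, `segment`, `fit`, `classify`, `trend`, `capture`, `run`).

## Worked example

Simulate a 300-event wild-type experiment at +120 mV and run the full
analysis (dwell fitting per level, model selection for the bimodal
steps, k-means population assignment):

```python
from porestep import RunConfig, run_pipeline

report = run_pipeline(RunConfig(construct="wt", n_events=300, seed=42))
fits = report["level_fits"]
print(fits["2"]["model"], fits["2"]["rates_s"], fits["2"]["weights"])
print(fits["3"]["model"], fits["3"]["rates_s"])
print(report["classification"]["fractions"])
print(report["duration_summary"]["median_ratio"])
```

prints (abbreviated):

```
step 2->3: double  rates [1108.6, 34.8] s^-1  weights [0.23, 0.77]
step 3->4: double  rates [12.72, 0.14] s^-1
population split: {'Y18-like': 0.76, 'Y26-like': 0.24}  silhouette 0.60
median durations: {'Y18-like': 0.88 s, 'Y26-like': 5.59 s}  ratio 6.4
```

Read: the level-2 dwell distribution is bimodal and decomposes into a
fast ~1100 s⁻¹ component (DNA on Y26) and a slow ~35 s⁻¹ component (DNA
on Y18); level 3 splits into ~13 s⁻¹ versus ~0.14 s⁻¹ — the Y26 kinetic
trap.  k-means on the two dwell features assigns ~76% of molecules to
the Y18-like population, and the Y26-like population traverses the pore
about six times slower.

The same analysis from the shell, via rendered noisy traces:

```bash
porestep simulate --construct wt --voltage 140 --n-events 150 --seed 5 --out tr
porestep segment  --trace tr --construct wt --out events.tsv
porestep fit      --events events.dwells.tsv --level 3 --model auto --seed 1
porestep classify --events events.dwells.tsv --seed 1 --out labels.tsv
```

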