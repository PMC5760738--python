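# gutflow

Compartment models and statistical inference linking **within-host gut
bacterial population dynamics** to quantities measurable from **fecal time
series**: the proportion of ingested cells that is egested, and the mean and
variance of their egestion times.

The package targets experiments of the kind performed with gnotobiotic
*Drosophila melanogaster* and its gut bacterium *Acetobacter tropicalis*:
flies ingest a pulse of GFP-labelled bacteria together with inert
fluorescent microspheres, and hourly fecal samples over a 5-hour horizon
are counted under the microscope. Because the microspheres transit
passively with the food bolus, they calibrate both the amount ingested and
the bulk-flow transit time, so deviations of the bacterial counts from the
microsphere counts carry information about death, retention and growth
inside the gut — without ever sampling the gut itself.

## The model

The gut is an ordered chain of *n*+1 well-mixed compartments (foregut,
midgut subregions, hindgut). In compartment *i* a particle emigrates
forward at per capita rate *mᵢ* (per hour) and has net reproduction rate
*rᵢ = bᵢ − dᵢ* (birth minus death-or-retention). For this linear model:

- mean egestion time **μ = Σᵢ 1/(mᵢ − rᵢ)**
- egestion-time variance **σ² = Σᵢ 1/(mᵢ − rᵢ)²**
- proportion of ingested particles egested **Πᵢ mᵢ/(mᵢ − rᵢ)**
  (exactly 1 for microspheres, which have *rᵢ* = 0)
- for *n* identical compartments, **μ²/σ² = n** — an estimate of the number
  of effective gut compartments from fecal data alone.

The conditional egestion time is hypoexponential (phase-type) with stage
rates *mᵢ − rᵢ*, so the coefficient of variation is always ≤ 1 and the mean
and variance move together. Two empirical signals then classify the
within-host dynamics in a 2×2 scheme: whether the proportion egested is
significantly below 1, and whether the bacterial egestion-time statistics
are significantly reduced relative to the microspheres. Loss confined to a
small, fast-transit region (e.g. the acidic proximal midgut) reduces the
totals but barely moves the egestion-time moments (**abrupt localized
loss**); loss spread along the gut biases egestion toward early times,
reducing mean and variance (**gradual widespread loss**).

## Worked example

`examples/fate_table.py` feeds the vial-level counts of a microbial-fate
experiment (matched ingested / egested / retained-CFU counts for five vials
of flies across three replicate days) through the egested/retained/lysed
partition and the hierarchical summary (vials averaged within replicate
days, mean ± SEM across days):

```
$ python examples/fate_table.py
axenic       egested   0.18 +/- 0.08 (2 replicate days)
axenic       retained  0.08 +/- 0.02 (2 replicate days)
axenic       lysed     0.74 +/- 0.09 (2 replicate days)
gnotobiotic  egested   0.53 +/- 0.11 (2 replicate days)
gnotobiotic  retained  0.13 +/- 0.03 (2 replicate days)
gnotobiotic  lysed     0.34 +/- 0.08 (2 replicate days)
headline: ~35% egested, ~10% retained, ~55% lysed
```

About a third of ingested cells transit intact, a tenth stay alive in the
host, and the rest are unaccounted for — inferred lysed in the gut.

`examples/classify_treatments.py` runs the full pipeline on a synthetic
four-treatment egestion experiment with known ground truth:

```
$ python examples/classify_treatments.py
...
HA: proportion 0.69 (p=0.000 vs 1), paired mean-diff p=0.000 -> gradual widespread loss
HG: proportion 0.46 (p=0.000 vs 1), paired mean-diff p=0.628 -> abrupt localized loss
LA: proportion 0.25 (p=0.000 vs 1), paired mean-diff p=0.842 -> abrupt localized loss
LG: proportion 0.29 (p=0.000 vs 1), paired mean-diff p=0.608 -> abrupt localized loss
```

The other examples compare closed forms against the particle simulator
(`theory_vs_simulation.py`) and recover a designed fate partition while
demonstrating growing interhost dispersion (`fate_recovery.py`).

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
gutflow synth --seed 5 --out data/            # synthetic dataset + ground truth
gutflow analyze --samples data/samples.csv --inoculum data/inoculum.csv --out results/
gutflow fate --table fate.csv --out report.csv
gutflow simulate --chains chains.csv --model base --n-particles 100000 --seed 1 --out sim.csv
gutflow recover --trials 20 --seed 1 --out recovery.csv
```

Exit codes: 0 success, 2 validation error, 3 degenerate data.

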