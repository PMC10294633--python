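# bdellosim

Quantitative toolkit for prey-size-dependent predation dynamics of the
predatory bacterium *Bdellovibrio bacteriovorus*. The predator invades a
Gram-negative prey cell, rounds it into a *bdelloplast*, grows as a
filament inside it and then divides — by binary fission in small prey
(*Proteus mirabilis*, two progeny) or nonbinary fission in larger prey
(*Salmonella enterica*, *Shigella flexneri*, up to eight progeny). This
package implements the quantitative backbone of that biology for
microbiologists and modellers:

* **Infection simulator** — a deterministic discrete-time two-compartment
  recursion over free predators *F*, bdelloplasts *B* and unattacked prey
  *P*. With attachment *A* = min(*F*, *P*) and per-prey progeny number
  *p*, each life-cycle step Δ applies

  *P′* = *P* − *A*,  *B′* = *A*,  *F′* = (*F* − *A*) + *p·B*,

  and reports the **complete-lysis time**: the first step with *P* = 0
  and *B* = 0.
* **Kill-curve model** — the four-parameter Weibull decay
  f(t) = c + (d − c)·exp(−exp(b·(ln t − ln e))) fitted to OD600 time
  series by bounded nonlinear least squares, with the closed-form
  effective kill time EKT_q = e·exp(ln(−ln(1 − q))/b) (EKT50 at q = ½).
* **Single-cell statistics** — summaries of per-cell event timings
  (replisome DnaN, segrosome ParB and divisome FtsZ focus appearance
  times), progeny-count distributions, progeny lengths and the
  prey-length/bdelloplast-diameter correlation, using normal-theory 95%
  confidence intervals (z = 1.96, n−1 sample SD).
* **Synthetic-data generators** — seeded emulators of the measured event
  tables, size tables and plate-reader kill curves, so every stage is
  testable without external data.

## Worked example

```python
from bdellosim import (load_prey_params, run, complete_lysis_time,
                       od_projection, fit_weibull4, ekt)

params = load_prey_params("P_mirabilis")       # OD 1.0 = 1.5e9 cells/mL
traj = run(params)                             # 2.1e7 predators vs 4.2e8 prey
print(complete_lysis_time(traj))               # 2500
print(traj.final.free_predators)               # 441000000.00000006

import numpy as np
curve = od_projection(traj, od_top=1.0, od_floor=0.05,
                      times=np.arange(0, 2501, 20))
fit = fit_weibull4(curve)
print(round(ekt(fit, 0.5), 1))                 # 1928.1
```

The simulation predicts complete clearing of a *P. mirabilis* culture
2,500 min after inoculation (ten 250-min predator life cycles), ending
with 4.41×10⁸ free predators — the initial 2.1×10⁷ plus two progeny per
consumed prey cell minus the one that entered it. The fitted EKT50 says
half of the prey optical signal is gone by ≈1,930 min. The same defaults
give 1,740 min for *S. enterica* and 1,520 min for *S. flexneri*; more
progeny per prey means faster population-level killing even though each
individual life cycle is longer.

The same pipeline is scriptable from the shell:

```bash
bdellosim simulate --prey P_mirabilis --out traj.csv   # "complete lysis at 2500 min"
bdellosim --seed 1 generate events --prey P_mirabilis --n 100 --out events.csv
bdellosim summarize events.csv --out summary.csv
bdellosim --seed 1 run-all --out-dir results/
```

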