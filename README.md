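# etsim — monocyte endotoxin-response simulator

`etsim` models how human blood monocytes respond to bacterial endotoxin
(lipopolysaccharide, LPS): resting cells are activated into a transient
proinflammatory state, then reprogrammed into **endotoxin tolerance
(ET)** — a refractory state marked by low TNFα and high CCL2 production
that is typical of monocytes from patients with sepsis.  The package is
aimed at systems immunologists who want to simulate LPS-challenge
experiments in silico, calibrate the model against cytokine assay data,
and quantify the tolerance status of a monocyte culture.

## The model

Six stocks evolve in continuous time (hours).  Cell counts: resting
monocytes $R$, proinflammatory monocytes $P$, ET monocytes $E$;
LPS concentration $L$ (ng/ml, assuming a 1 ml culture); cytokine masses
TNF $T$ and CCL2 $C$ (pg):

$$
\begin{aligned}
\dot R &= -R\,a(L), &
a(L) &= a_{\max}\frac{L^{n}}{AC_{50}^{\,n}+L^{n}},\\
\dot P &= R\,a(L) - \mu P, &
\dot E &= \mu P,\\
\dot L &= -k_L L, &
\dot T &= P(t-\tau)\,s(L) - k_T T, \quad
s(L) = s_{\max}\frac{L^{m}}{SC_{50}^{\,m}+L^{m}},\\
\dot C &= c_R R + c_P P + c_E E - k_C C.
\end{aligned}
$$

Activation and TNF synthesis are Hill functions of the current LPS
concentration; TNF production lags activation by the signalling delay
$\tau$ (1 h), making the system a delay differential equation.  The 14
default parameter values are the published calibration (packaged in
`etsim/data/default_parameters.json`).  The **tolerance index** extension
summarizes a culture by the percentage of monocytes starting in the ET
pool: index 0 is a naive culture, 100 a fully tolerant one.

The calibration stack reproduces the estimation workflow: one-phase
decay fits of two-stimulus tolerization assays give per-dose activation
rates; three-parameter Hill fits (unweighted least squares, log-spaced
multistarts) calibrate $a(L)$ and $s(L)$; remaining kinetic and CCL2
parameters are refined by minimizing the total squared error between
simulated and observed cytokine time courses over all doses at once; and
the tolerance index of an unknown culture is recovered by a bounded 1-D
search on a variance-standardized TNF+CCL2 objective.

## Worked example

```python
from etsim import *

p = ModelParameters()                      # published parameter set
control = simulate(preset("fig5_control"), p)   # 10^6 resting cells + 5 ng/ml LPS
et      = simulate(preset("fig5_et"), p)        # tolerant split 0/75,000/925,000

print(control.column("tnf_pg").max(), et.column("tnf_pg").max())
print(control.final_state.ccl2, et.final_state.ccl2)

fit = fit_hill(activation_rate_table())    # packaged empirical dose–rate table
print(fit.estimates)

obs = generate_timecourse(preset("fig6_tolerance"), p,
                          NoiseSpec(multiplicative_cv=0.1, replicates=3, seed=0)).summary
res = fit_tolerance_index(obs[["time_h", "tnf_pg", "ccl2_pg"]], total=1e6, p=p)
print(res.estimates["tolerance_index"])
```

prints (values rounded):

```
peak TNF, control: 21322 pg   peak TNF, ET: 1774 pg
CCL2 at 24 h, control: 14446 pg   ET: 16224 pg
activation Hill fit: vmax 4.4991 /h, c50 0.1889 ng/ml, coef 1.4825
estimated tolerance index: 69.0 %
```

The tolerant culture produces ~12× less TNF but more CCL2 than the
control — the ET phenotype — and the tolerance-index estimator recovers
the generating index (68%) from noisy synthetic data to within a point.

The same operations are available from the shell:

```bash
etsim simulate --preset fig4_dose_response --out traj/   # five dose scenarios
etsim fit-hill --in rates.csv --out fit.json
etsim synth --kind timecourse --preset fig6_tolerance --out obs.csv
etsim fit-tolerance --in obs.csv --out tolerance.json
```

## Acceptance script

`scripts/acceptance.py` re-runs the two packaged Hill calibrations from
scratch — the activation-rate fit (maximum rate, AC50, Hill n) and the
TNF-synthesis-rate fit (maximum rate, SC50, Hill m) — and writes the six
fitted values as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/etsim/model.py` — parameters, state, flows, Hill auxiliaries
- `src/etsim/simulate.py` — fixed-step RK4 integrator (method of steps)
- `src/etsim/calibrate.py` — decay/Hill fits, kinetic refinement, tolerance index
- `src/etsim/scenarios.py` — presets and synthetic-data generators
- `src/etsim/io.py`, `src/etsim/cli.py` — configs, fixtures, CLI
- `docs/methods.md` — modelling and numerical choices in detail
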