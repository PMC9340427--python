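# nirskinetics

Muscle deoxygenation and reoxygenation kinetics from the near-infrared
spectroscopy (NIRS) tissue saturation index (TSI), for sprint-interval
training (SIT) sessions: five 30 s all-out cycling sprints separated by
4 min of passive recovery, performed under normoxia, hypoxia or
blood-flow-restricted recovery.

The package is for exercise physiologists who record muscle oxygenation
(e.g. vastus lateralis) and crank power during repeated sprints and want
per-sprint kinetic and mechanical parameters in a reproducible, scriptable
pipeline.

## The models

TSI is the oxygenated fraction of haemoglobin, `TSI = 100·[O₂Hb]/[tHb]`
(percent). Raw 50 Hz data are averaged into 1 s bins, then smoothed with a
zero-phase second-order Butterworth low-pass (cutoff 0.1 Hz).

**Deoxygenation (sprint onset).** Over the first 10 samples of each sprint
(t = 0…9 s) the drop is linear:

    mTSI(t) = a·t + TSI₀

`a` (%·s⁻¹) is the deoxygenation rate, `TSI₀` the pre-sprint saturation.
Derived: `a_adj = a/W` (W = sprint total work, kJ) and `ΔTSI = max − min`
TSI over the 30 s sprint.

**Reoxygenation (recovery).** A delayed mono-exponential:

    TSIk(t) = TSIb + A·(1 − e^{−(t−TD)/τ})   for t > TD,   TSIb otherwise

with baseline `TSIb`, asymptotic amplitude `A`, time delay `TD` and time
constant `τ`. Derived: mean response time `MRT = TD + τ`, realised
amplitude `A′ = A·(1 − e^{−(Tend−TD)/τ})` at the end of the 240 s window,
and `adjR² = 1 − (1−R²)(n−1)/(n−k−1)` with k = 3. Fits with R² ≤ 0.80 are
excluded from group summaries.

**Performance.** Per sprint: peak power, mean power, total work
(trapezoidal integral); per session the power-decrease percentage
`100·Σmean/(best·n) − 100`.

Because no public dataset exists for this protocol, a synthetic-session
generator with known ground-truth parameters (centred on published group
means per condition) drives validation: noise-free sessions are recovered
exactly, noisy ones to quantified median errors.

## Worked example

```python
import nirskinetics as nk

spec = nk.default_spec("BFR")                 # condition-specific defaults
tsi, power, protocol, truth = nk.generate_session(spec, seed=42)
res = nk.analyze_session(tsi, protocol, power_trace=power)

r = res["reoxy_fits"][0]
print(f"sprint 1: TD={r.td:.1f} s  tau={r.tau:.1f} s  MRT={r.mrt:.1f} s  "
      f"A'={r.a_prime:.1f}%  R2={r.r2:.3f}  included={r.included}")
d = res["deoxy_fits"][0]
print(f"deoxygenation: a={d.a:.2f} %/s  TSI0={d.tsi0:.1f}%  a_adj={d.a_adj:.3f} %/s/kJ")
print(f"power decrease: {res['power_decrease']:.1f}%")
```

prints (seed 42):

```
sprint 1: TD=68.4 s  tau=16.3 s  MRT=84.7 s  A'=16.7%  R2=0.934  included=True
deoxygenation: a=-1.16 %/s  TSI0=79.3%  a_adj=-0.072 %/s/kJ
power decrease: -13.9%
```

i.e. after the first sprint of this simulated cuff-restriction session,
reoxygenation starts only ~68 s into recovery (the long delay is the BFR
signature) and then rises with a ~16 s time constant; the smoothed onset
window shows deoxygenation at ~1.2 % per second from a pre-sprint
saturation of ~79 %, and mean power fell ~14 % across the five sprints.

The same pipeline runs from the shell:

```bash
nirs simulate --condition BFR --seed 42 --out session/
nirs preprocess --in session/tsi_1hz.csv --protocol session/protocol.yaml --out segments/
nirs fit-reoxy --segments segments/ --out reoxy_fits.csv
```

and end-to-end from a YAML config with `nirs run --config config.yaml`.

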