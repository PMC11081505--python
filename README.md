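# msodev

Developmental tuning of interaural time difference (ITD) coding in neurons
of the medial superior olive (MSO): a spike timing-dependent plasticity
(STDP) model of how binaural coincidence detectors acquire their best ITD,
together with the analysis procedures used to measure ITD tuning in
juxtacellular recordings, and a seeded synthetic-data generator that makes
the whole pipeline testable without experimental data.

## The problem

MSO principal neurons fire maximally at a best ITD (bITD). Shortly after
hearing onset, contralateral sound-evoked activity arrives ~0.3 ms later
than ipsilateral activity, biasing juvenile bITDs to contralateral-leading
values outside the ecological range (the ±0.13-ms span an adult gerbil head
can produce). Over the following weeks the bITDs of high-frequency neurons
shift into the ecological range. The package's model asks whether an STDP
rule acting on the synaptic weights of a coincidence detector can produce
that shift — selecting, out of ipsi- and contralateral inputs with
dispersed latencies, the combinations whose delays are compensated by
naturally occurring ITDs.

The model neuron receives 30 inputs per side with latencies
`l_offset + N(0, l_SD) + U[0, 2]/f_i` (offsets 5.0/5.3 ms), alpha-function
EPSPs with amplitude equal to the synaptic weight, linear summation and an
expansive firing-rate nonlinearity. The STDP kernel

```
Δω(t) = 0.3·e^{(t−t_off)/0.5}                      t < t_off
Δω(t) = 0.5·e^{−(t−t_off)/0.5} − 0.2·e^{−(t−t_off)/5}   t ≥ t_off
```

potentiates inputs active before postsynaptic firing and depresses ones
active after; its maximal-potentiation-to-maximal-depression lag is
(5/9)·ln 25 ≈ 1.79 ms. Weights are clamped at zero and renormalised to a
constant sum after every update (homeostatic constraint). Training draws
teacher ITDs uniformly from the ecological range.

The analysis half implements: eAP detection by maximum repolarization rate,
two-pass-median first-spike latencies (FSL) to clicks, click-ITD
facilitation metrics (`1 − (1−P_ipsi)(1−P_contra)` prediction), eEPSP
onset/rise analysis, modified-Gabor bITD fits with a significance test,
vector strength with Rayleigh statistics, the juvenile ecological-range
model `limit = 41.5 µs + 2.6 µs/day`, the quadratic bITD-frequency
correction, and the Wilcoxon signed-rank normal approximation.

See `docs/methods.md` for the full model description, parameter table and
numerical choices.

## Layout

- `src/msodev/stdp_model.py` — model neuron, STDP kernel, training loops,
  population experiments
- `src/msodev/itd_analysis.py` — Gabor bITD fits, vector strength, the
  ecological-range and quadratic models, Wilcoxon approximation
- `src/msodev/spike_analysis.py` — event detection, click FSL/ITD metrics,
  eEPSP analysis
- `src/msodev/synthetic.py` — Zwuis tone sets, synthetic click recordings
  and Zwuis-driven spike trains with ground truth
- `src/msodev/pipeline.py`, `cli.py` — config-driven orchestration
  (`msodev simulate|synth|analyze|report`)
- `analysis/01…04_*.py` — the study's main computations as runnable
  scripts, writing tables under `results/`

## Worked example

Train a 1.8-kHz model neuron with ecological teacher ITDs:

```python
import numpy as np
from msodev.stdp_model import (ModelParams, STDPKernel, init_neuron,
                               itd_rate_curve, train_neuron)

params = ModelParams()
neuron = init_neuron(best_freq=1.8, params=params, seed=3)
print(f"initial bITD: {itd_rate_curve(neuron).bitd:+.2f} ms")
res = train_neuron(neuron, teacher_itd_range=(-0.13, 0.13), n_updates=1000,
                   kernel=STDPKernel(), params=params, seed=103)
print(f"final bITD:   {res.final_curve.bitd:+.2f} ms")
print(f"surviving inputs: {(neuron.weights > 1e-6).sum()} of 60")
```

```
initial bITD: +0.30 ms
final bITD:   +0.12 ms
surviving inputs: 56 of 60
```

The untrained neuron prefers contralateral-leading ITDs near the +0.3-ms
latency bias (individual neurons scatter around it); after 1,000 updates
with teacher ITDs in 0 ± 0.13 ms its bITD sits inside the ecological range,
with part of the inputs eliminated and the rest re-weighted toward
delay-compensated pairs. Population versions of this experiment (means over
frequency groups, retraining with an unnatural 0.6-ms teacher, kernel
ablations) are in `analysis/02_train_populations.py` and
`analysis/03_kernel_variants.py`.

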