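# Methods

This package has two halves: a computational model of how spike
timing-dependent plasticity (STDP) can retune the best interaural time
difference (bITD) of developing MSO neurons, and the spike/waveform analysis
procedures used to characterise ITD tuning in juxtacellular recordings. A
seeded synthetic-data generator stands in for experimental recordings so
that every analysis stage can be validated against known ground truth.

Conventions: time in ms and frequency in kHz inside the model; spike times
in seconds in the analysis code; positive ITD means the contralateral ear
leads, implemented by delaying the ipsilateral inputs.

## The coincidence-detector model

A model neuron receives 30 ipsilateral and 30 contralateral excitatory
inputs. Input *i* has a best frequency `f_i = bf·(1 + γ·U[−0.5,0.5])`, a
latency `l_i = l_offset + N(0, l_SD) + U[φ_low, φ_high]/f_i`, and a weight
`w_i`; weights start equal and always sum to 1 (homeostatic constraint).
The side offsets are 5.0 ms (ipsilateral) and 5.3 ms (contralateral): the
contralateral pathway is 0.3 ms slower, which is the bias the plasticity
must overcome. Each activation produces an alpha-function EPSP of amplitude
`w_i` and time constant `τ_EPSP`; summation is linear; the instantaneous
rate is an expansive, normalised sigmoid of the potential
(`R(0)=0`, `R(Σw)=R_max`). The expected firing at a given ITD is the time
sum of `R(t)·dt` divided by a 3-ms integration window, and the bITD is the
argmax over the ITD grid (−1.5…1.5 ms, 0.01-ms steps; ties break toward the
smallest |ITD|, and the ITD step equals the simulation `dt` so the
ipsilateral potential is shifted by whole samples).

### The STDP rule

The kernel (weight-change density per activation, as a function of the lag
between an input's onset and postsynaptic firing) is

```
Δω(t) = 0.3·exp((t−t_off)/(0.5·s))                          t < t_off
Δω(t) = 0.5·exp(−(t−t_off)/(0.5·s)) − 0.2·exp(−(t−t_off)/(5·s))   t ≥ t_off
```

with broadening factor `s` (1, 2, 3, 6 or 10). Both branches decay away
from `t_off`; the kernel is continuous (value 0.3) at `t_off`, crosses zero
at `t_off + (5/9)·ln(5/2)·s ≈ t_off + 0.509·s` ms and has its depression
minimum at `t_off + (5/9)·ln 25·s ≈ t_off + 1.788·s` ms, so the lag between
maximal potentiation and maximal depression is 1.79 ms at `s = 1`. `t_off`
aligns the rule on the EPSP peak (`−0.05 − τ_EPSP`) or on the zero crossing
(subtracting `(s−1)·(5/9)·(ln5−ln2)` as the rule is broadened). Ablated
variants zero the negative (depression) or positive (potentiation) lobe.

One update: draw a teacher ITD uniformly from the training range; jitter
every input by `N(0, t_SD)`; compute `v_m` and `R`; threshold `R` at
`R_min = R(0.15·Σw)`; form the raw weight change as the linear
cross-correlation `Δw(τ) = Σ_t R_thr(t)·Δω(τ−t)·dt` and evaluate it at each
input's onset; if no input would be potentiated, redraw the jitter (up to 8
redraws, then skip — redraws are i.i.d., so the acceptance probability is
insensitive to the exact bound); add, clamp negatives to zero, renormalise.
The cross-correlation (not a pointwise product) is what gives the rule its
pre-before-post asymmetry: an input whose onset precedes supra-threshold
firing sits on the potentiation side of the kernel. For the depression-only
variant the positivity condition is replaced by "any nonzero change":
a rule with no potentiation lobe can never produce a positive raw change,
yet its competition-by-normalisation dynamics are exactly what the ablation
experiment studies.

### Parameter values

The numerical values of `τ_EPSP`, `γ`, `l_SD`, `t_SD`, the phase range,
`k_E`, `v_c` and `R_max` are not published; the defaults here were
calibrated once against the qualitative target behaviour (the developmental
retuning of high-frequency neurons into the ecological range, the ordering
of retuning rates by best frequency, and the single-ipsilateral-survivor
outcome of the depression-only rule), with the analytic kernel properties
fixed throughout:

| parameter | default | role |
|---|---|---|
| τ_EPSP | 0.15 ms | EPSP time constant; sets coincidence resolution |
| γ | 0.2 | relative spread of input best frequencies |
| l_SD | 0.2 ms | Gaussian latency dispersion |
| φ_low, φ_high | 0, 2 cycles | phase-latency range, divided by `f_i` |
| t_SD | 0.12 ms | per-update activation jitter |
| k_E | 40 /w | excitability steepness |
| v_c | 0.5·Σw | sigmoid midpoint |
| R_max | 1 | rate scale (also the effective learning-rate scale) |

Two of these choices carry the model's qualitative behaviour and deserve
comment. First, the phase-latency range spans two cycles of the input's
best frequency, so the latency dispersion scales as `2/f`: 1.1 ms at
1.8 kHz and 5 ms at 0.4 kHz. Dispersion much wider than the kernel's
0.5-ms potentiation lobe is required for the rule to discriminate between
candidate coincidence groups; at the same time the wide dispersion of
low-frequency inputs keeps their summed potential low. Second, `v_c` sits
near the summed-potential peak of a *high-frequency* neuron (~0.47 at
1.8 kHz vs ~0.2 at 0.4 kHz at the default weights), which with the steep
sigmoid makes firing — and therefore plasticity — strong and temporally
sharp for high-frequency neurons and weak for low-frequency ones. This is
the mechanism behind the frequency-ordered retuning rate: 1.8-kHz
populations reach the teacher range within 1,000 updates, 1.0-kHz
populations move part of the way, and 0.4-kHz populations are essentially
frozen (their updates usually fail the plasticity threshold and are
skipped). The depression-only ablation needs far more updates (~10^5) to
complete its collapse: each depression event only prunes inputs lagging the
momentary firing, and the final competition between near-coincident early
inputs is resolved only by the activation jitter.

### Numerical choices

Simulation grid 0–15 ms at `dt = 0.01` ms. The per-update potential is
evaluated only on the sub-grid spanning the active EPSPs (elsewhere it is
identically zero), and the raw weight change is evaluated directly at the
60 input onsets rather than by a full convolution. The kernel's
exponential tails are kept exact (no truncation); an input ~5 ms ahead of
all firing receives a raw change ~10^−4 of an aligned input's. Weight
conservation is enforced to 1e−9 after every update. A fixed seed
reproduces a training run bit for bit.

## Analysis procedures

**Event detection.** Candidate peaks are local maxima at least 1 ms apart
with prominence above the noise scale; each candidate's metric is the most
negative first derivative within ±0.5 ms (the maximum repolarization rate),
thresholded by the user. Quality control fits 1- vs 2-component Gaussian
mixtures to the log metric (BIC difference > 10 ⇒ bimodal — events well
separated from background); the flag never removes events.

**Click FSL.** First events in [+0.5, +10.5] ms after each click are
pooled; the first-spike latency is the median of the values within 1 ms of
the provisional median (two-pass median). Per-intensity medians reuse the
same procedure; the intensity shift compares the FSL with the median at the
weakest intensity having more than 3 responses.

**Click-ITD facilitation.** Presentations with |ITD| ≥ 0.5 ms are
quasi-monaural and attributed to the leading ear (measured from that ear's
click in [+2.5, +8.5] ms, two-pass median). The difference between the
monaural latencies defines the compensating ITD; presentations within
±0.13 ms of it are binaural. Observed binaural spike probability is
compared with the independent-coincidence prediction
`1 − (1−P_ipsi)(1−P_contra)`; both probability-ratio conventions (vs the
prediction, vs the larger monaural probability) are reported, along with
the binaural latency shift.

**eEPSP analysis.** Snippets of −5…+4 ms around each eAP peak are smoothed
with a 50-µs moving average. The onset threshold is the lower of
`V_median + 2·SD` (SD over −3…−0.5 ms pre-peak) and `V_median + 0.1·(peak −
V_median)` — the one crossed first on an upward onset. The onset is the
threshold crossing that leads into the peak (first sample of the
supra-threshold run containing the peak): under stationary noise an
absolute first crossing anywhere in the snippet would be dominated by
chance 2-SD excursions. Maximal rise is the largest derivative between
onset and 0.2 ms pre-peak; recordings with seal ≤ 20 MΩ or median maximal
rise ≤ 1 V/s are excluded; the eEPSP-AP latency is the median onset-to-peak
interval.

**Best ITD (Gabor fit).** Mean rate vs ITD is fitted with
`r0 + A·exp(−(ITD−μ)²/2σ²)·[(1+cos 2πf(ITD−μ))/2]^p` (the power parameter
sharpens the carrier peaks), by bounded nonlinear least squares from
multiple starts (μ ∈ {−0.5, 0, 0.5, empirical peak}; carrier frequency from
the dominant Fourier component). The carrier is restricted to ≤ 2.5
cycles/ms and the envelope to ≥ 1.5 grid steps; without these bounds the
6-parameter family can interpolate single noisy points. Significance is a
variance-explained test against the constant-rate model; because the
multi-start nonlinear family is more flexible than its six nominal
parameters, its effective model dimension was calibrated on null
simulations (~10 for 41-point curves), under which R² ~ Beta(5, (n−11)/2).
Cells with p > 0.001 are flagged untuned and carry no bITD; otherwise the
bITD is the argmax of the fitted curve (not μ). Within-range metrics
(dynamic range and maximal slope inside ±0.2 ms) come from the fitted
curve.

**Phase locking.** Vector strength `|Σ exp(i2πf t_k)|/n` with Rayleigh
p = exp(−nVS²) for n ≥ 50 and the higher-order series correction for
smaller n (validated against Monte Carlo tails); best frequency is the
tone with the highest vector strength among those significant at p < 1e−4.

**Ecological range.** `limit(day) = 41.5 µs + 2.6 µs·day⁻¹`, ±0.13 ms for
adults; age groups use midpoint days (P15-17→16 … P26-28→27). The printed
P24-25 value (0.106 ms) differs from midpoint arithmetic (0.1052 ms) by
under 1 µs of rounding; the model is not force-matched to it.

**Quadratic frequency correction.** `bITD = β₂f² − β₁f + β₀` with the
published adult coefficients (0.098, 0.35, 0.33) as defaults; corrected
bITD = observed − predicted; a least-squares fitter recovers coefficients
from data.

**Wilcoxon normal approximation.** Sum of signed ranks, σ =
√(n(n+1)(2n+1)/6), two-sided normal p, no tie correction; exact zero
differences are dropped before ranking.

## The synthetic-data generator

**Zwuis tone sets.** Tones are integer multiples of 1/duration (3.33 Hz at
the default 0.3 s) in [50, 5000] Hz, with all primaries, pairwise sums and
absolute differences unique. Small sets are found by seeded rejection
sampling with the allowed-candidate set computed exactly at each step. A
30-tone set on the 3.33-Hz grid sits essentially at the combinatorial
limit (a Sidon-type bound), where random search fails; such sets are
instead built from a seeded rotation of the 30-element Singer
perfect-difference set of PG(2, 29) — a maximal Sidon set in [0, 870] —
anchored at the top of the band so that every pairwise sum clears the band;
the result is verified exhaustively. Consequence: the default 30-tone sets
occupy the upper part of the band (~2.1–5 kHz) rather than spreading to
50 Hz.

**Click recordings.** Each click evokes a spike with probability from an
intensity sigmoid; latency = truth FSL + Gaussian jitter; each spike is a
difference-of-Gaussians biphasic eAP (~0.3 ms wide, ~2 mV) preceded by an
alpha-shaped eEPSP at the truth onset lag; band-limited Gaussian noise is
added. In the ITD protocol, well-separated pairs are driven by the leading
ear only (forward suppression), and pairs whose ITD compensates the
latency difference are facilitated (probability multiplied, latency
advanced). Waveform shapes are emulation devices — they are validated by
analysis recovery, not by biophysical realism, and passing tests on them
says nothing about, e.g., bursting, adaptation or non-stationary noise in
real recordings.

**Zwuis spike trains.** Bernoulli thinning (20-µs grid) of
`base · G(ITD) · exp(κ cos 2πf_best t)/I₀(κ)`, with `G` a Gabor gain
centred on the truth bITD and `f_best` snapped to the nearest tone. The
phase factor makes the spike-phase distribution exactly von Mises, so the
expected vector strength is I₁(κ)/I₀(κ); κ = 0 with a flat gain is the
untuned null.

## Scale of the shipped experiments

The population analyses and acceptance checks run 50–100 neurons per
frequency group for 1,000 updates (the original figures use 400–500), and
the depression-only ablation runs 3 neurons for 150,000 updates; these
sizes keep the full suite to minutes on one core while leaving the group
means' standard errors well inside the asserted tolerances.

## Known limitations

- The model's open parameters are a calibrated set, not measured values;
  other calibrations satisfying the same qualitative targets exist.
- The depression-only collapse time depends strongly on the activation
  jitter; with much smaller jitter the final few coincident survivors
  become effectively permanent.
- The Gabor significance calibration (effective df ≈ 10) was established
  for ~41-point curves; very short curves fall back to a clipped value.
- The synthetic click generator's forward suppression is all-or-none; real
  trailing-click responses are graded.
- `curve_from_spikes` assumes a balanced trial design and infers the
  repeat count from the densest ITD condition.
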