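"""Coincidence-detector model of MSO neurons and the STDP rule that retunes them.

The model neuron receives two populations of excitatory inputs (ipsilateral and
contralateral), each input characterised by a best frequency, a conduction
latency and a synaptic weight.  Contralateral inputs start with a 0.3-ms longer
latency than ipsilateral ones, mirroring the longer travel path for
contralateral sound-evoked activity in the juvenile brainstem.  Inputs are
activated as idealised clicks: a single presynaptic event per input whose
timing is the input latency plus the interaural time difference (ITD, applied
to the ipsilateral side) plus jitter.  EPSPs are alpha functions, summation is
linear, and an expansive sigmoid maps membrane potential to instantaneous
firing rate.  A spike timing-dependent plasticity (STDP) kernel correlated
with the supra-threshold firing rate updates the synaptic weights; weights are
clamped at zero and renormalised so their sum is conserved (homeostatic
constraint).  Training with "teacher" ITDs drawn from the ecological range
gradually shifts the neuron's best ITD (bITD) toward that range.

Units: time in ms, frequencies in kHz, weights and rates dimensionless
(R_max = 1 by default).  Positive ITD means the contralateral ear leads,
implemented by delaying the ipsilateral onsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "SynapticInput",
    "ModelNeuron",
    "STDPKernel",
    "TrainingResult",
    "TuningCurve",
    "init_neuron",
    "epsp_trace",
    "membrane_potential",
    "firing_rate",
    "itd_rate_curve",
    "stdp_kernel",
    "kernel_t_off",
    "kernel_extrema",
    "apply_update",
    "train_neuron",
    "run_population_experiment",
]

Side = Literal["ipsi", "contra"]

#: separation constant of the depression lobe: ln(0.5/0.2) / (1/0.5 - 1/5)
_ZERO_CROSS_COEF = (5.0 / 9.0) * (math.log(5.0) - math.log(2.0))


@dataclass(frozen=True)
class ModelParams:
    """All tunable symbols of the model neuron and its training protocol.

    Latency offsets (5.0 / 5.3 ms) are the side-specific travel latencies;
    ``gamma`` is the relative spread of input best frequencies around the
    neuron's; ``l_SD`` the normal latency jitter; ``phi_low``/``phi_high``
    the uniform phase-latency range in cycles (divided by the input
    frequency); ``t_SD`` the per-update activation jitter.  The excitability
    sigmoid rho(v) = 1 / (1 + exp(k_E (v_c - v))) is normalised so firing is
    0 at v_m = 0 and R_max at v_m = total_weight.  ``r_min_fraction`` sets
    the plasticity threshold R_min = R(r_min_fraction * total_weight) and
    ``integration_window`` the 3-ms normaliser of the expected firing.
    """

    n_inputs_per_side: int = 30
    l_offset_ipsi: float = 5.0
    l_offset_contra: float = 5.3
    gamma: float = 0.2
    l_SD: float = 0.2
    t_SD: float = 0.12
    phi_low: float = 0.0
    phi_high: float = 2.0
    tau_EPSP: float = 0.15
    k_E: float = 40.0
    v_c: float = 0.5
    R_max: float = 1.0
    r_min_fraction: float = 0.15
    integration_window: float = 3.0
    dt: float = 0.01
    t_start: float = 0.0
    t_end: float = 15.0
    itd_min: float = -1.5
    itd_max: float = 1.5
    itd_step: float = 0.01
    total_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.n_inputs_per_side < 1:
            raise ValueError("n_inputs_per_side must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau_EPSP <= 0:
            raise ValueError("tau_EPSP must be positive")
        if self.total_weight <= 0:
            raise ValueError("total_weight must be positive")
        if self.gamma < 0 or self.gamma >= 2.0:
            raise ValueError(
                "gamma must lie in [0, 2): gamma >= 2 could yield a "
                "non-positive input frequency"
            )
        if self.itd_step <= 0 or self.itd_max <= self.itd_min:
            raise ValueError("invalid ITD grid")
        if not math.isclose(self.itd_min, -self.itd_max):
            raise ValueError("itd grid must be symmetric around 0")

    @property
    def t_grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.dt)) + 1
        return self.t_start + self.dt * np.arange(n)

    @property
    def itd_grid(self) -> np.ndarray:
        n = int(round((self.itd_max - self.itd_min) / self.itd_step)) + 1
        grid = self.itd_min + self.itd_step * np.arange(n)
        return grid

    @property
    def r_min(self) -> float:
        return float(
            firing_rate(np.array([self.r_min_fraction * self.total_weight]), self)[0]
        )


@dataclass
class SynapticInput:
    side: Side
    freq: float  # kHz
    latency: float  # ms
    weight: float

    def __post_init__(self) -> None:
        if self.freq <= 0:
            raise ValueError("input frequency must be positive")
        if self.latency <= 0:
            raise ValueError("input latency must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


@dataclass
class ModelNeuron:
    """A model MSO neuron: best frequency plus its 2 x n inputs."""

    best_freq: float  # kHz
    inputs: list[SynapticInput]
    params: ModelParams

    # -- vector views used by the numeric code ------------------------------
    @property
    def weights(self) -> np.ndarray:
        return np.array([inp.weight for inp in self.inputs])

    @weights.setter
    def weights(self, w: np.ndarray) -> None:
        for inp, wi in zip(self.inputs, w):
            inp.weight = float(wi)

    @property
    def latencies(self) -> np.ndarray:
        return np.array([inp.latency for inp in self.inputs])

    @property
    def is_ipsi(self) -> np.ndarray:
        return np.array([inp.side == "ipsi" for inp in self.inputs])

    def validate(self) -> None:
        n = self.params.n_inputs_per_side
        sides = [inp.side for inp in self.inputs]
        if sides.count("ipsi") != n or sides.count("contra") != n:
            raise ValueError(f"expected {n} inputs per side")
        if abs(self.weights.sum() - self.params.total_weight) > 1e-9:
            raise ValueError("weights do not sum to total_weight")


@dataclass(frozen=True)
class STDPKernel:
    """Two-exponential STDP kernel with amplitudes 0.3 / 0.5 / 0.2.

    ``t_scaling`` broadens the rule (the studied variants use 1, 2, 3, 6, 10);
    ``alignment`` shifts the kernel so that either the maximal potentiation
    ('peak') or the zero crossing ('zero_crossing') stays put as the rule is
    broadened; ablated variants zero one lobe.  Time constants are
    0.5 * t_scaling (fast) and 5 * t_scaling (slow) ms.
    """

    t_scaling: float = 1.0
    alignment: Literal["peak", "zero_crossing"] = "peak"
    variant: Literal["full", "potentiation_only", "depression_only"] = "full"
    a_pre: float = 0.3
    a_fast: float = 0.5
    a_slow: float = 0.2

    def __post_init__(self) -> None:
        if self.t_scaling <= 0:
            raise ValueError("t_scaling must be positive")

    def t_off(self, tau_EPSP: float) -> float:
        return kernel_t_off(self, tau_EPSP)

    @property
    def zero_crossing_offset(self) -> float:
        """Lag after t_off at which the full kernel crosses zero."""
        return _ZERO_CROSS_COEF * self.t_scaling


def kernel_t_off(kernel: STDPKernel, tau_EPSP: float) -> float:
    """Kernel shift aligning the rule on the EPSP peak or the zero crossing.

    Peak alignment puts the maximal potentiation at -0.05 - tau_EPSP (the lag
    between an input's onset and the postsynaptic firing it drives); zero
    crossing alignment additionally subtracts the broadening of the
    potentiation side, (t_scaling - 1) * (5/9) * (ln 5 - ln 2).
    """
    base = -0.05 - tau_EPSP
    if kernel.alignment == "peak":
        return base
    return base - (kernel.t_scaling - 1.0) * _ZERO_CROSS_COEF


def stdp_kernel(
    t: np.ndarray | float, kernel: STDPKernel, tau_EPSP: float
) -> np.ndarray:
    """Evaluate the weight-change density at lag ``t`` (input onset minus
    postsynaptic firing time).

    Both branches decay away from ``t_off``; the t >= t_off branch is the
    difference of a fast potentiating and a slow depressing exponential, so
    the kernel starts at 0.3, crosses zero at t_off + 0.509 * t_scaling and
    has a shallow depression lobe after.
    """
    t = np.asarray(t, dtype=float)
    t_off = kernel_t_off(kernel, tau_EPSP)
    s = t - t_off
    tau_fast = 0.5 * kernel.t_scaling
    tau_slow = 5.0 * kernel.t_scaling
    out = np.where(
        s < 0,
        kernel.a_pre * np.exp(np.minimum(s, 0.0) / tau_fast),
        kernel.a_fast * np.exp(-np.maximum(s, 0.0) / tau_fast)
        - kernel.a_slow * np.exp(-np.maximum(s, 0.0) / tau_slow),
    )
    if kernel.variant == "potentiation_only":
        out = np.where(out < 0, 0.0, out)
    elif kernel.variant == "depression_only":
        out = np.where(out > 0, 0.0, out)
    return out


def kernel_extrema(kernel: STDPKernel, tau_EPSP: float) -> dict:
    """Locate the kernel's extrema and zero crossing.

    Dense-grid search refined by a local ternary search on the analytic
    branch.  Returns times of maximal potentiation and maximal depression,
    the zero crossing, the extreme values, and their separation.  Missing
    lobes (ablated variants) are reported as None.
    """
    t_off = kernel_t_off(kernel, tau_EPSP)
    ts = kernel.t_scaling
    res: dict[str, float | None] = {
        "t_max_potentiation": None,
        "t_max_depression": None,
        "t_zero_crossing": None,
        "max_potentiation": None,
        "max_depression": None,
        "separation": None,
    }
    grid = t_off + np.arange(-20.0 * ts, 60.0 * ts, 0.005 * ts)
    vals = stdp_kernel(grid, kernel, tau_EPSP)
    if kernel.variant != "depression_only":
        i = int(np.argmax(vals))
        res["t_max_potentiation"] = float(grid[i])
        res["max_potentiation"] = float(vals[i])
    if kernel.variant != "potentiation_only":
        i = int(np.argmin(vals))
        # refine on the analytic two-exponential branch
        lo, hi = grid[max(i - 2, 0)] - t_off, grid[min(i + 2, len(grid) - 1)] - t_off
        for _ in range(200):
            m1 = lo + (hi - lo) / 3
            m2 = hi - (hi - lo) / 3
            f1 = kernel.a_fast * math.exp(-m1 / (0.5 * ts)) - kernel.a_slow * math.exp(
                -m1 / (5 * ts)
            )
            f2 = kernel.a_fast * math.exp(-m2 / (0.5 * ts)) - kernel.a_slow * math.exp(
                -m2 / (5 * ts)
            )
            if f1 < f2:
                hi = m2
            else:
                lo = m1
        s_min = 0.5 * (lo + hi)
        res["t_max_depression"] = float(t_off + s_min)
        res["max_depression"] = float(stdp_kernel(t_off + s_min, kernel, tau_EPSP))
    if kernel.variant == "full":
        res["t_zero_crossing"] = float(t_off + kernel.zero_crossing_offset)
        res["separation"] = res["t_max_depression"] - res["t_max_potentiation"]
    return res


# ---------------------------------------------------------------------------
# neuron construction and biophysics
# ---------------------------------------------------------------------------


def init_neuron(best_freq: float, params: ModelParams, seed) -> ModelNeuron:
    """Initialise a model neuron with 2 x n inputs and equal weights.

    Input frequencies are best_freq * (1 + gamma * U[-0.5, 0.5]); latencies
    are the side offset plus N(0, l_SD) plus a uniform phase U[phi_low,
    phi_high] divided by the input frequency (slower inputs have a wider
    phase-latency spread).
    """
    if best_freq <= 0:
        raise ValueError("best_freq must be positive")
    rng = np.random.default_rng(seed)
    n = params.n_inputs_per_side
    inputs: list[SynapticInput] = []
    w0 = params.total_weight / (2 * n)
    for side, offset in (("ipsi", params.l_offset_ipsi), ("contra", params.l_offset_contra)):
        freqs = best_freq * (1.0 + params.gamma * rng.uniform(-0.5, 0.5, size=n))
        phases = rng.uniform(params.phi_low, params.phi_high, size=n)
        lat = offset + rng.normal(0.0, params.l_SD, size=n) + phases / freqs
        for f, l in zip(freqs, lat):
            inputs.append(SynapticInput(side=side, freq=float(f), latency=float(l), weight=w0))
    neuron = ModelNeuron(best_freq=best_freq, inputs=inputs, params=params)
    neuron.validate()
    return neuron


def epsp_trace(
    inp: SynapticInput, onset_shift: float, t_grid: np.ndarray, tau_EPSP: float
) -> np.ndarray:
    """Alpha-type EPSP of one input: w * (s/tau) * exp(1 - s/tau) for
    s = t - (latency + onset_shift) >= 0, zero before onset.  The shift
    carries the ITD and any per-update jitter."""
    onset = inp.latency + onset_shift
    s = np.maximum((np.asarray(t_grid, dtype=float) - onset) / tau_EPSP, 0.0)
    s = np.minimum(s, 50.0)  # alpha fn is ~1e-20 there; avoids exp underflow
    return inp.weight * s * np.exp(1.0 - s)


def _onsets(neuron: ModelNeuron, itd: float, jitter: np.ndarray | None) -> np.ndarray:
    """Onset time of every input's EPSP.  Positive ITD (contralateral
    leading) delays the ipsilateral onsets."""
    onsets = neuron.latencies.copy()
    onsets[neuron.is_ipsi] += itd
    if jitter is not None:
        onsets = onsets + jitter
    return onsets


def _vm_from_onsets(
    weights: np.ndarray, onsets: np.ndarray, t_grid: np.ndarray, tau: float
) -> np.ndarray:
    s = (t_grid[None, :] - onsets[:, None]) / tau
    np.clip(s, 0.0, 50.0, out=s)
    return (weights[:, None] * (s * np.exp(1.0 - s))).sum(axis=0)


def membrane_potential(
    neuron: ModelNeuron,
    itd: float,
    jitter: np.ndarray | None = None,
    t_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Linear summation of all input EPSPs at a given ITD (and optional
    per-input jitter vector)."""
    if t_grid is None:
        t_grid = neuron.params.t_grid
    if jitter is not None and len(jitter) != len(neuron.inputs):
        raise ValueError("jitter vector length must equal the number of inputs")
    onsets = _onsets(neuron, itd, jitter)
    return _vm_from_onsets(neuron.weights, onsets, t_grid, neuron.params.tau_EPSP)


def firing_rate(v_trace: np.ndarray, params: ModelParams) -> np.ndarray:
    """Map membrane potential to instantaneous firing rate.

    R(v) = R_max * (rho(v) - rho(0)) / (rho(total_weight) - rho(0)) with the
    sigmoid rho(v) = 1/(1 + exp(k_E (v_c - v))); by construction R(0) = 0 and
    R(total_weight) = R_max.
    """
    def rho(v):
        return 1.0 / (1.0 + np.exp(np.clip(params.k_E * (params.v_c - v), -700, 700)))

    denom = rho(params.total_weight) - rho(0.0)
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("degenerate excitability normalization: rho(total)==rho(0)")
    return params.R_max * (rho(np.asarray(v_trace, dtype=float)) - rho(0.0)) / denom


@dataclass
class TuningCurve:
    """Expected firing versus ITD, with the best ITD (argmax)."""

    itd_grid: np.ndarray
    rate: np.ndarray
    bitd: float


def itd_rate_curve(neuron: ModelNeuron, params: ModelParams | None = None) -> TuningCurve:
    """Expected firing (sum of R(t) * dt / integration_window) for each ITD
    on the grid; no jitter is applied during evaluation.

    The ITD shifts the ipsilateral onsets by whole grid samples (the ITD step
    equals the simulation dt), so the ipsilateral potential is computed once
    and shifted, which keeps the grid error identical across ITDs.  Ties in
    the argmax are broken toward the smallest |ITD|.
    """
    if params is None:
        params = neuron.params
    t_grid = params.t_grid
    itds = params.itd_grid
    tau = params.tau_EPSP
    w = neuron.weights
    ipsi = neuron.is_ipsi
    lat = neuron.latencies
    v_ipsi = _vm_from_onsets(w[ipsi], lat[ipsi], t_grid, tau)
    v_contra = _vm_from_onsets(w[~ipsi], lat[~ipsi], t_grid, tau)

    shifts = np.round(itds / params.dt).astype(int)
    n = len(t_grid)
    vm = np.empty((len(itds), n))
    for k, sh in enumerate(shifts):
        if sh >= 0:
            vm[k, :sh] = v_contra[:sh]
            vm[k, sh:] = v_contra[sh:] + v_ipsi[: n - sh]
        else:
            vm[k, :sh] = v_contra[:sh] + v_ipsi[-sh:]
            vm[k, sh:] = v_contra[sh:]
    rate = firing_rate(vm, params).sum(axis=1) * params.dt / params.integration_window
    # argmax with ties toward smallest |ITD|
    best = np.flatnonzero(rate >= rate.max() - 1e-15)
    bitd = float(itds[best[np.argmin(np.abs(itds[best]))]])
    return TuningCurve(itd_grid=itds, rate=rate, bitd=bitd)


# ---------------------------------------------------------------------------
# plasticity
# ---------------------------------------------------------------------------


def apply_update(
    neuron: ModelNeuron,
    teacher_itd: float,
    kernel: STDPKernel,
    params: ModelParams,
    rng: np.random.Generator,
    max_retries: int = 8,
) -> dict:
    """One STDP update of the neuron's weights in place.

    Per-input activation jitter ~ N(0, t_SD) is drawn; the membrane potential
    and firing rate are computed; the rate is thresholded at
    R_min = R(r_min_fraction * total_weight); the raw weight change is the
    linear cross-correlation dW(tau) = sum_t R_thr(t) * kernel(tau - t) * dt,
    evaluated at each input's onset (latency + ITD shift + jitter).  If the
    kernel has a potentiation lobe and no dW value is positive, the jitter is
    redrawn; after ``max_retries`` redraws the update is skipped (the guard
    matters for neurons whose potential rarely reaches the plasticity
    threshold; because redraws are i.i.d. the acceptance probability is
    insensitive to the exact bound).  Weights are incremented, negatives
    clamped to zero, and the vector renormalised so the total weight is
    conserved.

    The potential is evaluated on the slice of the simulation grid that
    spans the active EPSPs; outside it v_m (hence R) is identically zero.

    Returns diagnostics: {'applied': bool, 'retries': int, 'dw': array}.
    """
    w = neuron.weights
    new_w, diag = _update_step(
        w, neuron.latencies, neuron.is_ipsi, teacher_itd, kernel, params, rng,
        params.r_min, max_retries,
    )
    if diag["applied"]:
        neuron.weights = new_w
    return diag


def _update_step(
    w: np.ndarray,
    lat: np.ndarray,
    ipsi: np.ndarray,
    teacher_itd: float,
    kernel: STDPKernel,
    params: ModelParams,
    rng: np.random.Generator,
    r_min: float,
    max_retries: int,
):
    """Array-level inner loop of one plasticity update (see apply_update)."""
    t_grid = params.t_grid
    t0 = t_grid[0]
    tau = params.tau_EPSP
    require_positive = kernel.variant != "depression_only"
    n_in = len(w)
    for attempt in range(max_retries + 1):
        onsets = lat + rng.normal(0.0, params.t_SD, size=n_in)
        onsets[ipsi] += teacher_itd
        lo = max(int((onsets.min() - t0) / params.dt), 0)
        hi = min(int((onsets.max() + 12.0 * tau - t0) / params.dt) + 2, len(t_grid))
        sub = t_grid[lo:hi]
        vm = _vm_from_onsets(w, onsets, sub, tau)
        r = firing_rate(vm, params)
        r_thr = np.where(r >= r_min, r, 0.0)
        idx = np.flatnonzero(r_thr)
        if idx.size == 0:
            continue
        lags = onsets[:, None] - sub[idx][None, :]
        dw = (r_thr[idx][None, :] * stdp_kernel(lags, kernel, tau)).sum(
            axis=1
        ) * params.dt
        ok = np.any(dw > 0) if require_positive else np.any(dw != 0)
        if ok:
            new_w = np.maximum(w + dw, 0.0)
            total = new_w.sum()
            if total <= 0:
                continue  # degenerate draw: all weights annihilated
            return new_w * (params.total_weight / total), {
                "applied": True, "retries": attempt, "dw": dw,
            }
    return w, {"applied": False, "retries": max_retries, "dw": np.zeros(n_in)}


@dataclass
class TrainingResult:
    """Weight and bITD trajectories of one trained neuron."""

    neuron: ModelNeuron
    checkpoints: list[int]
    weight_trajectory: list[np.ndarray]
    bitd_trajectory: list[float]
    final_curve: TuningCurve
    rng_seed: object
    skipped_updates: int = 0


DEFAULT_CHECKPOINTS = (1, 200, 400, 600, 800, 1000)


def train_neuron(
    neuron: ModelNeuron,
    teacher_itd_range: Sequence[float],
    n_updates: int,
    kernel: STDPKernel,
    params: ModelParams,
    seed,
    checkpoints: Sequence[int] = DEFAULT_CHECKPOINTS,
) -> TrainingResult:
    """Train a neuron for ``n_updates`` STDP updates.

    Each update draws a teacher ITD uniformly from ``teacher_itd_range`` and
    applies one plasticity step; the bITD (and weight vector) is recorded at
    the requested checkpoints.  Fully deterministic for a fixed seed.
    """
    if n_updates < 0:
        raise ValueError("n_updates must be >= 0")
    lo, hi = teacher_itd_range
    rng = np.random.default_rng(seed)
    cps = sorted(c for c in checkpoints if 0 < c <= n_updates)
    cps_set = set(cps)
    w_traj: list[np.ndarray] = []
    b_traj: list[float] = []
    skipped = 0
    w = neuron.weights
    lat = neuron.latencies
    ipsi = neuron.is_ipsi
    r_min = params.r_min
    for step in range(1, n_updates + 1):
        itd = rng.uniform(lo, hi)
        w, diag = _update_step(
            w, lat, ipsi, itd, kernel, params, rng, r_min, max_retries=8
        )
        if not diag["applied"]:
            skipped += 1
        if step in cps_set:
            neuron.weights = w
            w_traj.append(w.copy())
            b_traj.append(itd_rate_curve(neuron, params).bitd)
    neuron.weights = w
    final = itd_rate_curve(neuron, params)
    return TrainingResult(
        neuron=neuron,
        checkpoints=cps,
        weight_trajectory=w_traj,
        bitd_trajectory=b_traj,
        final_curve=final,
        rng_seed=seed,
        skipped_updates=skipped,
    )


# ---------------------------------------------------------------------------
# population experiments
# ---------------------------------------------------------------------------


def run_population_experiment(config: dict) -> dict:
    """Train a population of model neurons and tabulate the outcome.

    ``config`` keys:
      groups: list of {"best_freq": kHz, "n_neurons": int}
      teacher_range: [lo, hi] ms
      n_updates: int (default 1000)
      checkpoints: list of update counts (default (1,200,...,1000))
      kernel: dict of STDPKernel fields
      params: dict of ModelParams overrides
      seed: int

    Returns {"neurons": DataFrame, "weights": DataFrame} where ``neurons``
    has one row per neuron per checkpoint (plus update 0 for the initial
    bITD) with columns group_khz, neuron, update, bitd_ms, weight_entropy,
    and ``weights`` one row per input with the final weight.
    """
    import pandas as pd

    groups = config["groups"]
    if not groups:
        raise ValueError("config must list at least one group")
    for g in groups:
        if g.get("best_freq", 0) <= 0 or g.get("n_neurons", 0) < 1:
            raise ValueError(f"invalid group spec: {g}")
    teacher = tuple(config["teacher_range"])
    n_updates = int(config.get("n_updates", 1000))
    checkpoints = tuple(config.get("checkpoints", DEFAULT_CHECKPOINTS))
    params = ModelParams(**config.get("params", {}))
    kernel = STDPKernel(**config.get("kernel", {}))
    master = np.random.SeedSequence(config.get("seed", 0))

    neuron_rows = []
    weight_rows = []
    for g, g_seed in zip(groups, master.spawn(len(groups))):
        bf = g["best_freq"]
        for j, n_seed in enumerate(g_seed.spawn(g["n_neurons"])):
            init_seed, train_seed = n_seed.spawn(2)
            neuron = init_neuron(bf, params, init_seed)
            curve0 = itd_rate_curve(neuron, params)
            neuron_rows.append(
                dict(group_khz=bf, neuron=j, update=0, bitd_ms=curve0.bitd,
                     weight_entropy=_weight_entropy(neuron.weights))
            )
            result = train_neuron(
                neuron, teacher, n_updates, kernel, params, train_seed, checkpoints
            )
            for cp, w, b in zip(
                result.checkpoints, result.weight_trajectory, result.bitd_trajectory
            ):
                neuron_rows.append(
                    dict(group_khz=bf, neuron=j, update=cp, bitd_ms=b,
                         weight_entropy=_weight_entropy(w))
                )
            for inp in neuron.inputs:
                weight_rows.append(
                    dict(group_khz=bf, neuron=j, side=inp.side, freq_khz=inp.freq,
                         latency_ms=inp.latency, weight=inp.weight)
                )
    return {
        "neurons": pd.DataFrame(neuron_rows),
        "weights": pd.DataFrame(weight_rows),
    }


def _weight_entropy(w: np.ndarray) -> float:
    """Shannon entropy (nats) of the normalised weight vector; 0 when a
    single input carries all the weight."""
    p = np.asarray(w, dtype=float)
    p = p[p > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())
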