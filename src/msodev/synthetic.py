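"""Seeded generators for synthetic stimuli and juxtacellular-style recordings.

Everything the analysis pipeline consumes can be generated here with known
ground truth: multitone Zwuis stimulus sets whose primary tones and
second-order products are all unique in frequency; click recordings in which
each click evokes a biphasic extracellular AP (preceded by an eEPSP
deflection) with intensity-dependent probability and latency jitter; and
Zwuis-driven spike trains with von Mises phase locking to a best tone and a
Gabor-shaped ITD rate modulation.

The waveform shapes (difference-of-Gaussians eAP, alpha-function eEPSP,
band-limited noise) are emulation choices validated through
analysis-recovery, not biophysical models.  All generators are deterministic
under a fixed seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import special

from .spike_analysis import Recording

__all__ = [
    "ZwuisSet",
    "GroundTruth",
    "generate_zwuis",
    "synth_click_recording",
    "synth_click_itd_recording",
    "synth_zwuis_spikes",
    "eap_template",
]


# ---------------------------------------------------------------------------
# Zwuis stimulus sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZwuisSet:
    """A wideband multitone set whose primaries and second-order products
    (pairwise sums and differences) are all unique in frequency."""

    freqs_hz: tuple
    base_resolution_hz: float
    seed: object = None

    def __post_init__(self) -> None:
        if not _products_unique(self.grid_indices):
            raise ValueError("tone set violates second-order uniqueness")

    @property
    def grid_indices(self) -> list[int]:
        return [int(round(f / self.base_resolution_hz)) for f in self.freqs_hz]


def _products_unique(idx: list[int]) -> bool:
    """Exhaustive check: primaries, pairwise sums and absolute differences
    are all distinct (and nonzero)."""
    vals = list(idx)
    for a, b in itertools.combinations(sorted(idx), 2):
        vals.append(a + b)
        vals.append(b - a)
    return 0 not in vals and len(set(vals)) == len(vals)


def _singer_sidon_30() -> list[int]:
    """The 30-element Singer perfect-difference set of PG(2, 29): a Sidon set
    in [0, 870] (all pairwise differences distinct), computed in GF(29^3)."""
    q = 29
    v = q * q + q + 1
    p0 = p1 = None
    for a in range(q):
        for b in range(1, q):
            if all((x**3 + a * x + b) % q for x in range(q)):
                p1, p0 = a, b
                break
        if p0 is not None:
            break

    def mul(u, w):
        r = [0] * 5
        for i, ui in enumerate(u):
            for j, wj in enumerate(w):
                r[i + j] = (r[i + j] + ui * wj) % q
        r[1] = (r[1] - p1 * r[3] - p0 * r[4]) % q
        r[0] = (r[0] - p0 * r[3]) % q
        r[2] = (r[2] - p1 * r[4]) % q
        return (r[0], r[1], r[2])

    n_order = q**3 - 1

    def power(u, e):
        r = (1, 0, 0)
        while e:
            if e & 1:
                r = mul(r, u)
            u = mul(u, u)
            e >>= 1
        return r

    prim_factors = (2, 3, 7, 67, 271)  # prime factors of 29^3 - 1
    prim = None
    for a0 in range(q):
        for a1 in range(1, q):
            cand = (a0, a1, 0)
            if all(power(cand, n_order // p) != (1, 0, 0) for p in prim_factors):
                prim = cand
                break
        if prim:
            break
    D = set()
    x = (1, 0, 0)
    for i in range(n_order):
        if x[2] == 0:
            D.add(i % v)
        x = mul(x, prim)
    return sorted(D)


_SINGER_CACHE: dict = {}


def generate_zwuis(
    n_tones: int = 30,
    f_range_hz: tuple[float, float] = (50.0, 5000.0),
    seed=None,
    duration_s: float = 0.3,
    max_restarts: int = 200,
) -> ZwuisSet:
    """Construct a Zwuis tone set on the frequency grid set by the stimulus
    duration (tones are integer multiples of 1/duration).

    Small sets are found by seeded rejection sampling (greedy, with the
    allowed-candidate set computed exactly at every step).  Thirty tones on
    the default 3.33-Hz grid sit near the combinatorial limit where random
    search fails, so sets with n >= 25 are anchored on a rotation of the
    30-element Singer perfect-difference set (a maximal Sidon set), placed
    high in the band so that all pairwise sums clear the band; the rotation
    is drawn from the seeded stream and verified exhaustively.
    """
    if n_tones < 2:
        raise ValueError("need at least 2 tones")
    df = 1.0 / duration_s
    lo = int(math.ceil(f_range_hz[0] / df))
    hi = int(math.floor(f_range_hz[1] / df))
    if not (50.0 <= f_range_hz[0] and f_range_hz[1] <= 5000.0):
        raise ValueError("tone range must lie within [50, 5000] Hz")
    rng = np.random.default_rng(seed)
    idx = None
    if n_tones < 25:
        idx = _greedy_zwuis(n_tones, lo, hi, rng, max_restarts)
    if idx is None:
        idx = _singer_zwuis(n_tones, lo, hi, rng, max_restarts)
    if idx is None:
        raise RuntimeError(
            f"could not construct {n_tones} unique tones on the {df:.2f}-Hz grid"
        )
    return ZwuisSet(
        freqs_hz=tuple(i * df for i in sorted(idx)),
        base_resolution_hz=df,
        seed=seed,
    )


def _greedy_zwuis(n, lo, hi, rng, max_restarts):
    grid = np.arange(lo, hi + 1)
    vmax = 2 * hi + 2
    for _ in range(max_restarts):
        used = np.zeros(vmax, bool)
        S: list[int] = []
        ok = True
        for _step in range(n):
            allowed = ~used[grid]
            for a in S:
                allowed &= ~used[grid + a]
                allowed &= ~used[np.abs(grid - a)]
                allowed[grid == a] = False
            # degenerate midpoints/halves that would duplicate new products
            bad = {a // 2 for a in S if a % 2 == 0}
            for a, b in itertools.combinations(S, 2):
                if (a + b) % 2 == 0:
                    bad.add((a + b) // 2)
                if (b - a) % 2 == 0:
                    bad.add(abs(b - a) // 2)
            for bvalue in bad:
                if lo <= bvalue <= hi:
                    allowed[bvalue - lo] = False
            cand = grid[allowed]
            if cand.size == 0:
                ok = False
                break
            x = int(rng.choice(cand))
            used[x] = True
            for a in S:
                used[x + a] = True
                used[abs(x - a)] = True
            S.append(x)
        if ok and _products_unique(S):
            return S
    return None


def _singer_zwuis(n, lo, hi, rng, max_restarts):
    if n > 30:
        return None
    if "D" not in _SINGER_CACHE:
        _SINGER_CACHE["D"] = np.array(_singer_sidon_30())
    D = _SINGER_CACHE["D"]
    v = 871
    if hi - lo < v:
        return None
    for _ in range(max_restarts):
        r = int(rng.integers(0, v))
        S = np.sort((D - r) % v)
        if n < 30:
            S = np.sort(rng.choice(S, size=n, replace=False))
        cand = (S + (hi - S[-1])).tolist()  # anchor at the top of the band
        if cand[0] >= lo and _products_unique(cand):
            return cand
    return None


# ---------------------------------------------------------------------------
# ground truth and waveform templates
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Generating parameters for one synthetic cell.

    Latencies in ms, frequencies in kHz; ``facilitation`` multiplies the
    independent-coincidence binaural spike probability; the spike-probability
    sigmoid is p(I) = 1 / (1 + exp(-(I - midpoint)/slope)) in dB.
    """

    fsl_ipsi_ms: float = 4.6
    fsl_contra_ms: float = 4.9
    fsl_jitter_ms: float = 0.25
    eepsp_ap_latency_ms: float = 0.55
    eepsp_amplitude_mv: float = 0.45
    bitd_ms: float = 0.25
    best_freq_khz: float = 1.0
    kappa: float = 2.0
    facilitation: float = 1.2
    binaural_latency_advance_ms: float = 0.3
    p_midpoint_db: float = 45.0
    p_slope_db: float = 6.0
    p_click: float = 0.6
    eap_amplitude_mv: float = 2.0

    def spike_probability(self, intensity_db) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(np.asarray(intensity_db, float) - self.p_midpoint_db) / self.p_slope_db))


def eap_template(
    fs: float,
    amplitude_mv: float = 2.0,
    eepsp_amplitude_mv: float = 0.45,
    eepsp_onset_before_peak_ms: float = 0.55,
    eepsp_tau_ms: float = 0.2,
) -> tuple[np.ndarray, int]:
    """Biphasic eAP (difference of Gaussians, ~0.3 ms wide) preceded by an
    alpha-shaped eEPSP whose onset leads the eAP peak by the given lag.

    Returns (waveform, index of the eAP peak within the waveform).
    """
    pre_ms = max(1.5, eepsp_onset_before_peak_ms + 0.5)
    t = np.arange(-pre_ms, 2.5, 1e3 / fs)  # ms relative to eAP peak
    ap = amplitude_mv * (
        np.exp(-(t**2) / (2 * 0.05**2))
        - 0.55 * np.exp(-((t - 0.12) ** 2) / (2 * 0.08**2))
    )
    s = (t + eepsp_onset_before_peak_ms) / eepsp_tau_ms
    s = np.clip(s, 0.0, 50.0)
    epsp = eepsp_amplitude_mv * s * np.exp(1.0 - s)
    # EPSP ends at the AP peak: the AP takes over
    epsp[t > 0] *= np.exp(-((t[t > 0]) / 0.1) ** 2)
    wave = ap + epsp
    return wave, int(np.argmin(np.abs(t)))


def _band_limited_noise(n, fs, sigma_mv, rng, cutoff_hz=8000.0):
    white = rng.normal(0.0, 1.0, n)
    sos = _signal.butter(4, cutoff_hz, fs=fs, output="sos")
    filt = _signal.sosfiltfilt(sos, white)
    return filt / filt.std() * sigma_mv if filt.std() > 0 else filt


def _render(trace, wave, peak_idx, peak_sample):
    lo = peak_sample - peak_idx
    hi = lo + len(wave)
    if lo < 0 or hi > len(trace):
        return
    trace[lo:hi] += wave


# ---------------------------------------------------------------------------
# click recordings
# ---------------------------------------------------------------------------


def synth_click_recording(
    truth: GroundTruth,
    intensities_db=(30.0, 35.0, 40.0, 45.0, 50.0),
    n_repeats: int = 20,
    fs: float = 111600.0,
    noise_mv: float = 0.02,
    seed=None,
    inter_side_ms: float = 30.0,
    period_ms: float = 200.0,
    seal_mohm: float = 30.0,
    age_days: float = 20.0,
) -> Recording:
    """Click-intensity protocol: alternating contralateral/ipsilateral clicks
    (30 ms apart, one pair per 200-ms period) at a set of intensities.

    Each click evokes a spike with probability given by the intensity
    sigmoid; the spike is rendered as an eAP template (with its eEPSP
    precursor) at the truth latency plus Gaussian jitter.  Band-limited
    noise is added.
    """
    rng = np.random.default_rng(seed)
    rows = []
    t = 10e-3
    order = []
    for rep in range(n_repeats):
        for inten in intensities_db:
            order.append((t, "contra", inten))
            order.append((t + inter_side_ms * 1e-3, "ipsi", inten))
            t += period_ms * 1e-3
    n_samples = int(round((t + 20e-3) * fs))
    trace = _band_limited_noise(n_samples, fs, noise_mv, rng)
    wave, peak_idx = eap_template(
        fs, truth.eap_amplitude_mv, truth.eepsp_amplitude_mv,
        truth.eepsp_ap_latency_ms,
    )
    for t0, side, inten in order:
        rows.append(dict(time_s=t0, side=side, intensity_db=inten))
        if rng.random() < truth.spike_probability(inten):
            fsl = truth.fsl_ipsi_ms if side == "ipsi" else truth.fsl_contra_ms
            lat = fsl + rng.normal(0.0, truth.fsl_jitter_ms)
            _render(trace, wave, peak_idx, int(round((t0 + lat * 1e-3) * fs)))
    return Recording(
        trace=trace,
        fs=fs,
        clicks=pd.DataFrame(rows),
        meta={"seal_mohm": seal_mohm, "age_days": age_days,
              "truth_fsl_ipsi_ms": truth.fsl_ipsi_ms,
              "truth_fsl_contra_ms": truth.fsl_contra_ms,
              "truth_eepsp_ap_latency_ms": truth.eepsp_ap_latency_ms},
    )


def synth_click_itd_recording(
    truth: GroundTruth,
    itds_ms=None,
    n_repeats: int = 20,
    fs: float = 111600.0,
    noise_mv: float = 0.02,
    seed=None,
    period_ms: float = 250.0,
    seal_mohm: float = 30.0,
    age_days: float = 20.0,
) -> Recording:
    """Click-ITD protocol: binaural click pairs with varying ITD every 250 ms.

    Quasi-monaural presentations (|ITD| >= 0.5 ms) evoke a response to the
    leading ear's click with probability ``truth.p_click``; the lagging
    click's response is forward-suppressed (real MSO neurons rarely fire to
    the trailing click of a well-separated pair).  Pairs whose ITD
    compensates the interaural latency difference (within 0.13 ms) are
    facilitated: spike probability is ``facilitation`` times the
    independent-coincidence prediction (capped at 1) and the latency is
    advanced by ``binaural_latency_advance_ms``.
    """
    rng = np.random.default_rng(seed)
    delta_true = truth.fsl_contra_ms - truth.fsl_ipsi_ms
    if itds_ms is None:
        itds_ms = np.concatenate([
            np.arange(-2.0, 2.0001, 0.25),
            delta_true + np.array([-0.05, 0.0, 0.05]),
        ])
    rows = []
    t = 10e-3
    pairs = []
    for _rep in range(n_repeats):
        for itd in itds_ms:
            pairs.append((t, float(itd)))
            t += period_ms * 1e-3
    n_samples = int(round((t + 20e-3) * fs))
    trace = _band_limited_noise(n_samples, fs, noise_mv, rng)
    wave, peak_idx = eap_template(
        fs, truth.eap_amplitude_mv, truth.eepsp_amplitude_mv,
        truth.eepsp_ap_latency_ms,
    )
    p = truth.p_click
    p_bin = min(1.0, truth.facilitation * (1.0 - (1.0 - p) ** 2))
    for t0, itd in pairs:
        rows.append(dict(time_s=t0, itd_ms=itd))
        t_contra = t0
        t_ipsi = t0 + itd * 1e-3
        binaural = abs(itd - delta_true) <= 0.13
        if binaural:
            if rng.random() < p_bin:
                lat = (
                    truth.fsl_ipsi_ms
                    - truth.binaural_latency_advance_ms
                    + rng.normal(0.0, truth.fsl_jitter_ms)
                )
                _render(trace, wave, peak_idx,
                        int(round((t_ipsi + lat * 1e-3) * fs)))
        else:
            # leading ear drives; the trailing click is forward-suppressed
            if itd >= 0:
                t_click, fsl = t_contra, truth.fsl_contra_ms
            else:
                t_click, fsl = t_ipsi, truth.fsl_ipsi_ms
            if rng.random() < p:
                lat = fsl + rng.normal(0.0, truth.fsl_jitter_ms)
                _render(trace, wave, peak_idx,
                        int(round((t_click + lat * 1e-3) * fs)))
    return Recording(
        trace=trace,
        fs=fs,
        click_pairs=pd.DataFrame(rows),
        meta={"seal_mohm": seal_mohm, "age_days": age_days,
              "truth_delta_fsl_ms": delta_true,
              "truth_facilitation": truth.facilitation},
    )


# ---------------------------------------------------------------------------
# Zwuis-driven spike trains
# ---------------------------------------------------------------------------


def synth_zwuis_spikes(
    truth: GroundTruth,
    zwuis: ZwuisSet,
    itds_ms=None,
    n_repeats: int = 6,
    trial_duration_s: float = 0.3,
    base_rate_hz: float = 60.0,
    itd_sigma_ms: float = 0.6,
    itd_freq_khz: float | None = None,
    itd_power: float = 2.0,
    itd_baseline: float = 0.15,
    seed=None,
    dt_s: float = 2e-5,
) -> pd.DataFrame:
    """Per-trial spike times from an inhomogeneous Bernoulli process.

    rate(t; ITD) = base * G(ITD) * exp(kappa cos(2 pi f_best t)) / I0(kappa)

    where G is a Gabor-shaped ITD gain centred on the truth bITD.  The phase
    factor makes the spike-phase distribution at the best tone exactly von
    Mises with concentration kappa (vector strength I1(kappa)/I0(kappa));
    kappa = 0 and a flat gain give the untuned null.  Returns a DataFrame
    with columns (trial, itd_ms, spike_time_s).
    """
    from .itd_analysis import gabor

    rng = np.random.default_rng(seed)
    if itds_ms is None:
        itds_ms = np.arange(-2.0, 2.0001, 0.1)
    if itd_freq_khz is None:
        itd_freq_khz = truth.best_freq_khz
    f_hz = truth.best_freq_khz * 1e3
    # pick the zwuis tone closest to the nominal best frequency as the carrier
    tones = np.asarray(zwuis.freqs_hz)
    f_hz = float(tones[np.argmin(np.abs(tones - f_hz))])
    tgrid = np.arange(0.0, trial_duration_s, dt_s)
    phase_mod = np.exp(truth.kappa * np.cos(2 * np.pi * f_hz * tgrid))
    phase_mod /= special.i0(truth.kappa)
    gains = gabor(np.asarray(itds_ms, float), itd_baseline, 1.0 - itd_baseline,
                  truth.bitd_ms, itd_sigma_ms, itd_freq_khz, itd_power)
    out = []
    trial = 0
    for _rep in range(n_repeats):
        for itd, gain in zip(itds_ms, gains):
            rate = base_rate_hz * gain * phase_mod
            spikes = tgrid[rng.random(tgrid.size) < rate * dt_s]
            for s in spikes:
                out.append((trial, float(itd), float(s)))
            trial += 1
    return pd.DataFrame(out, columns=["trial", "itd_ms", "spike_time_s"])
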