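"""Event detection and click/eEPSP metrics for juxtacellular MSO recordings.

Loose-seal recordings of MSO principal neurons show extracellular action
potentials (eAPs) that ride on a compound extracellular EPSP (eEPSP).  The
procedures here turn a sampled voltage trace plus stimulus tables into:

* detected eAP events, using the maximum repolarization rate (the most
  negative first derivative around a candidate peak) as the detection metric,
  with a bimodality check of the metric histogram as quality control;
* first-spike latencies (FSL) to monaural clicks via a two-pass median that
  discards stragglers more than 1 ms from the provisional median;
* click-ITD metrics: quasi-monaural latencies from large-|ITD| presentations,
  the binaural presentation window (ITDs compensating the monaural latency
  difference), spike probabilities and the predicted binaural probability
  1 - (1 - P_ipsi)(1 - P_contra), plus the binaural latency shift;
* eEPSP onset/rise metrics from snippets around each eAP peak, and the
  eEPSP-to-AP latency;
* the expected SD of the FSL interaural difference under random pairing,
  sqrt(var_ipsi + var_contra).

Times are in seconds in the containers (sampling-rate world) and reported in
ms where the metric is conventionally quoted in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Recording",
    "EventSet",
    "ClickMetrics",
    "EEPSPMetrics",
    "detect_events",
    "click_fsl",
    "click_itd_metrics",
    "eepsp_metrics",
    "delta_fsl_expected_sd",
]


@dataclass
class Recording:
    """A sampled voltage trace plus its stimulus tables.

    ``trace`` in mV at ``fs`` Hz (nominally 111,600 Hz).  ``clicks`` has
    columns (time_s, side, intensity_db); ``click_pairs`` has columns
    (time_s, itd_ms) where time_s is the contralateral click onset and
    itd_ms > 0 means the contralateral click leads the ipsilateral one;
    ``zwuis`` has columns (onset_s, itd_ms) and ``zwuis_freqs_hz`` lists the
    tone frequencies.  ``meta`` carries seal_mohm and age_days.
    """

    trace: np.ndarray
    fs: float
    clicks: pd.DataFrame | None = None
    click_pairs: pd.DataFrame | None = None
    zwuis: pd.DataFrame | None = None
    zwuis_freqs_hz: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.trace = np.asarray(self.trace, dtype=float)

    @property
    def duration_s(self) -> float:
        return len(self.trace) / self.fs

    # ---- HDF5 container ---------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("trace", data=self.trace)
            f.attrs["fs"] = self.fs
            for key, val in self.meta.items():
                f.attrs[f"meta_{key}"] = val
            for name, df in (
                ("clicks", self.clicks),
                ("click_pairs", self.click_pairs),
                ("zwuis", self.zwuis),
            ):
                if df is not None:
                    grp = f.create_group(f"stimuli/{name}")
                    for col in df.columns:
                        data = df[col].to_numpy()
                        if data.dtype == object:
                            data = data.astype("S")
                        grp.create_dataset(col, data=data)
            if self.zwuis_freqs_hz is not None:
                f.create_dataset("stimuli/zwuis_freqs_hz", data=self.zwuis_freqs_hz)

    @classmethod
    def from_hdf5(cls, path) -> "Recording":
        import h5py

        with h5py.File(path, "r") as f:
            trace = f["trace"][:]
            fs = float(f.attrs["fs"])
            meta = {
                k[len("meta_"):]: (v.item() if hasattr(v, "item") else v)
                for k, v in f.attrs.items()
                if k.startswith("meta_")
            }
            dfs = {}
            for name in ("clicks", "click_pairs", "zwuis"):
                if f"stimuli/{name}" in f:
                    grp = f[f"stimuli/{name}"]
                    cols = {}
                    for col in grp:
                        data = grp[col][:]
                        if data.dtype.kind == "S":
                            data = data.astype(str)
                        cols[col] = data
                    dfs[name] = pd.DataFrame(cols)
                else:
                    dfs[name] = None
            freqs = (
                f["stimuli/zwuis_freqs_hz"][:]
                if "stimuli/zwuis_freqs_hz" in f
                else None
            )
        return cls(trace=trace, fs=fs, clicks=dfs["clicks"],
                   click_pairs=dfs["click_pairs"], zwuis=dfs["zwuis"],
                   zwuis_freqs_hz=freqs, meta=meta)


@dataclass
class EventSet:
    """Detected eAP peaks with their detection metric."""

    peak_times_s: np.ndarray
    peak_amplitudes_mv: np.ndarray
    max_repol_rate_v_per_s: np.ndarray  # positive magnitude of the repol. rate
    bimodal: bool
    threshold_v_per_s: float

    def __len__(self) -> int:
        return len(self.peak_times_s)


def _derivative(trace: np.ndarray, fs: float) -> np.ndarray:
    """Central-difference first derivative in V/s (trace in mV)."""
    return np.gradient(trace, 1.0 / fs) * 1e-3


def detect_events(
    rec: Recording, threshold_v_per_s: float, refractory_ms: float = 1.0
) -> EventSet:
    """Detect eAPs by their repolarization-rate signature.

    Candidate peaks are local maxima separated by at least ``refractory_ms``.
    For each candidate, the maximum repolarization rate is the most negative
    first-derivative value within +-0.5 ms of the peak; candidates whose rate
    magnitude exceeds ``threshold_v_per_s`` are accepted.  The per-event
    metric histogram is tested for bimodality (two- vs one-component Gaussian
    mixture on the log metric); the flag reports quality only and removes no
    events.
    """
    if threshold_v_per_s <= 0:
        raise ValueError("threshold must be positive")
    trace = rec.trace
    if len(trace) < 3:
        return EventSet(np.empty(0), np.empty(0), np.empty(0), False,
                        threshold_v_per_s)
    fs = rec.fs
    dist = max(int(round(refractory_ms * 1e-3 * fs)), 1)
    # restrict candidates to peaks that at least protrude from the noise
    prominence = 3.0 * np.median(np.abs(trace - np.median(trace))) / 0.6745
    peaks, _ = signal.find_peaks(trace, distance=dist, prominence=prominence)
    if peaks.size == 0:
        return EventSet(np.empty(0), np.empty(0), np.empty(0), False,
                        threshold_v_per_s)
    deriv = _derivative(trace, fs)
    half = int(round(0.5e-3 * fs))
    rates = np.empty(peaks.size)
    for i, pk in enumerate(peaks):
        lo, hi = max(pk - half, 0), min(pk + half + 1, len(deriv))
        rates[i] = -deriv[lo:hi].min()  # positive magnitude
    keep = rates > threshold_v_per_s
    metric = rates[keep]
    bimodal = _is_bimodal(rates) if rates.size >= 20 else False
    return EventSet(
        peak_times_s=peaks[keep] / fs,
        peak_amplitudes_mv=trace[peaks[keep]],
        max_repol_rate_v_per_s=metric,
        bimodal=bimodal,
        threshold_v_per_s=threshold_v_per_s,
    )


def _is_bimodal(metric: np.ndarray, delta_bic: float = 10.0) -> bool:
    """Two- vs one-component Gaussian mixture comparison on the log metric."""
    from sklearn.mixture import GaussianMixture

    x = np.log(metric[metric > 0]).reshape(-1, 1)
    if len(x) < 20:
        return False
    bics = []
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, random_state=0, n_init=2)
        gm.fit(x)
        bics.append(gm.bic(x))
    return bool(bics[0] - bics[1] > delta_bic)


# ---------------------------------------------------------------------------
# click latency
# ---------------------------------------------------------------------------


def _first_event_latencies(
    event_times_s: np.ndarray,
    stim_times_s: np.ndarray,
    window_ms: tuple[float, float],
) -> np.ndarray:
    """Latency (ms) of the first event in the analysis window after each
    stimulus; NaN when the window holds no event."""
    lats = np.full(len(stim_times_s), np.nan)
    lo, hi = window_ms
    for i, t0 in enumerate(stim_times_s):
        sel = event_times_s[
            (event_times_s >= t0 + lo * 1e-3) & (event_times_s <= t0 + hi * 1e-3)
        ]
        if sel.size:
            lats[i] = (sel[0] - t0) * 1e3
    return lats


def _two_pass_median(latencies_ms: np.ndarray, band_ms: float = 1.0):
    """Median latency after discarding values > band_ms from the first-pass
    median.  Returns (median, kept values); (nan, empty) without events."""
    lats = latencies_ms[~np.isnan(latencies_ms)]
    if lats.size == 0:
        return float("nan"), lats
    med1 = np.median(lats)
    kept = lats[np.abs(lats - med1) < band_ms]
    if kept.size == 0:
        return float("nan"), kept
    return float(np.median(kept)), kept


def click_fsl(
    events: EventSet,
    clicks: pd.DataFrame,
    window_ms: tuple[float, float] = (0.5, 10.5),
) -> dict:
    """First-spike latency to monaural clicks, per side.

    First events per click inside [+0.5, +10.5] ms are pooled over all
    intensities; the FSL is the two-pass median (values within 1 ms of the
    provisional median).  Per-intensity medians are computed the same way and
    the intensity latency shift is FSL minus the median latency at the
    smallest intensity with more than 3 responses.
    """
    out: dict[str, dict] = {}
    for side, grp in clicks.groupby("side"):
        lats = _first_event_latencies(
            events.peak_times_s, grp["time_s"].to_numpy(), window_ms
        )
        fsl, kept = _two_pass_median(lats)
        per_int = {}
        for inten, sub in grp.groupby("intensity_db"):
            il = _first_event_latencies(
                events.peak_times_s, sub["time_s"].to_numpy(), window_ms
            )
            med, ikept = _two_pass_median(il)
            per_int[float(inten)] = {"median_ms": med, "n_events": int(ikept.size)}
        shift = float("nan")
        for inten in sorted(per_int):
            if per_int[inten]["n_events"] > 3:
                shift = fsl - per_int[inten]["median_ms"]
                break
        out[side] = {
            "fsl_ms": fsl,
            "n_events": int(kept.size),
            "per_intensity": per_int,
            "intensity_shift_ms": shift,
        }
    return out


# ---------------------------------------------------------------------------
# click ITD
# ---------------------------------------------------------------------------


@dataclass
class ClickMetrics:
    fsl_ipsi_ms: float
    fsl_contra_ms: float
    delta_fsl_ms: float
    p_ipsi: float
    p_contra: float
    p_binaural: float | None
    p_binaural_predicted: float
    probability_ratio: float | None  # observed / predicted
    probability_ratio_vs_max: float | None  # observed / max monaural
    binaural_latency_shift_ms: float | None
    n_binaural: int


def predicted_binaural_probability(p_ipsi: float, p_contra: float) -> float:
    """Independent-coincidence prediction 1 - (1 - P_ipsi)(1 - P_contra)."""
    if not (0 <= p_ipsi <= 1 and 0 <= p_contra <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return 1.0 - (1.0 - p_ipsi) * (1.0 - p_contra)


def click_itd_metrics(
    events: EventSet,
    click_pairs: pd.DataFrame,
    window_ms: tuple[float, float] = (2.5, 8.5),
    monaural_itd_ms: float = 0.5,
    binaural_band_ms: float = 0.13,
) -> ClickMetrics:
    """Facilitation metrics from a binaural click-ITD protocol.

    Presentations with |ITD| >= 0.5 ms are treated as quasi-monaural
    irrespective of the aural order; the response is attributed to the
    leading ear, whose latency is measured from that ear's click in
    [+2.5, +8.5] ms with the two-pass median, giving the monaural latencies
    and their difference (delta = contra - ipsi).  Binaural presentations are those whose ITD lies
    within 0.13 ms of that difference (the ITD that compensates the latency
    mismatch at the coincidence detector).  Spike probabilities are events
    per presentation; the predicted binaural probability assumes independent
    monaural spike generation.  Both probability-ratio conventions (vs the
    prediction and vs the larger monaural probability) are reported, as is
    the binaural latency shift (mean binaural latency minus the ipsilateral
    monaural latency, measured from the ipsilateral click).
    """
    itds = click_pairs["itd_ms"].to_numpy()
    t_contra = click_pairs["time_s"].to_numpy()
    # itd > 0: contra leads; the ipsi click occurs itd ms later
    t_ipsi = t_contra + itds * 1e-3

    mono_c = itds >= monaural_itd_ms   # contra leads: response driven by contra
    mono_i = itds <= -monaural_itd_ms  # ipsi leads
    if not (mono_c.any() and mono_i.any()):
        raise ValueError(
            "protocol includes no quasi-monaural (|ITD| >= 0.5 ms) presentations for both ears"
        )
    lat_c = _first_event_latencies(events.peak_times_s, t_contra[mono_c], window_ms)
    lat_i = _first_event_latencies(events.peak_times_s, t_ipsi[mono_i], window_ms)
    fsl_c, kept_c = _two_pass_median(lat_c)
    fsl_i, kept_i = _two_pass_median(lat_i)
    delta = fsl_c - fsl_i

    p_contra = float(np.mean(~np.isnan(lat_c)))
    p_ipsi = float(np.mean(~np.isnan(lat_i)))
    p_pred = predicted_binaural_probability(p_ipsi, p_contra)

    binaural = np.abs(itds - delta) <= binaural_band_ms
    if binaural.any():
        lat_b = _first_event_latencies(events.peak_times_s, t_ipsi[binaural], window_ms)
        p_bin = float(np.mean(~np.isnan(lat_b)))
        kept_b = lat_b[~np.isnan(lat_b)]
        shift = float(np.mean(kept_b) - fsl_i) if kept_b.size else None
        ratio = p_bin / p_pred if p_pred > 0 else None
        ratio_max = (
            p_bin / max(p_ipsi, p_contra) if max(p_ipsi, p_contra) > 0 else None
        )
        n_bin = int(binaural.sum())
    else:
        p_bin = None
        shift = None
        ratio = None
        ratio_max = None
        n_bin = 0
    return ClickMetrics(
        fsl_ipsi_ms=fsl_i,
        fsl_contra_ms=fsl_c,
        delta_fsl_ms=delta,
        p_ipsi=p_ipsi,
        p_contra=p_contra,
        p_binaural=p_bin,
        p_binaural_predicted=p_pred,
        probability_ratio=ratio,
        probability_ratio_vs_max=ratio_max,
        binaural_latency_shift_ms=shift,
        n_binaural=n_bin,
    )


# ---------------------------------------------------------------------------
# eEPSP analysis
# ---------------------------------------------------------------------------


@dataclass
class EEPSPMetrics:
    eepsp_ap_latency_ms: float | None
    median_max_rise_v_per_s: float | None
    included: bool
    exclusion_reason: str | None
    onsets_ms_before_peak: np.ndarray
    n_skipped: int


def eepsp_metrics(
    rec: Recording,
    events: EventSet,
    snippet_ms: tuple[float, float] = (-5.0, 4.0),
    smooth_us: float = 50.0,
    sd_window_ms: tuple[float, float] = (-3.0, -0.5),
    min_seal_mohm: float = 20.0,
    min_rise_v_per_s: float = 1.0,
) -> EEPSPMetrics:
    """Extract the eEPSP onset and rise metrics around each eAP.

    Per event: a [-5, +4] ms snippet around the peak is smoothed with a
    centred 50-us moving average; the onset threshold is the lower of
    V_median + 2*SD (SD over [-3, -0.5] ms pre-peak) and V_median +
    0.1*(peak - V_median) (the one crossed first on an upward-going onset);
    the onset is the first forward threshold crossing before the peak; the
    maximal rate of rise is the largest first derivative between onset and
    0.2 ms before the peak.  The recording is excluded when the seal
    resistance is <= 20 MOhm or the median maximal rise is <= 1 V/s.  The
    eEPSP-AP latency is the median onset-to-peak interval.

    The onset is the threshold crossing that leads into the peak (the first
    sample of the supra-threshold run containing the peak): under stationary
    recording noise an absolute first crossing anywhere in the snippet would
    be dominated by chance 2-SD excursions.
    """
    seal = rec.meta.get("seal_mohm", np.inf)
    if seal <= min_seal_mohm:
        return EEPSPMetrics(None, None, False, "seal resistance <= 20 MOhm",
                            np.empty(0), 0)
    if len(events) == 0:
        return EEPSPMetrics(None, None, False, "no events", np.empty(0), 0)
    fs = rec.fs
    win = max(int(round(smooth_us * 1e-6 * fs)), 1)
    if win % 2 == 0:
        win += 1
    pre = int(round(-snippet_ms[0] * 1e-3 * fs))
    post = int(round(snippet_ms[1] * 1e-3 * fs))
    sd_lo = pre + int(round(sd_window_ms[0] * 1e-3 * fs))
    sd_hi = pre + int(round(sd_window_ms[1] * 1e-3 * fs))
    rise_end_off = int(round(0.2e-3 * fs))

    onsets = []
    rises = []
    skipped = 0
    kernel = np.ones(win) / win
    for t in events.peak_times_s:
        pk = int(round(t * fs))
        if pk - pre < 0 or pk + post >= len(rec.trace):
            skipped += 1
            continue
        snip = rec.trace[pk - pre : pk + post + 1]
        smth = np.convolve(snip, kernel, mode="same")
        v_med = np.median(smth)
        sd = np.std(smth[sd_lo:sd_hi])
        peak_v = smth[pre]
        thr = min(v_med + 2.0 * sd, v_med + 0.1 * (peak_v - v_med))
        below = np.flatnonzero(smth[: pre + 1] < thr)
        if below.size == 0 or below[-1] == pre:
            skipped += 1
            continue
        # crossing that leads into the peak: first supra-threshold sample of
        # the run containing the peak (last sub-threshold sample + 1)
        onset_idx = below[-1] + 1
        onset_ms = (pre - onset_idx) / fs * 1e3  # before the peak
        rise_seg = smth[onset_idx : max(pre - rise_end_off, onset_idx + 2)]
        rise = np.max(np.gradient(rise_seg, 1.0 / fs)) * 1e-3  # V/s
        onsets.append(onset_ms)
        rises.append(rise)
    onsets = np.asarray(onsets)
    rises = np.asarray(rises)
    if onsets.size == 0:
        return EEPSPMetrics(None, None, False, "no analysable snippets",
                            np.empty(0), skipped)
    med_rise = float(np.median(rises))
    if med_rise <= min_rise_v_per_s:
        return EEPSPMetrics(None, med_rise, False,
                            "median max rise <= 1 V/s", onsets, skipped)
    return EEPSPMetrics(
        eepsp_ap_latency_ms=float(np.median(onsets)),
        median_max_rise_v_per_s=med_rise,
        included=True,
        exclusion_reason=None,
        onsets_ms_before_peak=onsets,
        n_skipped=skipped,
    )


def delta_fsl_expected_sd(fsl_ipsi_ms, fsl_contra_ms) -> float:
    """Expected SD of the interaural FSL difference under random pairing of
    ipsi- and contralateral FSLs within an animal: sqrt(var_i + var_c) with
    sample variances.  Requires at least two values per side."""
    a = np.asarray(fsl_ipsi_ms, dtype=float)
    b = np.asarray(fsl_contra_ms, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 FSL values per side")
    return float(math.sqrt(np.var(a, ddof=1) + np.var(b, ddof=1)))
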