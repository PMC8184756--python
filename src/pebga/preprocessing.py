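"""From continuous recordings to baseline-normalized outcome-locked epochs.

The canonical broadband-gamma path: bipolar re-referencing of adjacent
contacts, stepped sub-band Hilbert envelopes (10 x 10 Hz for gamma, each
normalized to its session mean before averaging, to undo the 1/f amplitude
tilt), 250-ms smoothing, resampling to 64 Hz (15.625-ms resolution),
epoching at -3 .. +1.5 s around outcome onset, and per-trial z-scoring
against a 6-s baseline centered on the outcome (-3 .. +3 s). Lower bands
(theta 4-8, alpha 8-13, beta 13-33 Hz) follow the same path with 1- or
5-Hz steps.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import next_fast_len

ENVELOPE_RATE = 64.0  # Hz; 15.625 ms resolution
EPOCH_WINDOW = (-3.0, 1.5)
BASELINE_6S = "outcome-centered-6s"
BASELINE_PREFIX = "prefix-500ms"


@dataclass(frozen=True)
class BandSpec:
    """A frequency band analyzed as stepped sub-bands."""

    name: str
    range: tuple[float, float]
    step: float

    def __post_init__(self) -> None:
        lo, hi = self.range
        width = hi - lo
        n = width / self.step
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError(f"band {self.name}: range {self.range} not divisible by step {self.step}")

    @property
    def sub_bands(self) -> list[tuple[float, float]]:
        lo, _ = self.range
        n = int(round((self.range[1] - self.range[0]) / self.step))
        return [(lo + i * self.step, lo + (i + 1) * self.step) for i in range(n)]


GAMMA = BandSpec("gamma", (50.0, 150.0), 10.0)
BETA = BandSpec("beta", (13.0, 33.0), 5.0)
ALPHA = BandSpec("alpha", (8.0, 13.0), 1.0)
THETA = BandSpec("theta", (4.0, 8.0), 1.0)
#: combined low band used for the early/late theta-alpha features
THETA_ALPHA = BandSpec("theta_alpha", (4.0, 13.0), 1.0)

DEFAULT_BANDS = {b.name: b for b in (GAMMA, BETA, ALPHA, THETA)}


def bipolar_rereference(
    data: np.ndarray, ch_names: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Derive adjacent-contact difference channels along each electrode shaft.

    Contact labels must be shaft letters plus a contact number (``A1``,
    ``A2`` ...). Returns one channel per adjacent pair, labelled
    ``A1-A2``; a single-contact shaft yields no derivation (warned).
    """
    pat = re.compile(r"^([A-Za-z]+)(\d+)$")
    shafts: dict[str, list[tuple[int, int]]] = {}
    for idx, name in enumerate(ch_names):
        m = pat.match(name)
        if not m:
            raise ValueError(f"cannot parse contact label {name!r}")
        shafts.setdefault(m.group(1), []).append((int(m.group(2)), idx))
    out, names = [], []
    for shaft, contacts in shafts.items():
        contacts.sort()
        if len(contacts) < 2:
            warnings.warn(f"shaft {shaft} has a single contact; no bipolar derivation")
            continue
        for (na, ia), (nb, ib) in zip(contacts[:-1], contacts[1:]):
            out.append(data[ia] - data[ib])
            names.append(f"{shaft}{na}-{shaft}{nb}")
    return np.asarray(out), names


def stepped_band_envelope(
    x: np.ndarray, sfreq: float, band: BandSpec, mode: str = "stepped"
) -> np.ndarray:
    """Band-amplitude envelope as percent of the session mean, at native rate.

    ``stepped`` (default): band-pass each sub-band, take the Hilbert analytic
    amplitude, divide by its session mean x 100, then average sub-band
    envelopes. ``single``: one band-pass over the whole range (the simpler
    control variant, biased toward the low edge of wide bands).
    """
    if sfreq <= 2.0 * band.range[1]:
        raise ValueError(
            f"sampling rate {sfreq} Hz cannot resolve band {band.name} "
            f"(upper edge {band.range[1]} Hz)"
        )
    x = np.asarray(x, dtype=float)
    sub_bands = band.sub_bands if mode == "stepped" else [band.range]
    if mode not in ("stepped", "single"):
        raise ValueError(f"unknown mode {mode!r}")
    nfft = next_fast_len(len(x))
    acc = np.zeros(len(x))
    for lo, hi in sub_bands:
        sos = sps.butter(4, [lo, hi], btype="band", fs=sfreq, output="sos")
        filtered = sps.sosfiltfilt(sos, x)
        env = np.abs(sps.hilbert(filtered, N=nfft)[: len(x)])
        acc += 100.0 * env / env.mean()
    return acc / len(sub_bands)


def smooth_and_resample(
    env: np.ndarray, sfreq: float, window: float = 0.25, target_rate: float = ENVELOPE_RATE
) -> np.ndarray:
    """Centered moving average (edge-truncated) followed by decimation.

    The boxcar average is itself the anti-alias filter: at the 32-Hz output
    Nyquist a 250-ms window attenuates amplitude more than 20-fold. The
    native rate must be an integer multiple of ``target_rate``.
    """
    if window < 1.0 / target_rate:
        raise ValueError("smoothing window must cover at least one output sample")
    q = sfreq / target_rate
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"native rate {sfreq} is not an integer multiple of {target_rate}")
    w = int(round(window * sfreq))
    if w % 2 == 0:
        w += 1  # odd length keeps the average exactly centered
    kernel = np.ones(w)
    num = np.convolve(env, kernel, mode="same")
    den = np.convolve(np.ones(len(env)), kernel, mode="same")  # edge renormalization
    smoothed = num / den
    return smoothed[:: int(round(q))]


@dataclass
class EpochedPower:
    """Outcome-locked, baseline-z-scored power: trials x time at 64 Hz."""

    data: np.ndarray  # (n_trials, n_times)
    times: np.ndarray  # seconds relative to outcome onset
    trial_index: np.ndarray  # indices into the event table that survived
    baseline_mode: str
    artifact_mask: np.ndarray | None = None  # True = rejected

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def window_mean(self, window: tuple[float, float]) -> np.ndarray:
        """Per-trial mean power over a closed time window."""
        m = (self.times >= window[0]) & (self.times <= window[1])
        return self.data[:, m].mean(axis=1)

    def good_trials(self) -> np.ndarray:
        if self.artifact_mask is None:
            return np.ones(self.n_trials, dtype=bool)
        return ~self.artifact_mask


def epoch_grid(epoch: tuple[float, float] = EPOCH_WINDOW, rate: float = ENVELOPE_RATE) -> np.ndarray:
    """The outcome-locked sample grid; always contains t = 0 exactly."""
    k0 = int(round(epoch[0] * rate))
    k1 = int(round(epoch[1] * rate))
    return np.arange(k0, k1 + 1) / rate


def epoch_and_baseline(
    env: np.ndarray,
    events: pd.DataFrame,
    rate: float = ENVELOPE_RATE,
    epoch: tuple[float, float] = EPOCH_WINDOW,
    baseline_mode: str = BASELINE_6S,
) -> EpochedPower:
    """Cut outcome-locked epochs and z-score each trial against its baseline.

    ``events`` needs ``outcome_onset`` (and ``cue_onset`` for the 500-ms
    pre-fixation baseline variant). The default baseline is the 6-s window
    centered on outcome onset (-3 .. +3 s), computed per trial. Events whose
    epoch or baseline extends beyond the envelope are dropped with a warning.
    """
    times = epoch_grid(epoch, rate)
    rel = np.round(times * rate).astype(int)
    n = len(env)
    rows, kept = [], []
    for i, ev in enumerate(events.itertuples(index=False)):
        center = int(round(ev.outcome_onset * rate))
        if baseline_mode == BASELINE_6S:
            b0, b1 = center - int(3 * rate), center + int(3 * rate)
        elif baseline_mode == BASELINE_PREFIX:
            c = int(round(ev.cue_onset * rate))
            b0, b1 = c - int(0.5 * rate), c
        else:
            raise ValueError(f"unknown baseline mode {baseline_mode!r}")
        lo = min(center + rel[0], b0)
        hi = max(center + rel[-1], b1)
        if lo < 0 or hi >= n:
            continue
        baseline = env[b0 : b1 + 1]
        mu, sd = baseline.mean(), baseline.std(ddof=0)
        rows.append((env[center + rel[0] : center + rel[-1] + 1] - mu) / sd)
        kept.append(i)
    if len(kept) < len(events):
        warnings.warn(f"dropped {len(events) - len(kept)} events too close to recording edges")
    return EpochedPower(
        data=np.asarray(rows), times=times, trial_index=np.asarray(kept, dtype=int),
        baseline_mode=baseline_mode,
    )


def reject_artifact_trials(segments: np.ndarray, session_sd: float, k: float = 4.0) -> np.ndarray:
    """Flag trials whose raw activity exceeds k times the session SD.

    A trial is rejected iff any sample magnitude is *strictly* greater than
    ``k * session_sd``. Returns a boolean mask (True = artifact).
    """
    segments = np.atleast_2d(segments)
    return (np.abs(segments) > k * session_sd).any(axis=1)


def epoch_raw(
    x: np.ndarray, sfreq: float, outcome_onsets: np.ndarray, epoch: tuple[float, float] = EPOCH_WINDOW
) -> np.ndarray:
    """Cut raw-signal segments around outcome onsets (for artifact screening / TFR)."""
    k0, k1 = int(round(epoch[0] * sfreq)), int(round(epoch[1] * sfreq))
    segs = []
    for t0 in outcome_onsets:
        c = int(round(t0 * sfreq))
        if c + k0 < 0 or c + k1 >= len(x):
            raise ValueError("event too close to recording edge for raw epoching")
        segs.append(x[c + k0 : c + k1 + 1])
    return np.asarray(segs)


@dataclass
class TFRGrid:
    """Trial-averaged multitaper power on the two-regime frequency grid."""

    power: np.ndarray  # (n_freqs, n_times)
    freqs: np.ndarray
    times: np.ndarray  # seconds relative to epoch start offset


def multitaper_tfr(
    epochs: np.ndarray,
    sfreq: float,
    low_freqs: np.ndarray | None = None,
    high_freqs: np.ndarray | None = None,
) -> TFRGrid:
    """Multitaper time-frequency power of outcome-locked raw epochs.

    Two regimes: 4-32 Hz with 6-cycle windows and 3 Slepian tapers; 32-200 Hz
    with fixed 240-ms windows and a taper count growing linearly from 4 to 31
    across frequency. ``epochs`` is (n_trials, n_times); power is averaged
    across trials.
    """
    from mne.time_frequency import tfr_array_multitaper

    if low_freqs is None:
        low_freqs = np.arange(4.0, 32.0, 2.0)
    if high_freqs is None:
        high_freqs = np.arange(32.0, 200.1, 8.0)
    nyq = sfreq / 2.0
    dropped = [f for f in np.concatenate([low_freqs, high_freqs]) if f >= nyq]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} frequencies at/above Nyquist ({nyq} Hz)")
    low_freqs = np.array([f for f in low_freqs if f < nyq])
    high_freqs = np.array([f for f in high_freqs if f < nyq])

    x = epochs[:, None, :]  # (epochs, 1 channel, times)
    blocks, freq_blocks = [], []
    if len(low_freqs):
        p = tfr_array_multitaper(
            x, sfreq=sfreq, freqs=low_freqs, n_cycles=6.0, time_bandwidth=4.0,
            output="power", verbose="error",
        )
        blocks.append(p.mean(axis=0)[0])
        freq_blocks.append(low_freqs)
    if len(high_freqs):
        taper_counts = np.round(4 + 27 * (high_freqs - 32.0) / 168.0).astype(int)
        for k in np.unique(taper_counts):
            fsel = high_freqs[taper_counts == k]
            # half-bandwidth margin keeps all k tapers above MNE's
            # spectral-concentration cutoff
            p = tfr_array_multitaper(
                x, sfreq=sfreq, freqs=fsel, n_cycles=fsel * 0.24,
                time_bandwidth=float(k) + 1.5, output="power", verbose="error",
            )
            blocks.append(p.mean(axis=0)[0])
            freq_blocks.append(fsel)
    power = np.vstack(blocks)
    freqs = np.concatenate(freq_blocks)
    order = np.argsort(freqs)
    times = np.arange(epochs.shape[1]) / sfreq
    return TFRGrid(power=power[order], freqs=freqs[order], times=times)


def session_envelope(
    data: np.ndarray,
    ch_names: list[str],
    sfreq: float,
    band: BandSpec,
    mode: str = "stepped",
) -> tuple[np.ndarray, list[str]]:
    """Bipolar derivation + stepped envelope + smoothing/resampling, per site.

    Returns (n_sites, n_times64) percent-of-mean envelopes and site labels.
    """
    bip, names = bipolar_rereference(data, ch_names)
    envs = []
    for row in bip:
        e = stepped_band_envelope(row, sfreq, band, mode=mode)
        envs.append(smooth_and_resample(e, sfreq))
    return np.asarray(envs), names
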