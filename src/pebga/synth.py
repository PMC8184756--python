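"""Synthetic patients: QLr behavior plus continuous multichannel iEEG.

Each recording site is a two-contact electrode shaft. The deeper contact
carries a local source — band-limited noise carriers whose amplitude is
modulated trial-by-trial by the outcome and expectation regressors with
region-specific reward/punishment gains — while both contacts share a
distant 1/f source that cancels under bipolar derivation. This plants a
known effect structure (positive outcome coding, negative expectation
coding, reward-dominant vs punishment-dominant parcels) that the analysis
pipeline must recover.

By default only the broadband-gamma carrier carries prediction-error
information; beta and theta/alpha carriers are present but unmodulated, so
a frequency-band model comparison should find the gamma-only model
sufficient.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .edf import read_edf, write_edf
from .task import PUNISHMENT, REWARD, SessionTiming

#: parcels the anatomical pipeline can map (others are retained but flagged)
KNOWN_PARCELS = ("vmPFC", "lOFC", "aINS", "dlPFC", "HPC", "lVC", "cmVC", "mITC")

#: reward-PE-dominant and punishment-PE-dominant parcels of the planted model
REWARD_PARCELS = ("vmPFC", "lOFC")
PUNISHMENT_PARCELS = ("aINS", "dlPFC")


@dataclass(frozen=True)
class SiteSpec:
    """Ground-truth effect specification for one bipolar recording site.

    Gains are fractional amplitude modulations of the site's baseline
    band-carrier amplitude per z-unit of the corresponding regressor, applied
    inside ``response_window`` (seconds, outcome-locked). ``pre_outcome_gain``
    optionally modulates the carrier by the expectation regressor in
    ``pre_outcome_window`` before outcome onset. ``low_freq_profile`` is an
    optional (early, late) pair of theta/alpha PE gains.
    """

    site_id: str
    parcel: str
    gain_R: float = 0.0
    gain_Qr: float = 0.0
    gain_P: float = 0.0
    gain_Qp: float = 0.0
    response_band: tuple[float, float] = (50.0, 150.0)
    response_window: tuple[float, float] = (0.25, 1.0)
    pre_outcome_gain: float = 0.0
    pre_outcome_window: tuple[float, float] = (-1.2, -0.2)
    low_freq_profile: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for g in (self.gain_R, self.gain_Qr, self.gain_P, self.gain_Qp):
            if not np.isfinite(g):
                raise ValueError("gains must be finite")


#: Default planted gain table: positive outcome coding, negative expectation
#: coding everywhere; reward gains dominate in vmPFC/lOFC, punishment gains
#: in aINS/dlPFC; weak symmetric PE in HPC and visual parcels; outcome-only
#: coding in mITC.
DEFAULT_GAIN_TABLE: dict[str, dict[str, float]] = {
    "vmPFC": dict(gain_R=0.30, gain_Qr=-0.30, gain_P=0.12, gain_Qp=-0.12),
    "lOFC": dict(gain_R=0.30, gain_Qr=-0.30, gain_P=0.12, gain_Qp=-0.12),
    "aINS": dict(gain_R=0.12, gain_Qr=-0.12, gain_P=0.30, gain_Qp=-0.30),
    "dlPFC": dict(gain_R=0.12, gain_Qr=-0.12, gain_P=0.30, gain_Qp=-0.30),
    "HPC": dict(gain_R=0.15, gain_Qr=-0.15, gain_P=0.15, gain_Qp=-0.15),
    "lVC": dict(gain_R=0.15, gain_Qr=-0.15, gain_P=0.15, gain_Qp=-0.15),
    "cmVC": dict(gain_R=0.15, gain_Qr=-0.15, gain_P=0.15, gain_Qp=-0.15),
    "mITC": dict(gain_R=0.15, gain_Qr=0.0, gain_P=0.15, gain_Qp=0.0),
}

_SHAFTS = [chr(ord("A") + i) for i in range(26)]


def default_site_table(n_sites: int = 16, parcels: tuple[str, ...] = KNOWN_PARCELS) -> list[SiteSpec]:
    """Site specs cycling through the default parcels, one 2-contact shaft each."""
    specs = []
    for k in range(n_sites):
        parcel = parcels[k % len(parcels)]
        shaft = _SHAFTS[k % 26] + ("" if k < 26 else str(k // 26))
        gains = DEFAULT_GAIN_TABLE.get(parcel, {})
        specs.append(SiteSpec(site_id=f"{shaft}1-{shaft}2", parcel=parcel, **gains))
    return specs


@dataclass(frozen=True)
class NoiseConfig:
    """Amplitude budget (microvolt SD) and spectral shape of synthetic signals."""

    chi: float = 1.0  # 1/f^chi exponent of the background
    pink_sd: float = 25.0  # independent background per contact
    shared_sd: float = 40.0  # distant source common to both contacts of a shaft
    white_sd: float = 4.0
    gamma_carrier_sd: float = 7.0
    beta_carrier_sd: float = 10.0
    theta_alpha_carrier_sd: float = 15.0


@dataclass
class ContinuousRecording:
    """One session's continuous multichannel signal (microvolts)."""

    data: np.ndarray  # (n_channels, n_samples)
    sfreq: float
    ch_names: list[str]
    channels: pd.DataFrame  # name, shaft, parcel, status

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sfreq


def powerlaw_noise(n: int, chi: float, rng: np.random.Generator, sfreq: float = 1.0) -> np.ndarray:
    """Unit-SD noise with power spectral density proportional to 1/f^chi."""
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-chi / 2.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _band_carrier(n: int, band: tuple[float, float], sfreq: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD band-limited noise carrier (realistic stochastic envelope)."""
    lo, hi = band
    sos = sps.butter(4, [lo, hi], btype="band", fs=sfreq, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _window_mask(times: np.ndarray, onsets: np.ndarray, window: tuple[float, float]) -> list[slice]:
    out = []
    for t0 in onsets:
        a = np.searchsorted(times, t0 + window[0])
        b = np.searchsorted(times, t0 + window[1])
        out.append(slice(a, b))
    return out


def _modulation(
    n: int,
    sfreq: float,
    outcome_onsets: np.ndarray,
    window: tuple[float, float],
    per_trial_gain: np.ndarray,
    ramp: float = 0.1,
) -> np.ndarray:
    """Multiplicative amplitude envelope: 1 + gain inside each trial window.

    Edges are smoothed with a ``ramp``-second moving average so bursts have
    no spectral splatter; the envelope is floored at 0.05.
    """
    times = np.arange(n) / sfreq
    m = np.ones(n)
    for sl, g in zip(_window_mask(times, outcome_onsets, window), per_trial_gain):
        m[sl] += g
    w = max(int(round(ramp * sfreq)), 1)
    kernel = np.ones(w) / w
    m = np.convolve(m, kernel, mode="same")
    return np.clip(m, 0.05, None)


def _site_gain_series(spec: SiteSpec, events: pd.DataFrame) -> np.ndarray:
    """Per-trial fractional gamma-amplitude gain from the planted gain table."""
    is_reward = (events["condition"] == REWARD).to_numpy()
    r_z = events["outcome_z"].to_numpy()
    q_z = events["expectation_z"].to_numpy()
    gain = np.where(
        is_reward,
        spec.gain_R * r_z + spec.gain_Qr * q_z,
        spec.gain_P * r_z + spec.gain_Qp * q_z,
    )
    return gain


def generate_session_recording(
    site_specs: list[SiteSpec],
    behavior: pd.DataFrame,
    regressors: pd.DataFrame,
    rng: np.random.Generator | int,
    sfreq: float = 512.0,
    noise: NoiseConfig = NoiseConfig(),
    timing: SessionTiming = SessionTiming(),
) -> tuple[ContinuousRecording, pd.DataFrame]:
    """Render one behavioral session as a continuous recording plus events.

    ``regressors`` is the :func:`pebga.behavior.derive_regressors` slice for
    this session. Returns the recording (monopolar contacts; bipolar
    derivation is left to the preprocessing stage) and an event table holding
    onsets and the ground-truth regressor values per trial.
    """
    rng = np.random.default_rng(rng)
    if len(behavior) != len(regressors):
        raise ValueError("behavior and regressors must be trial-aligned")
    has_gamma = any(s.response_band[1] > sfreq / 2 for s in site_specs)
    if has_gamma:
        raise ValueError(
            f"sampling rate {sfreq} Hz puts the response band above Nyquist; "
            "use >= 512 Hz for broadband-gamma sites"
        )

    rts = behavior["rt_ms"].to_numpy() / 1000.0
    cue_onsets, outcome_onsets = timing.event_times(rts)
    duration = outcome_onsets[-1] + timing.post_task
    n = int(np.ceil(duration * sfreq))
    times = np.arange(n) / sfreq

    data = np.empty((2 * len(site_specs), n))
    ch_rows = []
    for k, spec in enumerate(site_specs):
        shaft = spec.site_id.split("-")[0].rstrip("0123456789")
        shared = noise.shared_sd * powerlaw_noise(n, noise.chi, rng, sfreq)

        gain = _site_gain_series(spec, regressors)
        m = _modulation(n, sfreq, outcome_onsets, spec.response_window, gain)
        if spec.pre_outcome_gain != 0.0:
            m *= _modulation(
                n, sfreq, outcome_onsets, spec.pre_outcome_window,
                spec.pre_outcome_gain * regressors["expectation_z"].to_numpy(),
            )
        local = noise.gamma_carrier_sd * m * _band_carrier(n, spec.response_band, sfreq, rng)
        local += noise.beta_carrier_sd * _band_carrier(n, (13.0, 33.0), sfreq, rng)
        ta = _band_carrier(n, (4.0, 13.0), sfreq, rng)
        if spec.low_freq_profile is not None:
            early, late = spec.low_freq_profile
            pe = regressors["pe_all_z"].to_numpy()
            m_ta = _modulation(n, sfreq, outcome_onsets, (0.0, 0.5), early * pe)
            m_ta *= _modulation(n, sfreq, outcome_onsets, (0.5, 1.0), late * pe)
            ta = m_ta * ta
        local += noise.theta_alpha_carrier_sd * ta

        for j in range(2):
            contact = noise.pink_sd * powerlaw_noise(n, noise.chi, rng, sfreq)
            contact += noise.white_sd * rng.standard_normal(n)
            data[2 * k + j] = shared + contact + (local if j == 0 else 0.0)
            ch_rows.append(
                {"name": f"{shaft}{j + 1}", "shaft": shaft, "parcel": spec.parcel,
                 "status": "good" if spec.parcel in KNOWN_PARCELS else "unmapped"}
            )

    events = regressors.copy()
    events["cue_onset"] = cue_onsets
    events["outcome_onset"] = outcome_onsets
    if not (np.diff(events["outcome_onset"]) > 0).all():
        raise ValueError("outcome onsets must be strictly increasing")
    rec = ContinuousRecording(
        data=data,
        sfreq=sfreq,
        ch_names=[r["name"] for r in ch_rows],
        channels=pd.DataFrame(ch_rows).drop_duplicates("name").reset_index(drop=True),
    )
    return rec, events


def write_dataset(
    root: Path | str,
    patient_id: str,
    recordings: list[ContinuousRecording],
    events: list[pd.DataFrame],
    site_specs: list[SiteSpec],
) -> Path:
    """Persist one synthetic patient: EDF per session, BIDS-iEEG-style TSVs,
    and the ground-truth gain table (the recovery oracle) as JSON."""
    root = Path(root)
    pdir = root / patient_id
    pdir.mkdir(parents=True, exist_ok=True)
    for i, (rec, ev) in enumerate(zip(recordings, events), start=1):
        write_edf(pdir / f"{patient_id}_ses-{i:02d}_ieeg.edf", rec.data, rec.sfreq,
                  rec.ch_names, patient_id=patient_id)
        ev.to_csv(pdir / f"{patient_id}_ses-{i:02d}_events.tsv", sep="\t", index=False)
    recordings[0].channels.to_csv(pdir / f"{patient_id}_channels.tsv", sep="\t", index=False)
    with open(pdir / f"{patient_id}_truth.json", "w") as fh:
        json.dump([asdict(s) for s in site_specs], fh, indent=2, default=list)
    return pdir


def read_dataset(root: Path | str, patient_id: str) -> tuple[list[ContinuousRecording], list[pd.DataFrame], list[SiteSpec]]:
    """Round-trip reader for :func:`write_dataset` (EDF via MNE)."""
    pdir = Path(root) / patient_id
    channels = pd.read_csv(pdir / f"{patient_id}_channels.tsv", sep="\t")
    recs, evs = [], []
    for edf_path in sorted(pdir.glob(f"{patient_id}_ses-*_ieeg.edf")):
        data, sfreq, ch_names = read_edf(edf_path)
        if list(channels["name"]) != ch_names:
            raise ValueError(f"channel table does not match EDF channels in {edf_path.name}")
        recs.append(ContinuousRecording(data=data, sfreq=sfreq, ch_names=ch_names, channels=channels))
        ev_path = Path(str(edf_path).replace("_ieeg.edf", "_events.tsv"))
        evs.append(pd.read_csv(ev_path, sep="\t"))
    with open(pdir / f"{patient_id}_truth.json") as fh:
        raw_specs = json.load(fh)
    specs = []
    for d in raw_specs:
        for key in ("response_band", "response_window", "pre_outcome_window"):
            d[key] = tuple(d[key])
        if d.get("low_freq_profile") is not None:
            d["low_freq_profile"] = tuple(d["low_freq_profile"])
        specs.append(SiteSpec(**d))
    return recs, evs, specs
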