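"""Synthetic ECoG generator with known phoneme coding and directed coupling.

The generator emulates a four-alternative audiovisual syllable task:
one second of silent mouth-articulation video, a 500 ms audio syllable,
and one second of post-audio video, with 16 video x audio stimulus
combinations.  Trials are epoched from -2.0 s to +1.5 s around audio
onset.

Three designated superior-temporal electrodes (posterior, middle,
anterior) carry a phoneme-specific high-gamma (75-200 Hz) burst that
starts at video onset and follows either the video or the audio identity
(``code_carrier``) on incongruent trials.  Each coding electrode receives
its own noise realization of the burst at equal base SNR; directional
coupling additionally injects the source electrode's realization into
the destination electrode, delayed by ``coupling_lag`` and scaled by
``coupling_gain``, only inside ``coupling_interval``.  A phoneme-
independent evoked response is locked to audio onset on all three coding
electrodes, largest on the middle one.  Remaining electrodes carry 1/f
background noise only.

The behavioral model reports the audio identity on congruent trials; on
incongruent trials it reports the video identity with probability
``mcgurk_prob`` and otherwise mostly the audio identity, with a small
lapse rate spread over the remaining alternatives.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    AUDIO_END,
    INTERVALS,
    PHONEMES,
    VIDEO_ONSET,
    EpochArray,
    TrialRecord,
)

#: Total standard deviation of the 1/f background, in microvolts.
NOISE_STD_UV = 40.0

#: Electrode roles in caudal-to-rostral order (Fig.-2-style layout).
ROLES = ("posterior", "middle", "anterior")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    snr is the amplitude ratio of the stimulus-locked high-gamma burst to
    the background noise within the same 75-200 Hz band.  coupling_edge
    names (source, destination) roles in caudal-to-rostral terms.
    """

    n_electrodes: int = 8
    n_trials_per_combo: int = 10
    fs: float = 1000.0
    phonemes: tuple[str, ...] = PHONEMES
    snr: float = 1.0
    code_carrier: str = "video"
    coupling_lag: float = 0.05
    coupling_gain: float = 2.0
    coupling_interval: str = "video_only"
    coupling_edge: tuple[str, str] = ("posterior", "middle")
    mcgurk_prob: float = 0.8
    lapse_prob: float = 0.1
    evoked_gain: float = 1.5
    coding_electrodes: tuple[int, int, int] = (2, 5, 7)
    t_start: float = -2.0
    t_stop: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_electrodes < 3:
            raise ValueError("need at least 3 electrodes")
        if len(self.phonemes) < 2:
            raise ValueError("need at least 2 phoneme labels")
        if self.fs < 2 * 200.0:
            raise ValueError(
                f"fs={self.fs} violates Nyquist for the 75-200 Hz band"
            )
        if self.coupling_lag >= self.t_stop - self.t_start:
            raise ValueError("coupling_lag must be shorter than the epoch")
        if not 0.0 <= self.mcgurk_prob <= 1.0:
            raise ValueError("mcgurk_prob must lie in [0, 1]")
        if not 0.0 <= self.lapse_prob <= 1.0:
            raise ValueError("lapse_prob must lie in [0, 1]")
        if self.coupling_gain < 0:
            raise ValueError("coupling_gain must be non-negative")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        if self.code_carrier not in ("video", "audio"):
            raise ValueError("code_carrier must be 'video' or 'audio'")
        if self.coupling_interval not in INTERVALS:
            raise ValueError(f"unknown coupling_interval {self.coupling_interval!r}")
        if any(r not in ROLES for r in self.coupling_edge):
            raise ValueError(f"coupling_edge roles must be among {ROLES}")
        if self.coupling_edge[0] == self.coupling_edge[1]:
            raise ValueError("coupling_edge must join two distinct roles")
        if len(set(self.coding_electrodes)) != 3:
            raise ValueError("coding_electrodes must be 3 distinct indices")
        if max(self.coding_electrodes) >= self.n_electrodes:
            raise ValueError("coding electrode index out of range")
        if self.t_start > -2.0 or self.t_stop < 1.5:
            raise ValueError("epoch must cover at least [-2.0, +1.5] s")

    @property
    def n_samples(self) -> int:
        return int(round((self.t_stop - self.t_start) * self.fs))

    @property
    def role_to_electrode(self) -> dict[str, int]:
        return dict(zip(ROLES, self.coding_electrodes))

    def channel_info(self) -> pd.DataFrame:
        roles = [""] * self.n_electrodes
        stg = [False] * self.n_electrodes
        for role, idx in self.role_to_electrode.items():
            roles[idx] = role
            stg[idx] = True
        return pd.DataFrame(
            {
                "electrode": np.arange(self.n_electrodes),
                "role": roles,
                "hemisphere": ["L"] * self.n_electrodes,
                "stg": stg,
            }
        ).set_index("electrode")


@dataclass
class GroundTruth:
    """Machine-readable record of the effects planted by a SimConfig."""

    code_carrier: str
    coupling_edge: tuple[str, str]
    coupling_interval: str
    coupling_present: bool
    expected_video_report_rate: float
    expected_decoding_order: str  # "video>audio" or "audio>video"
    coding_electrodes: tuple[int, int, int]
    #: expected sign of the caudal->rostral tendency on the coupled edge,
    #: per interval (+1 positive, 0 null).
    expected_tendency_sign: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def ground_truth(cfg: SimConfig) -> GroundTruth:
    """Summarize the effects a downstream analysis should recover."""
    cfg.validate()
    signs = {name: 0 for name in INTERVALS}
    if cfg.coupling_gain > 0 and cfg.snr > 0:
        # the destination electrode gains burst energy, hence stimulus
        # information, only inside the coupling interval
        caudal_to_rostral = ROLES.index(cfg.coupling_edge[1]) > ROLES.index(
            cfg.coupling_edge[0]
        )
        signs[cfg.coupling_interval] = 1 if caudal_to_rostral else -1
    order = "video>audio" if cfg.code_carrier == "video" else "audio>video"
    return GroundTruth(
        code_carrier=cfg.code_carrier,
        coupling_edge=cfg.coupling_edge,
        coupling_interval=cfg.coupling_interval,
        coupling_present=cfg.coupling_gain > 0,
        expected_video_report_rate=cfg.mcgurk_prob,
        expected_decoding_order=order,
        coding_electrodes=cfg.coding_electrodes,
        expected_tendency_sign=signs,
    )


# ---------------------------------------------------------------------------
# signal building blocks


def _pink_shaping(n_samples: int, fs: float) -> tuple[np.ndarray, float]:
    """rfft amplitude profile for 1/f-power noise and the variance
    fraction it places in the 75-200 Hz band."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    amp = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    amp[0] = 0.0
    power = amp**2
    band = (freqs >= 75.0) & (freqs <= 200.0)
    band_fraction = float(power[band].sum() / power.sum())
    return amp, band_fraction


def _pink_noise(rng: np.random.Generator, n_samples: int, n_channels: int,
                fs: float, std: float) -> np.ndarray:
    amp, _ = _pink_shaping(n_samples, fs)
    white = rng.standard_normal((n_channels, n_samples))
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * amp[None, :], n=n_samples, axis=1)
    shaped *= std / shaped.std(axis=1, keepdims=True)
    return shaped.T  # time x channel


def band_noise_rms(cfg: SimConfig) -> float:
    """RMS of the background noise inside 75-200 Hz (the snr reference)."""
    _, frac = _pink_shaping(cfg.n_samples, cfg.fs)
    return NOISE_STD_UV * np.sqrt(frac)


def _cosine_mask(times: np.ndarray, t_lo: float, t_hi: float,
                 ramp: float = 0.02) -> np.ndarray:
    """Unit mask over [t_lo, t_hi] with half-cosine edges of length ``ramp``."""
    m = np.zeros_like(times)
    inside = (times >= t_lo) & (times <= t_hi)
    m[inside] = 1.0
    rise = inside & (times < t_lo + ramp)
    m[rise] = 0.5 * (1 - np.cos(np.pi * (times[rise] - t_lo) / ramp))
    fall = inside & (times > t_hi - ramp)
    m[fall] = 0.5 * (1 + np.cos(np.pi * (times[fall] - (t_hi - ramp)) / ramp))
    return m


@dataclass
class _Template:
    carriers: np.ndarray  # (K,) Hz
    envelope: np.ndarray  # over the epoch time grid, zero outside the burst


def _draw_templates(rng: np.random.Generator, cfg: SimConfig,
                    times: np.ndarray) -> dict[str, _Template]:
    """One fixed random spectro-temporal template per phoneme (per seed)."""
    templates = {}
    support = _cosine_mask(times, VIDEO_ONSET, AUDIO_END, ramp=0.08)
    for ph in cfg.phonemes:
        carriers = rng.uniform(80.0, 190.0, size=3)
        env = np.zeros_like(times)
        for _ in range(3):
            c = rng.uniform(VIDEO_ONSET + 0.1, AUDIO_END - 0.1)
            w = rng.uniform(0.08, 0.25)
            h = rng.uniform(0.5, 1.0)
            env += h * np.exp(-0.5 * ((times - c) / w) ** 2)
        env *= support
        rms = np.sqrt(np.mean(env[support > 0.5] ** 2))
        env /= rms
        templates[ph] = _Template(carriers=carriers, envelope=env)
    return templates


#: Trial-to-trial variability of the induced high-gamma burst: lognormal
#: amplitude sigma, carrier-frequency jitter (Hz) and latency jitter (s).
#: Induced high-gamma is non-phase-locked and highly variable across
#: trials; these values keep single-trial, single-electrode decoding
#: well off ceiling so that planted coupling is measurable.
AMPLITUDE_SIGMA = 0.5
CARRIER_JITTER_HZ = 10.0
LATENCY_JITTER_S = 0.08


def _realize_burst(rng: np.random.Generator, tmpl: _Template,
                   times: np.ndarray, amplitude: float) -> np.ndarray:
    """Trial realization of a template: random carrier phases (induced,
    non-phase-locked activity) with per-trial amplitude, frequency and
    latency jitter around the fixed spectro-temporal template."""
    gain = np.exp(rng.normal(0.0, AMPLITUDE_SIGMA))
    shift = rng.normal(0.0, LATENCY_JITTER_S)
    carriers = tmpl.carriers + rng.normal(0.0, CARRIER_JITTER_HZ, tmpl.carriers.size)
    phases = rng.uniform(0, 2 * np.pi, size=carriers.size)
    shifted = times - shift
    env = np.interp(shifted, times, tmpl.envelope, left=0.0, right=0.0)
    carrier = np.sin(
        2 * np.pi * carriers[:, None] * (shifted - VIDEO_ONSET)[None, :]
        + phases[:, None]
    ).sum(axis=0)
    carrier /= np.sqrt(carriers.size / 2.0)  # unit-RMS carrier sum
    return amplitude * gain * env * carrier


def _evoked(rng: np.random.Generator, times: np.ndarray,
            hg_amp: float, lf_scale: float,
            ev_carriers: np.ndarray) -> np.ndarray:
    """Audio-onset-locked evoked response: a slow damped deflection plus a
    short broadband high-gamma burst."""
    lf = np.zeros_like(times)
    post = times >= 0
    lf[post] = 120.0 * lf_scale * np.exp(-times[post] / 0.15) * np.sin(
        2 * np.pi * 8.0 * times[post]
    )
    env = np.exp(-0.5 * ((times - 0.08) / 0.04) ** 2)
    phases = rng.uniform(0, 2 * np.pi, size=ev_carriers.size)
    carrier = np.sin(
        2 * np.pi * ev_carriers[:, None] * times[None, :] + phases[:, None]
    ).sum(axis=0) / np.sqrt(ev_carriers.size / 2.0)
    return lf + hg_amp * env * carrier


def _sample_response(rng: np.random.Generator, cfg: SimConfig,
                     video: str, audio: str) -> str:
    if video == audio:
        return audio
    u = rng.random()
    if u < cfg.mcgurk_prob:
        return video
    if u < cfg.mcgurk_prob + (1 - cfg.mcgurk_prob) * (1 - cfg.lapse_prob):
        return audio
    others = [p for p in cfg.phonemes if p not in (video, audio)]
    if not others:
        return audio
    return others[rng.integers(len(others))]


# ---------------------------------------------------------------------------
# main entry points


def simulate_dataset(cfg: SimConfig) -> tuple[list[TrialRecord], list[EpochArray]]:
    """Generate a full synthetic session.

    Returns one TrialRecord and one EpochArray per trial, in randomized
    presentation order.  Identical configs (including seed) yield
    bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    times = cfg.t_start + np.arange(n) / cfg.fs
    chan_info = cfg.channel_info()
    templates = _draw_templates(rng, cfg, times)
    ev_carriers = rng.uniform(80.0, 190.0, size=3)

    burst_amp = cfg.snr * band_noise_rms(cfg)
    evoked_amp = cfg.evoked_gain * band_noise_rms(cfg)
    role_to_el = cfg.role_to_electrode
    src_role, dst_role = cfg.coupling_edge
    lag_samples = int(round(cfg.coupling_lag * cfg.fs))
    couple_mask = _cosine_mask(times, *INTERVALS[cfg.coupling_interval])

    combos = [(v, a) for v in cfg.phonemes for a in cfg.phonemes]
    stim = [c for c in combos for _ in range(cfg.n_trials_per_combo)]
    order = rng.permutation(len(stim))

    trials: list[TrialRecord] = []
    epochs: list[EpochArray] = []
    for trial_id, k in enumerate(order):
        video, audio = stim[k]
        response = _sample_response(rng, cfg, video, audio)
        code_ph = video if cfg.code_carrier == "video" else audio

        data = _pink_noise(rng, n, cfg.n_electrodes, cfg.fs, NOISE_STD_UV)
        bursts = {}
        for role in ROLES:
            b = _realize_burst(rng, templates[code_ph], times, burst_amp)
            bursts[role] = b
            data[:, role_to_el[role]] += b
        if cfg.coupling_gain > 0 and lag_samples < n:
            injected = np.zeros(n)
            injected[lag_samples:] = bursts[src_role][: n - lag_samples]
            data[:, role_to_el[dst_role]] += cfg.coupling_gain * injected * couple_mask
        for role in ROLES:
            lf_scale = 1.6 if role == "middle" else 1.0
            data[:, role_to_el[role]] += _evoked(
                rng, times, evoked_amp, lf_scale, ev_carriers
            )

        trials.append(
            TrialRecord(
                trial_id=trial_id,
                video_phoneme=video,
                audio_phoneme=audio,
                response=response,
                audio_onset=0.0,
            )
        )
        epochs.append(
            EpochArray(data=data, fs=cfg.fs, t0=cfg.t_start, channel_info=chan_info)
        )
    return trials, epochs
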