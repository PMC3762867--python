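"""Multitaper spectrograms, band normalization, and difference statistics.

Spectrograms use Slepian (DPSS) tapers on a sliding window — by default a
500 ms window advanced in 10 ms steps with time-bandwidth product 7 and
the 11 leading tapers.  Power is a one-sided PSD estimate (uV^2/Hz)
averaged over tapers; window centers define the time axis and windows
that would need samples beyond the epoch are dropped, so every estimate
is computed from real data only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import dpss

from .containers import EpochArray, Spectrogram


@dataclass
class SpectrogramConfig:
    window_s: float = 0.5
    step_s: float = 0.010
    time_bandwidth: float = 7.0
    n_tapers: int = 11
    fmin: float = 0.0
    fmax: float = 250.0

    def validate(self) -> None:
        if self.n_tapers > 2 * self.time_bandwidth - 1:
            raise ValueError(
                f"n_tapers={self.n_tapers} exceeds the Slepian bound "
                f"2*NW-1={2 * self.time_bandwidth - 1:g}"
            )
        if self.n_tapers < 1:
            raise ValueError("need at least one taper")
        if self.step_s > self.window_s:
            raise ValueError("step_s must not exceed window_s")
        if not 0 <= self.fmin < self.fmax:
            raise ValueError("need 0 <= fmin < fmax")


def multitaper_spectrogram(
    epoch: EpochArray, electrode: int, cfg: SpectrogramConfig | None = None
) -> Spectrogram:
    """Sliding-window multitaper PSD for one electrode of one epoch.

    Each time-frequency cell averages ``n_tapers`` Slepian-tapered
    one-sided periodograms of the window centered at that time.
    """
    cfg = cfg or SpectrogramConfig()
    cfg.validate()
    x = epoch.data[:, electrode]
    fs = epoch.fs
    m = int(round(cfg.window_s * fs))
    step = max(int(round(cfg.step_s * fs)), 1)
    if m > x.size:
        raise ValueError("epoch shorter than one spectrogram window")

    tapers = dpss(m, cfg.time_bandwidth, cfg.n_tapers)  # (K, m), unit energy
    windows = sliding_window_view(x, m)[::step]  # (n_win, m)
    # (n_win, K, m) tapered segments -> one-sided periodograms
    tapered = windows[:, None, :] * tapers[None, :, :]
    spec = np.fft.rfft(tapered, n=m, axis=-1)
    psd = (spec.real**2 + spec.imag**2) / fs
    psd[..., 1:] *= 2.0
    if m % 2 == 0:
        psd[..., -1] /= 2.0
    power = psd.mean(axis=1)  # average over tapers

    freqs = np.fft.rfftfreq(m, 1.0 / fs)
    starts = np.arange(windows.shape[0]) * step
    times = epoch.t0 + (starts + (m - 1) / 2.0) / fs
    sel = (freqs >= cfg.fmin) & (freqs <= cfg.fmax)
    return Spectrogram(power=power[:, sel], times=times, freqs=freqs[sel])


def normalize_by_band(spec: Spectrogram, baseline: tuple[float, float]) -> Spectrogram:
    """Z-score each frequency row by its own mean and SD over the baseline
    interval (a stimulus-free stretch of the epoch)."""
    if spec.normalized:
        raise ValueError("spectrogram is already normalized")
    t_lo, t_hi = baseline
    sel = (spec.times >= t_lo) & (spec.times <= t_hi)
    if not sel.any():
        raise ValueError(f"baseline [{t_lo}, {t_hi}] not covered by spectrogram")
    base = spec.power[sel]
    mu = base.mean(axis=0)
    sd = base.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        # a row that is constant at its baseline mean z-scores to zeros;
        # zero baseline variance with genuine deviations is undefined
        dev = np.abs(spec.power[:, zero] - mu[zero]).max(axis=0)
        bad = zero[dev > 0]
        if bad.size:
            raise ValueError(
                f"zero baseline variance in frequency rows {bad.tolist()} "
                f"({spec.freqs[bad].tolist()} Hz)"
            )
        sd = sd.copy()
        sd[zero] = 1.0
    return Spectrogram(
        power=(spec.power - mu) / sd,
        times=spec.times,
        freqs=spec.freqs,
        normalized=True,
    )


def band_power(
    spec: Spectrogram, f_lo: float, f_hi: float, t_lo: float, t_hi: float
) -> float:
    """Mean power over a time-frequency rectangle (un-normalized units)."""
    if spec.normalized:
        raise ValueError("band_power expects un-normalized power")
    fsel = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    tsel = (spec.times >= t_lo) & (spec.times <= t_hi)
    if not fsel.any() or not tsel.any():
        raise ValueError("empty time-frequency selection")
    return float(spec.power[np.ix_(tsel, fsel)].mean())


def mean_spectrogram(specs: list[Spectrogram]) -> Spectrogram:
    """Average spectrograms that share a grid (e.g. over a trial set)."""
    if not specs:
        raise ValueError("no spectrograms to average")
    first = specs[0]
    for s in specs[1:]:
        if not first.same_grid(s) or s.normalized != first.normalized:
            raise ValueError("spectrogram grids or normalization states differ")
    return Spectrogram(
        power=np.mean([s.power for s in specs], axis=0),
        times=first.times,
        freqs=first.freqs,
        normalized=first.normalized,
    )


def difference_spectrogram_stat(
    spec_a: Spectrogram,
    spec_b: Spectrogram,
    t_lo: float = -1.0,
    t_hi: float = 1.0,
) -> float:
    """Mean absolute difference between two (mean) spectrograms over the
    [t_lo, t_hi] window — the scalar dissimilarity used to compare
    illusion trials with their matched controls.  Symmetric and >= 0."""
    if not spec_a.same_grid(spec_b):
        raise ValueError("spectrogram grids differ")
    tsel = (spec_a.times >= t_lo) & (spec_a.times <= t_hi)
    if spec_a.times[tsel].size == 0 or spec_a.times.min() > t_lo or spec_a.times.max() < t_hi:
        raise ValueError(f"spectrograms do not cover [{t_lo}, {t_hi}] s")
    return float(np.abs(spec_a.power[tsel] - spec_b.power[tsel]).mean())
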