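"""Peri-event spectral analysis and total power over baseline (TPoB).

The glial-excitability readout: traces are high-pass filtered at
100 Hz, short-time power spectra are computed around each stimulation
pulse (trials) and around matched pseudo-trials drawn from the
pre-stimulation baseline, and TPoB is the band-limited (100-600 Hz)
total power of the trial mean minus that of the pseudo-trial mean, in
mV².  TPoB may be negative; on an unstimulated electrode it is
null-centered.

The first 50 ms after each pulse is blanked (the stimulus artifact
rails the amplifier there), so a trial window starts at
``pulse + blank``; pseudo-trials use the same offset/spacing pattern
placed entirely before the first pulse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io import RawRecording

__all__ = [
    "TrialSet",
    "TPoBResult",
    "build_trials",
    "highpass_100",
    "peri_event_spectrogram",
    "band_power_per_trial",
    "tpob",
    "tpob_for_recording",
]

#: Conversion from µV² (trace units squared) to mV².
UV2_TO_MV2 = 1e-6


@dataclass
class TrialSet:
    """Aligned stimulation trials plus matched baseline pseudo-trials."""

    trial_starts: np.ndarray  # window starts, post-blank, in s
    pseudo_starts: np.ndarray
    window: float
    blank: float = 0.05

    def __post_init__(self) -> None:
        self.trial_starts = np.asarray(self.trial_starts, dtype=float)
        self.pseudo_starts = np.asarray(self.pseudo_starts, dtype=float)
        if self.window <= 0:
            raise ValueError("trial window must be positive")
        for name, starts in (("trials", self.trial_starts),
                             ("pseudo-trials", self.pseudo_starts)):
            if starts.size > 1 and np.min(np.diff(np.sort(starts))) < self.window:
                raise ValueError(f"{name} overlap")
        if self.trial_starts.size and self.pseudo_starts.size:
            if np.max(self.pseudo_starts) + self.window > np.min(
                self.trial_starts
            ) - self.blank:
                raise ValueError("pseudo-trials must end before the first pulse")

    @property
    def n_trials(self) -> int:
        return int(self.trial_starts.size)


def build_trials(
    pulse_times: np.ndarray,
    window: float,
    baseline_span: tuple[float, float],
    blank: float = 0.05,
) -> TrialSet:
    """One trial per pulse plus an equal count of baseline pseudo-trials.

    Pseudo-trials replicate the pulse spacing, shifted back so the last
    one ends before the first pulse.  Raises if the baseline segment is
    too short, naming the required length.
    """
    pulses = np.sort(np.asarray(pulse_times, dtype=float))
    if pulses.size == 0:
        raise ValueError("no pulses given")
    if pulses.size > 1:
        min_gap = float(np.min(np.diff(pulses)))
        if window + blank > min_gap:
            raise ValueError(
                f"trial window + blank ({window + blank:.3f} s) exceeds the "
                f"inter-pulse interval ({min_gap:.3f} s)"
            )
    b0, b1 = baseline_span
    span_needed = (pulses[-1] - pulses[0]) + blank + window
    avail = min(b1, pulses[0]) - b0
    if avail < span_needed:
        raise ValueError(
            f"baseline segment too short for matched pseudo-trials: need "
            f"{span_needed:.2f} s, have {avail:.2f} s"
        )
    trial_starts = pulses + blank
    offset = trial_starts[-1] + window - (min(b1, pulses[0]))
    pseudo_starts = trial_starts - offset - 1e-9
    if pseudo_starts[0] < b0:
        raise ValueError("baseline segment too short for matched pseudo-trials")
    return TrialSet(trial_starts=trial_starts, pseudo_starts=pseudo_starts,
                    window=window, blank=blank)


def highpass_100(trace: np.ndarray, fs: float, cutoff: float = 100.0,
                 order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth high-pass with -3 dB at ``cutoff``."""
    if fs <= 2 * cutoff:
        raise ValueError("fs must exceed twice the cutoff")
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=np.float64), axis=-1)


def peri_event_spectrogram(
    trace: np.ndarray,
    fs: float,
    starts: np.ndarray,
    window: float,
    stft_window: float = 0.25,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time power spectral density per trial.

    Returns ``(freqs, times, S)`` where ``S`` has shape
    (n_trials, n_freqs, n_times) in µV²/Hz (density scaling, Hann
    window), times relative to the trial start.  Summing
    ``S * df * dt_fraction`` over frequency and averaging over frames
    recovers the windowed signal variance (Parseval).
    """
    trace = np.asarray(trace, dtype=np.float64)
    nperseg = int(round(stft_window * fs))
    if nperseg > int(window * fs):
        raise ValueError("stft window must not exceed the trial window")
    noverlap = int(round(nperseg * overlap))
    n_win = int(round(window * fs))
    specs = []
    freqs = times = None
    for t0 in np.asarray(starts, dtype=float):
        i0 = int(round(t0 * fs))
        seg = trace[i0 : i0 + n_win]
        f, t, S = signal.spectrogram(
            seg, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
            detrend=False, scaling="density", mode="psd",
        )
        freqs, times = f, t
        specs.append(S)
    return freqs, times, np.array(specs)


def band_power_per_trial(
    freqs: np.ndarray, S: np.ndarray, band: tuple[float, float]
) -> np.ndarray:
    """Band-limited power per trial, in trace units squared (µV²).

    Integrates the PSD over the band and averages over STFT frames, so
    the value is the band-limited variance of the trial window.
    """
    lo, hi = band
    if lo < freqs.min() - 1e-9 or hi > freqs.max() + 1e-9:
        raise ValueError(
            f"band {band} outside the spectrogram range "
            f"[{freqs.min():.1f}, {freqs.max():.1f}] Hz"
        )
    df = freqs[1] - freqs[0]
    sel = (freqs >= lo) & (freqs <= hi)
    return (S[:, sel, :].sum(axis=1) * df).mean(axis=1)


def tpob(
    trial_powers: np.ndarray,
    pseudo_powers: np.ndarray,
) -> float:
    """Total power over baseline: mean trial band power minus mean
    pseudo-trial band power, converted to mV².  Exactly 0 when trials
    and pseudo-trials are the same windows; may be negative.
    """
    trial_powers = np.asarray(trial_powers, dtype=float)
    pseudo_powers = np.asarray(pseudo_powers, dtype=float)
    if trial_powers.size == 0 or pseudo_powers.size == 0:
        raise ValueError("both trial sets must be nonempty")
    return float((trial_powers.mean() - pseudo_powers.mean()) * UV2_TO_MV2)


@dataclass
class TPoBResult:
    table: pd.DataFrame  # electrode, stimulated, tpob_mv2, n_trials
    band: tuple[float, float]


def tpob_for_recording(
    rec: RawRecording,
    pulse_times: np.ndarray,
    stimulated: set[tuple[str, int]] | None = None,
    band: tuple[float, float] = (100.0, 600.0),
    window: float = 3.5,
    blank: float = 0.05,
    stft_window: float = 0.25,
    overlap: float = 0.5,
    highpass_hz: float = 100.0,
) -> TPoBResult:
    """Full TPoB chain for every electrode of a stimulation recording."""
    pulses = np.sort(np.asarray(pulse_times, dtype=float))
    trials = build_trials(pulses, window, baseline_span=(0.0, pulses[0]),
                          blank=blank)
    stimulated = stimulated or set()
    rows = []
    for row, key in enumerate(rec.electrode_ids):
        filt = highpass_100(rec.traces[row], rec.fs, cutoff=highpass_hz)
        f, _, S_tr = peri_event_spectrogram(
            filt, rec.fs, trials.trial_starts, window, stft_window, overlap
        )
        _, _, S_ps = peri_event_spectrogram(
            filt, rec.fs, trials.pseudo_starts, window, stft_window, overlap
        )
        p_tr = band_power_per_trial(f, S_tr, band)
        p_ps = band_power_per_trial(f, S_ps, band)
        rows.append(
            {
                "well": key[0],
                "electrode": key[1],
                "stimulated": tuple(key) in stimulated,
                "tpob_mv2": tpob(p_tr, p_ps),
                "n_trials": trials.n_trials,
            }
        )
    return TPoBResult(table=pd.DataFrame(rows), band=band)
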