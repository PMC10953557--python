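"""Ground-truth-known synthetic multi-well MEA plates.

The generator produces spike trains whose statistical structure matches
what a mature iPSC sensory/glia co-culture shows on a multi-well MEA:

* per-electrode background firing is homogeneous Poisson, with
  electrode-to-electrode rate heterogeneity (lognormal, CV ~0.6 — the
  dispersion a well-firing plate shows around a ~3.5 Hz mean);
* network bursts are a shared well-level Poisson event process; during
  each event every electrode independently joins with probability
  ``burst_participation`` (the synchrony knob) and emits a Poisson
  number of spikes at the intra-burst rate;
* voltage rendering places a charge-balanced biphasic template (~8 µV
  scale against ~1.5 µV Gaussian noise) at each spike time;
* bolus drug effects ramp in with a single-exponential,
  diffusion-delayed onset;
* electrical stimulation sessions add a decaying artifact transient on
  all electrodes and a band-limited (100–600 Hz) oscillation burst on
  stimulated electrodes only;
* temperature ramps (37→42 °C) scale the rate of an agonist-sensitive
  responder subpopulation multiplicatively per degree.

All generators are deterministic under a seed; per-well substreams are
derived from the root seed with ``numpy`` ``SeedSequence`` spawn keys,
so adding wells never perturbs existing ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import PlateLayout, RawRecording, SpikeTrainSet

__all__ = [
    "WellActivityParams",
    "TreatmentEffect",
    "WaveformModel",
    "StimProtocol",
    "DIV27",
    "TNF_ALPHA",
    "LIDOCAINE",
    "simulate_well_trains",
    "simulate_spike_trains",
    "render_voltage",
    "apply_treatment",
    "simulate_ocat_session",
    "simulate_temperature_ramp",
    "well_rng",
]

#: Minimum inter-spike interval enforced on generated trains (matches
#: the detector dead time).
MIN_ISI = 0.001


def well_rng(seed: int, well_index: int, stream: int = 0) -> np.random.Generator:
    """Named substream for one well; stable under plate growth."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(well_index, stream))
    return np.random.default_rng(ss)


@dataclass
class WellActivityParams:
    """Statistical description of one well's spontaneous activity.

    ``baseline_rate`` is the mean background rate per active electrode
    (Hz); ``rate_cv`` the lognormal electrode-to-electrode coefficient
    of variation around it.  Network bursts occur at ``burst_rate``
    events/s; each electrode joins an event with probability
    ``burst_participation`` and fires ~Poisson(intra_burst_rate x
    burst_duration) spikes spread over the event.
    """

    baseline_rate: float = 1.0
    burst_rate: float = 0.063
    burst_participation: float = 0.5
    intra_burst_rate: float = 85.0
    burst_duration: float = 1.0
    fraction_active: float = 0.97
    rate_cv: float = 0.59

    def __post_init__(self) -> None:
        for name in ("baseline_rate", "burst_rate", "intra_burst_rate",
                     "burst_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("burst_participation", "fraction_active"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rate_cv < 0:
            raise ValueError("rate_cv must be non-negative")

    @property
    def mean_rate(self) -> float:
        """Expected per-electrode rate including burst spikes (active electrodes)."""
        burst = (
            self.burst_rate
            * self.burst_participation
            * self.intra_burst_rate
            * self.burst_duration
        )
        return self.baseline_rate + burst


#: Mature-plate preset: a stable co-culture around 27 days in vitro.
#: Calibrated so the realized per-electrode mean firing rate is ~3.55 Hz
#: with wide electrode-to-electrode dispersion, and the within-well
#: synchrony score lands mid-range (~0.3-0.6).
DIV27 = WellActivityParams()


@dataclass
class TreatmentEffect:
    """Bolus-addition drug effect with diffusion-delayed onset.

    After addition at ``t_add`` the instantaneous rate follows
    ``r(t) = r0 * (1 + (rate_factor - 1) * (1 - exp(-(t - t_add)/onset_tau)))``.
    ``applies_to`` is the fraction of electrodes affected;
    ``synchrony_delta`` shifts the burst-participation probability
    (clipped to [0, 1]) when the effect is applied at the parameter
    level.
    """

    rate_factor: float = 1.0
    synchrony_delta: float = 0.0
    onset_tau: float = 10.0
    applies_to: float = 1.0

    def __post_init__(self) -> None:
        if self.rate_factor < 0:
            raise ValueError("rate_factor must be non-negative")
        if self.onset_tau < 0:
            raise ValueError("onset_tau must be non-negative")
        if not 0 <= self.applies_to <= 1:
            raise ValueError("applies_to must lie in [0, 1]")

    def rate_multiplier(self, t: np.ndarray | float, t_add: float) -> np.ndarray:
        """Multiplicative rate modulation at time(s) ``t`` (1 before t_add)."""
        t = np.asarray(t, dtype=float)
        dt = np.clip(t - t_add, 0.0, None)
        if self.onset_tau == 0:
            onset = (t >= t_add).astype(float)
        else:
            onset = np.where(t >= t_add, 1.0 - np.exp(-dt / self.onset_tau), 0.0)
        return 1.0 + (self.rate_factor - 1.0) * onset


#: Inflammatory-cytokine arm: 24 h incubation with 50 ng/ml TNF-alpha
#: produces a hyperexcitable phenotype.  The rate factor 2.6 corresponds
#: to a difference-over-sum MFR change of ~+0.45.
TNF_ALPHA = TreatmentEffect(rate_factor=2.6, onset_tau=10.0)

#: Sodium-channel-blocking control arm: 100 µM lidocaine suppresses
#: nearly all firing.
LIDOCAINE = TreatmentEffect(rate_factor=0.1, onset_tau=10.0)


@dataclass
class WaveformModel:
    """Biphasic extracellular spike template in Gaussian noise.

    The template is the first derivative of a Gaussian — biphasic and
    charge balanced (integrates to ~0) — scaled so the dominant
    (negative) peak is ``amplitude`` µV.  ``jitter_cv`` is the
    per-event amplitude coefficient of variation.
    """

    amplitude: float = 12.0
    noise_sd: float = 1.5
    width_s: float = 0.0004  # Gaussian sigma of the underlying pulse
    duration_s: float = 0.0024
    jitter_cv: float = 0.1
    negative_first: bool = True

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def template(self, fs: float) -> tuple[np.ndarray, int]:
        """Sampled template and the index of its dominant peak."""
        n = max(int(round(self.duration_s * fs)), 5)
        t = (np.arange(n) - n // 2) / fs
        w = self.width_s
        shape = t / w * np.exp(0.5 - 0.5 * (t / w) ** 2)  # peak magnitude 1
        if not self.negative_first:
            shape = -shape
        shape = shape - shape.mean()  # exact charge balance after sampling
        shape = shape / np.max(np.abs(shape))
        tmpl = self.amplitude * shape
        # Spike-time convention: the FIRST dominant lobe (what a
        # threshold detector fires on), not the later lobe.
        peak = int(np.flatnonzero(np.abs(tmpl) >= 0.9 * np.max(np.abs(tmpl)))[0])
        return tmpl, peak


@dataclass
class StimProtocol:
    """Electrical stimulation session: biphasic pulses plus the evoked
    oscillation (OCaT) on stimulated electrodes.

    Defaults follow the stimulation used for glial readouts: 10
    repetitions of 800 mV, 600 µs/phase charge-balanced biphasic pulses
    applied every 4 s.  The recorded stimulus artifact is modelled as a
    decaying transient on every electrode; the evoked response is a
    band-limited (100–600 Hz) oscillation burst present only on
    stimulated electrodes.
    """

    pulse_amplitude_mv: float = 800.0
    phase_width_us: float = 600.0
    n_pulses: int = 10
    interval_s: float = 4.0
    artifact_amplitude_uv: float = 300.0
    artifact_tau_s: float = 0.004
    response_freq_hz: float = 250.0
    response_duration_s: float = 1.0
    response_delay_s: float = 0.15
    response_amplitude_uv: float = 10.0

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if not 100.0 <= self.response_freq_hz <= 600.0:
            raise ValueError("response_freq_hz must lie in the 100-600 Hz band")
        needed = self.response_delay_s + self.response_duration_s
        if self.interval_s <= needed:
            raise ValueError(
                "inter-pulse interval must exceed artifact + response duration"
            )


# ---------------------------------------------------------------------------
# Spike-train generation
# ---------------------------------------------------------------------------

def _enforce_min_isi(ts: np.ndarray, min_isi: float = MIN_ISI) -> np.ndarray:
    """Delete spikes closer than ``min_isi`` to their predecessor."""
    if ts.size < 2:
        return ts
    keep = [0]
    last = ts[0]
    for i in range(1, ts.size):
        if ts[i] - last >= min_isi:
            keep.append(i)
            last = ts[i]
    return ts[keep]


def _poisson_times(rate: float, duration: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0 or duration <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def simulate_well_trains(
    params: WellActivityParams,
    n_electrodes: int,
    duration: float,
    rng: np.random.Generator,
) -> tuple[dict[int, np.ndarray], dict]:
    """Simulate one well; returns trains and a ground-truth record.

    Ground truth carries the network-burst event times, per-event
    participation masks, and the per-electrode background rates.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    active = rng.random(n_electrodes) < params.fraction_active
    if params.rate_cv > 0:
        sigma = np.sqrt(np.log1p(params.rate_cv**2))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_electrodes)
    else:
        factors = np.ones(n_electrodes)
    rates = np.where(active, params.baseline_rate * factors, 0.0)

    events = _poisson_times(params.burst_rate, duration, rng)
    participation = rng.random((events.size, n_electrodes)) < params.burst_participation
    participation &= active[None, :]

    trains: dict[int, np.ndarray] = {}
    for e in range(n_electrodes):
        ts = _poisson_times(rates[e], duration, rng)
        chunks = [ts]
        for i, t_e in enumerate(events):
            if participation[i, e]:
                n = rng.poisson(params.intra_burst_rate * params.burst_duration)
                if n:
                    chunks.append(
                        np.clip(
                            t_e + np.sort(rng.uniform(0, params.burst_duration, n)),
                            0.0,
                            duration,
                        )
                    )
        ts = np.sort(np.concatenate(chunks)) if len(chunks) > 1 else ts
        ts = np.unique(ts)
        trains[e] = _enforce_min_isi(ts)

    truth = {
        "event_times": events,
        "participation": participation,
        "background_rates": rates,
        "active_mask": active,
    }
    return trains, truth


def simulate_spike_trains(
    layout: PlateLayout,
    params_by_well: dict[str, WellActivityParams] | WellActivityParams,
    duration: float,
    seed: int,
) -> tuple[SpikeTrainSet, dict[str, dict]]:
    """Simulate a plate of wells; deterministic under ``seed``.

    ``params_by_well`` may be a single parameter set applied to every
    well or a per-well mapping.  Returns the spike trains and per-well
    ground truth.
    """
    trains: dict[tuple[str, int], np.ndarray] = {}
    truth: dict[str, dict] = {}
    for wi, well in enumerate(layout.wells):
        p = (
            params_by_well
            if isinstance(params_by_well, WellActivityParams)
            else params_by_well[well]
        )
        rng = well_rng(seed, wi)
        wt, gt = simulate_well_trains(p, layout.electrodes_per_well, duration, rng)
        for e, ts in wt.items():
            trains[(well, e)] = ts
        truth[well] = gt
    return SpikeTrainSet(trains=trains, duration=duration), truth


# ---------------------------------------------------------------------------
# Voltage rendering
# ---------------------------------------------------------------------------

def render_voltage(
    trains: SpikeTrainSet,
    waveform: WaveformModel,
    fs: float,
    seed: int,
    duration: float | None = None,
) -> RawRecording:
    """Render spike trains into noisy voltage traces.

    Each spike adds an amplitude-jittered copy of the biphasic template
    onto independent Gaussian noise, with the template's dominant peak
    aligned to the spike timestamp.
    """
    if fs < 10_000:
        raise ValueError("fs must be >= 10 kHz for the template to be representable")
    if duration is None:
        duration = trains.duration
    n_samples = int(round(duration * fs))
    tmpl, peak = waveform.template(fs)
    rate = trains.n_spikes / max(len(trains.trains), 1) / duration
    if rate > 0 and 1.0 / max(rate, 1e-12) < len(tmpl) / fs:
        warnings.warn(
            "mean inter-spike interval shorter than the template: spike "
            "waveforms will overlap",
            stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    ids = sorted(trains.trains.keys())
    traces = rng.normal(0.0, waveform.noise_sd, size=(len(ids), n_samples))
    for row, key in enumerate(ids):
        ts = trains.trains[key]
        if not ts.size:
            continue
        amp = rng.normal(1.0, waveform.jitter_cv, size=ts.size)
        centers = np.round(ts * fs).astype(int)
        for c, a in zip(centers, amp):
            start = c - peak
            stop = start + len(tmpl)
            lo = max(start, 0)
            hi = min(stop, n_samples)
            if hi <= lo:
                continue
            traces[row, lo:hi] += a * tmpl[lo - start : hi - start]
    return RawRecording(traces=traces, fs=fs, electrode_ids=ids)


# ---------------------------------------------------------------------------
# Treatment modulation
# ---------------------------------------------------------------------------

def apply_treatment(
    trains: SpikeTrainSet,
    effect: TreatmentEffect,
    t_add: float,
    seed: int,
) -> tuple[SpikeTrainSet, dict]:
    """Modulate existing trains by a drug effect added at ``t_add``.

    Rate reductions are realised by thinning spikes after ``t_add``
    with the time-dependent keep probability ``r(t)/r0``; increases by
    superposing an extra Poisson process at rate ``r0 * (m(t) - 1)``
    where ``m`` is the onset-shaped multiplier.  Burst spikes are
    thinned like background spikes, so the whole process scales.

    Returns the modulated trains plus a ground-truth record (affected
    electrodes, the effect, ``t_add``).
    """
    if not 0 <= t_add <= trains.duration:
        raise ValueError("t_add must fall within the recording")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    ids = sorted(trains.trains.keys())
    affected = {
        key: bool(rng.random() < effect.applies_to) for key in ids
    }
    out: dict[tuple[str, int], np.ndarray] = {}
    duration = trains.duration
    for key in ids:
        ts = trains.trains[key]
        if not affected[key] or effect.rate_factor == 1.0:
            out[key] = ts.copy()
            continue
        mult = effect.rate_multiplier(ts, t_add)
        if effect.rate_factor < 1.0:
            keep = rng.random(ts.size) < np.minimum(mult, 1.0)
            new = ts[keep]
        else:
            new = ts
        if effect.rate_factor > 1.0:
            # Superpose extra spikes via thinning of a dominating process.
            r0 = ts[ts < t_add].size / max(t_add, 1e-9) if t_add > 0 else (
                ts.size / duration
            )
            extra_max = r0 * (effect.rate_factor - 1.0)
            cand = _poisson_times(extra_max, duration - t_add, rng) + t_add
            if cand.size:
                m = effect.rate_multiplier(cand, t_add) - 1.0
                keep = rng.random(cand.size) < m / max(
                    effect.rate_factor - 1.0, 1e-12
                )
                new = np.sort(np.concatenate([new, cand[keep]]))
        out[key] = _enforce_min_isi(np.unique(new))
    truth = {"affected": affected, "effect": effect, "t_add": t_add}
    return SpikeTrainSet(trains=out, duration=duration), truth


# ---------------------------------------------------------------------------
# Stimulation sessions (OCaT)
# ---------------------------------------------------------------------------

def _artifact_shape(protocol: StimProtocol, fs: float) -> np.ndarray:
    """Decaying biphasic transient: what the amplifier records of a pulse."""
    n = int(round(5 * protocol.artifact_tau_s * fs))
    t = np.arange(n) / fs
    carrier = np.sign(np.sin(2 * np.pi * t / (2 * protocol.phase_width_us * 1e-6)))
    # The first millisecond rails; afterwards exponential recovery.
    return (
        protocol.artifact_amplitude_uv
        * np.exp(-t / protocol.artifact_tau_s)
        * np.where(t < 2 * protocol.phase_width_us * 1e-6, carrier, 1.0)
    )


def _oscillation_burst(protocol: StimProtocol, fs: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Gaussian-envelope sinusoid in the 100-600 Hz band (one trial)."""
    n = int(round(protocol.response_duration_s * fs))
    t = np.arange(n) / fs
    env = np.exp(
        -0.5 * ((t - protocol.response_duration_s / 2)
                / (protocol.response_duration_s / 4)) ** 2
    )
    phase = rng.uniform(0, 2 * np.pi)
    return protocol.response_amplitude_uv * env * np.sin(
        2 * np.pi * protocol.response_freq_hz * t + phase
    )


def simulate_ocat_session(
    n_electrodes: int,
    protocol: StimProtocol,
    stimulated: set[int] | list[int],
    noise_sd: float,
    seed: int,
    fs: float = 12_500.0,
    baseline_s: float = 45.0,
    well: str = "A1",
) -> tuple[RawRecording, np.ndarray]:
    """Simulate a stimulation session for one well.

    A baseline segment precedes the pulse train.  Every electrode
    receives the stimulus artifact at each pulse; only electrodes in
    ``stimulated`` additionally receive the post-pulse oscillation
    burst.  Returns the recording and the pulse times.
    """
    stimulated = set(stimulated)
    if not stimulated <= set(range(n_electrodes)):
        raise ValueError("stimulated electrodes must be a subset of the well")
    total = baseline_s + protocol.n_pulses * protocol.interval_s
    n_samples = int(round(total * fs))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    traces = rng.normal(0.0, noise_sd, size=(n_electrodes, n_samples))
    pulse_times = baseline_s + protocol.interval_s * np.arange(protocol.n_pulses)
    artifact = _artifact_shape(protocol, fs)
    for e in range(n_electrodes):
        for tp in pulse_times:
            i0 = int(round(tp * fs))
            hi = min(i0 + len(artifact), n_samples)
            traces[e, i0:hi] += artifact[: hi - i0]
            if e in stimulated:
                burst = _oscillation_burst(protocol, fs, rng)
                j0 = int(round((tp + protocol.response_delay_s) * fs))
                hj = min(j0 + len(burst), n_samples)
                traces[e, j0:hj] += burst[: hj - j0]
    ids = [(well, e) for e in range(n_electrodes)]
    rec = RawRecording(traces=traces, fs=fs, electrode_ids=ids)
    return rec, pulse_times


# ---------------------------------------------------------------------------
# Temperature ramp
# ---------------------------------------------------------------------------

def simulate_temperature_ramp(
    params: WellActivityParams,
    n_electrodes: int,
    responder_fraction: float,
    gain_per_deg: float,
    seed: int,
    baseline_s: float = 300.0,
    ramp_rate_deg_per_s: float = 1.0 / 30.0,
    hold_s: float = 120.0,
    t_start: float = 37.0,
    t_stop: float = 42.0,
    well: str = "A1",
) -> tuple[SpikeTrainSet, dict]:
    """Simulate a stage-temperature ramp from 37 to 42 °C.

    Responder electrodes scale their rate by ``gain_per_deg`` per
    degree above 37 °C (multiplicative: rate x gain^(T-37));
    non-responders are unchanged.  The returned ground truth carries
    the responder mask, epoch boundaries, and per-degree times.
    """
    if not 0 <= responder_fraction <= 1:
        raise ValueError("responder_fraction must lie in [0, 1]")
    if gain_per_deg <= 0:
        raise ValueError("gain_per_deg must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    ramp_s = (t_stop - t_start) / ramp_rate_deg_per_s
    duration = baseline_s + ramp_s + hold_s
    responders = rng.random(n_electrodes) < responder_fraction

    def temperature(t: np.ndarray) -> np.ndarray:
        return np.clip(t_start + (t - baseline_s) * ramp_rate_deg_per_s,
                       t_start, t_stop)

    max_gain = gain_per_deg ** (t_stop - t_start)
    trains: dict[tuple[str, int], np.ndarray] = {}
    sigma = np.sqrt(np.log1p(params.rate_cv**2)) if params.rate_cv > 0 else 0.0
    for e in range(n_electrodes):
        factor = rng.lognormal(-0.5 * sigma**2, sigma) if sigma else 1.0
        r0 = params.baseline_rate * factor
        if responders[e] and max_gain != 1.0:
            # Inhomogeneous Poisson by thinning a dominating process.
            r_max = r0 * max(max_gain, 1.0)
            cand = _poisson_times(r_max, duration, rng)
            if cand.size:
                rate = r0 * gain_per_deg ** (temperature(cand) - t_start)
                keep = rng.random(cand.size) < rate / r_max
                ts = cand[keep]
            else:
                ts = cand
        else:
            ts = _poisson_times(r0, duration, rng)
        trains[(well, e)] = _enforce_min_isi(ts)

    degree_times = baseline_s + np.arange(1, int(t_stop - t_start) + 1) / (
        ramp_rate_deg_per_s
    )
    truth = {
        "responders": responders,
        "baseline_epoch": (0.0, baseline_s),
        "ramp_epoch": (baseline_s, duration),
        "degree_times": degree_times,
        "gain_per_deg": gain_per_deg,
    }
    return SpikeTrainSet(trains=trains, duration=duration), truth
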