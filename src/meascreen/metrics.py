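"""Electrode-, well-, and plate-level activity and synchrony metrics.

Conventions:

* An electrode is *active* iff it fires at least 1 spike per minute
  (boundary inclusive); a well is *active* iff it has at least 5 active
  electrodes.  Inactive electrodes are excluded from rate metrics;
  inactive wells are flagged and excluded from aggregation.
* AEY% — active electrode yield — is the percentage of electrodes in
  scope (whole plate or one treatment group) that are active.
* MFR is the per-electrode spike rate; a well's MFR averages its active
  electrodes; WMFR divides the well's total spike count by
  (active electrodes x duration).  For equal-duration electrodes the
  two coincide.
* ISI CoV is SD/mean of inter-spike intervals (1 for Poisson firing,
  >1 for bursty firing); undefined below 2 intervals.
* AUNCC — area under the normalized cross-correlogram — scores each
  electrode pair by binning both trains (5 ms bins), forming
  ``NCC(tau) = sum x(t) y(t+tau) / sqrt(sum x^2 * sum y^2)`` for
  ``tau`` in ±100 ms, and dividing the positive area of the NCC by the
  positive area of the same-window autocorrelogram of the
  higher-count train.  A duplicated train scores exactly 1; independent
  Poisson trains score near 0.  The well value is the mean over pairs,
  clipped to [0, 1].
* Bursts are maximal runs of ≥5 spikes with consecutive ISIs ≤100 ms;
  a network burst is an alignment-window cluster of electrode-level
  bursts spanning ≥25% of the well's active electrodes.

Metrics that are undefined for an input (too few spikes, no active
electrodes) return ``nan`` and carry an exclusion flag in the well
table — never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PlateLayout, SpikeTrainSet

__all__ = [
    "MetricParams",
    "classify_active",
    "aey_percent",
    "mfr",
    "well_mfr",
    "well_wmfr",
    "isi_cov",
    "auncc",
    "detect_bursts",
    "burst_rate",
    "detect_network_bursts",
    "network_burst_rate",
    "compute_well_metrics",
]


@dataclass
class MetricParams:
    active_electrode_min_per_min: float = 1.0
    active_well_min_electrodes: int = 5
    correlogram_bin: float = 0.005
    correlogram_window: float = 0.1
    burst_max_isi: float = 0.1
    burst_min_spikes: int = 5
    network_burst_min_fraction: float = 0.25
    network_burst_window: float = 0.1

    def __post_init__(self) -> None:
        if self.correlogram_bin >= self.correlogram_window:
            raise ValueError("correlogram bin must be smaller than the window")
        for name in ("active_electrode_min_per_min", "correlogram_bin",
                     "correlogram_window", "burst_max_isi",
                     "network_burst_min_fraction", "network_burst_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def classify_active(train: np.ndarray, duration: float,
                    min_per_min: float = 1.0) -> bool:
    """Active iff the rate reaches ``min_per_min`` spikes/min (inclusive)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return np.asarray(train).size / duration * 60.0 >= min_per_min


def aey_percent(
    trains: SpikeTrainSet,
    duration: float | None = None,
    scope: list[tuple[str, int]] | None = None,
    min_per_min: float = 1.0,
) -> float:
    """Active electrode yield: 100 x active / total electrodes in scope.

    ``scope`` restricts the denominator to a subset of electrodes (a
    treatment group); default is the whole plate.
    """
    duration = duration or trains.duration
    keys = scope if scope is not None else trains.electrode_ids
    if not keys:
        raise ValueError("AEY scope contains no electrodes")
    active = sum(
        classify_active(trains.trains.get(tuple(k), np.empty(0)), duration,
                        min_per_min)
        for k in keys
    )
    return 100.0 * active / len(keys)


def mfr(train: np.ndarray, duration: float) -> float:
    if duration <= 0:
        raise ValueError("duration must be positive")
    return np.asarray(train).size / duration


def _active_trains(well_trains: dict[int, np.ndarray], duration: float,
                   min_per_min: float) -> dict[int, np.ndarray]:
    return {
        e: ts for e, ts in well_trains.items()
        if classify_active(ts, duration, min_per_min)
    }


def well_mfr(well_trains: dict[int, np.ndarray], duration: float,
             min_per_min: float = 1.0) -> float:
    """Mean firing rate over the well's active electrodes (nan if none)."""
    act = _active_trains(well_trains, duration, min_per_min)
    if not act:
        return float("nan")
    return float(np.mean([mfr(ts, duration) for ts in act.values()]))


def well_wmfr(well_trains: dict[int, np.ndarray], duration: float,
              min_per_min: float = 1.0) -> float:
    """Weighted MFR: total well spikes / (n_active x duration)."""
    act = _active_trains(well_trains, duration, min_per_min)
    if not act:
        return float("nan")
    total = sum(ts.size for ts in act.values())
    return total / (len(act) * duration)


def isi_cov(train: np.ndarray) -> float:
    """Coefficient of variation of inter-spike intervals (nan below 2 ISIs)."""
    train = np.asarray(train, dtype=float)
    if train.size < 3:
        return float("nan")
    isis = np.diff(train)
    m = isis.mean()
    if m == 0:
        return float("nan")
    return float(isis.std(ddof=0) / m)


# ---------------------------------------------------------------------------
# AUNCC
# ---------------------------------------------------------------------------

def _bin_trains(well_trains: dict[int, np.ndarray], duration: float,
                bin_s: float) -> tuple[np.ndarray, list[int]]:
    n_bins = max(int(np.ceil(duration / bin_s)), 1)
    keys = sorted(well_trains)
    mat = np.zeros((len(keys), n_bins))
    for row, e in enumerate(keys):
        ts = well_trains[e]
        if ts.size:
            idx = np.minimum((ts / bin_s).astype(int), n_bins - 1)
            np.add.at(mat[row], idx, 1.0)
    return mat, keys


def _lagged_inner(mat: np.ndarray, max_lag: int) -> np.ndarray:
    """All-pairs inner products at lags -max_lag..max_lag.

    Returns an array (2*max_lag+1, n, n) with entry [l, i, j] =
    sum_t x_i(t) x_j(t + lag_l).
    """
    n_lags = 2 * max_lag + 1
    n, T = mat.shape
    out = np.empty((n_lags, n, n))
    for li, lag in enumerate(range(-max_lag, max_lag + 1)):
        if lag >= 0:
            a = mat[:, : T - lag] if lag else mat
            b = mat[:, lag:]
        else:
            a = mat[:, -lag:]
            b = mat[:, :lag]
        out[li] = a @ b.T
    return out


def auncc(
    well_trains: dict[int, np.ndarray],
    duration: float,
    params: MetricParams | None = None,
) -> float:
    """Area under the normalized cross-correlogram, averaged over pairs.

    Pairs with an empty train are skipped; wells with fewer than two
    active electrodes return nan.  Invariant to electrode relabeling
    and to shifting both trains of a pair by the same offset.
    """
    params = params or MetricParams()
    act = _active_trains(well_trains, duration,
                         params.active_electrode_min_per_min)
    if len(act) < 2:
        return float("nan")
    mat, keys = _bin_trains(act, duration, params.correlogram_bin)
    n_bins = mat.shape[1]
    max_lag = int(round(params.correlogram_window / params.correlogram_bin))
    inner = _lagged_inner(mat, max_lag)
    energy = np.einsum("ij,ij->i", mat, mat)  # sum x^2 per electrode
    counts = mat.sum(axis=1)

    # Chance coincidence level per lag (shift predictor for homogeneous
    # firing) and its Poisson-scale fluctuation; correlogram mass is
    # counted only where it exceeds chance by 3 SDs, so independent
    # trains score near zero instead of their baseline coincidences.
    chance = np.outer(counts, counts) / n_bins
    gate = chance + 3.0 * np.sqrt(chance)
    excess = np.where(inner > gate[None, :, :], inner - chance[None, :, :], 0.0)
    pos_area = excess.sum(axis=0)  # (n, n)
    scores = []
    n = len(keys)
    for i in range(n):
        for j in range(i + 1, n):
            if counts[i] == 0 or counts[j] == 0:
                continue
            ncc_area = pos_area[i, j] / np.sqrt(energy[i] * energy[j])
            auto_i = pos_area[i, i] / energy[i]
            auto_j = pos_area[j, j] / energy[j]
            if counts[i] != counts[j]:
                acc_area = auto_i if counts[i] > counts[j] else auto_j
            else:  # label-free tie break
                acc_area = max(auto_i, auto_j)
            if acc_area == 0:
                continue
            scores.append(min(ncc_area / acc_area, 1.0))
    if not scores:
        return float("nan")
    return float(np.clip(np.mean(scores), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Bursts
# ---------------------------------------------------------------------------

def detect_bursts(
    train: np.ndarray, params: MetricParams | None = None
) -> list[tuple[float, float]]:
    """Maximal runs of ≥ min_spikes spikes with ISIs ≤ max_isi.

    Returns (start, stop) time intervals.
    """
    params = params or MetricParams()
    ts = np.asarray(train, dtype=float)
    if ts.size < params.burst_min_spikes:
        return []
    close = np.diff(ts) <= params.burst_max_isi
    bursts: list[tuple[float, float]] = []
    run_start = 0
    for i in range(close.size + 1):
        if i < close.size and close[i]:
            continue
        run_len = i - run_start + 1  # spikes in this run
        if run_len >= params.burst_min_spikes:
            bursts.append((float(ts[run_start]), float(ts[i])))
        run_start = i + 1
    return bursts


def burst_rate(train: np.ndarray, duration: float,
               params: MetricParams | None = None) -> float:
    if duration <= 0:
        raise ValueError("duration must be positive")
    return len(detect_bursts(train, params)) / duration


def detect_network_bursts(
    well_trains: dict[int, np.ndarray],
    duration: float,
    params: MetricParams | None = None,
) -> list[tuple[float, float]]:
    """Clusters of electrode-level bursts spanning ≥ min fraction of
    the well's active electrodes.

    Each electrode burst interval is padded by half the alignment
    window; maximal regions where padded intervals from enough distinct
    electrodes overlap form network bursts, with overlapping regions
    merged.
    """
    params = params or MetricParams()
    act = _active_trains(well_trains, duration,
                         params.active_electrode_min_per_min)
    if not act:
        return []
    need = max(int(np.ceil(params.network_burst_min_fraction * len(act))), 1)
    pad = params.network_burst_window / 2.0
    events: list[tuple[float, int, int]] = []  # (time, +1/-1, electrode)
    for e, ts in act.items():
        for b0, b1 in detect_bursts(ts, params):
            events.append((b0 - pad, +1, e))
            events.append((b1 + pad, -1, e))
    if not events:
        return []
    events.sort(key=lambda x: (x[0], -x[1]))
    depth: dict[int, int] = {}
    n_electrodes_in = 0
    regions: list[tuple[float, float]] = []
    open_t: float | None = None
    for t, delta, e in events:
        before = n_electrodes_in
        depth[e] = depth.get(e, 0) + delta
        if delta > 0 and depth[e] == 1:
            n_electrodes_in += 1
        elif delta < 0 and depth[e] == 0:
            n_electrodes_in -= 1
        if before < need <= n_electrodes_in and open_t is None:
            open_t = t
        elif open_t is not None and n_electrodes_in < need <= before:
            regions.append((max(open_t, 0.0), min(t, duration)))
            open_t = None
    if open_t is not None:
        regions.append((max(open_t, 0.0), duration))
    # Merge touching regions (shared padding).
    merged: list[tuple[float, float]] = []
    for r in regions:
        if merged and r[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], r[1]))
        else:
            merged.append(r)
    return merged


def network_burst_rate(well_trains: dict[int, np.ndarray], duration: float,
                       params: MetricParams | None = None) -> float:
    if duration <= 0:
        raise ValueError("duration must be positive")
    return len(detect_network_bursts(well_trains, duration, params)) / duration


# ---------------------------------------------------------------------------
# Well table
# ---------------------------------------------------------------------------

def compute_well_metrics(
    trains: SpikeTrainSet,
    layout: PlateLayout,
    params: MetricParams | None = None,
    epoch: str = "",
) -> pd.DataFrame:
    """One row per well: activity, rates, synchrony, bursts, exclusion flags.

    Wells below the active-electrode minimum are flagged ``excluded``;
    their rate metrics are still reported where defined, but downstream
    aggregation should drop them.
    """
    params = params or MetricParams()
    duration = trains.duration
    by_well = trains.by_well()
    rows = []
    for well in layout.wells:
        wt = by_well.get(well, {})
        act = _active_trains(wt, duration, params.active_electrode_min_per_min)
        n_active = len(act)
        covs = [isi_cov(ts) for ts in act.values()]
        covs = [c for c in covs if not np.isnan(c)]
        rows.append(
            {
                "well": well,
                "epoch": epoch,
                "group": layout.group_of(well),
                "n_active_electrodes": n_active,
                "total_spikes": int(sum(ts.size for ts in wt.values())),
                "mfr_hz": well_mfr(wt, duration,
                                   params.active_electrode_min_per_min),
                "wmfr_hz": well_wmfr(wt, duration,
                                     params.active_electrode_min_per_min),
                "isi_cov": float(np.mean(covs)) if covs else float("nan"),
                "auncc": auncc(wt, duration, params),
                "burst_rate_hz": float(
                    np.mean([burst_rate(ts, duration, params)
                             for ts in act.values()])
                ) if act else float("nan"),
                "network_burst_rate_hz": network_burst_rate(wt, duration,
                                                            params),
                "excluded": n_active < params.active_well_min_electrodes,
            }
        )
    return pd.DataFrame(rows)
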