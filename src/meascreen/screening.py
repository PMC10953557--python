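"""Assay-level statistics: stability, DoS, responsiveness, Z', hits.

The screening readout is the per-well log spike count,
``log10(total spikes + 1)`` over a fixed-duration epoch.  Assay
quality is the modified Z' factor

    Z' = 1 - 3 (sigma_p + sigma_n) / |mu_p - mu_n|

computed between a high-signal arm (vehicle, 0.1% DMSO) and a
low-signal arm (100 µM lidocaine); Z' > 0.5 is conventionally an
"excellent" assay.  A compound is a *hit* when its mean log spike
count falls more than 3x the median absolute deviation (MAD) away from
the median of a reference population of wells (default: the same
plate's pre-treatment baseline wells).

Treatment effects on rates are summarised by difference-over-sum
normalisation, ``DoS = (post - pre)/(post + pre)``, bounded in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "ControlStats",
    "HitThreshold",
    "StabilityVerdict",
    "dos",
    "prop_test",
    "assess_stability",
    "responsiveness",
    "percent_responsive",
    "zprime",
    "log_spike_count",
    "call_hits",
    "compare_groups",
    "dunn_posthoc",
]


def dos(pre, post):
    """Difference-over-sum normalisation, ``(post - pre)/(post + pre)``.

    Antisymmetric and bounded in [-1, 1]; nan (flagged undefined) when
    both inputs are zero.  Accepts scalars or arrays.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if np.any(pre < 0) or np.any(post < 0):
        raise ValueError("dos requires non-negative inputs")
    total = pre + post
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (post - pre) / np.where(total > 0, total, 1.0),
                       np.nan)
    return out if out.ndim else float(out)


def prop_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-sample z-test of proportions (two-sided).

    The squared z statistic equals the Pearson chi-square statistic of
    the 2x2 table without continuity correction.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
        if not 0 <= x <= n:
            raise ValueError("counts must satisfy 0 <= x <= n")
    if x1 == x2 and n1 == n2:
        return 0.0, 1.0
    z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


@dataclass
class StabilityVerdict:
    """Outcome of the three-recording stability criterion."""

    prop_p_values: list[float]
    kw_p_value: float
    stable: bool
    alpha: float = 0.05


def assess_stability(
    aey_counts: list[tuple[int, int]],
    wmfr_by_recording: list[np.ndarray],
    alpha: float = 0.05,
) -> StabilityVerdict:
    """Stability over three consecutive recordings.

    ``aey_counts`` holds (active, total) electrode counts per
    recording; ``wmfr_by_recording`` the per-well WMFR arrays.  The
    plate is stable iff all three pairwise proportion tests on AEY and
    the Kruskal-Wallis test across the WMFR distributions give
    p > alpha.
    """
    if len(aey_counts) != 3 or len(wmfr_by_recording) != 3:
        raise ValueError("stability assessment requires exactly 3 recordings")
    totals = {n for _, n in aey_counts}
    if len(totals) != 1:
        raise ValueError("recordings cover mismatched electrode sets")
    sizes = {len(np.asarray(w)) for w in wmfr_by_recording}
    if len(sizes) != 1:
        raise ValueError("recordings cover mismatched well sets")
    props = []
    for (xa, na), (xb, nb) in combinations(aey_counts, 2):
        _, p = prop_test(xa, na, xb, nb)
        props.append(p)
    arrs = [np.asarray(w, dtype=float) for w in wmfr_by_recording]
    arrs = [a[~np.isnan(a)] for a in arrs]
    if all(np.array_equal(arrs[0], a) for a in arrs[1:]):
        kw_p = 1.0  # identical samples: zero between-group rank variance
    else:
        _, kw_p = stats.kruskal(*arrs)
    stable = bool(all(p > alpha for p in props) and kw_p > alpha)
    return StabilityVerdict(prop_p_values=props, kw_p_value=float(kw_p),
                            stable=stable, alpha=alpha)


# ---------------------------------------------------------------------------
# Responsiveness
# ---------------------------------------------------------------------------

def _bin_counts(train: np.ndarray, duration: float, bin_s: float) -> np.ndarray:
    n_bins = int(duration // bin_s)
    if n_bins < 1:
        raise ValueError("epoch shorter than one bin")
    edges = np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(np.asarray(train, dtype=float), bins=edges)
    return counts


def responsiveness(
    baseline: np.ndarray,
    treatment: np.ndarray,
    baseline_duration: float,
    treatment_duration: float,
    bin_s: float = 30.0,
    mode: str = "chemical",
    floor: float = 1.0,
) -> bool:
    """2-fold rate-increase classification of one electrode.

    Chemical mode: responsive iff any treatment bin count reaches
    2x max(mean baseline bin count, ``floor``); the floor (1 spike per
    bin) keeps silent-baseline electrodes from trivially responding.
    Temperature mode: the maximum treatment (ramp) bin is compared with
    2x the maximum baseline bin.  Both comparisons are inclusive.
    """
    base = _bin_counts(baseline, baseline_duration, bin_s)
    treat = _bin_counts(treatment, treatment_duration, bin_s)
    if mode == "chemical":
        ref = max(base.mean(), floor)
    elif mode == "temperature":
        ref = max(base.max(), floor)
    else:
        raise ValueError("mode must be 'chemical' or 'temperature'")
    return bool(treat.max() >= 2.0 * ref)


def percent_responsive(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    baseline_duration: float,
    treatment_duration: float,
    bin_s: float = 30.0,
    mode: str = "chemical",
) -> float:
    """Percentage of electrodes classified responsive."""
    if not pairs:
        raise ValueError("no electrodes in scope")
    flags = [
        responsiveness(b, t, baseline_duration, treatment_duration, bin_s, mode)
        for b, t in pairs
    ]
    return 100.0 * sum(flags) / len(flags)


# ---------------------------------------------------------------------------
# Z' and hits
# ---------------------------------------------------------------------------

@dataclass
class ControlStats:
    """Per-arm location/scale of well log spike counts.

    The arms are named by what they measure — ``high`` (vehicle-like,
    high signal) and ``low`` (suppressed, low signal) — rather than by
    positive/negative labels, which vary by convention.
    """

    mu_high: float
    sigma_high: float
    mu_low: float
    sigma_low: float
    robust: bool = False
    n_high: int = 0
    n_low: int = 0


def _loc_scale(x: np.ndarray, robust: bool) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    if robust:
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med)))
        return med, 1.4826 * mad
    return float(np.mean(x)), float(np.std(x, ddof=1))


def zprime(low_wells: np.ndarray, high_wells: np.ndarray,
           robust: bool = False) -> float:
    """Modified Z' assay-quality factor on per-well log spike counts.

    ``Z' = 1 - 3 (sigma_low + sigma_high)/|mu_low - mu_high|``; the
    robust variant uses median and 1.4826 x MAD.  Always <= 1; equals 1
    at zero variance; -inf (flagged undefined separation) when the arm
    means coincide.
    """
    low = np.asarray(low_wells, dtype=float)
    high = np.asarray(high_wells, dtype=float)
    if low.size < 2 or high.size < 2:
        raise ValueError("each arm needs at least 2 wells")
    mu_l, sd_l = _loc_scale(low, robust)
    mu_h, sd_h = _loc_scale(high, robust)
    if mu_l == mu_h:
        return float("-inf")
    return 1.0 - 3.0 * (sd_l + sd_h) / abs(mu_h - mu_l)


def log_spike_count(total_spikes: int | np.ndarray) -> float | np.ndarray:
    """Per-well screening readout: log10(total spikes + 1)."""
    return np.log10(np.asarray(total_spikes, dtype=float) + 1.0)


@dataclass
class HitThreshold:
    median_ref: float
    mad_ref: float
    multiplier: float = 3.0
    reference: str = "baseline"

    @property
    def lower(self) -> float:
        return self.median_ref - self.multiplier * self.mad_ref

    @property
    def upper(self) -> float:
        return self.median_ref + self.multiplier * self.mad_ref


def call_hits(
    reference_log_counts: np.ndarray,
    compound_means: dict[str, float],
    multiplier: float = 3.0,
    reference_name: str = "baseline",
) -> tuple[pd.DataFrame, HitThreshold]:
    """MAD hit rule on per-compound mean log spike counts.

    A compound is a hit iff its mean log count differs from the
    reference median by more than ``multiplier`` x MAD (two-sided);
    direction records whether activity went up or down.  The rule is
    translation invariant: shifting all log counts by a constant
    changes no verdict.
    """
    ref = np.asarray(reference_log_counts, dtype=float)
    if ref.size < 3:
        raise ValueError("need at least 3 reference wells")
    med = float(np.median(ref))
    mad = float(np.median(np.abs(ref - med)))
    if mad == 0:
        raise ValueError("degenerate reference: MAD is zero")
    thr = HitThreshold(median_ref=med, mad_ref=mad, multiplier=multiplier,
                       reference=reference_name)
    rows = []
    for name, mean in compound_means.items():
        delta = mean - med
        hit = abs(delta) > multiplier * mad
        rows.append(
            {
                "compound": name,
                "mean_log_count": mean,
                "delta": delta,
                "hit": hit,
                "direction": "down" if delta < 0 else "up",
            }
        )
    return pd.DataFrame(rows), thr


# ---------------------------------------------------------------------------
# Group-comparison battery
# ---------------------------------------------------------------------------

def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based post-hoc test with tie correction.

    Pairwise z statistics on mean ranks of the pooled sample;
    two-sided p-values are Bonferroni adjusted over the number of
    comparisons (the conventional Dunn procedure).
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name, v in zip(names, values):
        mean_ranks[name] = ranks[start : start + v.size].mean()
        start += v.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        na, nb = groups[a].size if hasattr(groups[a], "size") else len(groups[a]), \
            groups[b].size if hasattr(groups[b], "size") else len(groups[b])
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = min(2.0 * stats.norm.sf(abs(z)) * m, 1.0)
        rows.append({"group_a": a, "group_b": b, "z": z, "p_adj": p})
    return pd.DataFrame(rows)


def compare_groups(
    values_by_group: dict[str, np.ndarray], alpha: float = 0.05
) -> dict:
    """Normality-gated omnibus comparison with post-hoc tests.

    Shapiro-Wilk is run per group at ``alpha``; if every group passes,
    a one-way ANOVA with Tukey post-hoc comparisons is used, otherwise
    Kruskal-Wallis with Dunn's post-hoc.  A constant group forces the
    nonparametric branch (its normality test is undefined).  Returns a
    report dict with the branch, statistics, p-values, and a post-hoc
    table.
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least 2 groups")
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, v in groups.items():
        if v.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")

    normal = True
    shapiro_p: dict[str, float] = {}
    for g, v in groups.items():
        if np.ptp(v) == 0:
            shapiro_p[g] = float("nan")  # constant group: test undefined
            normal = False
            continue
        _, p = stats.shapiro(v)
        shapiro_p[g] = float(p)
        if p < alpha:
            normal = False

    vals = list(groups.values())
    if all(np.array_equal(vals[0], v) for v in vals[1:]):
        # Identical groups: no between-group variance on either branch.
        return {
            "test": "kruskal-wallis" if not normal else "anova",
            "shapiro_p": shapiro_p,
            "statistic": 0.0,
            "p_value": 1.0,
            "significant": False,
            "posthoc": pd.DataFrame(),
            "alpha": alpha,
        }

    if normal:
        stat, p = stats.f_oneway(*vals)
        tk = stats.tukey_hsd(*vals)
        names = list(groups)
        rows = []
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                rows.append({
                    "group_a": a,
                    "group_b": names[j],
                    "p_adj": float(tk.pvalue[i, j]),
                })
        posthoc = pd.DataFrame(rows)
        test = "anova"
    else:
        stat, p = stats.kruskal(*vals)
        posthoc = dunn_posthoc(groups)
        test = "kruskal-wallis"
    return {
        "test": test,
        "shapiro_p": shapiro_p,
        "statistic": float(stat),
        "p_value": float(p),
        "significant": bool(p < alpha),
        "posthoc": posthoc,
        "alpha": alpha,
    }
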