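"""End-to-end screening runs: simulate -> detect -> metrics -> screen -> report.

``run_screen`` executes a full plate screen under one root seed.  The
demo configuration regenerates a 15-compound synthetic screen (4 wells
per compound plus vehicle / lidocaine / TNF-alpha arms) with epochs
scaled down to minutes; the designed compound effects are read from the
shipped ``screen15`` preset so the report can be compared against
ground truth.

All randomness flows from the root seed through named per-well
substreams, so adding wells does not perturb existing ones.  Two runs
with the same seed and config produce byte-identical tables.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    PlateLayout,
    SpikeTrainSet,
    config_hash,
    default_config,
    well_names,
    write_spike_table,
    read_spike_table,
)
from .metrics import MetricParams, aey_percent, classify_active, compute_well_metrics
from .screening import (
    StabilityVerdict,
    assess_stability,
    call_hits,
    dos,
    log_spike_count,
    zprime,
)
from .simulate import (
    StimProtocol,
    TreatmentEffect,
    WellActivityParams,
    apply_treatment,
    simulate_ocat_session,
    simulate_spike_trains,
    well_rng,
)
from .tpob import tpob_for_recording

__all__ = ["ScreenReport", "load_preset", "build_screen_layout", "run_screen",
           "run_demo"]


def load_preset(name: str) -> dict:
    """Load a shipped plain-text preset fragment (div27, tnfalpha, screen15)."""
    ref = importlib.resources.files("meascreen.presets") / f"{name}.yaml"
    return yaml.safe_load(ref.read_text())


@dataclass
class ScreenReport:
    """Everything a screening run produces, plus provenance."""

    well_metrics: pd.DataFrame  # per well per epoch
    log_counts: pd.DataFrame  # well, group, epoch, log spike count
    dos_table: pd.DataFrame  # group-level DoS of WMFR
    hit_table: pd.DataFrame
    hit_threshold: dict
    zprime_value: float
    stability: StabilityVerdict | None
    tpob_table: pd.DataFrame | None
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.well_metrics.to_csv(out / "well_metrics.csv", index=False)
        self.log_counts.to_csv(out / "log_counts.csv", index=False)
        self.dos_table.to_csv(out / "dos.csv", index=False)
        self.hit_table.to_csv(out / "hit_table.csv", index=False)
        if self.tpob_table is not None:
            self.tpob_table.to_csv(out / "tpob.csv", index=False)
        sidecar = {
            "zprime": self.zprime_value,
            "hit_threshold": self.hit_threshold,
            "stability": None
            if self.stability is None
            else {
                "prop_p_values": self.stability.prop_p_values,
                "kw_p_value": self.stability.kw_p_value,
                "stable": self.stability.stable,
            },
            "provenance": self.provenance,
        }
        with open(out / "screen.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
        with open(out / "run.log", "w") as fh:
            for k, v in sorted(self.provenance.items()):
                fh.write(f"{k}={v}\n")


def build_screen_layout(preset: dict | None = None) -> tuple[PlateLayout, dict]:
    """Virtual plate for the 15-compound screen.

    Pools the replicate wells of the three physical 48-well plates into
    one 72-well virtual layout (4 wells per compound, plus vehicle,
    lidocaine, and TNF-alpha arms).  Returns the layout and the
    per-group designed :class:`TreatmentEffect`.
    """
    preset = preset or load_preset("screen15")
    n_per = int(preset.get("wells_per_arm", 4))
    groups = {**preset["compounds"], **preset["controls"]}
    n_wells = n_per * len(groups)
    names = well_names(n_wells)
    well_groups: dict[str, str] = {}
    effects: dict[str, TreatmentEffect] = {}
    i = 0
    for gname, spec in groups.items():
        effects[gname] = TreatmentEffect(
            rate_factor=float(spec["rate_factor"]),
            onset_tau=float(spec.get("onset_tau_s", 10.0)),
        )
        for _ in range(n_per):
            well_groups[names[i]] = gname
            i += 1
    layout = PlateLayout(
        plate_id="screen15-virtual",
        n_wells=n_wells,
        electrodes_per_well=16,
        well_groups=well_groups,
    )
    return layout, effects


def _simulator_params(cfg: dict) -> WellActivityParams:
    s = cfg["simulator"]
    return WellActivityParams(
        baseline_rate=s["baseline_rate_hz"],
        burst_rate=s["burst_rate_hz"],
        burst_participation=s["burst_participation"],
        intra_burst_rate=s["intra_burst_rate_hz"],
        burst_duration=s["burst_duration_s"],
        fraction_active=s["fraction_active"],
        rate_cv=s["rate_cv"],
    )


def run_screen(
    config: dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    spike_table: str | Path | None = None,
    compute_metrics: bool = True,
    compute_tpob: bool = True,
    compute_stability: bool = True,
) -> ScreenReport:
    """Execute the full screening pipeline on a synthetic plate.

    If ``spike_table`` names a CSV written by a previous run, the
    simulation stage is skipped and the table is analysed as-is
    (stage composability); otherwise the plate is simulated under
    ``seed``.  Heavy stages (per-well metric battery, TPoB session,
    stability) can be toggled off for repeated-seed calibration runs.
    """
    cfg = config or default_config()
    preset = load_preset("screen15")
    layout, effects = build_screen_layout(preset)
    params = _simulator_params(cfg)
    base_s = float(cfg["simulator"]["baseline_epoch_s"])
    treat_s = float(cfg["simulator"]["treatment_epoch_s"])
    duration = base_s + treat_s

    if spike_table is not None:
        trains = read_spike_table(spike_table, duration=duration)
    else:
        trains, _ = simulate_spike_trains(layout, params, duration, seed)
        # Bolus addition at the epoch boundary, per-group designed effect.
        out: dict[tuple[str, int], np.ndarray] = {}
        for wi, well in enumerate(layout.wells):
            eff = effects[layout.group_of(well)]
            sub = SpikeTrainSet(
                {k: v for k, v in trains.trains.items() if k[0] == well},
                duration=duration,
            )
            treated, _ = apply_treatment(
                sub, eff, t_add=base_s,
                seed=int(well_rng(seed, wi, stream=1).integers(2**31)),
            )
            out.update(treated.trains)
        trains = SpikeTrainSet(out, duration=duration)

    baseline = trains.restrict(0.0, base_s)
    treatment = trains.restrict(base_s, duration)

    mp = MetricParams(
        active_electrode_min_per_min=cfg["metrics"]["active_electrode_min_per_min"],
        active_well_min_electrodes=cfg["metrics"]["active_well_min_electrodes"],
        correlogram_bin=cfg["metrics"]["correlogram_bin_s"],
        correlogram_window=cfg["metrics"]["correlogram_window_s"],
        burst_max_isi=cfg["metrics"]["burst_max_isi_s"],
        burst_min_spikes=cfg["metrics"]["burst_min_spikes"],
        network_burst_min_fraction=cfg["metrics"]["network_burst_min_fraction"],
        network_burst_window=cfg["metrics"]["network_burst_window_s"],
    )

    # --- per-well log spike counts -------------------------------------
    lc_rows = []
    for epoch_name, epoch in (("baseline", baseline), ("treatment", treatment)):
        by_well = epoch.by_well()
        for well in layout.wells:
            total = sum(ts.size for ts in by_well.get(well, {}).values())
            lc_rows.append(
                {
                    "well": well,
                    "group": layout.group_of(well),
                    "epoch": epoch_name,
                    "total_spikes": int(total),
                    "log_spike_count": float(log_spike_count(total)),
                }
            )
    log_counts = pd.DataFrame(lc_rows)

    # --- metric battery ------------------------------------------------
    if compute_metrics:
        wm = pd.concat(
            [
                compute_well_metrics(baseline, layout, mp, epoch="baseline"),
                compute_well_metrics(treatment, layout, mp, epoch="treatment"),
            ],
            ignore_index=True,
        )
    else:
        wm = pd.DataFrame()

    # --- DoS of WMFR per group -----------------------------------------
    dos_rows = []
    bw, tw = baseline.by_well(), treatment.by_well()
    for group in sorted(set(layout.well_groups.values())):
        vals = []
        for well in layout.wells_in_group(group):
            pre = sum(ts.size for ts in bw.get(well, {}).values()) / base_s
            post = sum(ts.size for ts in tw.get(well, {}).values()) / treat_s
            if pre + post > 0:
                vals.append(dos(pre, post))
        dos_rows.append(
            {
                "group": group,
                "dos_mean": float(np.mean(vals)) if vals else float("nan"),
                "dos_sd": float(np.std(vals, ddof=1)) if len(vals) > 1
                else float("nan"),
                "n_wells": len(vals),
            }
        )
    dos_table = pd.DataFrame(dos_rows)

    # --- hit calling ----------------------------------------------------
    base_lc = log_counts.query("epoch == 'baseline'")
    treat_lc = log_counts.query("epoch == 'treatment'")
    ref_mode = cfg["screening"]["hit_reference"]
    if ref_mode == "baseline":
        ref = base_lc["log_spike_count"].to_numpy()
    elif ref_mode == "vehicle":
        ref = treat_lc.query("group == 'vehicle'")["log_spike_count"].to_numpy()
    elif ref_mode == "tnf":
        ref = treat_lc.query("group == 'tnf_alpha'")["log_spike_count"].to_numpy()
    else:
        raise ValueError(f"unknown hit_reference {ref_mode!r}")
    compound_means = {
        g: float(treat_lc.query("group == @g")["log_spike_count"].mean())
        for g in preset["compounds"]
    }
    # Controls are scored too, for context (vehicle must not be a hit).
    control_means = {
        g: float(treat_lc.query("group == @g")["log_spike_count"].mean())
        for g in preset["controls"]
    }
    hit_table, thr = call_hits(
        ref, {**compound_means, **control_means},
        multiplier=cfg["screening"]["mad_multiplier"],
        reference_name=ref_mode,
    )
    hit_table["is_control"] = hit_table["compound"].isin(preset["controls"])
    hit_table["designed_rate_factor"] = hit_table["compound"].map(
        lambda g: effects[g].rate_factor
    )

    # --- Z' between control arms ---------------------------------------
    high = treat_lc.query("group == 'vehicle'")["log_spike_count"].to_numpy()
    low = treat_lc.query("group == 'lidocaine'")["log_spike_count"].to_numpy()
    zp = zprime(low, high, robust=cfg["screening"]["robust_zprime"])

    # --- stability over three consecutive baseline segments -------------
    stability = None
    if compute_stability:
        seg = base_s / 3.0
        counts, wmfrs = [], []
        for i in range(3):
            sub = trains.restrict(i * seg, (i + 1) * seg)
            active = sum(
                classify_active(ts, seg,
                                mp.active_electrode_min_per_min)
                for ts in sub.trains.values()
            )
            counts.append((int(active), len(sub.trains)))
            by_well = sub.by_well()
            wmfrs.append(
                np.array(
                    [
                        sum(ts.size for ts in by_well.get(w, {}).values()) / seg
                        for w in layout.wells
                    ]
                )
            )
        stability = assess_stability(counts, wmfrs)

    # --- TPoB session (one well, half the electrodes stimulated) --------
    tpob_table = None
    if compute_tpob:
        protocol = StimProtocol()
        n_el = 8
        stim = set(range(n_el // 2))
        rec, pulses = simulate_ocat_session(
            n_electrodes=n_el,
            protocol=protocol,
            stimulated=stim,
            noise_sd=cfg["simulator"]["noise_sd_uv"],
            seed=int(np.random.SeedSequence(entropy=int(seed),
                                            spawn_key=(9999,)).generate_state(1)[0]
                     % 2**31),
            fs=cfg["simulator"]["fs_hz"],
            well="A1",
        )
        res = tpob_for_recording(
            rec,
            pulses,
            stimulated={("A1", e) for e in stim},
            band=(cfg["tpob"]["band_low_hz"], cfg["tpob"]["band_high_hz"]),
            window=cfg["tpob"]["trial_window_s"],
            blank=cfg["tpob"]["blank_s"],
            stft_window=cfg["tpob"]["stft_window_s"],
            overlap=cfg["tpob"]["stft_overlap"],
            highpass_hz=cfg["tpob"]["highpass_hz"],
        )
        tpob_table = res.table

    report = ScreenReport(
        well_metrics=wm,
        log_counts=log_counts,
        dos_table=dos_table,
        hit_table=hit_table,
        hit_threshold={
            "median_ref": thr.median_ref,
            "mad_ref": thr.mad_ref,
            "multiplier": thr.multiplier,
            "reference": thr.reference,
        },
        zprime_value=float(zp),
        stability=stability,
        tpob_table=tpob_table,
        provenance={
            "config_hash": config_hash(cfg),
            "seed": int(seed),
            "version": __version__,
            "aey_percent_baseline": aey_percent(baseline),
        },
    )
    if out_dir is not None:
        report.write(out_dir)
        write_spike_table(trains, Path(out_dir) / "spike_table.csv")
    return report


def run_demo(seed: int = 0, out_dir: str | Path = "demo_out") -> ScreenReport:
    """Regenerate the full synthetic screen and emit summary figures.

    Produces the screen report plus a raster of one well, a log-count
    hit plot with the ±3 MAD band, and a TPoB bar chart.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = default_config()
    report = run_screen(cfg, seed=seed, out_dir=out)

    # Raster of one vehicle well (baseline epoch).
    layout, _ = build_screen_layout()
    params = _simulator_params(cfg)
    trains, _ = simulate_spike_trains(
        PlateLayout("demo", n_wells=1, electrodes_per_well=16),
        params, duration=120.0, seed=seed,
    )
    fig, ax = plt.subplots(figsize=(8, 3))
    for (well, e), ts in sorted(trains.trains.items()):
        ax.vlines(ts, e + 0.6, e + 1.4, lw=0.4, color="k")
    ax.set(xlabel="time (s)", ylabel="electrode", title="Spontaneous activity")
    fig.tight_layout()
    fig.savefig(out / "raster.png", dpi=120)
    plt.close(fig)

    # Hit plot.
    ht = report.hit_table
    thr = report.hit_threshold
    fig, ax = plt.subplots(figsize=(8, 4))
    colors = ["tab:red" if h else "tab:gray" for h in ht["hit"]]
    ax.bar(ht["compound"], ht["mean_log_count"], color=colors)
    ax.axhline(thr["median_ref"], color="k", lw=1)
    for sign in (-1, 1):
        ax.axhline(
            thr["median_ref"] + sign * thr["multiplier"] * thr["mad_ref"],
            color="k", ls="--", lw=1,
        )
    ax.set_ylabel("log10 spikes/well")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(out / "hits.png", dpi=120)
    plt.close(fig)

    # TPoB chart.
    if report.tpob_table is not None:
        tt = report.tpob_table
        fig, ax = plt.subplots(figsize=(5, 3))
        for flag, sub in tt.groupby("stimulated"):
            ax.bar(
                [f"{'stim' if flag else 'unstim'} e{e}" for e in sub["electrode"]],
                sub["tpob_mv2"],
                color="tab:blue" if flag else "tab:gray",
            )
        ax.set_ylabel("TPoB (mV$^2$)")
        ax.tick_params(axis="x", rotation=90)
        fig.tight_layout()
        fig.savefig(out / "tpob.png", dpi=120)
        plt.close(fig)
    return report
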