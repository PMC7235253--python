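"""End-to-end orchestration: simulate/load -> preprocess -> detect -> stats.

A :class:`PipelineConfig` (YAML or JSON on disk) either points at existing
inputs (HDF5/EDF signals, CSV event logs, TSV electrode metadata) or carries a
:class:`~hippotheta.synthdata.SimConfig` block to generate a synthetic cohort.
:func:`run_all` produces the band table, classification table, bout tables,
epoch-frequency table, correlation table, cohort statistics report, and a run
manifest.  All outputs embed the config hash and seed, and a rerun with the
same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hippotheta import bouts as bouts_mod
from hippotheta import cohortstats, electrodes, io, modal, preprocess, speedfreq
from hippotheta.synthdata import SimConfig, make_cohort
from hippotheta.types import Recording

__all__ = ["PipelineConfig", "run_all", "validate_inputs"]

logger = logging.getLogger("hippotheta")

FLOAT_FMT = io.FLOAT_FMT


@dataclass
class PipelineConfig:
    """Run configuration: inputs (or a simulation block), parameters, seed."""

    outdir: str = "hippotheta_out"
    seed: int = 0
    # input paths; ignored when `simulate` is set
    signals: dict[str, str] = field(default_factory=dict)  # subject -> file
    events: dict[str, str] = field(default_factory=dict)
    electrodes_path: str | None = None
    simulate: SimConfig | None = None
    # module parameters
    reference_scheme: str = "none"
    notch_hz: float = 60.0
    artifact_z: float = 5.0
    exclude_ramps: bool = True
    n_perm: int = 10_000

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        cfg = cls(**d)
        if sim is not None:
            cfg.simulate = SimConfig(**sim)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output path is excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def _load_inputs(config: PipelineConfig):
    recordings: dict[str, Recording] = {}
    trials = {}
    for subject_id, p in config.signals.items():
        recordings[subject_id] = io.read_recording(p)
    for subject_id, p in config.events.items():
        trials[subject_id] = io.read_events_csv(p)
    if config.electrodes_path is None:
        raise ValueError("electrodes_path is required when not simulating")
    recs = io.read_electrodes_tsv(config.electrodes_path)
    return recordings, recs, trials


def run_all(config: PipelineConfig) -> dict:
    """Run the full pipeline and write all result tables to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    header = f"# hippotheta config_hash={chash} seed={config.seed}\n"
    logger.info("pipeline start (config %s, seed %d)", chash, config.seed)

    if config.simulate is not None:
        cohort = make_cohort(config.simulate)
        recordings, elec_records, trials = (
            cohort.recordings, cohort.electrodes, cohort.trials,
        )
    else:
        recordings, elec_records, trials = _load_inputs(config)
    if not trials or all(len(t) == 0 for t in trials.values()):
        raise ValueError("empty cohort: no trials")

    # --- preprocess, detect, classify, derive gated traces (one pass) -----
    meta = {r.electrode_id: r for r in elec_records}
    subject_of = {r.electrode_id: r.subject_id for r in elec_records}
    masks: dict[str, np.ndarray] = {}
    gated: dict[tuple[str, str], object] = {}
    for subject_id in sorted(recordings):
        rec = preprocess.resample_if_needed(recordings[subject_id])
        rec = preprocess.rereference(rec, config.reference_scheme)
        rec = preprocess.notch_filter(rec, config.notch_hz)
        mask = preprocess.exclude_artifacts(rec, config.artifact_z)
        for c, cid in enumerate(rec.channel_ids):
            masks[cid] = mask[c]
            r = meta[cid]
            r.region = electrodes.split_region(r.ap_fraction)
            psd = modal.compute_psd(rec.data[c], rec.sampling_rate, mask[c])
            fit = modal.fit_background(psd)
            bands = modal.detect_bands(psd, fit)
            wspec = modal.window_spectra(rec.data[c], rec.sampling_rate)
            bands = [
                b for b in bands
                if modal.band_window_fraction(rec.data[c], rec.sampling_rate,
                                              b, fit, wspec)
                >= modal.MIN_WINDOW_FRACTION
            ]
            if not bands:
                r.excluded = True
                continue
            osc_class, merged, labels = electrodes.classify_oscillator(bands)
            r.oscillator_class, r.bands, r.band_labels = osc_class, merged, labels
            for b, lab in zip(merged, labels):
                tr = modal.instantaneous_trace(rec.data[c], b, rec.sampling_rate)
                gated[(cid, lab)] = modal.gate_presence(tr, rec.data[c], fit,
                                                        mask[c], wspec=wspec)
        logger.info("subject %s: processed %d channels", subject_id, rec.n_channels)

    kept = electrodes.deduplicate(elec_records)
    kept_ids = {r.electrode_id for r in kept}

    band_rows = []
    for r in elec_records:
        for b, lab in zip(r.bands, r.band_labels):
            band_rows.append({
                "electrode_id": r.electrode_id, "f_lo": b.f_lo, "f_hi": b.f_hi,
                "peak_freq": b.peak_freq, "label": lab,
            })
    band_table = pd.DataFrame(
        band_rows, columns=["electrode_id", "f_lo", "f_hi", "peak_freq", "label"]
    )

    # --- bouts ------------------------------------------------------------
    bout_frames = []
    for (cid, lab), tr in gated.items():
        bout_frames.append(bouts_mod.extract_bouts(tr, cid, lab))
    bout_table = (
        pd.concat(bout_frames, ignore_index=True)
        if bout_frames else pd.DataFrame(columns=bouts_mod.BOUT_COLUMNS)
    )
    bout_summary = bouts_mod.mean_bout_cycles(bout_table).rename("mean_cycles").reset_index() \
        if not bout_table.empty else pd.DataFrame(columns=["electrode_id", "label", "mean_cycles"])

    # --- speed-frequency --------------------------------------------------
    epoch_frames, corr_rows = [], []
    for (cid, lab), tr in sorted(gated.items()):
        subj = subject_of[cid]
        ef = speedfreq.epoch_frequency_table(
            tr, trials[subj], cid, lab, config.exclude_ramps
        )
        epoch_frames.append(ef)
        key = zlib.crc32(f"{cid}:{lab}".encode())  # stable across processes
        sub_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
        )
        picked = speedfreq.subsample_epochs(ef, sub_rng)
        res = speedfreq.speed_frequency_correlation(picked)
        r = meta[cid]
        corr_rows.append({
            "subject_id": subj, "electrode_id": cid, "label": lab,
            "region": r.region, "hemisphere": r.hemisphere,
            "oscillator_class": r.oscillator_class,
            "r": res["r"], "p": res["p"], "n_epochs": res["n_epochs"],
            "flag": res["flag"] or "",
        })
    epoch_table = (
        pd.concat(epoch_frames, ignore_index=True)
        if epoch_frames else pd.DataFrame(columns=speedfreq.EPOCH_FREQ_COLUMNS)
    )
    corr_table = pd.DataFrame(corr_rows, columns=[
        "subject_id", "electrode_id", "label", "region", "hemisphere",
        "oscillator_class", "r", "p", "n_epochs", "flag",
    ])

    # --- behavioral accuracy ---------------------------------------------
    acc_rows = []
    for subject_id, subj_trials in sorted(trials.items()):
        _, frac = speedfreq.behavioral_accuracy(subj_trials)
        acc_rows.append({"subject_id": subject_id, "accuracy": frac})
    accuracy_table = pd.DataFrame(acc_rows, columns=["subject_id", "accuracy"])

    # --- cohort statistics -------------------------------------------------
    stats_report = _cohort_statistics(
        elec_records, kept_ids, corr_table, bout_table, gated, config
    )

    # --- outputs -----------------------------------------------------------
    class_table = io.electrodes_to_frame(elec_records)
    class_table["kept_after_dedup"] = [
        r.electrode_id in kept_ids for r in elec_records
    ]
    _write_table(band_table, outdir / "band_table.tsv", header)
    _write_table(class_table, outdir / "classification_table.tsv", header)
    _write_table(bout_table, outdir / "bout_table.tsv", header)
    _write_table(bout_summary, outdir / "bout_summary.tsv", header)
    _write_table(epoch_table, outdir / "epoch_frequency_table.tsv", header)
    _write_table(corr_table, outdir / "correlation_table.tsv", header)
    _write_table(accuracy_table, outdir / "accuracy_table.tsv", header)
    io.write_mask_json(masks, outdir / "artifact_masks.json")
    (outdir / "stats_report.json").write_text(
        json.dumps({"config_hash": chash, "seed": config.seed,
                    "results": stats_report}, indent=1, sort_keys=True,
                   default=_json_default)
    )
    manifest = {
        "package": "hippotheta",
        "version": _package_version(),
        "config_hash": chash,
        "seed": config.seed,
        "config": self_config_dict(config),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    logger.info("pipeline done: %d electrodes, %d bouts", len(elec_records),
                len(bout_table))
    return {
        "band_table": band_table,
        "classification_table": class_table,
        "bout_table": bout_table,
        "bout_summary": bout_summary,
        "epoch_frequency_table": epoch_table,
        "correlation_table": corr_table,
        "accuracy_table": accuracy_table,
        "stats": stats_report,
        "outdir": outdir,
    }


def self_config_dict(config: PipelineConfig) -> dict:
    return config.to_dict()


def _package_version() -> str:
    from hippotheta import __version__

    return __version__


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _cohort_statistics(elec_records, kept_ids, corr_table, bout_table,
                       gated, config: PipelineConfig) -> dict:
    """All group-level tests that the cohort supports; others are flagged."""
    report: dict = {}
    kept = [r for r in elec_records if r.electrode_id in kept_ids and not r.excluded]

    # prevalence of significant positive speed-frequency correlations
    for osc_class in ("single", "dual"):
        sel = corr_table[
            (corr_table["oscillator_class"] == osc_class)
            & (corr_table["label"] == "high")
            & (corr_table["flag"] == "")
        ]
        n = len(sel)
        k = int(((sel["r"] > 0) & (sel["p"] < 0.05)).sum())
        entry = {"k_significant": k, "n": n}
        if n > 0:
            entry["p_binomial"] = cohortstats.binomial_prevalence_test(k, n)
        report[f"prevalence_high_{osc_class}"] = entry
    low = corr_table[(corr_table["label"] == "low") & (corr_table["flag"] == "")]
    high = corr_table[(corr_table["label"] == "high") & (corr_table["flag"] == "")]
    k_lo = int(((low["r"] > 0) & (low["p"] < 0.05)).sum())
    k_hi = int(((high["r"] > 0) & (high["p"] < 0.05)).sum())
    if len(low) and len(high):
        report["low_vs_high_proportion"] = dict(
            cohortstats.proportion_z_test(k_hi, len(high), k_lo, len(low)),
            k_high=k_hi, n_high=len(high), k_low=k_lo, n_low=len(low),
        )

    # anatomy: logistic class model + frequency gradient
    classified = [r for r in kept if r.oscillator_class is not None]
    classes = [r.oscillator_class for r in classified]
    try:
        report["oscillator_logistic"] = cohortstats.oscillator_logistic(
            np.array([r.ap_fraction for r in classified]), np.array(classes)
        )
    except ValueError as e:
        report["oscillator_logistic"] = {"flag": str(e)}
    hs_rows = [
        {"electrode_id": r.electrode_id, "ap_fraction": r.ap_fraction,
         "hemisphere": r.hemisphere, "peak_hz": b.peak_freq,
         "subregion": r.subregion, "oscillator_class": r.oscillator_class,
         "label": lab}
        for r in classified for b, lab in zip(r.bands, r.band_labels)
    ]
    hs_table = pd.DataFrame(hs_rows)
    if len(hs_table):
        gradient_in = hs_table[
            (hs_table["oscillator_class"] == "single") & (hs_table["label"] == "high")
        ]
        report["gradient"] = {
            by: cohortstats.gradient_correlation(gradient_in, by)
            for by in ("all", "L", "R")
        }
        try:
            report["hemisphere"] = cohortstats.hemisphere_tests(hs_table)
        except ValueError as e:
            report["hemisphere"] = {"flag": str(e)}

    # bout durations: high vs low
    if not bout_table.empty:
        per = bouts_mod.mean_bout_cycles(bout_table)
        try:
            hi_v = per.xs("high", level="label").to_numpy()
            lo_v = per.xs("low", level="label").to_numpy()
            t, df, p = bouts_mod.compare_bout_groups(hi_v, lo_v)
            report["bout_high_vs_low"] = {
                "t": t, "df": df, "p": p,
                "mean_high": float(hi_v.mean()), "mean_low": float(lo_v.mean()),
            }
        except (KeyError, ValueError) as e:
            report["bout_high_vs_low"] = {"flag": str(e)}

    # dual-oscillator structure
    duals = [r for r in kept if r.oscillator_class == "dual"]
    if len(duals) >= 5:
        f_low = np.array([r.bands[0].peak_freq for r in duals])
        f_high = np.array([r.bands[1].peak_freq for r in duals])
        report["harmonic_permutation"] = cohortstats.harmonic_permutation_test(
            f_low, f_high, config.n_perm, np.random.default_rng(config.seed)
        )
        pairs = []
        for r in duals:
            lo_tr = gated.get((r.electrode_id, "low"))
            hi_tr = gated.get((r.electrode_id, "high"))
            if lo_tr is not None and hi_tr is not None:
                pairs.append((lo_tr.presence, hi_tr.presence))
        if pairs:
            res = cohortstats.cooccurrence_test(pairs)
            res.pop("statistics", None)
            report["cooccurrence"] = res

    # two-way ANOVA of subject-level prevalence
    try:
        cells = cohortstats.subject_cell_table(corr_table[corr_table["flag"] == ""])
        report["speedfreq_anova"] = cohortstats.speedfreq_anova(cells)
    except (ValueError, KeyError) as e:
        report["speedfreq_anova"] = {"flag": str(e)}
    return report


def validate_inputs(events: dict[str, str] | None = None,
                    electrodes_path: str | None = None,
                    signals: dict[str, str] | None = None) -> list[dict]:
    """Schema and range checks on input files; returns a list of issues."""
    issues: list[dict] = []
    if events:
        for subject_id, path in events.items():
            try:
                df = pd.read_csv(path)
            except Exception as e:  # noqa: BLE001
                issues.append({"file": str(path), "issue": f"unreadable: {e}"})
                continue
            missing = set(io.EVENT_COLUMNS) - set(df.columns)
            if missing:
                issues.append({"file": str(path),
                               "issue": f"missing columns {sorted(missing)}"})
                continue
            for tid, g in df.groupby("trial_id"):
                if len(g) != 3:
                    issues.append({"file": str(path),
                                   "issue": f"trial {tid}: epochs != 3 ({len(g)})"})
                if (g["t_end_s"] <= g["t_start_s"]).any():
                    issues.append({"file": str(path),
                                   "issue": f"trial {tid}: nonpositive epoch duration"})
    if electrodes_path:
        try:
            df = pd.read_csv(electrodes_path, sep="\t")
            missing = set(io.ELECTRODE_COLUMNS) - set(df.columns)
            if missing:
                issues.append({"file": str(electrodes_path),
                               "issue": f"missing columns {sorted(missing)}"})
            elif ((df["ap_fraction"] < 0) | (df["ap_fraction"] > 1)).any():
                issues.append({"file": str(electrodes_path),
                               "issue": "ap out of range [0, 1]"})
        except Exception as e:  # noqa: BLE001
            issues.append({"file": str(electrodes_path), "issue": f"unreadable: {e}"})
    if signals:
        for subject_id, path in signals.items():
            try:
                rec = io.read_recording(path)
            except Exception as e:  # noqa: BLE001
                issues.append({"file": str(path), "issue": f"unreadable: {e}"})
                continue
            if rec.sampling_rate not in preprocess.NATIVE_RATES:
                issues.append({
                    "file": str(path),
                    "issue": f"sampling rate {rec.sampling_rate} Hz not in "
                             f"{preprocess.NATIVE_RATES} (will be resampled)",
                })
    return issues
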