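"""End-to-end pipeline driver.

Chain: simulate or ingest a session -> preprocess -> Morlet spectrogram
-> baseline-normalized band summaries and time courses -> unit response
detection -> unit-type classification -> behavioral quantification ->
statistics.  Deterministic given the seed; emits CSV tables plus a
machine-readable JSON summary, each stamped with the package version,
configuration hash, and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behavior, lfp, stats, synth, units
from .io import build_dataclass, config_hash, load_session, write_session, write_table
from .params import BandTable, PreprocessParams, PSTHParams, SpectrogramParams
from .session import RecordingSession
from .synth import SimulationConfig, UnitSpec

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input fingerprint."""

    def __init__(self, stage: str, fingerprint: str, cause: Exception):
        self.stage = stage
        self.fingerprint = fingerprint
        super().__init__(f"stage {stage!r} failed on input {fingerprint}: {cause}")


@dataclasses.dataclass
class PipelineConfig:
    """Resolved run configuration (schema-validated, unknown keys rejected)."""

    seed: int = 0
    session_dir: str | None = None  # ingest instead of simulate when set
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    preprocess: PreprocessParams = dataclasses.field(default_factory=PreprocessParams)
    spectrogram: SpectrogramParams = dataclasses.field(default_factory=SpectrogramParams)
    psth: PSTHParams = dataclasses.field(default_factory=PSTHParams)
    bands: BandTable = dataclasses.field(default_factory=BandTable)
    include_nonwithdrawal: bool = False  # spectrograms normally use withdrawal trials
    cluster_mode: str = "final"
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", None)
        if isinstance(sim, dict):
            sim = dict(sim)
            specs = sim.pop("unit_specs", None)
            sim = build_dataclass(SimulationConfig, sim)
            if specs is not None:
                sim.unit_specs = [build_dataclass(UnitSpec, s) for s in specs]
        cfg = build_dataclass(cls, data)
        if sim is not None:
            cfg.simulation = sim
        for name, sub in (
            ("preprocess", PreprocessParams),
            ("spectrogram", SpectrogramParams),
            ("psth", PSTHParams),
            ("bands", BandTable),
        ):
            v = getattr(cfg, name)
            if isinstance(v, dict):
                setattr(cfg, name, build_dataclass(sub, v))
        return cfg

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = synth._config_to_dict(self.simulation)
        return d


def run_pipeline(config: PipelineConfig | dict, out_dir) -> dict:
    """Run the full analysis chain; returns the summary dict."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    logging.basicConfig(level=config.log_level)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = config.resolved()
    sha = config_hash(resolved)
    meta = {"evlock_version": __version__, "config_sha": sha, "seed": config.seed}
    (out / "resolved_config.json").write_text(
        json.dumps({**meta, "config": resolved}, indent=1, default=str)
    )
    summary: dict = {"meta": meta}

    def stage(name, fn, *args, **kwargs):
        try:
            logger.info("stage %s", name)
            return fn(*args, **kwargs)
        except Exception as e:  # noqa: BLE001 - rewrapped with stage context
            raise StageError(name, sha, e) from e

    # --- session ---------------------------------------------------------
    if config.session_dir:
        session: RecordingSession = stage("load_session", load_session, config.session_dir)
    else:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        session = stage("simulate", synth.simulate_session, sim)
        stage("write_session", write_session, session, out / "session", config.seed)

    trials = session.trials
    wd = trials[(trials["withdrawal"] == 1) & trials.get("valid", True)]
    onsets = wd["onset_s"].to_numpy(float)

    # --- LFP spectral ----------------------------------------------------
    pre_trace = stage("preprocess", lfp.preprocess_lfp, session.lfp, session.fs,
                      config.preprocess)
    spec = stage("spectrogram", lfp.morlet_spectrogram, pre_trace,
                 config.preprocess.fs_out, config.spectrogram)
    use = trials if config.include_nonwithdrawal else wd
    nspec = stage("normalize", lfp.extract_and_normalize, spec,
                  use["onset_s"].to_numpy(float), config.spectrogram)

    band_rows = []
    tc_frames = []
    for band in config.bands.as_dict():
        change = lfp.band_power_change(
            nspec, band, config.spectrogram.quant_window, config.bands
        )
        band_rows.append({"band": band, "pct_change": change, "n_trials": nspec.n_trials})
        tc = lfp.band_timecourse(
            nspec, band, config.spectrogram.timecourse_bin, config.bands,
            withdrawal_latencies=wd["latency_s"].dropna().to_numpy(),
        )
        tc["band"] = band
        tc_frames.append(tc)
    band_summary = pd.DataFrame(band_rows)
    write_table(band_summary, out / "band_summary.csv", config.seed, sha)
    timecourse = pd.concat(tc_frames, ignore_index=True)
    write_table(timecourse, out / "timecourse.csv", config.seed, sha)

    # full normalized spectrogram, wide form (rows = frequency, cols = time)
    wide = pd.DataFrame(nspec.matrix, index=nspec.freqs, columns=nspec.times)
    wide.index.name = "freq_hz"
    write_table(wide.reset_index(), out / "nspec_full.csv", config.seed, sha)

    # per-force band change
    force_rows = []
    for force, sub in wd.groupby("force_g"):
        try:
            nf = lfp.extract_and_normalize(
                spec, sub["onset_s"].to_numpy(float), config.spectrogram
            )
        except ValueError:
            continue
        for band in config.bands.as_dict():
            force_rows.append(
                {
                    "force_g": force,
                    "band": band,
                    "pct_change": lfp.band_power_change(
                        nf, band, config.spectrogram.quant_window, config.bands
                    ),
                    "n_trials": nf.n_trials,
                }
            )
    by_force = pd.DataFrame(force_rows)
    write_table(by_force, out / "band_by_force.csv", config.seed, sha)

    # --- units -----------------------------------------------------------
    responses = []
    features = []
    for u in session.units:
        r = stage(
            "unit_responses", units.analyze_unit, u.unit_id, u.spike_times, onsets,
            config.psth, session.duration,
        )
        responses.append(r)
        features.append(
            units.extract_waveform_features(
                u.waveform, u.fs_wave, u.spike_times, session.duration, u.unit_id
            )
        )
    resp_table = units.response_magnitudes(responses)
    resp_table["included"] = resp_table["label"] != "excluded"
    write_table(resp_table, out / "unit_responses.csv", config.seed, sha)
    feat_table = pd.DataFrame([f.as_row() for f in features])
    if len(feat_table):
        write_table(feat_table, out / "unit_features.csv", config.seed, sha)
    classable = feat_table[feat_table["classifiable"]] if len(feat_table) else feat_table
    if len(classable) >= 2:
        labels = stage(
            "classify", units.cluster_unit_types, classable, config.cluster_mode,
            config.seed,
        )
        classes = classable[["unit_id"]].assign(unit_class=labels)
        write_table(classes, out / "unit_classes.csv", config.seed, sha)
        summary["unit_classes"] = classes["unit_class"].value_counts().to_dict()

    # --- behavior --------------------------------------------------------
    curve = stage("behavior", behavior.response_curve, trials)
    write_table(curve, out / "curves.csv", config.seed, sha)
    thr, slope = config.simulation.psychometric
    seqs = [
        synth.simulate_updown_responses(
            thr, slope, config.simulation.filament_forces, start_force=0.4,
            seed=int(np.random.default_rng([config.seed, 0x5D, i]).integers(2**31)),
        )
        for i in range(5)
    ]
    thresholds = [
        behavior.updown_threshold(
            behavior.UpDownSequence(
                [f for f, _ in s], [r for _, r in s],
                tuple(config.simulation.filament_forces),
            )
        )
        for s in seqs
    ]
    write_table(
        pd.DataFrame({"sequence": range(len(thresholds)), "threshold_g": thresholds}),
        out / "thresholds.csv", config.seed, sha,
    )

    # --- stats -----------------------------------------------------------
    stat_rows = []
    per_trial_changes = {}
    for band in config.bands.as_dict():
        vals = []
        for onset in onsets:
            n1 = lfp.extract_and_normalize(spec, [onset], config.spectrogram)
            vals.append(
                lfp.band_power_change(n1, band, config.spectrogram.quant_window,
                                      config.bands)
            )
        per_trial_changes[band] = vals
        if len(vals) >= 2:
            r = stats.one_sample_t(vals, 0.0)
            stat_rows.append(
                {
                    "test": f"one_sample_t[{band}]",
                    "statistic": r.statistic,
                    "df": r.df,
                    "p": r.p_value,
                    "p_adj": "",
                    "method": r.method,
                }
            )
    label_counts = resp_table["label"].value_counts()
    summary["unit_labels"] = label_counts.to_dict()
    write_table(pd.DataFrame(stat_rows), out / "stats.csv", config.seed, sha)

    summary["band_pct_change"] = {
        r["band"]: r["pct_change"] for r in band_rows
    }
    summary["n_withdrawal_trials"] = int(len(wd))
    summary["updown_threshold_g"] = {
        "median": float(np.median(thresholds)),
        "values": [float(t) for t in thresholds],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary
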