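"""End-to-end study orchestration.

A single YAML config drives the whole analysis: simulate (or load) raw
recordings, segment them on the stimulus schedule, extract HRV and EDA
indices per epoch, score questionnaires, assemble the per-spot indicator
tables, fit one path model per spot with bootstrap significance, and run
the gender permutation comparison.  Everything is deterministic under the
configured master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .eda import eda_features
from .hrv import build_nn_series, detect_r_peaks, hrv_indices
from .plspm import (PathModelSpec, align_indicator_signs, bootstrap_paths,
                    default_model, fit_plspm, permutation_group_test)
from .recall import ScoringScheme, default_scheme, load_scheme, score_questionnaire
from .simulate import (LatentGroundTruth, RawRecording, StimulusSchedule,
                       default_schedule, generate_ecg, generate_eda,
                       generate_indicator_table, generate_nn_series)

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "segment_epochs", "assemble_indicator_table",
           "simulate_study_signals", "extract_features", "run_study",
           "write_report"]

MV_COLUMNS = ("lf", "sdnn", "ns_scr", "mean_scl", "hf", "pnn50", "rmssd",
              "lf_hf", "avnn")
TABLE_COLUMNS = MV_COLUMNS + ("recall_score", "gender")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Validated study configuration (see ``from_dict`` for the YAML shape)."""

    seed: int
    synthetic: dict | None
    recordings_dir: str | None
    schedule: StimulusSchedule
    model: PathModelSpec
    scheme: ScoringScheme
    analysis: dict = field(default_factory=dict)
    n_spots: int | None = None
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        if "seed" not in d:
            raise ValueError("config requires a seed")
        schedule = d.get("schedule", "default")
        if schedule == "default" or schedule is None:
            schedule = default_schedule()
        elif isinstance(schedule, StimulusSchedule):
            pass
        else:
            schedule = StimulusSchedule.from_jsonable(schedule)
        model = d.get("model", "default")
        if model == "default" or model is None:
            model = default_model()
        elif isinstance(model, PathModelSpec):
            pass
        else:
            model = PathModelSpec.from_jsonable(model)
        scheme = d.get("scoring", "default")
        if scheme == "default" or scheme is None:
            scheme = default_scheme()
        elif isinstance(scheme, ScoringScheme):
            pass
        else:
            scheme = load_scheme(scheme)
        analysis = {"scheme": "path", "tol": 1e-7, "max_iter": 300,
                    "n_boot": 500, "n_perm": 199, "alpha": 0.05,
                    "min_span_s": 45.0}
        analysis.update(d.get("analysis") or {})
        cfg = cls(seed=int(d["seed"]), synthetic=d.get("synthetic"),
                  recordings_dir=d.get("recordings_dir"), schedule=schedule,
                  model=model, scheme=scheme, analysis=analysis,
                  n_spots=d.get("n_spots"), raw=d)
        if cfg.synthetic is None and cfg.recordings_dir is None:
            raise ValueError("config needs a synthetic block or recordings_dir")
        n_spots = cfg.n_spots
        if n_spots is not None and n_spots != len(schedule.spots):
            raise ValueError(
                f"schedule has {len(schedule.spots)} spots but the model run "
                f"declares {n_spots}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self.raw), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# Segmentation and assembly
# ---------------------------------------------------------------------------

def segment_epochs(recording: RawRecording, schedule: StimulusSchedule
                   ) -> dict[str, dict[str, np.ndarray]]:
    """Sample-accurate signal slices, one per schedule epoch."""
    if recording.duration_s < schedule.total_duration_s - 1e-9:
        raise ValueError(
            f"recording ({recording.duration_s:.1f} s) shorter than the "
            f"schedule ({schedule.total_duration_s:.1f} s)")
    fs = recording.fs_hz
    out: dict[str, dict[str, np.ndarray]] = {}
    for epoch in schedule.epochs:
        i0 = int(round(epoch.start_s * fs))
        i1 = int(round(epoch.end_s * fs))
        out[epoch.label] = {name: ch[i0:i1]
                            for name, ch in recording.channels.items()}
    return out


def assemble_indicator_table(hrv: pd.DataFrame, eda: pd.DataFrame,
                             recall: pd.DataFrame,
                             gender: Mapping[str, str]) -> pd.DataFrame:
    """Join per-epoch features into one row per subject-by-spot.

    ``hrv`` and ``eda`` carry ``subject_id``/``epoch`` keys plus their index
    columns; ``recall`` carries ``subject_id``/``epoch``/``recall_score``.
    Subjects missing any epoch present for other subjects are dropped with a
    log entry; duplicated keys are an error.
    """
    for name, df in (("hrv", hrv), ("eda", eda), ("recall", recall)):
        if df.duplicated(subset=["subject_id", "epoch"]).any():
            raise ValueError(f"duplicate subject-epoch keys in {name}")
    merged = hrv.merge(eda, on=["subject_id", "epoch"], how="outer")
    merged = merged.merge(recall, on=["subject_id", "epoch"], how="outer")
    epochs = sorted(merged["epoch"].unique())
    complete, dropped = [], []
    for sid, g in merged.groupby("subject_id"):
        if sorted(g["epoch"]) == epochs and not g[list(MV_COLUMNS)
                                                  + ["recall_score"]].isna().any().any():
            complete.append(g)
        else:
            dropped.append(sid)
    if dropped:
        logger.warning("dropping %d subject(s) with incomplete epochs: %s",
                       len(dropped), ", ".join(map(str, dropped)))
    if not complete:
        raise ValueError("no subject has complete features for every epoch")
    table = pd.concat(complete, ignore_index=True)
    table["gender"] = table["subject_id"].map(dict(gender))
    cols = ["subject_id", "epoch"] + list(TABLE_COLUMNS)
    return table[cols]


# ---------------------------------------------------------------------------
# Signals-mode simulation
# ---------------------------------------------------------------------------

def _merge_beats(per_epoch: list[np.ndarray], min_gap_s: float = 0.25
                 ) -> np.ndarray:
    beats = np.concatenate(per_epoch)
    beats.sort()
    kept = [beats[0]]
    for b in beats[1:]:
        if b - kept[-1] >= min_gap_s:
            kept.append(b)
    return np.asarray(kept)


def simulate_study_signals(config: StudyConfig
                           ) -> tuple[dict[str, RawRecording],
                                      dict[str, str],
                                      pd.DataFrame]:
    """Raw recordings, genders, and recall scores for a synthetic cohort.

    Autonomic parameters are drawn per subject and epoch; per-emotion shifts
    of mean RR and SCR rate can be supplied under
    ``synthetic.emotion_shifts`` as ``{emotion: {mean_rr_ms, scr_rate}}``.
    """
    syn = config.synthetic or {}
    n_subjects = int(syn.get("n_subjects", 10))
    fs = float(syn.get("fs_hz", 250.0))
    p_recall = float(syn.get("p_recall", 0.5))
    shifts = syn.get("emotion_shifts", {}) or {}
    schedule = config.schedule
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))

    recordings: dict[str, RawRecording] = {}
    genders: dict[str, str] = {}
    recall_rows = []
    for s in range(n_subjects):
        sid = f"s{s + 1:03d}"
        genders[sid] = "F" if s % 2 == 0 else "M"
        base_rr = rng.normal(850.0, 60.0)
        beats_per_epoch = []
        scr_events = []
        for epoch in schedule.epochs:
            shift = shifts.get(epoch.emotion, {})
            mean_rr = base_rr + float(shift.get("mean_rr_ms", 0.0)) \
                + rng.normal(0.0, 20.0)
            nn = generate_nn_series(
                epoch.duration_s + 2.0, mean_rr_ms=mean_rr,
                lf_amp_ms=rng.uniform(5.0, 30.0),
                hf_amp_ms=rng.uniform(5.0, 30.0),
                lf_freq_hz=rng.uniform(0.07, 0.13),
                hf_freq_hz=rng.uniform(0.2, 0.3),
                jitter_sd_ms=25.0,
                seed=int(rng.integers(2 ** 31)))
            beats_per_epoch.append(nn.beat_times_s + epoch.start_s)
            rate = max(0.5, 3.0 + float(shift.get("scr_rate", 0.0)))
            n_scr = int(rng.poisson(rate))
            onsets = np.sort(rng.uniform(epoch.start_s + 1.0,
                                         epoch.end_s - 5.0, size=n_scr))
            for o in onsets:
                scr_events.append((float(o), float(rng.uniform(0.2, 0.8)),
                                   0.7, 3.0))
        beats = _merge_beats(beats_per_epoch)
        beats = beats[beats <= schedule.total_duration_s + 1.0]
        nn_full = build_nn_series(beats, ectopic_rel_threshold=1.0)
        ecg = generate_ecg(nn_full, fs_hz=fs, amplitude_mv=1.0,
                           noise_sd_mv=0.02,
                           seed=int(rng.integers(2 ** 31)))
        eda = generate_eda(schedule.total_duration_s + 2.0,
                           scl_level_us=float(rng.uniform(1.5, 4.0)),
                           drift_us_per_min=float(rng.uniform(-0.2, 0.2)),
                           scr_events=scr_events, fs_hz=fs,
                           noise_sd_us=0.005,
                           seed=int(rng.integers(2 ** 31)))
        n_target = int(round((schedule.total_duration_s + 1.0) * fs))
        ecg = np.pad(ecg, (0, max(0, n_target - len(ecg))))[:n_target]
        eda = eda[:n_target]
        recordings[sid] = RawRecording(
            channels={"ecg": ecg, "eda": eda}, fs_hz=fs, schedule=schedule,
            units={"ecg": "mV", "eda": "uS"})

        for epoch in schedule.spots:
            responses = {}
            for item in config.scheme.items:
                if item.kind == "suggested_message":
                    key = list(item.key)
                    picked = [k for k in key if rng.random() < p_recall]
                    responses[item.item_id] = ";".join(picked)
                else:
                    correct = rng.random() < p_recall
                    responses[item.item_id] = (str(item.key) if correct
                                               else "__wrong__")
            score = score_questionnaire(responses, config.scheme,
                                        subject_id=sid)
            recall_rows.append({"subject_id": sid, "epoch": epoch.label,
                                "recall_score": score.score})
    return recordings, genders, pd.DataFrame(recall_rows)


def _load_study_inputs(config: StudyConfig
                       ) -> tuple[dict[str, RawRecording], dict[str, str],
                                  pd.DataFrame]:
    """Recordings plus questionnaire scores from an on-disk study.

    Expects ``recordings_dir`` with the CSV/JSON sidecar layout of
    :mod:`ansrecall.io`, a ``responses_csv`` with columns
    ``subject_id, epoch, item_id, answer``, and a ``genders_csv`` with
    ``subject_id, gender``.
    """
    from .io import list_subjects, read_recording

    subjects = list_subjects(config.recordings_dir)
    if not subjects:
        raise ValueError(f"no recordings found in {config.recordings_dir!r}")
    recordings = {sid: read_recording(config.recordings_dir, sid)
                  for sid in subjects}
    responses_csv = config.raw.get("responses_csv")
    genders_csv = config.raw.get("genders_csv")
    if responses_csv is None or genders_csv is None:
        raise ValueError("non-synthetic runs need responses_csv and "
                         "genders_csv in the config")
    genders = pd.read_csv(genders_csv).set_index("subject_id")["gender"]
    resp = pd.read_csv(responses_csv)
    rows = []
    for (sid, epoch), g in resp.groupby(["subject_id", "epoch"]):
        answers = dict(zip(g["item_id"], g["answer"]))
        score = score_questionnaire(answers, config.scheme, subject_id=sid)
        rows.append({"subject_id": sid, "epoch": epoch,
                     "recall_score": score.score})
    return recordings, dict(genders), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_features(recordings: Mapping[str, RawRecording],
                     schedule: StimulusSchedule,
                     min_span_s: float = 45.0
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per subject-by-epoch HRV and EDA feature tables."""
    hrv_rows, eda_rows = [], []
    for sid, rec in recordings.items():
        beats = detect_r_peaks(rec.channels["ecg"], rec.fs_hz)
        nn_full = build_nn_series(beats)
        slices = segment_epochs(rec, schedule)
        for epoch in schedule.epochs:
            try:
                nn = nn_full.restrict(epoch.start_s, epoch.end_s)
                idx = hrv_indices(nn, min_span_s=min_span_s)
            except ValueError as exc:
                logger.warning("subject %s epoch %s: HRV failed (%s)",
                               sid, epoch.label, exc)
                continue
            hrv_rows.append({
                "subject_id": sid, "epoch": epoch.label,
                "emotion": epoch.emotion, "avnn": idx.avnn,
                "sdnn": idx.sdnn, "rmssd": idx.rmssd, "pnn50": idx.pnn50,
                "lf": idx.lf_norm, "hf": idx.hf_norm, "lf_hf": idx.lf_hf})
            feats = eda_features(slices[epoch.label]["eda"], rec.fs_hz)
            eda_rows.append({"subject_id": sid, "epoch": epoch.label,
                             "mean_scl": feats.mean_scl,
                             "ns_scr": feats.ns_scr})
    return pd.DataFrame(hrv_rows), pd.DataFrame(eda_rows)


# ---------------------------------------------------------------------------
# Study driver
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (StimulusSchedule, PathModelSpec)):
        return obj.to_jsonable()
    return obj


def _spot_tables_from_synthetic_table_mode(config: StudyConfig
                                           ) -> dict[str, pd.DataFrame]:
    syn = config.synthetic or {}
    spec = config.model
    n = int(syn.get("n_subjects", 100))
    loadings_cfg = syn.get("loadings", 1.0)
    noise_cfg = syn.get("noise_sd", 0.0)
    mvs = spec.all_mvs()
    loadings = ({mv: float(loadings_cfg) for mv in mvs}
                if np.isscalar(loadings_cfg) else dict(loadings_cfg))
    noise = ({mv: float(noise_cfg) for mv in mvs}
             if np.isscalar(noise_cfg) else dict(noise_cfg))
    betas_cfg = syn.get("path_coefficients") or {}
    betas = {}
    for key, val in betas_cfg.items():
        if isinstance(key, str):
            s, t = key.split("->")
            betas[(s.strip(), t.strip())] = float(val)
        else:
            betas[tuple(key)] = float(val)
    ss = np.random.SeedSequence([config.seed, 202])
    tables = {}
    for child, epoch in zip(ss.spawn(len(config.schedule.spots)),
                            config.schedule.spots):
        truth = LatentGroundTruth(
            loadings=loadings, path_coefficients=betas, noise_sd=noise,
            n_subjects=n, seed=int(child.generate_state(1)[0]))
        tables[epoch.label] = generate_indicator_table(truth, spec)
    return tables


def run_study(config: StudyConfig, out_dir=None) -> dict:
    """Execute the full pipeline and return the study report."""
    analysis = config.analysis
    spec = config.model
    syn_mode = (config.synthetic or {}).get("mode", "signals")

    excluded: list[str] = []
    features_tables = None
    if config.synthetic is not None and syn_mode == "table":
        spot_tables = _spot_tables_from_synthetic_table_mode(config)
        recall_df = pd.concat(
            [t.assign(epoch=label)[["epoch", "recall_score", "gender"]]
             for label, t in spot_tables.items()], ignore_index=True)
    else:
        if config.synthetic is not None:
            recordings, genders, recall_df_long = simulate_study_signals(config)
        else:
            recordings, genders, recall_df_long = _load_study_inputs(config)
        hrv_df, eda_df = extract_features(
            recordings, config.schedule,
            min_span_s=float(analysis["min_span_s"]))
        # baseline features are kept for the audit CSVs but the model only
        # sees the spot epochs
        spot_labels = [e.label for e in config.schedule.spots]
        table = assemble_indicator_table(
            hrv_df[hrv_df["epoch"].isin(spot_labels)],
            eda_df[eda_df["epoch"].isin(spot_labels)],
            recall_df_long, genders)
        features_tables = (hrv_df, eda_df)
        all_sids = sorted(recordings)
        kept = sorted(table["subject_id"].unique())
        excluded = [s for s in all_sids if s not in kept]
        spot_tables = {e.label: table[table["epoch"] == e.label]
                       .reset_index(drop=True)
                       for e in config.schedule.spots}
        recall_df = table[["epoch", "recall_score", "gender"]]

    recall_summary = {}
    for label, g in recall_df.groupby("epoch"):
        recall_summary[label] = {
            "mean": float(g["recall_score"].mean()),
            "sd": float(g["recall_score"].std(ddof=1)),
            "by_gender": {gen: float(sub["recall_score"].mean())
                          for gen, sub in g.groupby("gender")},
        }

    ss = np.random.SeedSequence([config.seed, 303])
    spot_seeds = ss.generate_state(2 * len(spot_tables), dtype=np.uint32)
    spots_report = {}
    for k, (label, table) in enumerate(spot_tables.items()):
        data = table[[c for c in TABLE_COLUMNS if c != "gender"]]
        aligned, flips = align_indicator_signs(data, spec)
        fit = fit_plspm(aligned, spec, scheme=analysis["scheme"],
                        tol=float(analysis["tol"]),
                        max_iter=int(analysis["max_iter"]))
        fit.flips = flips
        entry = fit.to_jsonable()
        n_boot = int(analysis["n_boot"])
        if n_boot > 0:
            boot = bootstrap_paths(data, spec, n_boot=n_boot,
                                   seed=int(spot_seeds[2 * k]),
                                   alpha=float(analysis["alpha"]),
                                   scheme=analysis["scheme"],
                                   tol=float(analysis["tol"]),
                                   max_iter=int(analysis["max_iter"]))
            entry["bootstrap"] = {
                "n_boot": boot["n_boot"], "n_redraws": boot["n_redraws"],
                "edges": {f"{s}->{t}": v for (s, t), v
                          in boot["edges"].items()}}
        n_perm = int(analysis["n_perm"])
        labels = table["gender"].to_numpy()
        counts = pd.Series(labels).value_counts()
        max_preds = max(len(spec.predecessors(lv)) for lv in spec.blocks)
        min_group = max(3, max_preds + 2)
        if n_perm > 0 and len(counts) == 2 and counts.min() >= min_group:
            try:
                comp = permutation_group_test(
                    data, spec, labels, n_perm=n_perm,
                    seed=int(spot_seeds[2 * k + 1]),
                    scheme=analysis["scheme"], tol=float(analysis["tol"]),
                    max_iter=int(analysis["max_iter"]))
                entry["gender_comparison"] = comp.to_jsonable()
            except ValueError as exc:
                logger.warning("spot %s: gender comparison skipped (%s)",
                               label, exc)
                entry["gender_comparison"] = {"skipped": str(exc)}
        spots_report[label] = entry

    report = {
        "provenance": {
            "package": "ansrecall",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": config.config_hash(),
            "note": "no multiple-testing correction across spots or edges",
        },
        "schedule": config.schedule.to_jsonable(),
        "model": spec.to_jsonable(),
        "excluded_subjects": excluded,
        "recall_summary": recall_summary,
        "spots": spots_report,
    }
    report = _jsonable(report)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report(report, out_dir)
        for label, table in spot_tables.items():
            table.to_csv(out_dir / f"indicators_{label}.csv", index=False)
        if features_tables is not None:
            features_tables[0].to_csv(out_dir / "hrv_features.csv",
                                      index=False)
            features_tables[1].to_csv(out_dir / "eda_features.csv",
                                      index=False)
    return report


def write_report(report: dict, out_dir) -> None:
    """JSON report plus a flat CSV of per-spot structural results."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2))
    rows = []
    for label, entry in report["spots"].items():
        for edge, beta in entry["path_coefficients"].items():
            boot = entry.get("bootstrap", {}).get("edges", {}).get(edge, {})
            rows.append({
                "spot": label, "edge": edge, "beta": beta,
                "r_squared": entry["r_squared"].get(edge.split("->")[1]),
                "gof": entry["gof"],
                "ci_low": boot.get("ci_low"), "ci_high": boot.get("ci_high"),
                "significant": boot.get("significant"),
            })
    pd.DataFrame(rows).to_csv(out_dir / "structural_summary.csv", index=False)
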