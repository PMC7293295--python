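"""End-to-end orchestration: cohort -> features -> statistics -> classification.

Feature extraction per recording follows the task protocol: pauses are
detected on the relative intensity contour and removed before the cepstral
(MFCC) analysis; syllable-nuclei tempo features are computed on the original
recording with the pause intervals attached; semantic features come from the
picture-description transcript and an embedding table.  A picture-task row
therefore carries 130 + 16 + 61 = 207 feature columns.
"""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acoustic import acoustic_feature_vector, compute_mfcc
from .audio import AudioRecording, compute_intensity, detect_pauses, read_wav, remove_pauses, truncate
from .classify import CVConfig, FEATURE_SETS_BY_TASK, reports_to_frame, run_cv_grid
from .errors import ConfigurationError, ParameterError
from .prosody import prosodic_feature_vector
from .semantics import EmbeddingTable, Transcript, semantic_feature_vector
from .stats import partial_correlation, rank_features
from .synth import SyntheticCohortConfig, cohort_embeddings, iter_cohort

__all__ = [
    "RunConfig",
    "extract_recording_features",
    "extract_feature_table",
    "run_pipeline",
    "duration_ablation",
]

logger = logging.getLogger("pdvoice")


@dataclass
class RunConfig:
    """One pipeline run: input source, CV settings, output directory."""

    mode: str = "synthetic"  # or "manifest"
    outdir: str = "pdvoice_out"
    seed: int = 0
    cohort: SyntheticCohortConfig | None = None
    manifest_path: str | None = None
    embeddings_path: str | None = None
    tasks: tuple[str, ...] = ("picture", "counting", "ddk")
    cv: CVConfig = field(default_factory=CVConfig)
    max_duration_s: float | None = None  # optional truncation before extraction
    top_k_partial: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "manifest"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic" and self.cohort is None:
            self.cohort = SyntheticCohortConfig(rng_seed=self.seed, task_set=tuple(self.tasks))
        if self.mode == "manifest":
            if self.manifest_path is None:
                raise ConfigurationError("manifest mode requires manifest_path")
            if not Path(self.manifest_path).exists():
                raise ConfigurationError(f"manifest not found: {self.manifest_path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort" in raw and raw["cohort"] is not None:
            raw["cohort"] = SyntheticCohortConfig(**raw["cohort"])
        if "cv" in raw and raw["cv"] is not None:
            raw["cv"] = CVConfig(**raw["cv"])
        for key in ("tasks",):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def extract_recording_features(
    rec: AudioRecording,
    transcript: Transcript | None = None,
    embeddings: EmbeddingTable | None = None,
    max_duration_s: float | None = None,
) -> dict[str, float]:
    """All feature families applicable to one recording."""
    if max_duration_s is not None:
        rec = truncate(rec, max_duration_s)
    contour = compute_intensity(rec)
    pauses = detect_pauses(contour)
    speech = remove_pauses(rec, pauses)
    if speech.samples.size == 0:
        raise ParameterError("recording is entirely silent after pause removal")
    features = acoustic_feature_vector(compute_mfcc(speech))
    features.update(prosodic_feature_vector(rec))
    if transcript is not None:
        if embeddings is None:
            raise ConfigurationError("semantic features require an embedding table")
        features.update(semantic_feature_vector(transcript, embeddings))
    return features


def _iter_recordings(config: RunConfig):
    """Yield (subject, task, state, recording, transcript) from either source."""
    if config.mode == "synthetic":
        for subj in iter_cohort(config.cohort):
            for (task, state), rec in subj.recordings.items():
                transcript = subj.transcripts.get(state) if task == "picture" else None
                yield subj.subject_id, task, state, rec, transcript
    else:
        manifest_dir = Path(config.manifest_path).parent
        manifest = pd.read_csv(config.manifest_path)
        for _, row in manifest.iterrows():
            wav = manifest_dir / row["wav_path"]
            if not wav.exists():
                raise ConfigurationError(
                    f"manifest row (subject={row['subject']}, task={row['task']}, "
                    f"state={row['state']}): missing WAV {wav}"
                )
            rec = read_wav(wav)
            rec.subject_id, rec.task, rec.state = row["subject"], row["task"], row["state"]
            transcript = None
            if row["task"] == "picture" and isinstance(row.get("transcript_path"), str) and row["transcript_path"]:
                transcript = Transcript.from_tsv(manifest_dir / row["transcript_path"])
            yield row["subject"], row["task"], row["state"], rec, transcript


def _load_embeddings(config: RunConfig) -> EmbeddingTable | None:
    if config.embeddings_path:
        return EmbeddingTable.from_text(config.embeddings_path)
    if config.mode == "synthetic":
        return cohort_embeddings(config.cohort)
    return None


def extract_feature_table(
    config: RunConfig, max_duration_s: float | None = None
) -> pd.DataFrame:
    """Wide feature table with (subject, task, state) key columns.

    Recordings are processed one at a time, so cohorts of long audio never
    live in memory at once.  Any stage failure is re-raised naming the
    offending (subject, task, state).
    """
    embeddings = _load_embeddings(config)
    max_dur = max_duration_s if max_duration_s is not None else config.max_duration_s
    rows = []
    for subject, task, state, rec, transcript in _iter_recordings(config):
        if task not in config.tasks:
            continue
        try:
            features = extract_recording_features(rec, transcript, embeddings, max_dur)
        except Exception as exc:
            raise type(exc)(
                f"feature extraction failed for (subject={subject}, task={task}, "
                f"state={state}): {exc}"
            ) from exc
        rows.append({"subject": subject, "task": task, "state": state, **features})
    if not rows:
        raise ConfigurationError("no recordings matched the configured tasks")
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={config_hash}\n")
        df.to_csv(fh, index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Full run: features, per-task rankings, partial correlations, CV table.

    Writes a report bundle under ``config.outdir`` and returns the in-memory
    pieces (feature table, rankings, CV reports, partial correlations).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logger.info("run config hash %s (seed %d)", chash, config.seed)

    table = extract_feature_table(config)
    _write_csv(table, outdir / "features.csv", chash)

    rank_rows, rankings = [], {}
    for task in config.tasks:
        if task not in set(table["task"]):
            continue
        sub = table[table["task"] == task].dropna(axis=1, how="all")
        ranked = rank_features(sub, task)
        rankings[task] = ranked
        rank_rows += [
            {
                "task": task,
                "rank": i + 1,
                "feature": r.feature,
                "p_value": r.p_value,
                "t_statistic": r.t_statistic,
                "significant": r.significant,
            }
            for i, r in enumerate(ranked)
        ]
    _write_csv(pd.DataFrame(rank_rows), outdir / "feature_ranking.csv", chash)

    # partial correlations among the top picture-task features, per state
    partials = {}
    if "picture" in rankings:
        top = [r.feature for r in rankings["picture"][: config.top_k_partial] if not r.degenerate]
        pic = table[table["task"] == "picture"]
        for state in ("ON", "OFF"):
            X = pic.loc[pic["state"] == state, top].dropna().to_numpy()
            try:
                P = partial_correlation(X)
            except ParameterError as exc:
                warnings.warn(f"partial correlation skipped for {state}: {exc}", stacklevel=2)
                continue
            partials[state] = pd.DataFrame(P, index=top, columns=top)
            _write_csv(partials[state], outdir / f"partial_corr_{state}.csv", chash, index=True)

    cv_config = CVConfig(**{**asdict(config.cv), "rng_seed": config.seed})
    reports = run_cv_grid(table, cv_config, tasks=tuple(t for t in config.tasks if t in set(table["task"])))
    cv_frame = reports_to_frame(reports)
    _write_csv(cv_frame, outdir / "cv_results.csv", chash)

    best = cv_frame.loc[cv_frame.groupby("task")["accuracy_mean"].idxmax()]
    _write_csv(best, outdir / "best_per_task.csv", chash)

    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"pdvoice {__version__}\nconfig_hash {chash}\nseed {config.seed}\n")
        fh.write(f"numpy {np.__version__}\npandas {pd.__version__}\n")
    return {
        "features": table,
        "rankings": rankings,
        "partial_correlations": partials,
        "cv_reports": reports,
        "cv_frame": cv_frame,
    }


def duration_ablation(
    config: RunConfig,
    durations_s: list[float],
    tasks: tuple[str, ...] = ("picture",),
    feature_sets: dict | None = None,
) -> pd.DataFrame:
    """Re-run extraction + CV with recordings truncated to each duration.

    ``None`` in ``durations_s`` means the full recording.  Returns a tidy
    frame of CV results with a ``duration_s`` column and writes it to the
    output directory.
    """
    for d in durations_s:
        if d is not None and d <= 0.025:
            raise ParameterError(f"duration {d} s is shorter than one analysis window")
    feature_sets = feature_sets or {t: FEATURE_SETS_BY_TASK[t] for t in tasks}
    frames = []
    for dur in durations_s:
        table = extract_feature_table(config, max_duration_s=dur)
        cv_config = CVConfig(**{**asdict(config.cv), "rng_seed": config.seed})
        reports = run_cv_grid(
            table, cv_config,
            tasks=tuple(t for t in tasks if t in set(table["task"])),
            feature_sets=feature_sets,
        )
        frame = reports_to_frame(reports)
        frame.insert(0, "duration_s", np.inf if dur is None else dur)
        frames.append(frame)
    result = pd.concat(frames, ignore_index=True)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_csv(result, outdir / "duration_ablation.csv", config.config_hash())
    return result
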