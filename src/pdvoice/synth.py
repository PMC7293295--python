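"""Synthetic paired ON/OFF cohorts: audio, transcripts and toy embeddings.

The clinical recordings behind this pipeline are not public, so this module
fabricates a paired cohort with known, controllable state effects:

* **spectral**: each utterance is a train of voiced bursts (harmonic pulse
  train through a single resonance, plus aspiration noise) that is split at
  8 kHz and the two bands re-gained per state — a crude stand-in for the
  high-frequency energy changes of hypokinetic dysarthria;
* **tempo**: inter-syllable intervals get a state-dependent upper-tail
  lengthening, so the robust maximum (pct90) of the interval distribution
  separates the states;
* **semantic**: picture-description transcripts draw their verbs from an
  action pool with a state-dependent probability, and the toy embeddings
  place action words opposite non-action words along one axis.

Every generated recording carries its ground truth (burst onset times, pause
intervals, applied gains), so each downstream stage has an oracle.  The
default configuration IS the strong-effect study condition (+6 dB high band,
0.1 s tail shift, action-verb probability 0.8 vs 0.2); ``null()`` zeroes all
state effects for false-positive controls.  Identical config + seed gives a
bit-identical cohort.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .audio import AudioRecording, write_wav
from .errors import ConfigurationError, ParameterError
from .semantics import EmbeddingTable, SEED_WORDS, Transcript

__all__ = [
    "ACTION_VERBS",
    "NON_ACTION_VERBS",
    "NOUNS",
    "FUNCTION_WORDS",
    "SyntheticCohortConfig",
    "SyntheticSubject",
    "synthesize_utterance",
    "generate_transcript",
    "generate_toy_embeddings",
    "generate_cohort",
    "iter_cohort",
    "generate_feature_table",
    "write_cohort",
]

TASKS = ("picture", "counting", "ddk")

# In-package word pools (picture-description vocabulary).  Seed words are kept
# out of the pools; they enter the vocabulary separately.
ACTION_VERBS = (
    "run", "jump", "swim", "climb", "reach", "grab", "throw", "catch", "push",
    "pull", "wash", "dry", "walk", "steal", "fall", "slip", "stand", "carry",
    "lift", "drop", "spill", "wipe", "stretch", "kick", "swing", "hand",
    "point", "step", "tip", "scrub",
)
NON_ACTION_VERBS = (
    "think", "hope", "want", "know", "believe", "seem", "like", "love",
    "wish", "remember", "forget", "notice", "wonder", "feel", "mean",
    "imagine", "expect", "guess", "suppose", "dream", "worry", "care",
    "prefer", "doubt", "agree", "understand", "intend", "assume", "recall",
    "consider",
)
NOUNS = (
    "boy", "girl", "mother", "cookie", "jar", "stool", "sink", "water",
    "window", "curtain", "plate", "kitchen", "cupboard", "counter", "dish",
    "floor", "ladder", "bulb", "lamp", "chair", "table", "garden", "cup",
    "towel", "shelf", "door", "hand", "apron", "faucet", "ceiling",
)
FUNCTION_WORDS = (
    "the", "a", "and", "is", "are", "on", "in", "to", "of", "with", "while",
    "she", "he", "it", "there", "that", "this", "over", "under", "by",
)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort-level generator settings; defaults are the strong-effect condition."""

    n_subjects: int = 25
    rng_seed: int = 0
    task_set: tuple[str, ...] = TASKS
    sample_rate: int = 44100
    duration_s: float = 20.0          # picture / counting speech duration
    ddk_duration_s: float = 10.0      # rapid "pa-ta-ka" task duration
    syllable_rate_on: float = 4.0     # syllables / s
    syllable_rate_off: float = 4.0
    ddk_syllable_rate: float = 5.0
    interval_tail_shift: float = 0.1  # s added to upper-tail ON intervals
    tail_prob: float = 0.25           # fraction of intervals in the upper tail
    high_band_gain_on: float = 6.0    # dB in the high band
    high_band_gain_off: float = 0.0
    low_band_gain_on: float = 0.0     # dB below the low cut
    low_band_gain_off: float = 0.0
    low_cut_hz: float = 8000.0
    high_band_hz: tuple[float, float] = (9500.0, 12600.0)
    gain_jitter_db: float = 1.5       # per-recording session variability, dB sd
    rate_jitter: float = 0.15         # per-recording tempo variability, syll/s sd
    f0_mean: float = 120.0            # glottal pulse rate, Hz
    f0_sd: float = 5.0                # between-subject f0 spread
    pause_rate: float = 6.0           # pauses / min
    pause_duration_s: float = 0.5
    action_verb_prob_on: float = 0.8
    action_verb_prob_off: float = 0.2
    words_per_transcript: int = 120
    embedding_dim: int = 16
    noise_sd: float = 0.001           # amplitude units

    def __post_init__(self) -> None:
        object.__setattr__(self, "task_set", tuple(self.task_set))
        object.__setattr__(self, "high_band_hz", tuple(self.high_band_hz))
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be at least 2")
        for name in ("action_verb_prob_on", "action_verb_prob_off", "tail_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {p}")
        for name in (
            "sample_rate", "duration_s", "ddk_duration_s", "syllable_rate_on",
            "syllable_rate_off", "ddk_syllable_rate", "pause_duration_s",
            "words_per_transcript", "embedding_dim",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.pause_rate < 0 or self.noise_sd < 0 or self.interval_tail_shift < 0:
            raise ParameterError("rates, noise_sd and tail shift must be non-negative")
        unknown = set(self.task_set) - set(TASKS)
        if unknown:
            raise ParameterError(f"unknown tasks {sorted(unknown)}")

    @classmethod
    def null(cls, **overrides) -> "SyntheticCohortConfig":
        """Zero-effect configuration: ON and OFF are exchangeable."""
        base = dict(
            interval_tail_shift=0.0,
            high_band_gain_on=0.0,
            high_band_gain_off=0.0,
            low_band_gain_on=0.0,
            low_band_gain_off=0.0,
            action_verb_prob_on=0.5,
            action_verb_prob_off=0.5,
            syllable_rate_on=4.0,
            syllable_rate_off=4.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticSubject:
    """One subject's paired recordings, transcripts and drawn ground truth."""

    subject_id: str
    recordings: dict[tuple[str, str], AudioRecording]  # (task, state) -> audio
    truths: dict[tuple[str, str], dict]                # burst times, pauses, gains
    transcripts: dict[str, Transcript]                 # state -> picture transcript
    params: dict


def _voiced_carrier(n: int, sr: int, f0: float) -> np.ndarray:
    """Peak-normalised harmonic pulse train through one vocal-tract resonance."""
    pulses = np.zeros(n)
    period = max(int(round(sr / f0)), 1)
    pulses[::period] = 1.0
    # single resonance around 500 Hz (two-pole IIR, r=0.97)
    r, theta = 0.97, 2 * np.pi * 500.0 / sr
    voiced = sps.lfilter([1.0], [1.0, -2 * r * np.cos(theta), r * r], pulses)
    peak = np.max(np.abs(voiced))
    return voiced / peak if peak > 0 else voiced


def _voiced_burst(n: int, sr: int, f0: float, rng: np.random.Generator) -> np.ndarray:
    """One syllable: enveloped harmonic carrier plus aspiration noise."""
    aspiration = 0.2 * rng.standard_normal(n)
    return (_voiced_carrier(n, sr, f0) + aspiration) * np.hanning(n)


def synthesize_utterance(
    duration_s: float,
    syllable_rate: float,
    band_gains: tuple[float, float] = (0.0, 0.0),
    pause_spec: tuple[float, float] | None = None,
    sample_rate: int = 44100,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.001,
    interval_tail_shift: float = 0.0,
    tail_prob: float = 0.25,
    low_cut_hz: float = 8000.0,
    high_band_hz: tuple[float, float] = (9500.0, 12600.0),
    f0: float = 120.0,
    amplitude: float = 0.3,
    interval_jitter: float = 0.08,
    bridge_level_db: float = -20.0,
) -> tuple[AudioRecording, dict]:
    """One synthetic utterance plus its ground truth.

    ``band_gains`` is (low_dB, high_dB): the low gain applies below
    ``low_cut_hz`` and the high gain inside the ``high_band_hz`` band;
    ``pause_spec`` is (pauses_per_minute, pause_duration_s); pauses are
    spliced into inter-burst gaps, lengthening the recording.  A continuous
    low-level voicing "bridge" (about -22 dB re the burst peaks) fills the
    short gaps between syllables, so only the spliced silences fall under a
    -25 dB pause threshold.  Returns ``(recording, truth)`` where ``truth``
    holds burst onset times (seconds), pause intervals and the applied gains.
    """
    if duration_s < 1.0:
        raise ParameterError("duration_s must be at least 1 s")
    if not 0.5 < syllable_rate < 10.0:
        raise ParameterError("syllable_rate must lie in (0.5, 10) syllables/s")
    rng = np.random.default_rng(0) if rng is None else rng
    sr = sample_rate
    base = 1.0 / syllable_rate
    burst_len = int(round(0.55 * base * sr))

    # draw syllable onsets; upper-tail intervals optionally lengthened
    onsets, t = [], 0.02
    while t + burst_len / sr <= duration_s:
        onsets.append(t)
        gap = base * float(np.exp(rng.normal(0.0, interval_jitter))) if interval_jitter > 0 else base
        if interval_tail_shift > 0 and rng.random() < tail_prob:
            gap += interval_tail_shift
        t += gap
    n_total = int(round((onsets[-1] if onsets else 0) * sr)) + burst_len
    n_total = max(n_total, int(round(duration_s * sr)))
    sig = np.zeros(n_total)
    for onset in onsets:
        i = int(round(onset * sr))
        sig[i : i + burst_len] += amplitude * _voiced_burst(burst_len, sr, f0, rng)

    # continuous voicing bridge, bridge_level_db below the loudest 32 ms frame,
    # so inter-syllable gaps stay above a -25 dB pause threshold
    win = int(round(0.032 * sr))
    frames = np.lib.stride_tricks.sliding_window_view(sig, win)[:: int(round(0.010 * sr))]
    r_max = float(np.sqrt(np.max(np.mean(frames**2, axis=1))))
    carrier = _voiced_carrier(n_total, sr, f0)
    c_rms = float(np.sqrt(np.mean(carrier**2)))
    if c_rms > 0 and r_max > 0:
        sig = sig + carrier * (r_max * 10 ** (bridge_level_db / 20.0) / c_rms)

    low_db, high_db = band_gains
    if low_db != 0.0:
        sos = sps.butter(4, low_cut_hz, btype="low", fs=sr, output="sos")
        low = sps.sosfiltfilt(sos, sig)
        sig = sig + low * (10 ** (low_db / 20.0) - 1.0)
    if high_db != 0.0:
        sos = sps.butter(4, high_band_hz, btype="bandpass", fs=sr, output="sos")
        band = sps.sosfiltfilt(sos, sig)
        sig = sig + band * (10 ** (high_db / 20.0) - 1.0)

    onsets_arr = np.array(onsets)
    pauses: list[tuple[float, float]] = []
    if pause_spec is not None and pause_spec[0] > 0 and len(onsets) > 3:
        per_min, pdur = pause_spec
        n_pauses = int(round(per_min * duration_s / 60.0))
        n_pause_samples = int(round(pdur * sr))
        # splice silence into randomly chosen inter-burst gaps, front to back
        # so earlier insertions shift everything that follows consistently
        candidate_gaps = np.arange(1, len(onsets) - 1)
        chosen = np.sort(
            rng.choice(candidate_gaps, size=min(n_pauses, candidate_gaps.size), replace=False)
        )
        for g in chosen:
            cut_t = onsets_arr[g] - 0.2 * base  # just before burst g
            cut = int(round(cut_t * sr))
            sig = np.concatenate([sig[:cut], np.zeros(n_pause_samples), sig[cut:]])
            onsets_arr[g:] += pdur
            pauses.append((cut_t, cut_t + pdur))

    sig = sig + noise_sd * rng.standard_normal(sig.size) if noise_sd > 0 else sig
    rec = AudioRecording(samples=np.clip(sig, -1.0, 1.0), sample_rate=sr)
    truth = {
        "burst_times": onsets_arr,
        "pauses": pauses,
        "band_gains": (low_db, high_db),
        "syllable_rate": syllable_rate,
    }
    return rec, truth


def generate_transcript(
    state: str, config: SyntheticCohortConfig, rng: np.random.Generator
) -> Transcript:
    """Tokens with noun/verb/other tags; verbs come from the action pool with
    the state's action-verb probability."""
    if not (ACTION_VERBS and NON_ACTION_VERBS and NOUNS and FUNCTION_WORDS):
        raise ConfigurationError("word pools must be nonempty")
    p_action = (
        config.action_verb_prob_on if state == "ON" else config.action_verb_prob_off
    )
    tokens: list[tuple[str, str]] = []
    for _ in range(config.words_per_transcript):
        u = rng.random()
        if u < 0.5:
            tokens.append((str(rng.choice(FUNCTION_WORDS)), "other"))
        elif u < 0.75:
            tokens.append((str(rng.choice(NOUNS)), "noun"))
        else:
            pool = ACTION_VERBS if rng.random() < p_action else NON_ACTION_VERBS
            tokens.append((str(rng.choice(pool)), "verb"))
    return Transcript(tokens=tokens)


def generate_toy_embeddings(
    vocab, dim: int, rng: np.random.Generator, spread: float = 0.4
) -> EmbeddingTable:
    """Unit-norm toy vectors with action words opposite non-action words.

    One random unit axis ``u`` anchors action concepts (+u) and non-action
    concepts (-u); pool words scatter around their anchor with Gaussian noise
    of scale ``spread``; all other words are isotropic.  This guarantees
    action-pool words are nearer the action seeds than the non-action seeds.
    """
    if dim < 2:
        raise ParameterError("embedding_dim must be at least 2")
    vocab = set(vocab)
    missing = set(SEED_WORDS) - vocab
    if missing:
        raise ConfigurationError(f"vocabulary must include the seed words; missing {sorted(missing)}")
    u = rng.standard_normal(dim)
    u /= np.linalg.norm(u)
    action_like = set(ACTION_VERBS) | {"action", "act", "move", "play", "energetic"}
    non_action_like = set(NON_ACTION_VERBS) | {"inaction", "sleep", "rest", "sit", "wait"}
    vectors: dict[str, np.ndarray] = {}
    for word in sorted(vocab):
        if word in action_like:
            v = u + spread * rng.standard_normal(dim)
        elif word in non_action_like:
            v = -u + spread * rng.standard_normal(dim)
        else:
            v = rng.standard_normal(dim)
        vectors[word] = v / np.linalg.norm(v)
    return EmbeddingTable(vectors)


def default_vocabulary() -> set[str]:
    return set(ACTION_VERBS) | set(NON_ACTION_VERBS) | set(NOUNS) | set(FUNCTION_WORDS) | set(SEED_WORDS)


def _subject_rng(seed: int, *path: int) -> np.random.Generator:
    """Independent stream per (subject, task, state): adding subjects never
    perturbs existing ones."""
    return np.random.default_rng([seed & 0x7FFFFFFF, *path])


def iter_cohort(config: SyntheticCohortConfig):
    """Yield SyntheticSubject one at a time (memory-friendly for long audio)."""
    state_idx = {"OFF": 0, "ON": 1}
    for s in range(config.n_subjects):
        sid = f"S{s + 1:02d}"
        base_rng = _subject_rng(config.rng_seed, s, 99, 99)
        rate_offset = float(base_rng.normal(0.0, 0.25))     # subject tempo baseline
        gain_offset = float(base_rng.normal(0.0, 0.75))     # subject spectral baseline, dB
        f0 = float(base_rng.normal(config.f0_mean, config.f0_sd))
        recordings: dict[tuple[str, str], AudioRecording] = {}
        truths: dict[tuple[str, str], dict] = {}
        transcripts: dict[str, Transcript] = {}
        for t_idx, task in enumerate(TASKS):
            if task not in config.task_set:
                continue
            for state in ("OFF", "ON"):
                rng = _subject_rng(config.rng_seed, s, t_idx, state_idx[state])
                # per-recording session variability on gains and tempo
                jit_low = float(rng.normal(0.0, config.gain_jitter_db))
                jit_high = float(rng.normal(0.0, config.gain_jitter_db))
                jit_rate = float(rng.normal(0.0, config.rate_jitter))
                if task == "ddk":
                    rate = config.ddk_syllable_rate + rate_offset + jit_rate
                    dur = config.ddk_duration_s
                    pause_spec = None
                else:
                    rate = (
                        config.syllable_rate_on if state == "ON" else config.syllable_rate_off
                    ) + rate_offset + jit_rate
                    dur = config.duration_s
                    pause_spec = (config.pause_rate, config.pause_duration_s)
                gains = (
                    (config.low_band_gain_on if state == "ON" else config.low_band_gain_off)
                    + gain_offset + jit_low,
                    (config.high_band_gain_on if state == "ON" else config.high_band_gain_off)
                    + gain_offset + jit_high,
                )
                rec, truth = synthesize_utterance(
                    duration_s=dur,
                    syllable_rate=rate,
                    band_gains=gains,
                    pause_spec=pause_spec,
                    sample_rate=config.sample_rate,
                    rng=rng,
                    noise_sd=config.noise_sd,
                    interval_tail_shift=(
                        config.interval_tail_shift if state == "ON" else 0.0
                    ),
                    tail_prob=config.tail_prob,
                    low_cut_hz=config.low_cut_hz,
                    high_band_hz=config.high_band_hz,
                    f0=f0,
                )
                rec.subject_id, rec.task, rec.state = sid, task, state
                recordings[(task, state)] = rec
                truths[(task, state)] = truth
                if task == "picture":
                    transcripts[state] = generate_transcript(state, config, rng)
        yield SyntheticSubject(
            subject_id=sid,
            recordings=recordings,
            truths=truths,
            transcripts=transcripts,
            params={"rate_offset": rate_offset, "gain_offset": gain_offset},
        )


def generate_cohort(config: SyntheticCohortConfig) -> list[SyntheticSubject]:
    """The full paired cohort as a list (see :func:`iter_cohort`)."""
    return list(iter_cohort(config))


def cohort_embeddings(config: SyntheticCohortConfig) -> EmbeddingTable:
    """The toy embedding table shared by a cohort (seeded from the config)."""
    rng = _subject_rng(config.rng_seed, 7_777)
    return generate_toy_embeddings(default_vocabulary(), config.embedding_dim, rng)


def generate_feature_table(
    n_subjects: int,
    feature_spec: list[tuple[str, float, float]],
    rng: np.random.Generator,
    task: str = "picture",
) -> pd.DataFrame:
    """Fast Gaussian paired feature table for classifier/statistics tests.

    ``feature_spec`` lists (name, within-state sd, ON-OFF mean shift); each
    subject gets a N(0,1) baseline shared by both states, so the paired
    design recovers the shift against the within-state sd.
    """
    if n_subjects < 2:
        raise ParameterError("n_subjects must be at least 2")
    rows = []
    for s in range(n_subjects):
        sid = f"S{s + 1:02d}"
        off_row = {"subject": sid, "task": task, "state": "OFF"}
        on_row = {"subject": sid, "task": task, "state": "ON"}
        for name, sd, shift in feature_spec:
            baseline = rng.normal(0.0, 1.0)
            off_row[name] = baseline + rng.normal(0.0, sd)
            on_row[name] = baseline + shift + rng.normal(0.0, sd)
        rows.append(off_row)
        rows.append(on_row)
    return pd.DataFrame(rows)


def write_cohort(
    cohort: list[SyntheticSubject] | SyntheticCohortConfig,
    outdir: str | Path,
    embeddings: EmbeddingTable | None = None,
) -> Path:
    """Write WAVs, transcripts, embeddings and a manifest CSV under ``outdir``.

    Accepts either a materialised cohort or a config (streamed subject by
    subject).  Returns the manifest path.
    """
    outdir = Path(outdir)
    (outdir / "wav").mkdir(parents=True, exist_ok=True)
    (outdir / "transcripts").mkdir(exist_ok=True)
    if isinstance(cohort, SyntheticCohortConfig):
        if embeddings is None:
            embeddings = cohort_embeddings(cohort)
        subjects = iter_cohort(cohort)
    else:
        subjects = iter(cohort)
    rows = []
    for subj in subjects:
        for (task, state), rec in subj.recordings.items():
            wav_path = outdir / "wav" / f"{subj.subject_id}_{task}_{state}.wav"
            write_wav(rec, wav_path)
            truth = subj.truths[(task, state)]
            transcript_path = ""
            if task == "picture":
                tpath = outdir / "transcripts" / f"{subj.subject_id}_{state}.tsv"
                subj.transcripts[state].to_tsv(tpath)
                transcript_path = str(tpath.relative_to(outdir))
            rows.append(
                {
                    "subject": subj.subject_id,
                    "task": task,
                    "state": state,
                    "wav_path": str(wav_path.relative_to(outdir)),
                    "transcript_path": transcript_path,
                    "n_bursts": len(truth["burst_times"]),
                    "low_gain_db": truth["band_gains"][0],
                    "high_gain_db": truth["band_gains"][1],
                    "syllable_rate": truth["syllable_rate"],
                }
            )
    if embeddings is not None:
        embeddings.to_text(outdir / "embeddings.txt")
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
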