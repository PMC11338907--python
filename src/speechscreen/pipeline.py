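"""End-to-end orchestration: synthesize or ingest -> extract -> test -> evaluate.

Every run writes a manifest (config snapshot, seeds, package version, SHA-256
of each artifact) so a rerun with identical config and seed is bit-identical
and auditable.  All randomness flows from one master seed, split per stage
with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acoustic import AcousticConfig, extract_acoustic
from .audio import AudioSignal, SegmentSet, read_wav, write_wav
from .linguistic import (
    IULexicon,
    extract_linguistic,
    read_transcripts_jsonl,
    write_transcripts_jsonl,
)
from .perm import difference_table
from .schema import ACOUSTIC_COLUMNS, LINGUISTIC_COLUMNS, validate_feature_table
from .evaluate import compare_feature_sets, render_accuracy_table, render_metrics_table, zscore_by_gender
from .synth import gen_transcript, gen_subject_cohort, synthesize_voice


@dataclass
class RunConfig:
    """Flat run configuration; paths may be None in synthetic mode."""

    out_dir: str = "speechscreen_run"
    seed: int = 0
    # synthetic-cohort stage
    synthetic: bool = True
    n_hc: int = 4
    n_mci: int = 4
    n_ad: int = 4
    duration_s: float = 2.5
    sample_rate_hz: float = 16000.0
    n_tokens: int = 120
    # ingest paths (used when synthetic = False)
    audio_dir: str | None = None
    segments_tsv: str | None = None
    transcripts_jsonl: str | None = None
    metadata_csv: str | None = None
    lexicon_json: str | None = None
    # acoustic parameters
    pitch_floor_hz: float = 75.0
    pitch_ceiling_hz: float = 500.0
    # statistics
    n_perm: int = 2000
    alternative: str = "two-sided"
    # evaluation
    tasks: tuple = ("HC_vs_AD", "HC_vs_CI")
    feature_sets: tuple = ("acoustic", "linguistic", "all")
    nested: bool = False

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")
        if not self.synthetic:
            for name in ("audio_dir", "segments_tsv", "transcripts_jsonl", "metadata_csv"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"non-synthetic run requires {name}")
                if not Path(p).exists():
                    raise ValueError(f"{name} does not exist: {p}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.alternative not in ("two-sided", "greater"):
            raise ValueError("alternative must be 'two-sided' or 'greater'")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def synth_stage(config: RunConfig, out: Path, seed: int) -> tuple[Path, Path, Path, Path]:
    """Write synthetic WAVs, segment table, transcripts and subject metadata."""
    audio_dir = out / "audio"
    audio_dir.mkdir(parents=True, exist_ok=True)
    subjects = gen_subject_cohort(
        {"HC": config.n_hc, "MCI": config.n_mci, "AD": config.n_ad},
        seed=seed,
        duration_s=config.duration_s,
        sample_rate_hz=config.sample_rate_hz,
        n_tokens=config.n_tokens,
    )
    fs = config.sample_rate_hz
    gap = np.zeros(int(0.15 * fs))
    lead = np.zeros(int(0.2 * fs))
    seg_rows = []
    transcripts = []
    meta_rows = []
    for s in subjects:
        voice, _, _ = synthesize_voice(s.voice)
        third = len(voice.samples) // 3
        chunks = [voice.samples[:third], voice.samples[third : 2 * third], voice.samples[2 * third :]]
        pieces, t = [lead], len(lead) / fs
        for i, ch in enumerate(chunks):
            seg_rows.append({"subject_id": s.subject_id, "start_s": round(t, 6),
                             "end_s": round(t + len(ch) / fs, 6)})
            pieces.append(ch)
            t += len(ch) / fs
            if i < len(chunks) - 1:
                pieces.append(gap)
                t += len(gap) / fs
        pieces.append(lead)
        write_wav(audio_dir / f"{s.subject_id}.wav", AudioSignal(np.concatenate(pieces), fs))
        transcripts.append(gen_transcript(s.transcript, subject_id=s.subject_id))
        meta_rows.append({"subject_id": s.subject_id, "gender": s.gender, "group": s.group})

    segments_tsv = out / "segments.tsv"
    pd.DataFrame(seg_rows).to_csv(segments_tsv, sep="\t", index=False)
    transcripts_jsonl = out / "transcripts.jsonl"
    write_transcripts_jsonl(transcripts_jsonl, transcripts)
    metadata_csv = out / "subjects.csv"
    pd.DataFrame(meta_rows).to_csv(metadata_csv, index=False)
    return audio_dir, segments_tsv, transcripts_jsonl, metadata_csv


def read_segments_tsv(path: str | Path) -> dict[str, SegmentSet]:
    df = pd.read_csv(path, sep="\t")
    needed = {"subject_id", "start_s", "end_s"}
    if not needed <= set(df.columns):
        raise ValueError(f"segment table needs columns {sorted(needed)}")
    return {
        str(sid): SegmentSet(sub[["start_s", "end_s"]].to_numpy())
        for sid, sub in df.groupby("subject_id", sort=True)
    }


def extract_stage(
    audio_dir: Path,
    segments_tsv: Path,
    transcripts_jsonl: Path,
    metadata_csv: Path,
    lexicon_json: Path | None,
    acoustic_config: AcousticConfig,
) -> pd.DataFrame:
    """Per-subject acoustic + linguistic extraction merged with metadata."""
    meta = pd.read_csv(metadata_csv, dtype={"subject_id": str})
    segments = read_segments_tsv(segments_tsv)
    lex = IULexicon.from_json(lexicon_json) if lexicon_json else IULexicon.default()
    transcripts = {t.subject_id: t for t in read_transcripts_jsonl(transcripts_jsonl)}

    rows = []
    for sid in meta["subject_id"]:
        wav = Path(audio_dir) / f"{sid}.wav"
        if not wav.exists():
            raise FileNotFoundError(f"extract stage: no audio for subject {sid}: {wav}")
        if sid not in segments:
            raise ValueError(f"extract stage: no segments for subject {sid}")
        if sid not in transcripts:
            raise ValueError(f"extract stage: no transcript for subject {sid}")
        ac = extract_acoustic(read_wav(wav), segments[sid], acoustic_config)
        lg = extract_linguistic(transcripts[sid], lex)
        rows.append(
            {"subject_id": sid,
             **dict(zip(ACOUSTIC_COLUMNS, ac.to_list())),
             **dict(zip(LINGUISTIC_COLUMNS, lg.to_list()))}
        )
    feats = pd.DataFrame(rows)
    table = meta.merge(feats, on="subject_id", validate="one_to_one")
    validate_feature_table(table)
    return table


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the artifact set plus a manifest.

    Returns the manifest dict.  Reruns with identical config and seed
    produce byte-identical artifacts.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seed_synth, seed_stats, seed_eval = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )

    if config.synthetic:
        audio_dir, segments_tsv, transcripts_jsonl, metadata_csv = synth_stage(
            config, out / "synth", seed_synth
        )
    else:
        audio_dir = Path(config.audio_dir)
        segments_tsv = Path(config.segments_tsv)
        transcripts_jsonl = Path(config.transcripts_jsonl)
        metadata_csv = Path(config.metadata_csv)

    acfg = AcousticConfig(
        pitch_floor_hz=config.pitch_floor_hz, pitch_ceiling_hz=config.pitch_ceiling_hz
    )
    table = extract_stage(
        audio_dir, segments_tsv, transcripts_jsonl, metadata_csv,
        Path(config.lexicon_json) if config.lexicon_json else None, acfg,
    )
    features_csv = out / "features.csv"
    table.to_csv(features_csv, index=False)

    perm_csv = out / "permutation_results.csv"
    difference_table(table, n_perm=config.n_perm, seed=seed_stats,
                     alternative=config.alternative).to_csv(perm_csv, index=False)

    normalized = zscore_by_gender(table, feature_cols=ACOUSTIC_COLUMNS + LINGUISTIC_COLUMNS)
    results = compare_feature_sets(
        normalized, seed=seed_eval, tasks=config.tasks,
        feature_sets=config.feature_sets, nested=config.nested,
    )
    eval_json = out / "evaluation.json"
    eval_json.write_text(
        json.dumps([r.to_dict() for r in results], indent=2, sort_keys=True) + "\n"
    )
    tables_md = out / "report_tables.md"
    tables_md.write_text(render_accuracy_table(results) + "\n" + render_metrics_table(results))

    artifacts = [features_csv, perm_csv, eval_json, tables_md]
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "stage_seeds": {"synth": seed_synth, "stats": seed_stats, "eval": seed_eval},
        "n_subjects": int(len(table)),
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
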