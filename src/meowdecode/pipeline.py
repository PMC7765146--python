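"""End-to-end pipeline: synthesis -> features -> exemplars -> survey -> PCA.

`run_pipeline` executes the full chain on synthetic inputs (or on a
directory of WAV files plus a labels CSV) and writes every intermediate
table to the output directory, together with a manifest recording the
configuration hash, seeds and package version.  Given the same config and
seed, reruns produce byte-identical CSV output.

The master seed fans out to fixed per-stage offsets so each stage is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .audio import read_wav, write_wav
from .exemplars import anova_screen, select_exemplars
from .features import (
    DEFAULT_CONF_THRESHOLD,
    DEFAULT_FMAX,
    DEFAULT_FMIN,
    FRAME_LEN,
    HOP,
    features_dataframe,
)
from .pca import pca_descriptors, plot_pca, valence_summary
from .survey import analyze, cohort_frames
from .synth import CohortSpec, synth_cohort, synth_corpus

log = logging.getLogger(__name__)

# Fixed per-stage seed offsets from the master seed.
_AUDIO_SEED_OFFSET = 0
_COHORT_SEED_OFFSET = 1009


@dataclass
class PipelineConfig:
    """All pipeline parameters, serializable to/from YAML."""

    # inputs: either synthesize (default) or point at real recordings
    synth_audio: bool = True
    n_per_class: int = 10
    audio_dir: str | None = None
    labels_csv: str | None = None
    # framing
    frame_len: int = FRAME_LEN
    hop: int = HOP
    fmin: float = DEFAULT_FMIN
    fmax: float = DEFAULT_FMAX
    conf_threshold: float = DEFAULT_CONF_THRESHOLD
    # screening/selection
    alpha: float = 0.05
    standardize: bool = True
    # survey
    n_participants: int = 225
    chisq_correction: bool = False
    # pca
    pca_mode: str = "correlation"
    pca_subset: str = "correct_only"
    # reproducibility
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    # Every output carries the config hash so files can be traced to the
    # exact run that produced them.
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_labeled_corpus(audio_dir, labels_csv):
    """Load (clip_id, context, clip) triples from a labels CSV.

    The CSV needs columns ``clip_id, context, path`` with paths relative
    to ``audio_dir``.
    """
    labels = pd.read_csv(labels_csv, comment="#")
    corpus = []
    for _, row in labels.iterrows():
        clip = read_wav(Path(audio_dir) / row["path"])
        corpus.append((str(row["clip_id"]), str(row["context"]), clip))
    return corpus


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run every stage and write the report directory; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stage = "setup"
    try:
        # --- stage 1: audio corpus -------------------------------------
        stage = "synth_audio"
        if config.synth_audio:
            corpus = synth_corpus(n_per_class=config.n_per_class,
                                  seed=config.seed + _AUDIO_SEED_OFFSET)
            wav_dir = out / "audio"
            wav_dir.mkdir(exist_ok=True)
            rows = []
            for clip_id, ctx, clip in corpus:
                rel = f"{clip_id}.wav"
                write_wav(wav_dir / rel, clip)
                rows.append({"clip_id": clip_id, "context": ctx, "path": rel})
            _write_csv(pd.DataFrame(rows), out / "labels.csv", chash)
        else:
            if not (config.audio_dir and config.labels_csv):
                raise ValueError("need audio_dir and labels_csv when "
                                 "synth_audio is false")
            corpus = read_labeled_corpus(config.audio_dir, config.labels_csv)

        # --- stage 2: acoustic features --------------------------------
        stage = "features"
        feats = features_dataframe(
            corpus, frame_len=config.frame_len, hop=config.hop,
            fmin=config.fmin, fmax=config.fmax,
            conf_threshold=config.conf_threshold)
        _write_csv(feats, out / "features.csv", chash)

        # --- stage 3: screen + exemplars --------------------------------
        stage = "exemplar_selection"
        screen = anova_screen(feats, alpha=config.alpha)
        _write_csv(screen.table, out / "screen.csv", chash)
        exemplars = select_exemplars(feats, screen.kept or None
                                     or screen.table["feature"].tolist(),
                                     standardize=config.standardize)
        _write_csv(exemplars.to_frame(), out / "exemplars.csv", chash)

        # --- stage 4: survey cohort + statistics ------------------------
        stage = "survey"
        cohort = synth_cohort(CohortSpec(
            n_participants=config.n_participants,
            seed=config.seed + _COHORT_SEED_OFFSET))
        participants, responses = cohort_frames(cohort)
        _write_csv(participants, out / "participants.csv", chash)
        _write_csv(responses, out / "responses.csv", chash)
        report = analyze(participants, responses)
        scores = report.pop("scores")
        _write_csv(scores, out / "participant_scores.csv", chash)
        acc_rows = []
        for ctx, d in report["contexts"].items():
            for variant in ("medioid", "outlier"):
                acc_rows.append({"context": ctx, "variant": variant,
                                 **{k: d[variant][k] for k in
                                    ("correct", "incorrect", "pct_correct",
                                     "pct_incorrect")}})
        _write_csv(pd.DataFrame(acc_rows), out / "accuracy.csv", chash)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)

        # --- stage 5: descriptor PCA ------------------------------------
        stage = "pca"
        pca_res = pca_descriptors(responses, subset=config.pca_subset,
                                  mode=config.pca_mode)
        _write_csv(pca_res.loadings.rename_axis("descriptor").reset_index(),
                   out / "pca_loadings.csv", chash)
        _write_csv(pca_res.scores.reset_index(drop=True),
                   out / "pca_scores.csv", chash)
        _write_csv(pd.DataFrame({
            "component": [f"PC{i + 1}" for i in
                          range(len(pca_res.explained_variance_pct))],
            "explained_variance_pct": pca_res.explained_variance_pct,
        }), out / "pca_explained.csv", chash)
        summary = valence_summary(pca_res)
        _write_csv(summary["context_scores"], out / "pca_context_scores.csv",
                   chash)
        plot_pca(pca_res, out / "pca_plot.svg")

        # --- manifest ----------------------------------------------------
        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "config": dataclasses.asdict(config),
            "config_hash": chash,
            "stage_seeds": {
                "audio": config.seed + _AUDIO_SEED_OFFSET,
                "cohort": config.seed + _COHORT_SEED_OFFSET,
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return out


def demo_config(seed: int = 0) -> PipelineConfig:
    """Small, fast demonstration configuration (fully synthetic)."""
    return PipelineConfig(n_per_class=6, n_participants=120, seed=seed)
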