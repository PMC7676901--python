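"""End-to-end pipeline: simulate -> preprocess -> extract -> pca -> model.

Every stage reads from / writes to a run directory, stamps its outputs with
a hash of the configuration, and draws all randomness from the single
configured seed, so a rerun with identical (config, seed) is bit-identical
for simulation-driven runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import edfio, preprocess, synth
from .features import FeatureConfig, extract_table
from .montage import default_subregion_map
from .pca import build_matrix, fit_pca, subregion_scores
from .recording import ConditionManifest
from .stats import exam_zscores, predict_exam, score_models

log = logging.getLogger("eeglisten")

STAGES = ("simulate", "preprocess", "extract", "pca", "model")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with study-scale defaults.

    The cohort block mirrors the target study design (23 participants, 13
    lecture topics, 64 channels at 512 Hz); reduce it for desk-scale runs.
    Estimator parameters default to the analysis conventions: 0.5-134 Hz
    band-pass of order 3380, Welch with 1 s Hamming windows and 2^14 bins,
    DFA fit on 5-18 s, nine PCs carried into the statistics stage.
    """

    out: str = "runs/run0"
    seed: int = 0
    # the preprocess stage only materializes fragment EDFs on disk; feature
    # extraction streams the same preprocessing, so it is opt-in
    stages: tuple = ("simulate", "extract", "pca", "model")
    # cohort
    n_participants: int = 23
    n_channels: int = 64
    fs: float = 512.0
    n_topics: int = 13
    n_background_fragments: int = 12
    # every topic needs >= 2 pink-noise presentations for the exam
    # reference, so n_participants must be >= 2 x len(backgrounds)
    backgrounds: tuple = ("PK", "MT", "HW", "FT")
    la_duration_s: float = 300.0
    ba_duration_s: float = 180.0
    onef_exponent: float = 1.0
    sync_delay_range: tuple = (20, 200)  # samples, drawn per participant
    # planted effects
    fixed_shifts: dict = field(default_factory=dict)
    exam_weights: dict = field(default_factory=lambda: {"hurst": -2.0})
    participant_sd: float = 0.1
    fragment_sd: float = 0.1
    exam_noise_sd: float = 1.5
    # preprocessing
    reference: str = "Nose"
    band: tuple | None = None  # default (0.5, min(134, 0.45 fs))
    filter_order: int = 3380
    exclusions_csv: str | None = None  # manual artifact-rejection stand-in
    # features
    features: FeatureConfig = field(default_factory=FeatureConfig)
    # pca / stats
    k_pcs: int = 9
    exam_model_mode: str = "mixed"
    alpha_level: float = 0.05

    def cohort_spec(self) -> synth.CohortSpec:
        return synth.CohortSpec(
            n_participants=self.n_participants, fs=self.fs,
            n_channels=self.n_channels, seed=self.seed,
            backgrounds=tuple(self.backgrounds), n_topics=self.n_topics,
            n_background_fragments=self.n_background_fragments,
            fragment_duration_s={"LA": self.la_duration_s,
                                 "BA": self.ba_duration_s,
                                 "BUA": self.ba_duration_s})

    def effect_plan(self) -> synth.EffectPlan:
        shifts = {tuple(k.split(":")) if isinstance(k, str) else tuple(k): v
                  for k, v in self.fixed_shifts.items()}
        return synth.EffectPlan(
            fixed_shifts=shifts, participant_sd=self.participant_sd,
            fragment_sd=self.fragment_sd, exam_weights=dict(self.exam_weights),
            exam_noise_sd=self.exam_noise_sd)

    def band_edges(self) -> tuple:
        if self.band is not None:
            return tuple(self.band)
        return (0.5, min(134.0, 0.45 * self.fs))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fixed_shifts"] = {":".join(map(str, k)) if isinstance(k, tuple)
                             else k: v for k, v in self.fixed_shifts.items()}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        feat = raw.pop("features", None)
        tup = ("stages", "band", "sync_delay_range", "backgrounds")
        cfg = cls(**{k: tuple(v) if k in tup and v is not None else v
                     for k, v in raw.items()})
        if feat:
            cfg.features = FeatureConfig(**feat)
        return cfg


def _outdir(cfg: PipelineConfig) -> Path:
    p = Path(cfg.out)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _write_meta(cfg: PipelineConfig, stage: str, outputs: list) -> None:
    p = _outdir(cfg) / "manifest.json"
    meta = {}
    if p.exists():
        meta = json.loads(p.read_text())
    meta.setdefault("config_hash", cfg.config_hash())
    if meta["config_hash"] != cfg.config_hash():
        raise RuntimeError("config hash mismatch: run directory belongs to a "
                           "different configuration")
    meta.setdefault("config", cfg.to_dict())
    meta.setdefault("stages", {})
    meta["stages"][stage] = sorted(str(o) for o in outputs)
    p.write_text(json.dumps(meta, indent=2, default=str))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> list:
    """Write per-participant EDFs (with reference drift, playback-delayed
    content and a sync sound channel), the manifest, the planted ground
    truth, the presented audio and the exam table."""
    out = _outdir(cfg)
    spec = cfg.cohort_spec()
    plan = cfg.effect_plan()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    outputs = []
    manifest_rows = []
    truth_all = []
    delays = {}
    for pid, rec, rows, truth_rows in synth.generate_cohort(
            spec, plan, onef_exponent=cfg.onef_exponent):
        manifest_rows.extend(rows)
        truth_all.extend(truth_rows)
        n = rec.n_samples
        t = np.arange(n) / rec.fs
        # common reference drift seen by every electrode incl. the nose
        drift = (20.0 * np.sin(2 * np.pi * 0.3 * t + 2 * np.pi * rng.random())
                 + 5.0 * rng.standard_normal())
        nose = drift + 0.01 * rng.standard_normal(n)
        delay = int(rng.integers(*cfg.sync_delay_range))
        delays[pid] = delay
        audio = synth.synthetic_audio(rec.duration_s, rec.fs, rng)
        data = np.roll(rec.data + drift[None, :], delay, axis=1)
        data[:, :delay] = 0.0
        shifted = rec.copy(data=np.vstack([data, nose]),
                           labels=list(rec.labels) + ["Nose"])
        full = synth.generate_sync_channel(shifted, audio, delay,
                                           noise_sd=0.05, rng=rng)
        path = out / f"{pid}.edf"
        edfio.write_edf(path, full)
        np.save(out / f"{pid}_audio.npy", audio.astype(np.float32))
        outputs += [path, out / f"{pid}_audio.npy"]
        log.info("simulated %s (%d ch, %.0f s, delay %d samples)",
                 pid, full.n_channels, full.duration_s, delay)
    mdf = pd.DataFrame(manifest_rows, columns=[
        "participant", "task", "background", "topic", "start_s", "stop_s"])
    mdf.to_csv(out / "manifest.csv", index=False)
    tdf = pd.DataFrame(truth_all)
    tdf.to_csv(out / "ground_truth.csv", index=False)
    exam = synth.generate_exam_table(plan, tdf, seed=cfg.seed + 1)
    exam.to_csv(out / "exam.csv", index=False)
    sidecar = {"delays": delays, "seed": cfg.seed,
               "config_hash": cfg.config_hash()}
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
    outputs += [out / "manifest.csv", out / "ground_truth.csv",
                out / "exam.csv", out / "ground_truth.json"]
    _write_meta(cfg, "simulate", outputs)
    return outputs


def _preprocessed_fragments(cfg: PipelineConfig):
    """Read each participant EDF, re-reference, synchronize, filter and split;
    yields (fragment, tags)."""
    out = _outdir(cfg)
    manifest = ConditionManifest.from_csv(out / "manifest.csv")
    band = cfg.band_edges()
    exclusions = (preprocess.read_exclusions(cfg.exclusions_csv)
                  if cfg.exclusions_csv else {})
    for pid in sorted(manifest.fragments["participant"].unique()):
        rec = edfio.read_edf(out / f"{pid}.edf")
        rec.exclusions |= exclusions.get(pid, set())
        audio = np.load(out / f"{pid}_audio.npy").astype(np.float64)
        scalp = [lab for lab in rec.labels if lab not in ("Nose", "Sound")]
        delay = preprocess.estimate_delay(rec.channel("Sound"), audio)
        rec = preprocess.rereference(rec, cfg.reference)
        rec = preprocess.compensate_delay(rec, delay, scalp_labels=scalp)
        order = min(cfg.filter_order, rec.n_samples // 3)
        rec = preprocess.resample_filter(rec, target_fs=cfg.fs, band=band,
                                         order=order)
        log.info("preprocessed %s (delay %d)", pid, delay)
        for frag, tags in preprocess.split_fragments(rec, manifest, pid):
            frag_scalp = frag.copy(
                data=np.vstack([frag.channel(lab) for lab in scalp]),
                labels=scalp)
            frag_scalp.meta = frag.meta
            yield frag_scalp, tags


def stage_preprocess(cfg: PipelineConfig) -> list:
    """Write the preprocessed per-condition fragments as EDF files (for
    inspection or external tools; extraction streams them independently)."""
    out = _outdir(cfg)
    frag_dir = out / "fragments"
    frag_dir.mkdir(exist_ok=True)
    outputs = []
    for i, (frag, tags) in enumerate(_preprocessed_fragments(cfg)):
        name = (f"{tags['participant']}_{i:03d}_{tags['task']}_"
                f"{tags['background']}.edf")
        path = frag_dir / name
        edfio.write_edf(path, frag)
        outputs.append(path)
    _write_meta(cfg, "preprocess", outputs)
    return outputs


def stage_extract(cfg: PipelineConfig) -> list:
    out = _outdir(cfg)
    table = extract_table(_preprocessed_fragments(cfg), cfg.features)
    meta = {"config_hash": cfg.config_hash(),
            "features": cfg.features.__dict__}
    path = out / "features.csv"
    table.to_csv(path, index=False)
    (out / "features_meta.json").write_text(
        json.dumps(meta, indent=2, default=str))
    _write_meta(cfg, "extract", [path])
    return [path]


def stage_pca(cfg: PipelineConfig) -> list:
    out = _outdir(cfg)
    table = pd.read_csv(out / "features.csv")
    registry = [c for c in cfg.features.feature_names() if c in table.columns]
    fm = build_matrix(table, registry)
    model = fit_pca(fm)
    k = min(cfg.k_pcs, model.scores.shape[1])
    scores = model.scores_frame(k)
    sub = subregion_scores(model, default_subregion_map(
        sorted(table["channel"].unique(), key=str)), k)
    outputs = []
    for name, df in (("pc_scores", scores), ("subregion_scores", sub)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        outputs.append(p)
    loadings = pd.DataFrame(model.loadings, index=model.feature_names,
                            columns=[f"PC{i+1}" for i in
                                     range(model.loadings.shape[1])])
    loadings.to_csv(out / "pc_loadings.csv")
    pd.DataFrame({"explained_var": model.explained_var}).to_csv(
        out / "pc_explained.csv", index=False)
    model.contributions().to_csv(out / "pc_contributions.csv")
    outputs += [out / "pc_loadings.csv", out / "pc_explained.csv",
                out / "pc_contributions.csv"]
    try:
        from .plotting import scree_plot

        scree_plot(model.explained_var, out / "scree.png")
        outputs.append(out / "scree.png")
    except Exception as exc:  # rendering is never load-bearing
        log.warning("scree plot skipped: %s", exc)
    _write_meta(cfg, "pca", outputs)
    return outputs


def stage_model(cfg: PipelineConfig) -> list:
    out = _outdir(cfg)
    sub = pd.read_csv(out / "subregion_scores.csv")
    exam = pd.read_csv(out / "exam.csv")
    examz = exam_zscores(exam)
    examz.to_csv(out / "exam_zscores.csv", index=False)
    outputs = [out / "exam_zscores.csv"]

    k = min(cfg.k_pcs, sum(c.startswith("PC") for c in sub.columns))
    pred = predict_exam(examz, sub, mode=cfg.exam_model_mode, k=k)
    pred["comparisons"].to_csv(out / "exam_model_comparisons.csv", index=False)
    outputs.append(out / "exam_model_comparisons.csv")

    report = ["# Exam prediction models", ""]
    for name, fit in pred["fits"].items():
        report.append(f"- **{name}**: AIC = {fit.aic:.2f}, "
                      f"logLik = {fit.llf:.2f}, edf = {fit.edf}")
    report.append("")
    report.append(f"Stepwise-retained terms: {', '.join(pred['retained']) or 'none'}")
    coef = pred["fits"]["stepwise_eeg"].params
    report.append("")
    report.append("## Stepwise coefficients")
    for name, val in coef.items():
        report.append(f"- {name}: {val:+.3f}")

    tuk_frames = []
    for by in ("background", "task"):
        try:
            fam = score_models(sub, by=by, k=k)
        except ValueError as exc:
            log.warning("score models by %s skipped: %s", by, exc)
            continue
        for (pc, level), d in fam.items():
            tri = d["tukey"].to_triangular()
            tuk_frames.append(f"\n### {pc} | {by} = {level}\n")
            tuk_frames.append(tri.to_string())
    (out / "model_report.md").write_text("\n".join(report) + "\n")
    (out / "tukey_tables.txt").write_text("\n".join(tuk_frames) + "\n")
    outputs += [out / "model_report.md", out / "tukey_tables.txt"]
    _write_meta(cfg, "model", outputs)
    return outputs


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "extract": stage_extract,
    "pca": stage_pca,
    "model": stage_model,
}


def run(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order."""
    done = {}
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        log.info("=== stage %s ===", stage)
        done[stage] = _STAGE_FUNCS[stage](cfg)
    return done
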