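"""End-to-end experiment orchestration.

``run_experiment`` ties the whole analysis together: synthesize the
factorial stimulus catalog, habituate each configured backbone's autoencoder
on every video, score dishabituation as classification scores with
bootstrap CIs, build dissimilarity matrices, and (optionally) run the
infant looking-time analysis on synthetic records — all from one explicit
configuration with explicit seeds, so every reported number is regenerable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import classify
from .backbones import make_backbone
from .habituation import AutoencoderState, habituate, precompute_features, test_error
from .stimuli import RenderConfig, default_render_config, generate_stimulus_set

log = logging.getLogger("skelshape")

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "compare_backbones"]


@dataclass
class ExperimentConfig:
    """One self-contained experiment description.

    ``task`` selects the counterbalanced test design: "skeleton" (familiar
    test object shares the habituated skeleton, novel one differs — both
    differ in surface form) or "surface_form" (familiar shares the surface
    form, novel differs — both differ in skeleton).
    """

    n_skeletons: int = 3
    n_forms: int = 2
    image_size: int = 64
    n_frames: int = 60
    backbones: tuple = (
        {"name": "skeleton"},
        {"name": "pixel"},
    )
    task: str = "skeleton"
    cap: int = 100
    learning_rate: float = 1e-2
    batch_size: int = 4
    adapter_channels: int = 16
    bootstrap_iterations: int = 5000
    seed: int = 0
    infant: Optional[dict] = None     # kwargs for synth_looking_times, or None
    out_dir: Optional[str] = None

    def render_config(self) -> RenderConfig:
        return default_render_config(self.image_size, self.n_frames)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["backbones"] = [dict(b) for b in self.backbones]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "backbones" in d:
            d["backbones"] = tuple(dict(b) for b in d["backbones"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class ExperimentReport:
    """Everything one run produced, regenerable from config + seeds."""

    config: dict
    config_hash: str
    scores: dict = field(default_factory=dict)          # backbone -> ClassificationScore
    unit_scores: dict = field(default_factory=dict)     # backbone -> list per unit
    matrices: dict = field(default_factory=dict)        # backbone -> DataFrame
    traces: dict = field(default_factory=dict)          # backbone -> {key: trace}
    infant_report: Optional[dict] = None

    def to_json_dict(self) -> dict:
        out = {"config": self.config, "config_hash": self.config_hash, "scores": {}}
        for name, s in self.scores.items():
            out["scores"][name] = {"score": s.score, "ci": [s.ci_low, s.ci_high],
                                   "n_units": s.n_units,
                                   "unit_scores": list(s.unit_scores)}
        out["matrices"] = {k: v.to_dict() for k, v in self.matrices.items()}
        return out


def _test_pairs(catalog, task: str):
    """Counterbalanced (habituation, familiar, novel) triples.

    skeleton task: habituate on (s, f); familiar = (s, f') (same skeleton,
    other form); novel = (s', f') for every s' != s — both test objects
    differ from the habituation object in surface form.

    surface_form task: familiar = (s', f) (same form, other skeleton);
    novel = (s', f') — both test objects differ in skeleton.
    """
    triples = []
    n_s, n_f = catalog.n_skeletons, catalog.n_forms
    for s in range(n_s):
        for f in range(n_f):
            for f2 in range(n_f):
                if f2 == f:
                    continue
                if task == "skeleton":
                    for s2 in range(n_s):
                        if s2 == s:
                            continue
                        triples.append(((s, f), (s, f2), (s2, f2)))
                elif task == "surface_form":
                    for s2 in range(n_s):
                        if s2 == s:
                            continue
                        triples.append(((s, f), (s2, f), (s2, f2)))
                else:
                    raise ValueError("task must be 'skeleton' or 'surface_form'")
    return triples


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the full pipeline for one configuration.

    For each backbone, a fresh autoencoder is habituated on every catalog
    video; each counterbalanced (familiar, novel) test pair contributes one
    unit classification score (responses normalized to the end of
    habituation).  Deterministic for a fixed config.
    """
    t0 = time.time()
    log.info("generating stimulus catalog (%d skeletons x %d forms, %dpx, %d frames)",
             config.n_skeletons, config.n_forms, config.image_size, config.n_frames)
    catalog = generate_stimulus_set(config.n_skeletons, config.n_forms,
                                    seed=config.seed, cfg=config.render_config())
    triples = _test_pairs(catalog, config.task)
    report = ExperimentReport(config=config.to_dict(), config_hash=config.config_hash())
    engine_params = dict(adapter_channels=config.adapter_channels,
                         learning_rate=config.learning_rate,
                         batch_size=config.batch_size)
    for bcfg in config.backbones:
        bcfg = dict(bcfg)
        name = bcfg.pop("name")
        log.info("backbone %s: habituating on %d videos", name, len(catalog.keys()))
        backbone = make_backbone(name, **bcfg)
        cache = {key: precompute_features(backbone, catalog.videos[key])
                 for key in catalog.keys()}
        states, traces = {}, {}
        for i, key in enumerate(catalog.keys()):
            st = AutoencoderState(backbone, seed=config.seed + 1000 + i, **engine_params)
            traces[key] = habituate(st, catalog.videos[key], cap=config.cap,
                                    precomputed=cache[key])
            states[key] = st
        errors = {}
        for hab_key, st in states.items():
            for key in catalog.keys():
                errors[(hab_key, key)] = test_error(st, catalog.videos[key],
                                                    precomputed=cache[key])
        novel_resp, familiar_resp = [], []
        for hab, fam, nov in triples:
            tail = traces[hab].end_level
            familiar_resp.append(errors[(hab, fam)] - tail)
            novel_resp.append(errors[(hab, nov)] - tail)
        score = classify.score_units(novel_resp, familiar_resp,
                                     iterations=config.bootstrap_iterations,
                                     seed=config.seed)
        report.scores[name] = score
        report.unit_scores[name] = list(score.unit_scores)
        keys = catalog.keys()
        mat = np.array([[errors[(hi, kj)] - traces[hi].end_level for kj in keys]
                        for hi in keys])
        import pandas as pd
        names = [f"s{s}f{f}" for s, f in keys]
        report.matrices[name] = pd.DataFrame(mat, index=names, columns=names)
        report.traces[name] = traces
        log.info("backbone %s: score %.3f CI [%.3f, %.3f] (%.1fs elapsed)",
                 name, score.score, score.ci_low, score.ci_high, time.time() - t0)
    if config.infant is not None:
        from .infant import run_infant_analysis, synth_looking_times
        params = dict(config.infant)
        params.setdefault("seed", config.seed)
        records = synth_looking_times(**params)
        report.infant_report = run_infant_analysis(
            records, bootstrap_iterations=config.bootstrap_iterations, seed=config.seed)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report.to_json_dict(), indent=1))
        for name, df in report.matrices.items():
            df.to_csv(out / f"dissimilarity_{name}.csv")
    return report


def compare_backbones(report: ExperimentReport, iterations: int = 5000,
                      seed: int = 0) -> dict:
    """Bootstrap CIs on pairwise score differences over shared test units."""
    names = list(report.unit_scores)
    if len(names) < 2:
        raise ValueError("need at least 2 backbones to compare")
    rng = np.random.default_rng(seed)
    out = {}
    for a in names:
        for b in names:
            ua = np.asarray(report.unit_scores[a])
            ub = np.asarray(report.unit_scores[b])
            n = min(ua.size, ub.size)
            diffs = ua[:n] - ub[:n]
            idx = rng.integers(0, n, size=(iterations, n))
            means = diffs[idx].mean(axis=1)
            out[(a, b)] = {"diff": float(diffs.mean()),
                           "ci": (float(np.quantile(means, 0.025)),
                                  float(np.quantile(means, 0.975)))}
    return out
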