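"""End-to-end pipeline orchestration from a single config file.

Stages run in a fixed order (simulate -> sample -> reliability/resolve ->
train-dict -> score -> build-series -> itsa); each can be toggled.  All
randomness derives from one seed, every written artifact is listed in a
manifest with its SHA-256 hash, and a rerun with the same config reproduces
identical hashes.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import coding, io, itsa, sentiment, series, simulate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "sample", "reliability", "resolve",
          "train_dict", "score", "build_series", "itsa")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All stage parameters plus paths, read from one YAML file."""

    seed: int = 0
    outdir: str = "out"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # simulate
    synthetic: dict = field(default_factory=dict)
    n_policies: int = 15
    policy_effects: list = field(default_factory=list)
    # sample / clean
    cap: int = 400
    meaningless_threshold: float = 0.20
    # coding QC
    calibration_sample: int = 50
    reliability_target: float = 0.9
    # sentiment
    alpha_smoothing: float = 1.0
    tau: float = 0.5
    train_end: dt.date = dt.date(2016, 12, 31)
    stopwords: list = field(default_factory=list)
    # series
    min_comments: int = 2
    # itsa
    post_points: int = 30
    alpha: float = 0.05
    error_mode: str = "auto"
    lag_days: dict = field(default_factory=dict)     # policy_id -> lag
    # external inputs (used when simulate is disabled)
    comments_path: str | None = None
    codes_path: str | None = None
    policies_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key == "train_end" and isinstance(value, str):
                value = dt.date.fromisoformat(value)
            if key == "stages":
                unknown = set(value) - set(STAGES)
                if unknown:
                    raise ValueError(f"unknown stages {sorted(unknown)}")
                merged = {s: True for s in STAGES}
                merged.update(value)
                value = merged
            setattr(cfg, key, value)
        return cfg

    def content_hash(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the enabled stages in order; return the artifact manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    enabled = {s: bool(config.stages.get(s, True)) for s in STAGES}

    comments = codes_by_rater = truth = policies = None
    consensus = None
    scored_codes = None
    analysis_series = None

    def emit(path: Path):
        written.append(path)

    # -- simulate ----------------------------------------------------------
    stage = "simulate"
    try:
        if enabled[stage]:
            syn_kwargs = dict(config.synthetic)
            effects = [simulate.PolicyEffect(**e) for e in config.policy_effects]
            syn = simulate.SyntheticConfig(
                seed=config.seed, policy_effects=effects, **syn_kwargs
            )
            schedule = simulate.generate_policy_schedule(syn, config.n_policies)
            latent = simulate.generate_latent_rates(syn, schedule)
            comments, truth = simulate.generate_comments(syn, latent)
            codes_by_rater = simulate.generate_rater_codes(truth, syn)
            policies = schedule
            io.write_comments(comments, outdir / "comments.jsonl")
            emit(outdir / "comments.jsonl")
            io.write_codes(truth, outdir / "truth_codes.jsonl")
            emit(outdir / "truth_codes.jsonl")
            all_codes = [c for r in sorted(codes_by_rater) for c in codes_by_rater[r]]
            io.write_codes(all_codes, outdir / "rater_codes.jsonl")
            emit(outdir / "rater_codes.jsonl")
            io.write_policies(policies, outdir / "policies.csv")
            emit(outdir / "policies.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    def load_inputs(need_codes: bool):
        nonlocal comments, codes_by_rater
        if comments is None:
            if not config.comments_path:
                raise FileNotFoundError("no comments available (set comments_path)")
            comments = io.read_comments(config.comments_path)
        if need_codes and codes_by_rater is None:
            if not config.codes_path:
                raise FileNotFoundError("no codes available (set codes_path)")
            rows = io.read_codes(config.codes_path)
            codes_by_rater = {}
            for c in rows:
                codes_by_rater.setdefault(c.rater_id or "R1", []).append(c)

    # -- sample ------------------------------------------------------------
    stage = "sample"
    sampled = None
    try:
        if enabled[stage]:
            load_inputs(need_codes=False)
            flagged = {c.comment_id for c in comments if "meaningless" in c.flags}
            by_case: dict[str, list] = {}
            for c in comments:
                by_case.setdefault(c.case_id, []).append(c)
            sampled, reports = [], []
            for k, case in enumerate(sorted(by_case)):
                pool = by_case[case]
                picked, _ = coding.area_sample(
                    pool, cap=config.cap, seed=config.seed * 1000 + k
                )
                picked_ids = {c.comment_id for c in picked}
                rest = [c for c in pool if c.comment_id not in picked_ids]
                cleaned, rep = coding.clean_sample(
                    picked,
                    lambda c: c.comment_id in flagged,
                    refill_pool=rest,
                    threshold=config.meaningless_threshold,
                    seed=config.seed * 1000 + 500 + k,
                )
                sampled.extend(cleaned)
                reports.append({"case_id": case, **rep.__dict__})
            io.write_comments(sampled, outdir / "sampled.jsonl")
            emit(outdir / "sampled.jsonl")
            import pandas as pd

            pd.DataFrame(reports).to_csv(outdir / "sampling_report.csv", index=False)
            emit(outdir / "sampling_report.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    analysed = sampled if sampled is not None else comments

    # -- reliability -------------------------------------------------------
    stage = "reliability"
    try:
        if enabled[stage]:
            load_inputs(need_codes=True)
            result = coding.calibration_loop(
                codes_by_rater,
                sample_size=config.calibration_sample,
                target=config.reliability_target,
                seed=config.seed,
            )
            (outdir / "reliability.json").write_text(
                json.dumps(result.__dict__, indent=2) + "\n"
            )
            emit(outdir / "reliability.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- resolve -----------------------------------------------------------
    stage = "resolve"
    try:
        if enabled[stage]:
            load_inputs(need_codes=True)
            consensus, adjudicate = coding.resolve_consensus(codes_by_rater)
            io.write_codes(consensus, outdir / "consensus_codes.jsonl")
            emit(outdir / "consensus_codes.jsonl")
            (outdir / "adjudication.txt").write_text(
                "".join(cid + "\n" for cid in adjudicate)
            )
            emit(outdir / "adjudication.txt")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- train dictionary --------------------------------------------------
    stage = "train_dict"
    dictionary = None
    try:
        if enabled[stage]:
            load_inputs(need_codes=True)
            if consensus is None:
                consensus, _ = coding.resolve_consensus(codes_by_rater)
            by_id = {c.comment_id: c for c in analysed}
            train_pairs = [
                (by_id[c.comment_id], c)
                for c in consensus
                if c.comment_id in by_id and by_id[c.comment_id].date <= config.train_end
            ]
            dictionary = sentiment.build_dictionary(
                train_pairs, alpha=config.alpha_smoothing, stopwords=config.stopwords
            )
            dictionary.save(outdir / "dictionary.csv")
            emit(outdir / "dictionary.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- score -------------------------------------------------------------
    stage = "score"
    try:
        if enabled[stage]:
            if dictionary is None:
                dictionary = sentiment.SentimentDictionary.load(outdir / "dictionary.csv")
            if consensus is None:
                load_inputs(need_codes=True)
                consensus, _ = coding.resolve_consensus(codes_by_rater)
            early_ids = {x.comment_id for x in analysed if x.date <= config.train_end}
            scored_codes = [c for c in consensus if c.comment_id in early_ids]
            for c in analysed:
                if c.date <= config.train_end:
                    continue
                _, labels = sentiment.score_and_classify(dictionary, c, tau=config.tau)
                scored_codes.append(io.CodedComment(c.comment_id, labels, rater_id="model"))
            io.write_codes(scored_codes, outdir / "scored_codes.jsonl")
            emit(outdir / "scored_codes.jsonl")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- build series ------------------------------------------------------
    stage = "build_series"
    try:
        if enabled[stage]:
            if scored_codes is None:
                if consensus is None:
                    load_inputs(need_codes=True)
                    consensus, _ = coding.resolve_consensus(codes_by_rater)
                scored_codes = consensus
            analysis_series = series.build_series(
                analysed, scored_codes, min_comments=config.min_comments
            )
            io.write_series(analysis_series, outdir / "series.csv")
            emit(outdir / "series.csv")
            summary = series.yearly_summary(
                series.attach_dates(analysed, scored_codes)
            )
            summary.to_csv(outdir / "yearly_summary.csv", index=False)
            emit(outdir / "yearly_summary.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- itsa --------------------------------------------------------------
    stage = "itsa"
    try:
        if enabled[stage]:
            if analysis_series is None:
                analysis_series = io.read_series(outdir / "series.csv")
            if policies is None:
                if not config.policies_path:
                    raise FileNotFoundError("no policy table available (set policies_path)")
                policies = io.read_policies(config.policies_path)
            policies = [
                io.PolicyEvent(
                    p.policy_id, p.promulgation_date,
                    int(config.lag_days.get(p.policy_id, p.lag_days)), p.title,
                )
                for p in policies
            ]
            usable = [
                p for p in policies
                if analysis_series[0].date < p.effect_date <= analysis_series[-1].date
            ]
            skipped = [p.policy_id for p in policies if p not in usable]
            if skipped:
                logger.warning("policies outside the series span skipped: %s", skipped)
            for outcome, name in (("support_rate", "fits_support.csv"),
                                  ("blame_rate", "fits_blame.csv")):
                fits = itsa.summarize_policies(
                    analysis_series, usable, outcome,
                    post_points=config.post_points, alpha=config.alpha,
                    error_mode=config.error_mode,
                )
                io.write_fits(fits, outdir / name)
                emit(outdir / name)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest = {
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "artifacts": {str(p): _sha256(p) for p in sorted(set(written))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
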