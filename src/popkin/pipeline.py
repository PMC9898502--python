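"""End-to-end orchestration: simulate -> QC -> features -> compare/correlate/
classify, with logged, hash-manifested, reproducible artifacts.

A run is configured by a :class:`PipelineConfig` (YAML-loadable).  All
randomness flows from the single ``seed``; re-running the same config+seed
produces byte-identical artifacts (the manifest records SHA-256 digests so
this is checkable).  Three-group cohorts are analysed as pairwise designs
(e.g. NT vs autistic, autistic vs autistic+ADHD), never as omnibus
three-level tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierSpec, greedy_select, roc_auc
from .features import FEATURE_COLUMNS, features_table
from .session import GameConfig, SessionRecord, qc_filter, read_session, write_session
from .simulate import (
    AgeModel,
    CohortSpec,
    case_profile,
    nt_profile,
    simulate_cohort,
)
from .stats import compare_all, spearman_partial

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "make_report"]

logger = logging.getLogger("popkin")

# classifier candidates: the mean-level features the selection studies use
DEFAULT_CLASSIFIER_FEATURES = [
    "touch_length_mean",
    "touch_duration_mean",
    "time_on_target_mean",
    "distance_to_center_mean",
    "number_of_targeted_bubbles",
    "screen_exploratory_percentage",
    "bubble_popping_rate",
]


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs."""

    cohort: CohortSpec | str  # spec to simulate, or a directory of session JSON
    game: GameConfig = field(default_factory=GameConfig)
    covariates: list[str] = field(default_factory=lambda: ["age_months"])
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    correlation_targets: list[str] = field(default_factory=list)
    classifier: ClassifierSpec = field(default_factory=lambda: ClassifierSpec.small_grid())
    classifier_features: list[str] = field(default_factory=lambda: list(DEFAULT_CLASSIFIER_FEATURES))
    alpha: float = 0.05
    output_dir: str = "popkin_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @staticmethod
    def from_yaml(path: str | os.PathLike) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return PipelineConfig.from_dict(doc)

    @staticmethod
    def from_dict(doc: dict) -> "PipelineConfig":
        game = GameConfig(**doc.get("game", {}))
        seed = int(doc.get("seed", 0))
        cdoc = doc.get("cohort", {})
        cohort: CohortSpec | str
        if isinstance(cdoc, str):
            cohort = cdoc
        else:
            groups = {}
            for label, gdoc in (cdoc.get("groups") or {}).items():
                base = case_profile() if gdoc.get("base") == "case" else nt_profile()
                overrides = {k: v for k, v in gdoc.items() if k not in ("base", "n")}
                profile = dataclasses.replace(base, **overrides)
                groups[label] = (profile, int(gdoc.get("n", 30)))
            if not groups:
                groups = {"NT": (nt_profile(), 30), "autistic": (case_profile(), 30)}
            age = AgeModel(**cdoc["age_model"]) if "age_model" in cdoc else AgeModel()
            scores = {k: tuple(v) for k, v in (cdoc.get("clinical_score_model") or {}).items()}
            iq_model = {k: tuple(v) for k, v in (cdoc.get("iq_model") or {}).items()} or None
            cohort = CohortSpec(groups=groups, age_model=age, iq_model=iq_model,
                                clinical_score_model=scores, config=game,
                                seed=int(cdoc.get("seed", seed)))
        clf_doc = dict(doc.get("classifier", {}))
        if clf_doc.pop("grid", "small") == "full":
            clf = ClassifierSpec(seed=seed, **clf_doc)
        else:
            clf = ClassifierSpec.small_grid(
                seed=seed, max_features=int(clf_doc.get("max_features", 3))
            )
        comparisons = [tuple(p) for p in doc.get("comparisons", [])]
        return PipelineConfig(
            cohort=cohort, game=game,
            covariates=list(doc.get("covariates", ["age_months"])),
            comparisons=comparisons,
            correlation_targets=list(doc.get("correlation_targets", [])),
            classifier=clf,
            classifier_features=list(doc.get("classifier_features",
                                             DEFAULT_CLASSIFIER_FEATURES)),
            alpha=float(doc.get("alpha", 0.05)),
            output_dir=str(doc.get("output_dir", "popkin_run")),
            seed=seed,
        )


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    artifacts: dict[str, str]  # relative path -> sha256
    stages: list[str]
    started_at: float
    finished_at: float
    complete: bool = True

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return float(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


def _load_sessions(path: str) -> list[SessionRecord]:
    files = sorted(Path(path).glob("*.json"))
    return [read_session(f) for f in files]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every configured stage; abort on the first stage failure."""
    started = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    artifacts: dict[str, str] = {}
    stages: list[str] = []

    def record_artifact(path: Path) -> None:
        artifacts[str(path.relative_to(out))] = _sha256(path)

    try:
        # -- pre-flight --------------------------------------------------
        known = {"age_months", "iq"}
        if isinstance(config.cohort, CohortSpec):
            known |= set(config.cohort.clinical_score_model)
        missing = [c for c in config.covariates if c not in known]
        if isinstance(config.cohort, CohortSpec) and missing:
            raise ValueError(f"unknown covariate column(s): {missing}")

        # -- simulate / load ---------------------------------------------
        t0 = time.time()
        if isinstance(config.cohort, CohortSpec):
            sessions, meta = simulate_cohort(config.cohort)
            sdir = out / "sessions"
            sdir.mkdir(exist_ok=True)
            for rec in sessions:
                record_artifact(Path(write_session(rec, sdir / f"{rec.session_id}.json")))
            meta.to_csv(out / "cohort.csv", index=False)
            record_artifact(out / "cohort.csv")
            stages.append("simulate")
        else:
            sessions = _load_sessions(config.cohort)
            stages.append("load")
        logger.info("stage %s: %d sessions (%.2fs)", stages[-1], len(sessions),
                    time.time() - t0)
        if not isinstance(config.cohort, CohortSpec) and missing:
            cols = set()
            for r in sessions:
                cols |= set(r.clinical_scores)
            still = [c for c in missing if c not in cols]
            if still:
                raise ValueError(f"unknown covariate column(s): {still}")

        # -- QC ----------------------------------------------------------
        kept, excluded = qc_filter(sessions)
        qc_doc = {
            "n_input": len(sessions),
            "n_kept": len(kept),
            "excluded": [
                {"session_id": r.session_id, "reason": reason,
                 "n_touches": r.n_touches}
                for r, reason in excluded
            ],
        }
        with open(out / "qc.json", "w") as f:
            json.dump(qc_doc, f, indent=1, sort_keys=True)
        record_artifact(out / "qc.json")
        stages.append("qc")
        logger.info("stage qc: kept %d / %d", len(kept), len(sessions))

        # -- features ------------------------------------------------------
        t0 = time.time()
        table = features_table(kept)
        table.to_csv(out / "features.csv", index=False)
        record_artifact(out / "features.csv")
        stages.append("features")
        logger.info("stage features: %d rows (%.2fs)", len(table), time.time() - t0)

        comparisons = config.comparisons or _default_pairs(table)

        # -- compare -------------------------------------------------------
        rows = []
        for g1, g2 in comparisons:
            sub = table[table["group"].isin([g1, g2])]
            for r in compare_all(sub, "group", config.covariates, alpha=config.alpha):
                rows.append({"comparison": f"{g1}_vs_{g2}",
                             **dataclasses.asdict(r)})
        pd.DataFrame(rows).to_csv(out / "comparisons.csv", index=False)
        record_artifact(out / "comparisons.csv")
        stages.append("compare")

        # -- correlate -----------------------------------------------------
        crows = []
        for target in config.correlation_targets:
            if target not in table.columns:
                raise ValueError(f"unknown correlation target {target!r}")
            cov = table[config.covariates].to_numpy(dtype=float) \
                if config.covariates else None
            for feat in [c for c in FEATURE_COLUMNS if c in table.columns]:
                try:
                    res = spearman_partial(
                        table[feat].to_numpy(dtype=float),
                        table[target].to_numpy(dtype=float),
                        cov, x_name=feat, y_name=target,
                        covariate_names=config.covariates,
                    )
                    crows.append({"feature": feat, "target": target,
                                  "rho": res.rho, "p": res.p, "n": res.n})
                except ValueError:
                    crows.append({"feature": feat, "target": target,
                                  "rho": math.nan, "p": math.nan, "n": 0})
        if config.correlation_targets:
            pd.DataFrame(crows).to_csv(out / "correlations.csv", index=False)
            record_artifact(out / "correlations.csv")
            stages.append("correlate")

        # -- classify ------------------------------------------------------
        if config.classifier_features:
            t0 = time.time()
            cls_doc = {}
            for g1, g2 in comparisons:
                sub = table[table["group"].isin([g1, g2])]
                feats = [c for c in config.classifier_features if c in sub.columns]
                X = sub[feats].to_numpy(dtype=float)
                ok = ~np.isnan(X).any(axis=1)
                X, ysub = X[ok], (sub["group"].to_numpy()[ok] == g2).astype(int)
                trace = greedy_select(X, ysub, config.classifier, feature_names=feats)
                roc_points, pooled_auc = roc_auc(trace.pooled_scores, ysub)
                cls_doc[f"{g1}_vs_{g2}"] = {
                    "steps": [
                        {"feature": s.feature, "auc": s.auc,
                         "ci": [s.estimate.ci_low, s.estimate.ci_high],
                         "se": s.estimate.se}
                        for s in trace.steps
                    ],
                    "pooled_auc": pooled_auc,
                    "pooled_scores": trace.pooled_scores.tolist(),
                    "roc": roc_points,
                    "n": int(len(ysub)),
                }
            with open(out / "classification.json", "w") as f:
                json.dump(cls_doc, f, indent=1, sort_keys=True)
            record_artifact(out / "classification.json")
            stages.append("classify")
            logger.info("stage classify (%.2fs)", time.time() - t0)

        manifest = RunManifest(
            config_hash=_config_hash(config), seed=config.seed,
            version=__version__, artifacts=artifacts, stages=stages,
            started_at=started, finished_at=time.time(), complete=True,
        )
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest.to_json(), f, indent=1, sort_keys=True)
        return manifest
    except Exception as exc:
        stage = stages[-1] if stages else "pre-flight"
        manifest = RunManifest(
            config_hash=_config_hash(config), seed=config.seed,
            version=__version__, artifacts=artifacts,
            stages=stages + [f"FAILED after {stage}"],
            started_at=started, finished_at=time.time(), complete=False,
        )
        try:
            with open(out / "manifest.json", "w") as f:
                json.dump(manifest.to_json(), f, indent=1, sort_keys=True)
        except OSError:
            pass
        logger.error("pipeline failed during %s: %s", stage, exc)
        raise
    finally:
        logger.removeHandler(fh)
        fh.close()


def _default_pairs(table: pd.DataFrame) -> list[tuple[str, str]]:
    groups = list(dict.fromkeys(table["group"]))
    return [(groups[i], groups[i + 1]) for i in range(len(groups) - 1)]


def make_report(output_dir: str | os.PathLike) -> str:
    """Render a markdown report from a completed run directory."""
    out = Path(output_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {out}")
    with open(manifest_path) as f:
        manifest = json.load(f)
    if not manifest.get("complete", False):
        raise ValueError("manifest marks run as incomplete")

    lines = ["# Bubble-popping analysis report", ""]
    lines.append(f"- package version: {manifest['version']}")
    lines.append(f"- seed: {manifest['seed']}")
    lines.append(f"- config hash: `{manifest['config_hash'][:16]}...`")
    lines.append("")

    if (out / "qc.json").exists():
        with open(out / "qc.json") as f:
            qc = json.load(f)
        lines += ["## Engagement QC", "",
                  f"{qc['n_kept']} of {qc['n_input']} sessions kept; "
                  f"{len(qc['excluded'])} excluded for insufficient engagement "
                  "(fewer than three touches).", ""]

    if (out / "comparisons.csv").exists():
        comp = pd.read_csv(out / "comparisons.csv")
        comp = comp.sort_values(["comparison", "p_adjusted"])
        lines += ["## Group comparisons (ANCOVA, BH-adjusted)", ""]
        lines.append("| comparison | feature | F | df | p (adj) | eta^2 | n |")
        lines.append("|---|---|---|---|---|---|---|")
        for _, r in comp.iterrows():
            if isinstance(r.get("skipped_reason"), str) and r["skipped_reason"]:
                lines.append(f"| {r['comparison']} | {r['feature']} | skipped: "
                             f"{r['skipped_reason']} | | | | |")
            else:
                lines.append(
                    f"| {r['comparison']} | {r['feature']} | {r['F']:.2f} | "
                    f"({r['df_effect']:.0f}, {r['df_error']:.0f}) | "
                    f"{r['p_adjusted']:.3g} | {r['eta_squared']:.3f} | "
                    f"{r['n_used']:.0f} |")
        lines.append("")

    if (out / "correlations.csv").exists():
        corr = pd.read_csv(out / "correlations.csv")
        lines += ["## Partial Spearman correlations", ""]
        lines.append("| feature | clinical target | rho | p | n |")
        lines.append("|---|---|---|---|---|")
        for _, r in corr.iterrows():
            lines.append(f"| {r['feature']} | {r['target']} | {r['rho']:.3f} | "
                         f"{r['p']:.3g} | {r['n']:.0f} |")
        lines.append("")

    if (out / "classification.json").exists():
        with open(out / "classification.json") as f:
            cls = json.load(f)
        lines += ["## Classification (greedy LOOCV-AUC selection)", ""]
        for task, doc in cls.items():
            lines.append(f"### {task}")
            lines.append("")
            lines.append("| step | feature added | pooled AUC | 95% CI |")
            lines.append("|---|---|---|---|")
            for i, s in enumerate(doc["steps"], 1):
                lines.append(f"| {i} | {s['feature']} | {s['auc']:.3f} | "
                             f"({s['ci'][0]:.3f}, {s['ci'][1]:.3f}) |")
            lines.append("")

    report = "\n".join(lines)
    with open(out / "report.md", "w", encoding="utf-8") as f:
        f.write(report)
    return report
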