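"""Orchestration: the whole analysis behind one config and one seed.

Stages run in the fixed order preprocess -> topics -> regress -> kano ->
report.  Every artifact is a CSV or JSON file; the run manifest records
each stage's outputs with SHA-256 digests and timings, so a rerun with the
same config and seed can be verified bit-for-bit on the same platform.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import descriptives, kano, lda, preprocess, tobit
from .io import ReviewDataset, attach_apps, read_apps, read_reviews, write_reviews

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "make_table2", "format_p"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    reviews_path: str | None = None
    apps_path: str | None = None
    out_dir: str = "kanosat_out"
    seed: int = 0
    # preprocessing
    window_start: str = "2019-01-01"
    window_end: str = "2024-12-31"
    min_chars: int = 2
    alignment: dict[str, list[int]] = field(
        default_factory=lambda: {"positive": [4, 5], "neutral": [3], "negative": [1, 2]}
    )
    stopwords_path: str | None = None
    # corpus / lda
    min_doc_freq: int = 2
    max_doc_fraction: float = 0.5
    k: int | None = None  # fixed topic count; None -> use k_grid
    k_grid: list[int] = field(default_factory=lambda: [4, 8, 12, 16, 20])
    lda_alpha: float | None = None
    lda_eta: float = 0.01
    n_iterations: int = 1000
    burn_in: int = 500
    heldout_fraction: float = 0.1
    n_keywords: int = 30
    # regression / kano
    lower: float = 0.0
    upper: float = 4.0
    include_intercept: bool = False
    alpha_sig: float = 0.05
    satisfaction_threshold: int = 4
    wald_mode: str = "difference"
    # report
    concentration_top_n: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def format_p(p: float) -> str:
    """Publication-style p rendering: values below .001 print as '<.001'."""
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0") if p < 1 else "1.000"


def make_table2(
    fit_pd: tobit.TobitFit,
    fit_nd: tobit.TobitFit,
    wald_results: list[tobit.WaldResult],
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Coefficient table for the two models plus the per-topic Wald columns.

    Each model contributes beta (3 decimals), SE (3), the 95% CI as
    beta ± 1.96·SE, a formatted summary cell, and the p-value.
    """
    labels = labels or fit_pd.names
    rows = []
    for j, lab in enumerate(labels):
        row: dict[str, Any] = {"topic": lab}
        for tag, fit in (("m1", fit_pd), ("m2", fit_nd)):
            b, s = fit.beta[j], fit.se[j]
            lo, hi = b - 1.96 * s, b + 1.96 * s
            row[f"{tag}_beta"] = round(float(b), 3)
            row[f"{tag}_se"] = round(float(s), 3)
            row[f"{tag}_ci_low"] = round(float(lo), 3)
            row[f"{tag}_ci_high"] = round(float(hi), 3)
            row[f"{tag}_p"] = format_p(float(fit.p[j]))
            row[f"{tag}_cell"] = f"{b:.3f} ({s:.3f}; {lo:.3f} to {hi:.3f})"
        row["wald_chi2"] = round(wald_results[j].statistic, 1)
        row["wald_p"] = format_p(wald_results[j].p)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig, dataset: ReviewDataset | None = None
) -> dict:
    """Execute every stage and return the run manifest.

    ``dataset`` may be passed directly (e.g. fresh from the generator);
    otherwise ``reviews_path``/``apps_path`` are read.  On stage failure the
    partial outputs are quarantined under ``<out_dir>/failed`` and a
    :class:`StageError` naming the stage is raised.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "started": _dt.datetime.now().isoformat(timespec="seconds"),
        "stages": [],
    }
    artifacts: list[Path] = []

    def emit(stage: str, name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        artifacts.append(path)
        return path

    def finish_stage(stage: str, t0: float, outputs: list[Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "seconds": round(time.perf_counter() - t0, 3),
                "outputs": {p.name: _sha256(p) for p in outputs},
            }
        )

    stage = "preprocess"
    try:
        t0 = time.perf_counter()
        if dataset is None:
            if config.reviews_path is None:
                raise ValueError("no dataset given and no reviews_path configured")
            reviews = read_reviews(config.reviews_path).reviews
            apps = read_apps(config.apps_path) if config.apps_path else []
            if apps:
                dataset, orphans = attach_apps(reviews, apps)
                if orphans:
                    raise ValueError(f"{len(orphans)} reviews reference unknown apps")
            else:
                dataset = ReviewDataset(reviews=reviews)
        window = (
            _dt.date.fromisoformat(config.window_start),
            _dt.date.fromisoformat(config.window_end),
        )
        matrix = preprocess.AlignmentMatrix.from_config(config.alignment)
        stopwords = (
            preprocess.load_stopwords(config.stopwords_path)
            if config.stopwords_path
            else None
        )
        clean, report = preprocess.run_preprocess(
            dataset, window=window, matrix=matrix, min_chars=config.min_chars,
            stopwords=stopwords,
        )
        outs = [
            emit(stage, "clean_reviews.jsonl", lambda p: write_reviews(clean, p, "jsonl")),
            emit(stage, "preprocess_report.json", lambda p: p.write_text(
                json.dumps(report.to_dict(), indent=2), encoding="utf-8")),
        ]
        finish_stage(stage, t0, outs)

        stage = "topics"
        t0 = time.perf_counter()
        corpus = lda.build_corpus(clean, config.min_doc_freq, config.max_doc_fraction)
        template = lda.LdaConfig(
            k=config.k or config.k_grid[0], alpha=config.lda_alpha, eta=config.lda_eta,
            n_iterations=config.n_iterations, burn_in=config.burn_in, seed=config.seed,
        )
        outs = []
        if config.k is None:
            curve = lda.select_k(
                corpus, config.k_grid, template,
                heldout_fraction=config.heldout_fraction, seed=config.seed,
            )
            chosen_k = curve.chosen_k
            outs.append(emit(stage, "perplexity_curve.csv", lambda p: pd.DataFrame(
                {"k": curve.k_grid, "perplexity": curve.perplexities}).to_csv(p, index=False)))
        else:
            chosen_k = config.k
        fit = lda.fit_lda(corpus, dataclasses.replace(template, k=chosen_k))
        best = np.array([lda.best_topic(row) for row in fit.theta])
        keywords = {
            f"topic_{k}": lda.top_keyword_tokens(fit, corpus, k, config.n_keywords)
            for k in range(fit.k)
        }
        outs += [
            emit(stage, "phi.csv", lambda p: pd.DataFrame(
                fit.phi, columns=corpus.vocabulary).to_csv(p, index=False)),
            emit(stage, "theta.csv", lambda p: pd.DataFrame(
                fit.theta, index=corpus.doc_ids).to_csv(p)),
            emit(stage, "keywords.json", lambda p: p.write_text(
                json.dumps(keywords, ensure_ascii=False, indent=2), encoding="utf-8")),
            emit(stage, "best_topics.csv", lambda p: pd.DataFrame(
                {"review_id": corpus.doc_ids, "best_topic": best}).to_csv(p, index=False)),
        ]
        finish_stage(stage, t0, outs)

        stage = "regress"
        t0 = time.perf_counter()
        by_id = {r.review_id: r for r in clean.reviews}
        modeled = [by_id[rid] for rid in corpus.doc_ids]
        if not clean.apps:
            raise ValueError("regression needs app comprehensive ratings")
        ratings = [r.rating for r in modeled]
        comp = [clean.apps[r.app_id].comprehensive_rating for r in modeled]
        dev = tobit.compute_deviations(ratings, comp)
        x, constant = tobit.minmax_normalize(fit.theta)
        tcfg = tobit.TobitConfig(
            lower=config.lower, upper=config.upper,
            include_intercept=config.include_intercept,
        )
        topic_labels = [f"topic_{k}" for k in range(fit.k)]
        fit_pd, fit_nd = tobit.fit_both_models(dev, x, tcfg, names=topic_labels)
        offset = int(config.include_intercept)
        wald_results = [
            tobit.wald_asymmetry(fit_pd, fit_nd, j + offset, mode=config.wald_mode)
            for j in range(fit.k)
        ]
        table2 = make_table2(fit_pd, fit_nd, wald_results,
                             labels=(["intercept"] if offset else []) + topic_labels)
        # uncentered VIF: the fitted model has no intercept, and the attention
        # columns are affinely tied through the theta simplex, which would make
        # centered VIF infinite by construction
        vif_report = tobit.vif(x[:, ~constant],
                               [l for l, c in zip(topic_labels, constant) if not c],
                               include_intercept=config.include_intercept)
        outs = [
            emit(stage, "table2.csv", lambda p: table2.to_csv(p, index=False)),
            emit(stage, "vif.csv", lambda p: pd.DataFrame(
                sorted(vif_report.items()), columns=["topic", "vif"]).to_csv(p, index=False)),
        ]
        finish_stage(stage, t0, outs)

        stage = "kano"
        t0 = time.perf_counter()
        sat = np.array([r.rating >= config.satisfaction_threshold for r in modeled])
        n_sat = np.bincount(best[sat], minlength=fit.k) if sat.any() else np.zeros(fit.k, int)
        n_dis = np.bincount(best[~sat], minlength=fit.k) if (~sat).any() else np.zeros(fit.k, int)
        evidence = []
        for j in range(fit.k):
            jj = j + offset
            evidence.append(kano.TopicEvidence(
                label=topic_labels[j],
                beta_pd=float(fit_pd.beta[jj]), se_pd=float(fit_pd.se[jj]),
                p_pd=float(fit_pd.p[jj]),
                beta_nd=float(fit_nd.beta[jj]), se_nd=float(fit_nd.se[jj]),
                p_nd=float(fit_nd.p[jj]),
                wald_p=wald_results[j].p,
                n_satisfied=int(n_sat[j]), n_dissatisfied=int(n_dis[j]),
            ))
        kano_report = kano.classify_all(evidence, alpha=config.alpha_sig)
        kano_df = pd.DataFrame(
            [
                {
                    "topic": lab,
                    "category": kano_report.categories[lab],
                    **dataclasses.asdict(kano_report.indicators[lab]),
                    "abs_beta_nd": kano_report.quadrant[lab][0],
                    "abs_beta_pd": kano_report.quadrant[lab][1],
                }
                for lab in topic_labels
            ]
        )
        outs = [
            emit(stage, "kano.csv", lambda p: kano_df.to_csv(p, index=False)),
            emit(stage, "kano_counts.json", lambda p: p.write_text(
                json.dumps(kano_report.counts, indent=2), encoding="utf-8")),
        ]
        finish_stage(stage, t0, outs)

        stage = "report"
        t0 = time.perf_counter()
        overall = descriptives.satisfaction_rate(
            [r.rating for r in clean.reviews], config.satisfaction_threshold)
        rates = descriptives.group_rates(clean, "platform_year",
                                         config.satisfaction_threshold)
        shares = descriptives.share_table(fit, corpus, best, topic_labels)
        summary = {"overall_satisfaction_rate": overall.value, "n_reviews": len(clean)}
        if clean.apps:
            downloads = [a.downloads for a in clean.apps.values()]
            top_n = min(config.concentration_top_n, len(downloads))
            summary["download_concentration_top_n"] = top_n
            summary["download_concentration"] = descriptives.concentration(
                downloads, top_n).value
        rates_out = rates.reset_index()
        rates_out["group"] = rates_out["group"].astype(str)
        outs = [
            emit(stage, "share_table.csv", lambda p: shares.to_csv(p)),
            emit(stage, "group_rates.csv", lambda p: rates_out.to_csv(p, index=False)),
            emit(stage, "summary.json", lambda p: p.write_text(
                json.dumps(summary, indent=2), encoding="utf-8")),
        ]
        finish_stage(stage, t0, outs)
    except Exception as exc:
        failed = out_dir / "failed"
        failed.mkdir(exist_ok=True)
        for p in artifacts:
            if p.exists():
                shutil.move(str(p), str(failed / p.name))
        raise StageError(stage, exc) from exc

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
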