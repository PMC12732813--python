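"""End-to-end orchestration of the analysis stages.

``run_pipeline`` sequences simulate -> normalize -> cluster -> select-genes
-> score -> reclassify -> respond -> bayes -> survive on a synthetic cohort
(or user-supplied files), writing every artifact plus a manifest with input
checksums, parameters, package version and stage timings. All randomness
flows from the single config seed.
"""

from __future__ import annotations

import hashlib
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as hio
from .bayes_compare import compare_arms
from .clinical_stats import reclassify_table
from .preprocess import (DEFAULT_MIN_SPREAD, DEFAULT_TAU_HIGH, DEFAULT_TAU_LOW,
                         compute_tpm, filter_genes, transform_for_clustering)
from .response_model import classify_responders, fit_logistic, roc_analysis
from .signature import (DEFAULT_Q_MAX, DEFAULT_R2_MIN, DEFAULT_W_MIN,
                        build_signature, score_samples)
from .subtype_discovery import (CORE_AMPLICON_GENES, amplicon_core_score,
                                cluster_solution, compare_groups)
from .survival import cox_model, km_logrank, median_split
from .synthetic_data import SimulationConfig, simulate_cohort

log = logging.getLogger("her2mtgx")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str = "her2mtgx_run"
    # input paths; None -> simulate a synthetic cohort instead
    counts_path: str | None = None
    annotation_path: str | None = None
    cnv_path: str | None = None
    clinical_path: str | None = None
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    tau_low: float = DEFAULT_TAU_LOW
    tau_high: float = DEFAULT_TAU_HIGH
    min_spread: float = DEFAULT_MIN_SPREAD
    k_min: int = 2
    k_max: int = 6
    q_max: float = DEFAULT_Q_MAX
    r2_min: float = DEFAULT_R2_MIN
    w_min: float = DEFAULT_W_MIN
    alpha: float = 0.01
    prior: tuple[float, float] = (1.0, 1.0)
    n_draws: int = 100_000
    baseline_counts: tuple[int, int] = (13, 38)  # pCR / RD without targeted tx
    lift_deltas: tuple[float, ...] = (0.0, 1.0)
    amplicon_genes: tuple[str, ...] = tuple(CORE_AMPLICON_GENES)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls(**hio.read_config(path))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "parameters": asdict(config), "stages": {}, "inputs": {}}
    stage = "validate"
    try:
        for name in ("counts_path", "annotation_path", "cnv_path",
                     "clinical_path"):
            p = getattr(config, name)
            if p is not None:
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name} does not exist: {p}")
                manifest["inputs"][name] = {"path": str(p),
                                            "sha256": _sha256(Path(p))}

        def _run(name, fn):
            t0 = _time.perf_counter()
            result = fn()
            manifest["stages"][name] = {
                "seconds": round(_time.perf_counter() - t0, 3)}
            log.info("stage %s done in %.2fs", name,
                     _time.perf_counter() - t0)
            return result

        # --- simulate / load -------------------------------------------
        stage = "simulate"
        if config.counts_path is None:
            sim = SimulationConfig(**{**config.simulation, "seed": config.seed})
            counts, cnv, clinical, truth = _run(stage,
                                                lambda: simulate_cohort(sim))
            hio.write_counts_bundle(counts, out)
            cnv.to_csv(out / "cnv.tsv", sep="\t")
            hio.write_clinical(clinical, out / "clinical.tsv")
        else:
            mat = hio.read_expression(config.counts_path)
            ann = hio.read_gene_annotation(config.annotation_path)
            from .synthetic_data import CountsMatrix
            counts = CountsMatrix(mat, ann)
            cnv = (pd.read_csv(config.cnv_path, sep="\t", index_col=0)
                   if config.cnv_path else None)
            clinical = hio.read_clinical(config.clinical_path)
            truth = None
            manifest["stages"][stage] = {"seconds": 0.0, "loaded": True}

        # --- normalize --------------------------------------------------
        stage = "normalize"
        def _normalize():
            tpm = compute_tpm(counts)
            transformed = transform_for_clustering(
                counts, config.tau_low, config.tau_high)
            kept = filter_genes(transformed, config.min_spread)
            return tpm, transformed.loc[kept]
        tpm, transformed = _run(stage, _normalize)
        hio.write_expression(transformed, out / "transformed.tsv")

        # --- cluster ----------------------------------------------------
        stage = "cluster"
        sol = _run(stage, lambda: cluster_solution(
            transformed, range(config.k_min, config.k_max + 1)))
        hio.write_json(sol.to_dict(), out / "clusters.json")
        if cnv is not None:
            amp, _missing = amplicon_core_score(cnv, config.amplicon_genes)
            report = compare_groups(amp.to_numpy(),
                                    sol.labels.loc[amp.index].to_numpy())
            hio.write_json({"f": report.f_statistic, "p": report.anova_p,
                            "group_means": report.group_means,
                            "pairwise": report.pairwise.to_dict("records")},
                           out / "amplicon.json")

        # --- select genes (on known groups when simulating) -------------
        stage = "select-genes"
        groups = (truth.group_labels if truth is not None
                  else clinical["group"])
        sig = _run(stage, lambda: build_signature(
            tpm, groups.loc[tpm.columns],
            config.q_max, config.r2_min, config.w_min))
        (out / "signature.json").write_text(sig.to_json())

        # --- score ------------------------------------------------------
        stage = "score"
        ms = _run(stage, lambda: score_samples(np.log2(tpm + 1.0), sig))
        scores_tsv = ms.scores.copy()
        scores_tsv.columns = [c.lower() for c in scores_tsv.columns]
        scores_tsv["profile"] = ms.profile
        scores_tsv.to_csv(out / "scores.tsv", sep="\t")

        # --- reclassify -------------------------------------------------
        stage = "reclassify"
        clinical = clinical.copy()
        clinical["her2_status"] = _run(stage,
                                       lambda: reclassify_table(clinical))
        hio.write_clinical(clinical, out / "clinical_reclassified.tsv")

        # --- respond ----------------------------------------------------
        stage = "respond"
        def _respond():
            fit = fit_logistic(ms.scores, clinical["pcr"],
                               strata=clinical["stratum"])
            probs = pd.Series(fit.predict(), index=ms.scores.index)
            roc = roc_analysis(probs, clinical["pcr"])
            calls, summary = classify_responders(
                probs, clinical["pcr"], alpha=config.alpha)
            return fit, probs, roc, calls, summary
        fit, probs, roc, calls, summary = _run(stage, _respond)
        calls.to_csv(out / "responders.tsv", sep="\t")
        hio.write_json({
            "odds_ratios": fit.odds_ratios.round(4).to_dict("index"),
            "auc": roc.auc, "threshold": roc.threshold,
            "sensitivity": roc.sensitivity, "specificity": roc.specificity,
            "counts": summary.counts, "ppv": summary.ppv, "npv": summary.npv,
            "regular_rate": summary.regular_rate,
            "wald_interval": [summary.interval.lower, summary.interval.upper],
        }, out / "response_report.json")

        # --- bayes ------------------------------------------------------
        stage = "bayes"
        def _bayes():
            good = calls["responder_class"] == "good"
            s = int(clinical.loc[good[good].index, "pcr"].sum())
            f = int(good.sum() - s)
            return compare_arms(*config.baseline_counts, s, f,
                                prior=config.prior, deltas=config.lift_deltas,
                                n_draws=config.n_draws, seed=config.seed)
        comp = _run(stage, _bayes)
        hio.write_json(comp.to_dict(), out / "bayes.json")

        # --- survive ----------------------------------------------------
        stage = "survive"
        def _survive():
            split = median_split(ms.scores["HER2"])
            km = km_logrank(clinical["time_months"], clinical["event"], split)
            df = clinical.assign(her2_class=(split == "high").astype(int))
            cox = cox_model(df, ["her2_class", "stage"])
            return split, km, cox
        split, km, cox = _run(stage, _survive)
        km.curves.to_csv(out / "km_curves.tsv", sep="\t", index=False)
        hio.write_json({
            "logrank_p": km.logrank_p, "medians": km.medians,
            "univariate": cox.univariate.round(4).to_dict("index"),
            "multivariate": cox.multivariate.round(4).to_dict("index"),
        }, out / "survival_report.json")

    except Exception as exc:
        hio.write_json(manifest, out / "manifest.json")  # keep partials
        raise PipelineError(stage, exc) from exc

    manifest["outputs"] = sorted(p.name for p in out.iterdir()
                                 if p.name != "manifest.json")
    hio.write_json(manifest, out / "manifest.json")
    return manifest
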