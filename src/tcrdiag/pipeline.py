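"""End-to-end orchestration: simulate/load → stats → features → benchmark →
panel → external validation, with persisted stage artifacts and a
machine-readable run report."""

from __future__ import annotations

import json
import logging
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import (
    FeatureMatrix,
    FeatureVocabulary,
    anova_reduce,
    build_vocabulary,
    stratified_split,
    vectorize,
)
from .importance import (
    panel_recovery_score,
    permutation_importance_cv,
    retrain_on_panel,
    select_panel,
)
from .io import Cohort, read_cohort, write_cohort
from .models import (
    FAMILIES,
    EvalReport,
    ModelSpec,
    TrainedModel,
    benchmark_all,
    default_specs,
    derive_seed,
    evaluate,
)
from .simulate import GroundTruth, SimulationConfig, generate_cohort
from .stats import (
    cohort_summary_table,
    compare_groups,
    comparison_table,
    gene_usage_table,
    vj_combination_table,
)

logger = logging.getLogger("tcrdiag")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    outdir: str = "tcrdiag_run"
    seed: int = 0
    # data source: either a simulation block or a cohort directory
    simulation: dict | None = None
    cohort_dir: str | None = None
    external_simulation: dict | None = None
    external_cohort_dir: str | None = None
    # feature construction
    top_k: int = 1000
    m_out: int = 500
    scope: str = "train_only"
    test_fraction: float = 0.30
    # models
    families: Sequence[str] = field(default_factory=lambda: list(FAMILIES))
    importance_family: str = "transformer"
    # importance / panel
    k_panel: int = 50
    n_repeats: int = 5
    importance_metric: str = "auc"

    _KNOWN = None  # populated below

    def __post_init__(self) -> None:
        if self.simulation is None and self.cohort_dir is None:
            raise ValueError("config needs a 'simulation' block or a 'cohort_dir'")
        if self.simulation is not None and self.cohort_dir is not None:
            raise ValueError("give either 'simulation' or 'cohort_dir', not both")
        if self.scope not in ("train_only", "global"):
            raise ValueError("scope must be 'train_only' or 'global'")
        unknown = [f for f in self.families if f not in FAMILIES]
        if unknown:
            raise ValueError(f"unknown model families: {unknown}")
        if self.importance_family not in FAMILIES:
            raise ValueError(f"unknown importance_family {self.importance_family!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__) - {"_KNOWN"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k != "_KNOWN"
        }
        d["families"] = list(self.families)
        return d


def _load_cohorts(
    config: RunConfig,
) -> tuple[Cohort, GroundTruth | None, Cohort | None, GroundTruth | None]:
    if config.simulation is not None:
        sim = SimulationConfig.from_dict(
            {"seed": derive_seed(config.seed, "simulate"), **config.simulation}
        )
        cohort, truth = generate_cohort(sim)
    else:
        cohort = read_cohort(config.cohort_dir)
        truth = None
    ext_cohort = ext_truth = None
    if config.external_simulation is not None:
        ext_sim = SimulationConfig.from_dict(
            {"seed": derive_seed(config.seed, "simulate-external"),
             **config.external_simulation}
        )
        # an external cohort of the same disease shares the discovery
        # cohort's public signature clonotypes
        shared = truth.signature_cdr3s if truth is not None else None
        if shared is not None and len(shared) != ext_sim.n_signature:
            shared = None
        ext_cohort, ext_truth = generate_cohort(ext_sim, signatures=shared)
    elif config.external_cohort_dir is not None:
        ext_cohort = read_cohort(config.external_cohort_dir)
    return cohort, truth, ext_cohort, ext_truth


def build_features(
    cohort: Cohort,
    top_k: int,
    m_out: int,
    scope: str,
    test_fraction: float,
    seed: int,
) -> tuple[FeatureMatrix, FeatureMatrix, FeatureVocabulary]:
    """Vocabulary → ANOVA reduction → vectorization → stratified split.

    In ``train_only`` scope the split is made first and the vocabulary and
    ANOVA filter see only training samples; in ``global`` scope both are
    fit on the full cohort (the published procedure, which leaks test-set
    information into the feature definition).
    """
    split_seed = derive_seed(seed, "split")
    if scope == "train_only":
        labels_fm = FeatureMatrix(
            X=np.zeros((cohort.n_samples, 0)),
            y=np.array([1 if l == "CRC" else 0 for l in cohort.labels]),
            sample_ids=list(cohort.sample_ids),
            feature_names=[],
        )
        tr_ids_fm, te_ids_fm = stratified_split(labels_fm, test_fraction, split_seed)
        train_ids = tr_ids_fm.sample_ids
        vocab0 = build_vocabulary(cohort, top_k=top_k, scope=scope, train_ids=train_ids)
        fm_all = vectorize(cohort, vocab0)
        id_pos = {s: i for i, s in enumerate(fm_all.sample_ids)}
        fm_train0 = fm_all.subset_rows([id_pos[s] for s in train_ids])
        vocab = anova_reduce(fm_train0, m_out=min(m_out, len(vocab0)))
        fm = vectorize(cohort, vocab)
        fm_train = fm.subset_rows([id_pos[s] for s in train_ids])
        fm_test = fm.subset_rows([id_pos[s] for s in te_ids_fm.sample_ids])
    else:
        vocab0 = build_vocabulary(cohort, top_k=top_k, scope="global")
        fm_all = vectorize(cohort, vocab0)
        vocab = anova_reduce(fm_all, m_out=min(m_out, len(vocab0)))
        fm = vectorize(cohort, vocab)
        fm_train, fm_test = stratified_split(fm, test_fraction, split_seed)
    return fm_train, fm_test, vocab


def external_validate(
    model: TrainedModel, vocab: FeatureVocabulary, cohort: Cohort
) -> EvalReport:
    """Score an external cohort with a frozen model and vocabulary.

    The cohort is vectorized against the frozen vocabulary (CDR3s unseen at
    training time contribute nothing, by the zero-imputation rule) and
    scored without any refitting.
    """
    fm_ext = vectorize(cohort, vocab)
    if fm_ext.X.sum() == 0:
        logger.warning(
            "external cohort shares no CDR3 with the frozen vocabulary; "
            "the model emits its baseline score for every sample"
        )
    return evaluate(model, fm_ext)


def _report_to_dict(r: EvalReport) -> dict:
    return {
        "family": r.family,
        "accuracy": r.accuracy,
        "auc": r.auc,
        "recall": r.recall,
        "f1": r.f1,
        "n_features": r.n_features,
        "note": r.note,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, persist every intermediate artifact under
    ``config.outdir``, and return the run report (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "timings_s": {},
    }
    t0 = time.time()

    def _stage(name):
        report["timings_s"][name] = round(time.time() - t0, 3)

    cohort, truth, ext_cohort, ext_truth = _load_cohorts(config)
    if config.simulation is not None:
        write_cohort(cohort, outdir / "cohort")
        truth.to_json(outdir / "ground_truth.json")
    _stage("load")

    # repertoire statistics
    summary = cohort_summary_table(cohort)
    summary.to_csv(outdir / "repertoire_summary.tsv", sep="\t")
    stat_comparisons = compare_groups(
        cohort, summary[["n_unique", "shannon_bits", "clonality", "hec_ratio",
                         "fraction_length_le_14"]]
    )
    usage = gene_usage_table(cohort, "V")
    usage_comparisons = compare_groups(cohort, usage)
    comparison_table(stat_comparisons).to_csv(
        outdir / "stat_comparisons.tsv", sep="\t", index=False
    )
    comparison_table(usage_comparisons).to_csv(
        outdir / "v_usage_comparisons.tsv", sep="\t", index=False
    )
    # top-50 TRBV/TRBJ combinations by mean usage, compared between arms
    vj = vj_combination_table(cohort)
    top_combos = vj.mean(axis=0).nlargest(min(50, vj.shape[1])).index
    vj_comparisons = compare_groups(cohort, vj[top_combos])
    comparison_table(vj_comparisons).to_csv(
        outdir / "vj_combination_comparisons.tsv", sep="\t", index=False
    )
    _stage("stats")

    # feature construction
    fm_train, fm_test, vocab = build_features(
        cohort, config.top_k, config.m_out, config.scope,
        config.test_fraction, config.seed,
    )
    (outdir / "vocabulary.json").write_text(
        json.dumps(
            [
                {
                    "cdr3_aa": c,
                    "v_gene": vocab.vj[c][0],
                    "j_gene": vocab.vj[c][1],
                    "global_rank": vocab.global_rank[c],
                    "anova_f": vocab.f_scores.get(c),
                }
                for c in vocab.cdr3s
            ],
            indent=1,
        )
    )
    fm_train.to_frame().to_csv(outdir / "features_train.tsv", sep="\t")
    fm_test.to_frame().to_csv(outdir / "features_test.tsv", sep="\t")
    pd.DataFrame(
        {
            "sample_id": fm_train.sample_ids + fm_test.sample_ids,
            "partition": ["train"] * fm_train.n_samples
            + ["test"] * fm_test.n_samples,
        }
    ).to_csv(outdir / "split_manifest.csv", index=False)
    _stage("features")

    # benchmark
    specs = default_specs(config.seed, config.families)
    table, models, reports = benchmark_all(specs, fm_train, fm_test)
    table.to_csv(outdir / "benchmark.tsv", sep="\t", index=False)
    (outdir / "best_params.json").write_text(
        json.dumps({fam: m.params for fam, m in models.items()}, indent=2)
    )
    for fam, rep in reports.items():
        pd.DataFrame(rep.roc, columns=["fpr", "tpr"]).to_csv(
            outdir / f"roc_{fam}.tsv", sep="\t", index=False
        )
    report["benchmark"] = table.to_dict(orient="records")
    _stage("benchmark")

    # permutation importance + panel
    imp_spec = next(
        (s for s in specs if s.family == config.importance_family), None
    )
    if imp_spec is None:
        imp_spec = ModelSpec(
            family=config.importance_family,
            seed=derive_seed(config.seed, config.importance_family),
        )
    imp = permutation_importance_cv(
        imp_spec, fm_train, n_repeats=config.n_repeats,
        metric=config.importance_metric, seed=derive_seed(config.seed, "importance"),
    )
    imp.to_frame().to_csv(outdir / "importance.tsv", sep="\t", index=False)
    panel = select_panel(imp, k=min(config.k_panel, fm_train.n_features))
    panel.to_frame().to_json(outdir / "panel.json", orient="records", indent=2)
    panel_report, panel_model, _ = retrain_on_panel(
        imp_spec, fm_train, fm_test, panel
    )
    report["panel_evaluation"] = _report_to_dict(panel_report)
    if truth is not None:
        report["panel_recovery"] = panel_recovery_score(panel, truth)
    _stage("panel")

    # persistence of frozen artifacts
    with open(outdir / "models.pkl", "wb") as fh:
        pickle.dump({"models": models, "panel_model": panel_model,
                     "vocab": vocab, "panel": panel}, fh)

    # external validation (frozen model, no refit)
    if ext_cohort is not None and models:
        best_family = table.iloc[0]["family"]
        ext_report = external_validate(models[best_family], vocab, ext_cohort)
        report["external_validation"] = _report_to_dict(ext_report)
        panel_vocab = vocab.restrict(panel.cdr3s)
        ext_panel_report = external_validate(panel_model, panel_vocab, ext_cohort)
        report["external_validation_panel"] = _report_to_dict(ext_panel_report)
    _stage("external")

    report["internal_test"] = {
        fam: _report_to_dict(rep) for fam, rep in reports.items()
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2))
    logger.info("run complete: %s", outdir / "run_report.json")
    return report
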