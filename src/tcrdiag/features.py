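"""Clonotype-frequency feature construction.

The feature recipe mirrors the diagnostic-modelling workflow: all unique
CDR3 amino-acid sequences across samples form the candidate feature set;
the top 1000 most frequent clones are selected globally (summed relative
frequency across in-scope samples); an ANOVA F-value filter reduces them to
500; each sample becomes a vector of CDR3 frequencies with absent
sequences imputed as zero; labels are encoded 1 = CRC, 0 = HC; and the
cohort is divided by a stratified 70/30 split.

Selecting the vocabulary "globally" (on all samples, the published
procedure) leaks test-set information into the feature definition, so the
default ``scope`` is ``train_only``; ``scope="global"`` reproduces the
published behaviour.  Both modes log which one was used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif

from .io import Cohort

logger = logging.getLogger("tcrdiag")

TOP_K_DEFAULT = 1000
M_OUT_DEFAULT = 500


@dataclass
class FeatureVocabulary:
    """Ordered CDR3 feature set with majority (V, J) annotation and
    provenance (global-frequency rank, ANOVA F score when reduced)."""

    cdr3s: list[str]
    vj: dict[str, tuple[str, str]]
    global_rank: dict[str, int]
    f_scores: dict[str, float] = field(default_factory=dict)
    scope: str = "train_only"

    def __post_init__(self) -> None:
        if len(set(self.cdr3s)) != len(self.cdr3s):
            raise ValueError("vocabulary contains duplicate CDR3s")

    def __len__(self) -> int:
        return len(self.cdr3s)

    def restrict(self, cdr3s: Sequence[str]) -> "FeatureVocabulary":
        keep = [c for c in self.cdr3s if c in set(cdr3s)]
        return FeatureVocabulary(
            cdr3s=keep,
            vj={c: self.vj[c] for c in keep},
            global_rank={c: self.global_rank[c] for c in keep},
            f_scores={c: self.f_scores[c] for c in keep if c in self.f_scores},
            scope=self.scope,
        )


@dataclass
class FeatureMatrix:
    """Samples × CDR3-frequency matrix with aligned binary labels
    (1 = CRC, 0 = HC)."""

    X: np.ndarray
    y: np.ndarray
    sample_ids: list[str]
    feature_names: list[str]
    vocab: FeatureVocabulary | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("matrix shape does not match ids/feature names")
        if self.y.shape != (len(self.sample_ids),):
            raise ValueError("labels do not align with rows")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            X=self.X[idx],
            y=self.y[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_names=list(self.feature_names),
            vocab=self.vocab,
        )

    def subset_features(self, names: Sequence[str]) -> "FeatureMatrix":
        pos = {n: j for j, n in enumerate(self.feature_names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        cols = [pos[n] for n in names]
        return FeatureMatrix(
            X=self.X[:, cols],
            y=self.y,
            sample_ids=list(self.sample_ids),
            feature_names=list(names),
            vocab=self.vocab.restrict(names) if self.vocab is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, index=self.sample_ids, columns=self.feature_names)
        df.insert(0, "label", self.y)
        return df


def build_vocabulary(
    cohort: Cohort,
    top_k: int = TOP_K_DEFAULT,
    scope: str = "train_only",
    train_ids: Sequence[str] | None = None,
    ranking: str = "frequency",
) -> FeatureVocabulary:
    """Rank unique CDR3s and keep the ``top_k`` most frequent.

    ``ranking="frequency"`` sums relative frequencies across in-scope
    samples (robust to sequencing depth); ``ranking="presence"`` counts the
    samples carrying the CDR3.  Ties break lexicographically.  With
    ``scope="train_only"`` the ranking sees only the samples named in
    ``train_ids``; ``scope="global"`` ranks over the whole cohort.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if scope not in ("train_only", "global"):
        raise ValueError("scope must be 'train_only' or 'global'")
    if ranking not in ("frequency", "presence"):
        raise ValueError("ranking must be 'frequency' or 'presence'")
    if scope == "train_only":
        if train_ids is None:
            raise ValueError("scope='train_only' requires train_ids")
        in_scope = set(train_ids)
        reps = [r for r in cohort.repertoires if r.sample_id in in_scope]
        if not reps:
            raise ValueError("no cohort samples match train_ids")
    else:
        reps = cohort.repertoires
    logger.info(
        "building vocabulary: scope=%s over %d samples, top_k=%d, ranking=%s",
        scope, len(reps), top_k, ranking,
    )

    score: dict[str, float] = {}
    vj_weight: dict[str, dict[tuple[str, str], float]] = {}
    for rep in reps:
        for c, f in rep.cdr3_frequencies().items():
            score[c] = score.get(c, 0.0) + (f if ranking == "frequency" else 1.0)
        for r in rep.records:
            vj_weight.setdefault(r.cdr3_aa, {})
            key = (r.v_gene, r.j_gene)
            vj_weight[r.cdr3_aa][key] = vj_weight[r.cdr3_aa].get(key, 0.0) + r.frequency

    ranked = sorted(score.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k > len(ranked):
        logger.warning(
            "top_k=%d exceeds the %d unique CDR3s in scope; keeping all",
            top_k, len(ranked),
        )
    kept = ranked[:top_k]
    cdr3s = [c for c, _ in kept]
    vj = {
        c: max(vj_weight[c].items(), key=lambda kv: (kv[1], kv[0]))[0] for c in cdr3s
    }
    return FeatureVocabulary(
        cdr3s=cdr3s,
        vj=vj,
        global_rank={c: i + 1 for i, (c, _) in enumerate(kept)},
        scope=scope,
    )


def anova_f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way (two-group) ANOVA F statistic per column; all-constant
    columns receive F = 0."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("ANOVA reduction requires both classes")
    constant = np.all(X == X[0], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f, _ = f_classif(X, y)
    f = np.nan_to_num(f, nan=0.0, posinf=np.finfo(float).max)
    f[constant] = 0.0
    return f


def anova_reduce(
    fm: FeatureMatrix, m_out: int = M_OUT_DEFAULT
) -> FeatureVocabulary:
    """Keep the ``m_out`` highest-F columns of ``fm`` (ties lexicographic on
    CDR3), returning the reduced vocabulary with F scores attached."""
    if fm.vocab is None:
        raise ValueError("feature matrix lacks a vocabulary")
    if m_out > fm.n_features:
        raise ValueError(
            f"m_out={m_out} exceeds the {fm.n_features} available features"
        )
    f = anova_f_scores(fm.X, fm.y)
    order = sorted(
        range(fm.n_features), key=lambda j: (-f[j], fm.feature_names[j])
    )
    keep = [fm.feature_names[j] for j in order[:m_out]]
    vocab = fm.vocab.restrict(keep)
    vocab.f_scores = {fm.feature_names[j]: float(f[j]) for j in order[:m_out]}
    return vocab


def vectorize(cohort: Cohort, vocab: FeatureVocabulary) -> FeatureMatrix:
    """Per-sample frequency vectors over the vocabulary, zeros for absent
    CDR3s; labels encoded 1 = CRC, 0 = HC."""
    col = {c: j for j, c in enumerate(vocab.cdr3s)}
    X = np.zeros((cohort.n_samples, len(vocab)))
    for i, rep in enumerate(cohort.repertoires):
        for c, f in rep.cdr3_frequencies().items():
            j = col.get(c)
            if j is not None:
                X[i, j] = f
    y = np.array([1 if lab == "CRC" else 0 for lab in cohort.labels])
    return FeatureMatrix(
        X=X,
        y=y,
        sample_ids=list(cohort.sample_ids),
        feature_names=list(vocab.cdr3s),
        vocab=vocab,
    )


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    """Read a feature matrix written by ``FeatureMatrix.to_frame().to_csv``
    (TSV with a leading ``label`` column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing 'label' column")
    y = df.pop("label").to_numpy(dtype=int)
    return FeatureMatrix(
        X=df.to_numpy(dtype=float),
        y=y,
        sample_ids=[str(s) for s in df.index],
        feature_names=[str(c) for c in df.columns],
    )


def _largest_remainder_counts(
    class_sizes: dict[int, int], test_fraction: float
) -> dict[int, int]:
    """Per-class test-set sizes: round each class's share, reconciling by
    largest fractional remainder so the total equals round(n · fraction)."""
    total_target = int(round(sum(class_sizes.values()) * test_fraction))
    raw = {c: n * test_fraction for c, n in class_sizes.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = total_target - sum(counts.values())
    remainders = sorted(raw, key=lambda c: (-(raw[c] - counts[c]), c))
    for c in remainders[:short]:
        counts[c] += 1
    return counts


def stratified_split(
    fm: FeatureMatrix, test_fraction: float = 0.30, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Deterministic stratified train/test split.

    Per-class test counts follow rounding with largest-remainder
    reconciliation (123 CRC + 187 HC at 30% → 37 + 56 = 93); membership is
    a seeded draw within each class.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    classes, counts = np.unique(fm.y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("stratified split requires both classes")
    class_sizes = {int(c): int(n) for c, n in zip(classes, counts)}
    for c, n in class_sizes.items():
        if n < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
    test_counts = _largest_remainder_counts(class_sizes, test_fraction)
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for c in sorted(class_sizes):
        members = np.flatnonzero(fm.y == c)
        chosen = rng.choice(members, size=test_counts[c], replace=False)
        test_idx.extend(int(i) for i in chosen)
    test_set = set(test_idx)
    train_idx = [i for i in range(fm.n_samples) if i not in test_set]
    return fm.subset_rows(train_idx), fm.subset_rows(sorted(test_idx))
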