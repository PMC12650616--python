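"""Clonotype table I/O and cohort assembly.

A *clonotype* is a unique CDR3 amino-acid sequence observed in one sample,
annotated with the TRBV/TRBJ gene segments it rearranged from and the number
of sequencing reads supporting it.  A *repertoire* is the set of clonotypes
of one blood sample; a *cohort* is a labelled, batch-annotated collection of
repertoires and is the unit on which group comparisons, normalization and
train/test splitting operate.

Three tabular dialects are supported:

``airr``
    AIRR Rearrangement TSV: ``junction_aa``, ``v_call``, ``j_call``,
    ``duplicate_count``.
``mixcr``
    MiXCR clone export TSV: ``aaSeqCDR3``, ``allVHitsWithScore``,
    ``allJHitsWithScore``, ``cloneCount``.
``simple``
    A four-column TSV with header ``cdr3_aa  v_gene  j_gene  count`` —
    the package's own interchange format (also what
    :func:`write_clonotype_table` emits).

Nonproductive sequences (containing a stop ``*`` or frameshift ``_``), empty
CDR3s, and CDR3s with characters outside the 20-letter amino-acid alphabet
are dropped at read time and reported in the repertoire's skip tally.
Gene names are normalized by stripping allele suffixes (``TRBV9*01`` →
``TRBV9``) and MiXCR score annotations; multi-hit fields keep the first
(best-scoring) hit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tcrdiag")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

VALID_LABELS = ("CRC", "HC")

#: column mappings per dialect: cdr3, v, j, count
_DIALECTS: dict[str, tuple[str, str, str, str]] = {
    "airr": ("junction_aa", "v_call", "j_call", "duplicate_count"),
    "mixcr": ("aaSeqCDR3", "allVHitsWithScore", "allJHitsWithScore", "cloneCount"),
    "simple": ("cdr3_aa", "v_gene", "j_gene", "count"),
}


class FormatError(ValueError):
    """A clonotype table does not conform to the requested dialect."""


class EmptyRepertoireError(ValueError):
    """A repertoire has zero total reads."""


class CohortError(ValueError):
    """Metadata and repertoires cannot be aligned into a cohort."""


def normalize_gene(name: str) -> str:
    """Strip allele suffix and score annotation; keep the first hit only.

    ``"TRBV9*01"`` → ``"TRBV9"``; ``"TRBV28(1200.5),TRBV9(800)"`` →
    ``"TRBV28"``.
    """
    first = str(name).split(",")[0].strip()
    first = first.split("(")[0]
    first = first.split("*")[0]
    return first.strip()


def _valid_cdr3(seq: str) -> bool:
    return bool(seq) and all(c in _AA_SET for c in seq)


@dataclass(frozen=True)
class ClonotypeRecord:
    """One clonotype in one sample.

    ``count`` may be fractional after cross-cohort proportional scaling
    (pseudo-counts); ``frequency`` is the fraction of the sample total and
    is filled in when the owning repertoire is finalized.
    """

    cdr3_aa: str
    v_gene: str
    j_gene: str
    count: float
    frequency: float = 0.0

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")
        if self.count < 0:
            raise ValueError(f"negative count for {self.cdr3_aa}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.cdr3_aa, self.v_gene, self.j_gene)


@dataclass
class Repertoire:
    """All clonotypes of one sample, with finalized frequencies.

    ``n_unique`` counts distinct CDR3 amino-acid sequences (V/J variants of
    the same CDR3 collapse), which is the N entering diversity and
    clonality.  ``n_skipped`` tallies rows dropped by validation at read
    time.
    """

    sample_id: str
    records: list[ClonotypeRecord]
    total_reads: float = 0.0
    n_skipped: int = 0

    def finalize(self) -> "Repertoire":
        """Recompute total reads and per-record frequencies from counts."""
        total = float(sum(r.count for r in self.records))
        if total <= 0:
            raise EmptyRepertoireError(
                f"repertoire {self.sample_id!r} has zero total reads"
            )
        self.total_reads = total
        self.records = [replace(r, frequency=r.count / total) for r in self.records]
        return self

    @property
    def n_unique(self) -> int:
        return len({r.cdr3_aa for r in self.records})

    def cdr3_frequencies(self) -> dict[str, float]:
        """Frequency per unique CDR3, aggregated over V/J variants."""
        out: dict[str, float] = {}
        for r in self.records:
            out[r.cdr3_aa] = out.get(r.cdr3_aa, 0.0) + r.frequency
        return out

    def scaled(self, factor: float) -> "Repertoire":
        """Return a copy with every count multiplied by ``factor``."""
        rep = Repertoire(
            sample_id=self.sample_id,
            records=[replace(r, count=r.count * factor) for r in self.records],
            n_skipped=self.n_skipped,
        )
        return rep.finalize()


def _merge_records(
    rows: Iterable[tuple[str, str, str, float]]
) -> list[ClonotypeRecord]:
    merged: dict[tuple[str, str, str], float] = {}
    for cdr3, v, j, count in rows:
        key = (cdr3, v, j)
        merged[key] = merged.get(key, 0.0) + float(count)
    return [
        ClonotypeRecord(cdr3_aa=k[0], v_gene=k[1], j_gene=k[2], count=c)
        for k, c in merged.items()
    ]


def read_clonotype_table(
    path: str | Path,
    dialect: str = "simple",
    sample_id: str | None = None,
) -> Repertoire:
    """Read one sample's clonotype table into a finalized :class:`Repertoire`.

    Rows with empty, nonproductive (``*``/``_``) or non-amino-acid CDR3s are
    dropped and counted in ``Repertoire.n_skipped``; duplicate
    (CDR3, V, J) rows are merged by summing counts.

    Raises
    ------
    FormatError
        If a mandatory column for the dialect is missing.
    EmptyRepertoireError
        If no valid rows with positive counts remain.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    cdr3_col, v_col, j_col, count_col = _DIALECTS[dialect]
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in (cdr3_col, v_col, j_col, count_col):
        if col not in table.columns:
            raise FormatError(
                f"{path.name}: missing mandatory column {col!r} for dialect {dialect!r}"
            )
    rows: list[tuple[str, str, str, float]] = []
    skipped = 0
    for cdr3, v, j, count in zip(
        table[cdr3_col], table[v_col], table[j_col], table[count_col]
    ):
        cdr3 = "" if pd.isna(cdr3) else str(cdr3).strip()
        if not _valid_cdr3(cdr3):
            skipped += 1
            continue
        rows.append(
            (cdr3, normalize_gene(v), normalize_gene(j), float(count))
        )
    if skipped:
        logger.info("%s: skipped %d invalid CDR3 rows", path.name, skipped)
    rep = Repertoire(
        sample_id=sample_id if sample_id is not None else path.stem,
        records=_merge_records(rows),
        n_skipped=skipped,
    )
    return rep.finalize()


def write_clonotype_table(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire in the ``simple`` dialect (tab-separated).

    Frequencies are recomputed from counts before writing, so a repertoire
    whose frequency fields were never set round-trips correctly.
    """
    path = Path(path)
    if rep.records:
        rep = Repertoire(rep.sample_id, list(rep.records), n_skipped=rep.n_skipped)
        rep.finalize()
    df = pd.DataFrame(
        {
            "cdr3_aa": [r.cdr3_aa for r in rep.records],
            "v_gene": [r.v_gene for r in rep.records],
            "j_gene": [r.j_gene for r in rep.records],
            "count": [r.count for r in rep.records],
            "frequency": [r.frequency for r in rep.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass
class Cohort:
    """Labelled, batch-annotated collection of repertoires."""

    repertoires: list[Repertoire]
    labels: list[str]
    batch_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.repertoires)
        if len(self.labels) != n or len(self.batch_ids) != n:
            raise CohortError("labels and batch_ids must align with repertoires")
        ids = self.sample_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate sample ids: {dupes}")
        bad = sorted(set(self.labels) - set(VALID_LABELS))
        if bad:
            raise CohortError(f"unknown labels {bad}; expected {VALID_LABELS}")

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.repertoires]

    @property
    def n_samples(self) -> int:
        return len(self.repertoires)

    def class_counts(self) -> dict[str, int]:
        return {lab: self.labels.count(lab) for lab in VALID_LABELS}

    def subset(self, indices: Sequence[int]) -> "Cohort":
        return Cohort(
            repertoires=[self.repertoires[i] for i in indices],
            labels=[self.labels[i] for i in indices],
            batch_ids=[self.batch_ids[i] for i in indices],
        )

    def by_label(self, label: str) -> list[Repertoire]:
        return [r for r, l in zip(self.repertoires, self.labels) if l == label]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata table (CSV or TSV) with columns
    ``sample_id,label,batch``."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    meta = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sample_id", "label", "batch"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    return meta


def assemble_cohort(
    repertoires: Sequence[Repertoire], metadata: pd.DataFrame
) -> Cohort:
    """Align repertoires with a metadata table into a :class:`Cohort`.

    Every metadata row must have a matching repertoire and vice versa;
    labels are restricted to ``CRC``/``HC``.  The returned cohort preserves
    the order of ``repertoires``.
    """
    meta = metadata.copy()
    if meta["sample_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"])
        raise CohortError(f"duplicate sample ids in metadata: {dupes}")
    bad_labels = sorted(set(meta["label"]) - set(VALID_LABELS))
    if bad_labels:
        raise CohortError(f"unknown labels {bad_labels}; expected {VALID_LABELS}")
    by_id = {r.sample_id: r for r in repertoires}
    if len(by_id) != len(repertoires):
        raise CohortError("duplicate sample ids among repertoires")
    meta_ids = set(meta["sample_id"])
    missing_reps = sorted(meta_ids - set(by_id))
    if missing_reps:
        raise CohortError(f"metadata samples lacking a repertoire: {missing_reps}")
    extra_reps = sorted(set(by_id) - meta_ids)
    if extra_reps:
        raise CohortError(f"repertoires lacking metadata: {extra_reps}")
    meta_map = meta.set_index("sample_id")
    labels = [str(meta_map.loc[r.sample_id, "label"]) for r in repertoires]
    batches = [str(meta_map.loc[r.sample_id, "batch"]) for r in repertoires]
    return Cohort(repertoires=list(repertoires), labels=labels, batch_ids=batches)


def proportional_scale_normalize(
    cohort: Cohort, baseline_batch: str, statistic: str = "median"
) -> Cohort:
    """Scale every sample's clone counts to the baseline batch's typical depth.

    Clone counts from the baseline batch define the anchor depth (its
    ``median`` — or ``mean`` — total reads); every sample's counts are then
    multiplied by ``anchor / sample_total``, producing real-valued
    pseudo-counts.  The scaling is uniform within a sample, so per-sample
    frequency vectors are unchanged; all scaled totals equal the anchor.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    base_totals = [
        r.total_reads
        for r, b in zip(cohort.repertoires, cohort.batch_ids)
        if b == baseline_batch
    ]
    if not base_totals:
        raise CohortError(f"baseline batch {baseline_batch!r} absent or empty")
    anchor = float(np.median(base_totals) if statistic == "median" else np.mean(base_totals))
    scaled = [r.scaled(anchor / r.total_reads) for r in cohort.repertoires]
    return Cohort(
        repertoires=scaled,
        labels=list(cohort.labels),
        batch_ids=list(cohort.batch_ids),
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write a cohort as per-sample simple-dialect TSVs plus metadata CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rep in cohort.repertoires:
        write_clonotype_table(rep, outdir / f"{rep.sample_id}.tsv")
    meta = pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "label": cohort.labels,
            "batch": cohort.batch_ids,
        }
    )
    meta.to_csv(outdir / "metadata.csv", index=False)


def read_cohort(indir: str | Path, dialect: str = "simple") -> Cohort:
    """Read a cohort written by :func:`write_cohort` (or any directory of
    clonotype TSVs plus a ``metadata.csv``)."""
    indir = Path(indir)
    meta = read_metadata(indir / "metadata.csv")
    reps = [
        read_clonotype_table(indir / f"{sid}.tsv", dialect=dialect, sample_id=sid)
        for sid in meta["sample_id"]
    ]
    return assemble_cohort(reps, meta)
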