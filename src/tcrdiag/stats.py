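"""Per-sample repertoire statistics and case/control group comparisons.

Summary statistics follow the conventions of peripheral-blood TCRβ
profiling studies:

* Shannon diversity ``H = −Σ pᵢ log₂ pᵢ`` in bits, where ``pᵢ`` is the
  frequency of unique CDR3 sequence *i* (V/J variants of the same CDR3 are
  aggregated before the formula is applied) and *N* is the number of unique
  sequences.
* Clonality ``1 − H / log₂(N)``: 0 for a perfectly even repertoire,
  approaching 1 under extreme oligoclonal expansion.  For ``N = 1`` the
  expression is 0/0; it is defined as 0 here, since a single clone has no
  diversity deficit to normalize.
* High-expansion clones (HEC): unique CDR3s whose aggregated frequency is
  strictly above 0.5% of total reads.
* CDR3 length distribution (frequency-weighted) and its mass at
  lengths ≤ 14.
* V/J gene usage fractions, read- or clone-weighted.

Group comparisons between the CRC and HC arms use the two-sided
Mann–Whitney U test with Benjamini–Hochberg FDR correction applied jointly
within each feature family, and the conventional star notation on adjusted
q-values (* q < 0.05, ** q < 0.01, *** q < 0.001).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import Cohort, EmptyRepertoireError, Repertoire

HEC_THRESHOLD = 0.005
LENGTH_SPLIT = 14


# ---------------------------------------------------------------------------
# per-repertoire statistics

def _unique_freqs(rep: Repertoire) -> np.ndarray:
    freqs = np.array(list(rep.cdr3_frequencies().values()), dtype=float)
    if freqs.size == 0:
        raise EmptyRepertoireError(f"repertoire {rep.sample_id!r} is empty")
    return freqs


def shannon_diversity(rep: Repertoire) -> float:
    """Shannon entropy (bits) of the unique-CDR3 frequency distribution,
    with the 0·log 0 := 0 convention."""
    p = _unique_freqs(rep)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def clonality(rep: Repertoire) -> float:
    """``1 − H/log₂(N)``; 0 by convention for N = 1."""
    n = rep.n_unique
    if n == 0:
        raise EmptyRepertoireError(f"repertoire {rep.sample_id!r} is empty")
    if n == 1:
        return 0.0
    value = 1.0 - shannon_diversity(rep) / math.log2(n)
    # guard tiny negative round-off on perfectly even repertoires
    return float(min(max(value, 0.0), 1.0))


def hec_stats(rep: Repertoire, threshold: float = HEC_THRESHOLD) -> tuple[int, float]:
    """Count of unique CDR3s with aggregated frequency strictly above
    ``threshold``, and its ratio over the unique-clone count."""
    p = _unique_freqs(rep)
    count = int((p > threshold).sum())
    return count, count / p.size


def cdr3_length_summary(
    rep: Repertoire, split_at: int = LENGTH_SPLIT
) -> tuple[dict[int, float], float]:
    """Frequency-weighted CDR3 length histogram and the mass at lengths
    ≤ ``split_at``."""
    hist: dict[int, float] = {}
    for cdr3, f in rep.cdr3_frequencies().items():
        hist[len(cdr3)] = hist.get(len(cdr3), 0.0) + f
    frac = sum(m for l, m in hist.items() if l <= split_at)
    return dict(sorted(hist.items())), float(frac)


def gene_usage(
    rep: Repertoire, segment: str = "V", weighting: str = "read"
) -> dict[str, float]:
    """Per-gene usage fractions for the V or J segment.

    ``read`` weighting sums clone frequencies per gene; ``clone`` weighting
    counts unique clonotypes per gene.
    """
    if segment not in ("V", "J"):
        raise ValueError(f"segment must be 'V' or 'J', got {segment!r}")
    if weighting not in ("read", "clone"):
        raise ValueError(f"weighting must be 'read' or 'clone', got {weighting!r}")
    usage: dict[str, float] = {}
    for r in rep.records:
        gene = r.v_gene if segment == "V" else r.j_gene
        w = r.frequency if weighting == "read" else 1.0
        usage[gene] = usage.get(gene, 0.0) + w
    total = sum(usage.values())
    return {g: w / total for g, w in sorted(usage.items())}


@dataclass
class RepertoireSummary:
    """All per-sample statistics in one row-like object."""

    sample_id: str
    n_unique: int
    shannon_bits: float
    clonality: float
    hec_count: int
    hec_ratio: float
    fraction_length_le_split: float
    length_histogram: dict[int, float]
    v_usage: dict[str, float]
    j_usage: dict[str, float]


def summarize_repertoire(
    rep: Repertoire,
    hec_threshold: float = HEC_THRESHOLD,
    split_at: int = LENGTH_SPLIT,
) -> RepertoireSummary:
    hec_count, hec_ratio = hec_stats(rep, hec_threshold)
    hist, frac = cdr3_length_summary(rep, split_at)
    return RepertoireSummary(
        sample_id=rep.sample_id,
        n_unique=rep.n_unique,
        shannon_bits=shannon_diversity(rep),
        clonality=clonality(rep),
        hec_count=hec_count,
        hec_ratio=hec_ratio,
        fraction_length_le_split=frac,
        length_histogram=hist,
        v_usage=gene_usage(rep, "V"),
        j_usage=gene_usage(rep, "J"),
    )


def cohort_summary_table(cohort: Cohort) -> pd.DataFrame:
    """One row per sample: unique clones, diversity, clonality, HEC count
    and ratio, short-CDR3 mass, plus the label and batch columns."""
    rows = []
    for rep, lab, batch in zip(cohort.repertoires, cohort.labels, cohort.batch_ids):
        s = summarize_repertoire(rep)
        rows.append(
            {
                "sample_id": s.sample_id,
                "label": lab,
                "batch": batch,
                "n_unique": s.n_unique,
                "shannon_bits": s.shannon_bits,
                "clonality": s.clonality,
                "hec_count": s.hec_count,
                "hec_ratio": s.hec_ratio,
                "fraction_length_le_14": s.fraction_length_le_split,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def gene_usage_table(
    cohort: Cohort, segment: str = "V", weighting: str = "read"
) -> pd.DataFrame:
    """Samples × genes usage-fraction matrix (absent genes are 0)."""
    usages = [gene_usage(r, segment, weighting) for r in cohort.repertoires]
    genes = sorted({g for u in usages for g in u})
    data = [[u.get(g, 0.0) for g in genes] for u in usages]
    return pd.DataFrame(data, index=cohort.sample_ids, columns=genes)


def vj_combination_table(cohort: Cohort) -> pd.DataFrame:
    """Samples × (TRBV, TRBJ) combination frequency matrix."""
    rows = []
    for rep in cohort.repertoires:
        combo: dict[str, float] = {}
        for r in rep.records:
            key = f"{r.v_gene}/{r.j_gene}"
            combo[key] = combo.get(key, 0.0) + r.frequency
        rows.append(combo)
    keys = sorted({k for row in rows for k in row})
    data = [[row.get(k, 0.0) for k in keys] for row in rows]
    return pd.DataFrame(data, index=cohort.sample_ids, columns=keys)


def disease_specific_ranking(
    cohort: Cohort, top_n: int = 30
) -> list[tuple[str, int]]:
    """CRC-specific CDR3s ranked by the number of CRC samples carrying them.

    Sequences seen in any HC sample are eliminated; the remaining
    CRC-specific CDR3s are ranked by occurrence (descending), ties broken
    lexicographically, truncated to ``top_n``.
    """
    crc_reps = cohort.by_label("CRC")
    hc_reps = cohort.by_label("HC")
    if not crc_reps or not hc_reps:
        raise ValueError("disease_specific_ranking requires both CRC and HC samples")
    hc_seqs = {c for rep in hc_reps for c in rep.cdr3_frequencies()}
    occurrence: dict[str, int] = {}
    for rep in crc_reps:
        for c in rep.cdr3_frequencies():
            if c not in hc_seqs:
                occurrence[c] = occurrence.get(c, 0) + 1
    ranked = sorted(occurrence.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]


# ---------------------------------------------------------------------------
# nonparametric group comparison with FDR control

@lru_cache(maxsize=None)
def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of the Mann–Whitney U statistic without ties:
    entry u holds the number of rank assignments with U = u.

    Subset-sum dynamic program: count size-``n1`` subsets of the ranks
    ``1..n1+n2`` by rank sum, then shift by the minimum rank sum
    ``n1(n1+1)/2`` so the index is U itself.
    """
    n = n1 + n2
    max_sum = n1 * n + 1
    dp = np.zeros((n1 + 1, max_sum), dtype=float)
    dp[0, 0] = 1.0
    for k in range(1, n + 1):
        for i in range(min(k, n1), 0, -1):
            dp[i, k:] += dp[i - 1, :-k]
    min_sum = n1 * (n1 + 1) // 2
    return dp[n1, min_sum : min_sum + n1 * n2 + 1].copy()


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Midranks handle ties in the U statistic.  The p-value is exact for
    small samples — by direct enumeration of all group assignments when
    ``n1 + n2 ≤ 10`` (valid with ties), or by the tie-free null-U
    recursion when ``min(n1, n2) ≤ 8`` without ties; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if n1 + n2 <= 10:
        from itertools import combinations

        center = n1 * n2 / 2.0
        dev = abs(u1 - center)
        hits = total = 0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - center) >= dev - 1e-12:
                hits += 1
        return float(u1), float(hits / total)

    if min(n1, n2) <= 8 and not has_ties:
        counts = _exact_u_counts(n1, n2)
        total = counts.sum()
        u_lo = min(u1, u2)
        p = 2.0 * counts[: int(round(u_lo)) + 1].sum() / total
        return float(u1), float(min(p, 1.0))

    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:  # all values identical
        return float(u1), 1.0
    z = (abs(u1 - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    from scipy.stats import norm

    p = 2.0 * norm.sf(z)
    return float(u1), float(min(p, 1.0))


def fdr_adjust(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """Benjamini–Hochberg (or Benjamini–Yekutieli) step-up adjusted q-values,
    monotone in sorted-p order and clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("bh", "by"):
        raise ValueError("method must be 'bh' or 'by'")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    if method == "by":
        ranked *= np.sum(1.0 / np.arange(1, m + 1))
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def significance_tier(q: float) -> str:
    """Star notation on the FDR-adjusted value."""
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    """One feature's CRC-vs-HC comparison."""

    feature: str
    median_crc: float
    median_hc: float
    u_statistic: float
    p_value: float
    q_value: float
    tier: str
    degenerate: bool = False


def compare_groups(
    cohort: Cohort,
    features: pd.DataFrame,
    fdr_method: str = "bh",
) -> list[GroupComparison]:
    """Mann–Whitney comparison of every feature column between arms, with
    FDR correction applied jointly across the supplied feature family.

    ``features`` is a samples × features table whose index matches the
    cohort's sample ids.  All-constant features are flagged degenerate and
    assigned p = 1.
    """
    labels = pd.Series(cohort.labels, index=cohort.sample_ids)
    feats = features.loc[labels.index]
    is_crc = (labels == "CRC").to_numpy()
    if is_crc.all() or not is_crc.any():
        raise ValueError("compare_groups requires both CRC and HC samples")

    names, pvals, medians, us, degenerate = [], [], [], [], []
    for col in feats.columns:
        v = feats[col].to_numpy(dtype=float)
        x, y = v[is_crc], v[~is_crc]
        names.append(str(col))
        medians.append((float(np.median(x)), float(np.median(y))))
        if np.all(v == v[0]):
            us.append(len(x) * len(y) / 2.0)
            pvals.append(1.0)
            degenerate.append(True)
        else:
            u, p = mann_whitney_u(x, y)
            us.append(u)
            pvals.append(p)
            degenerate.append(False)
    qvals = fdr_adjust(pvals, method=fdr_method)
    return [
        GroupComparison(
            feature=nm,
            median_crc=md[0],
            median_hc=md[1],
            u_statistic=u,
            p_value=p,
            q_value=float(q),
            tier=significance_tier(float(q)),
            degenerate=d,
        )
        for nm, md, u, p, q, d in zip(names, medians, us, pvals, qvals, degenerate)
    ]


def comparison_table(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    """Stable-column-order table of group comparisons (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "feature": c.feature,
                "median_CRC": c.median_crc,
                "median_HC": c.median_hc,
                "U": c.u_statistic,
                "p": c.p_value,
                "q": c.q_value,
                "significance": c.tier,
                "degenerate": c.degenerate,
            }
            for c in comparisons
        ]
    )
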