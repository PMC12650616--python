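"""Synthetic TCRβ repertoire cohorts with case/control structure.

The generator emulates the statistical contrasts reported between
colorectal-cancer (CRC) patients and healthy controls (HC) in peripheral
blood TCRβ sequencing, so that the full diagnostic pipeline can be exercised
and validated without any real accession data:

* heavy-tailed clone-size distributions (Zipf over rank), with a steeper
  exponent in cases — producing higher clonality and lower Shannon
  diversity in the CRC arm;
* fewer unique clones per case than per control;
* a CDR3 length distribution shifted toward shorter sequences (mass moved
  toward lengths ≤ 14) in cases;
* differential V-gene usage via per-gene case multipliers; and
* a set of disease-associated *public* clonotypes: CDR3s shared across
  individuals, carried by cases and controls alike but present at an
  elevated frequency in cases.  These spiked clonotypes are the ground
  truth against which biomarker-panel recovery is scored.

All randomness flows through :func:`numpy.random.default_rng` seeded from
``SimulationConfig.seed``; each sample draws from a substream keyed by its
index, so cohorts are reproducible and order-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .io import AA_ALPHABET, ClonotypeRecord, Cohort, Repertoire

# Functional TRBV/TRBJ segment pools used for gene assignment.  Base usage is
# a fixed, dispersed profile (earlier segments somewhat more used, as in
# peripheral blood); cases modulate it through ``v_usage_skew``.
V_GENES = (
    "TRBV2", "TRBV4-1", "TRBV5-1", "TRBV6-1", "TRBV6-5", "TRBV7-2",
    "TRBV7-9", "TRBV9", "TRBV10-3", "TRBV11-2", "TRBV12-3", "TRBV15",
    "TRBV16", "TRBV18", "TRBV19", "TRBV20-1", "TRBV25-1", "TRBV27",
    "TRBV28", "TRBV30",
)
J_GENES = (
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6",
    "TRBJ2-7",
)

_AA = np.frombuffer(AA_ALPHABET.encode("ascii"), dtype=np.uint8)

MIN_CDR3_LEN = 8
MAX_CDR3_LEN = 24


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic case/control repertoire model.

    Defaults encode the qualitative contrasts of the emulated study at desk
    scale: controls have more unique clones and flatter clone-size spectra;
    cases have steeper spectra (higher clonality), shorter CDR3s, skewed
    V usage, and enriched public signature clonotypes.
    """

    n_cases: int = 100
    n_controls: int = 100
    #: mean unique-clone count per sample (HC > CRC)
    repertoire_size_hc: int = 2000
    repertoire_size_crc: int = 1600
    #: clone-size power-law exponents; CRC steeper → higher clonality
    zipf_exponent_hc: float = 1.0
    zipf_exponent_crc: float = 1.2
    #: sequencing depth (reads) per sample
    total_reads: int = 20_000
    #: disease-associated public clonotypes
    n_signature: int = 30
    signature_enrichment: float = 10.0
    signature_carrier_rate: float = 0.2
    #: per-carrier frequency of a signature clonotype in controls; cases
    #: multiply this by ``signature_enrichment``
    signature_base_frequency: float = 2.5e-4
    #: CDR3 length-center offset for cases (mass moved toward length ≤ 14)
    length_shift: float = 1.0
    #: V genes whose case usage is multiplied (>1 up in CRC, <1 down)
    v_usage_skew: Mapping[str, float] = field(
        default_factory=lambda: {"TRBV16": 1.8, "TRBV30": 1.8, "TRBV6-1": 0.5}
    )
    seed: int = 0

    # length-distribution shape (truncated discrete Gaussian on [8, 24])
    length_center_hc: float = 14.5
    length_sd: float = 2.2

    def validate(self) -> None:
        if min(self.n_cases, self.n_controls) < 1:
            raise ValueError("need at least one sample per arm")
        if min(self.repertoire_size_hc, self.repertoire_size_crc) < 1:
            raise ValueError("repertoire sizes must be positive")
        if self.total_reads < 1:
            raise ValueError("total_reads must be positive")
        if not 0.0 <= self.signature_carrier_rate <= 1.0:
            raise ValueError("signature_carrier_rate must lie in [0, 1]")
        if self.signature_enrichment < 1.0:
            raise ValueError("signature_enrichment must be >= 1")
        if self.n_signature < 0:
            raise ValueError("n_signature must be >= 0")
        if not 0.0 < self.signature_base_frequency < 1.0 / max(self.n_signature, 1):
            raise ValueError("signature_base_frequency out of range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["v_usage_skew"] = dict(self.v_usage_skew)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**dict(d))


@dataclass
class GroundTruth:
    """Spiked signature clonotypes of a generated cohort — the oracle for
    panel-recovery scoring."""

    signature_cdr3s: list[tuple[str, str, str]]  # (cdr3_aa, v_gene, j_gene)
    config: SimulationConfig

    @property
    def cdr3_set(self) -> frozenset[str]:
        return frozenset(c for c, _, _ in self.signature_cdr3s)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "signature_cdr3s": [list(t) for t in self.signature_cdr3s],
            "config": self.config.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            signature_cdr3s=[tuple(t) for t in payload["signature_cdr3s"]],
            config=SimulationConfig.from_dict(payload["config"]),
        )


def _truncated_gaussian_lengths(
    rng: np.random.Generator, n: int, center: float, sd: float
) -> np.ndarray:
    """Discrete CDR3 lengths from a Gaussian truncated to [8, 24]."""
    lengths = np.arange(MIN_CDR3_LEN, MAX_CDR3_LEN + 1)
    w = np.exp(-0.5 * ((lengths - center) / sd) ** 2)
    w /= w.sum()
    return rng.choice(lengths, size=n, p=w)


def _random_cdr3s(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    """CDR3 strings ``C`` + random junction + ``F`` with the given total
    amino-acid lengths."""
    mid = lengths - 2  # conserved C...F flanks
    total = int(mid.sum())
    chars = _AA[rng.integers(0, len(_AA), size=total)]
    blob = chars.tobytes().decode("ascii")
    ends = np.cumsum(mid)
    starts = ends - mid
    return ["C" + blob[a:b] + "F" for a, b in zip(starts, ends)]


def _gene_probs(
    genes: tuple[str, ...], skew: Mapping[str, float] | None
) -> np.ndarray:
    # mildly decreasing base usage over the ordered segment pool
    base = 1.0 / (1.0 + 0.05 * np.arange(len(genes)))
    if skew:
        unknown = set(skew) - set(genes)
        if unknown:
            raise ValueError(f"v_usage_skew names unknown genes: {sorted(unknown)}")
        for g, m in skew.items():
            base[genes.index(g)] *= float(m)
    return base / base.sum()


def _draw_signatures(config: SimulationConfig) -> list[tuple[str, str, str]]:
    """Draw the cohort-level public signature clonotypes (deterministic in
    the config seed; independent of arm sizes)."""
    rng = np.random.default_rng([config.seed, 0x516])
    lengths = _truncated_gaussian_lengths(
        rng, config.n_signature, config.length_center_hc, config.length_sd
    )
    cdr3s = _random_cdr3s(rng, lengths)
    vs = rng.choice(len(V_GENES), size=config.n_signature)
    js = rng.choice(len(J_GENES), size=config.n_signature)
    out = []
    seen: set[str] = set()
    for c, vi, ji in zip(cdr3s, vs, js):
        # regenerate on the (vanishingly rare) CDR3 collision
        while c in seen:
            c = _random_cdr3s(rng, np.array([lengths[0]]))[0]
        seen.add(c)
        out.append((c, V_GENES[int(vi)], J_GENES[int(ji)]))
    return out


def sample_repertoire(
    config: SimulationConfig,
    label: str,
    rng: np.random.Generator,
    sample_id: str = "S0",
    signatures: list[tuple[str, str, str]] | None = None,
) -> Repertoire:
    """Draw one labelled repertoire.

    The number of background clones is Poisson around the arm mean; clone
    probabilities follow rank^(−zipf_exponent); CDR3 strings, V and J genes
    are drawn per clone.  Signature clonotypes are then included with
    probability ``signature_carrier_rate`` at ``signature_base_frequency``
    (× ``signature_enrichment`` for cases), all probabilities are
    renormalized, and read counts are one multinomial draw of
    ``total_reads`` — so spiked clones experience the same sampling noise
    as background clones.
    """
    config.validate()
    if label not in ("CRC", "HC"):
        raise ValueError(f"label must be CRC or HC, got {label!r}")
    is_case = label == "CRC"
    if signatures is None:
        signatures = _draw_signatures(config)

    mean_size = config.repertoire_size_crc if is_case else config.repertoire_size_hc
    zipf = config.zipf_exponent_crc if is_case else config.zipf_exponent_hc
    n_clones = max(int(rng.poisson(mean_size)), 2)

    probs = 1.0 / np.arange(1, n_clones + 1, dtype=float) ** zipf
    probs /= probs.sum()

    center = config.length_center_hc - (config.length_shift if is_case else 0.0)
    lengths = _truncated_gaussian_lengths(rng, n_clones, center, config.length_sd)
    cdr3s = _random_cdr3s(rng, lengths)

    v_probs = _gene_probs(V_GENES, config.v_usage_skew if is_case else None)
    j_probs = _gene_probs(J_GENES, None)
    v_idx = rng.choice(len(V_GENES), size=n_clones, p=v_probs)
    j_idx = rng.choice(len(J_GENES), size=n_clones, p=j_probs)

    keys = [
        (c, V_GENES[int(vi)], J_GENES[int(ji)])
        for c, vi, ji in zip(cdr3s, v_idx, j_idx)
    ]

    # public signature clonotypes, carried by both arms, enriched in cases
    sig_freq = config.signature_base_frequency * (
        config.signature_enrichment if is_case else 1.0
    )
    carried = rng.random(len(signatures)) < config.signature_carrier_rate
    sig_keys = [s for s, hit in zip(signatures, carried) if hit]
    if sig_keys:
        sig_mass = sig_freq * len(sig_keys)
        probs = probs * (1.0 - sig_mass)
        probs = np.concatenate([probs, np.full(len(sig_keys), sig_freq)])
        keys = keys + sig_keys
    probs /= probs.sum()

    counts = rng.multinomial(config.total_reads, probs)

    merged: dict[tuple[str, str, str], float] = {}
    for key, cnt in zip(keys, counts):
        if cnt > 0:
            merged[key] = merged.get(key, 0.0) + float(cnt)
    records = [
        ClonotypeRecord(cdr3_aa=k[0], v_gene=k[1], j_gene=k[2], count=c)
        for k, c in merged.items()
    ]
    rep = Repertoire(sample_id=sample_id, records=records)
    return rep.finalize()


def generate_cohort(
    config: SimulationConfig,
    n_batches: int = 1,
    signatures: list[tuple[str, str, str]] | None = None,
) -> tuple[Cohort, GroundTruth]:
    """Generate a labelled cohort of ``n_cases + n_controls`` repertoires.

    Cases come first (``CRC_000`` …), then controls (``HC_000`` …).  Batch
    ids cycle over ``n_batches`` batches by sample index.  Each sample uses
    an independent substream seeded by ``(config.seed, sample index)``.

    ``signatures`` fixes the public signature clonotypes explicitly —
    an external-validation cohort of the same disease shares the
    disease-associated clonotypes of the discovery cohort, so it is
    generated with a fresh seed but the discovery cohort's signatures.
    """
    config.validate()
    if signatures is None:
        signatures = _draw_signatures(config)
    elif len(signatures) != config.n_signature:
        raise ValueError(
            f"{len(signatures)} signatures supplied but config.n_signature"
            f" = {config.n_signature}"
        )
    reps: list[Repertoire] = []
    labels: list[str] = []
    n_total = config.n_cases + config.n_controls
    for i in range(n_total):
        is_case = i < config.n_cases
        label = "CRC" if is_case else "HC"
        sid = f"{label}_{i if is_case else i - config.n_cases:03d}"
        rng = np.random.default_rng([config.seed, 1 + i])
        reps.append(
            sample_repertoire(config, label, rng, sample_id=sid, signatures=signatures)
        )
        labels.append(label)
    batch_ids = [f"batch{i % n_batches}" for i in range(n_total)]
    cohort = Cohort(repertoires=reps, labels=labels, batch_ids=batch_ids)
    return cohort, GroundTruth(signature_cdr3s=signatures, config=config)
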