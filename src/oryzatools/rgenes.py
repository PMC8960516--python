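"""Blast-resistance (R) gene analytics.

NLR domain-composition classification, BLAST-style hit filtering at the
cloned-R-gene search thresholds (e-value < 1e-10, identity >= 70%, query
coverage >= 70%), the orthologue -> blastp -> blastn presence/absence/mutated
decision tree, a chi-squared goodness-of-fit test for resistant/non-resistant
orthologue ratios, and the FDR < alpha positive-selection filter.

E-values are consumed from evidence tables, never computed here; "better
blastn hit" is operationalized as genome-hit bitscore exceeding the best
protein-hit bitscore (the only comparable score in tabular BLAST output).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import AnalysisError, ConfigError

#: Per-domain e-value cutoff for NLR classification (standard domain-scan
#: practice; configurable per call).
DOMAIN_EVALUE_MAX = 1e-5

#: Cloned-R-gene search thresholds.
EVALUE_MAX = 1e-10
MIN_IDENTITY = 70.0
MIN_COVERAGE = 70.0
#: Fallback "gene found" coverage when no orthologue is known.
FALLBACK_COVERAGE = 50.0

#: Positive-selection screen threshold.
FDR_ALPHA = 0.05


# ---------------------------------------------------------------------------
# NLR domain classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainHit:
    """One predicted protein domain (domtblout-style evidence row)."""

    protein_id: str
    domain_name: str  # NB-ARC, LRR, TIR, CC, kinase, other, ...
    evalue: float
    env_start: int
    env_end: int

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ConfigError("domain e-value must be > 0")
        if self.env_start > self.env_end:
            raise ConfigError("domain envelope start > end")


class NLRClass(str, Enum):
    NLR = "NLR"
    NB_ARC_ONLY = "NB-ARC-only"
    LRR_ONLY = "LRR-only"
    NON_NLR = "non-NLR"


def classify_nlr(
    hits: Sequence[DomainHit], evalue_max: float = DOMAIN_EVALUE_MAX
) -> NLRClass:
    """Classify one protein by its domain composition: NLR when both an
    NB-ARC and an LRR domain pass the cutoff, NB-ARC-only / LRR-only when
    exactly one does, non-NLR otherwise."""
    ids = {h.protein_id for h in hits}
    if len(ids) > 1:
        raise ConfigError(f"hits from multiple proteins: {sorted(ids)}")
    names = {h.domain_name for h in hits if h.evalue < evalue_max}
    has_nbarc = "NB-ARC" in names
    has_lrr = "LRR" in names
    if has_nbarc and has_lrr:
        return NLRClass.NLR
    if has_nbarc:
        return NLRClass.NB_ARC_ONLY
    if has_lrr:
        return NLRClass.LRR_ONLY
    return NLRClass.NON_NLR


# ---------------------------------------------------------------------------
# Hit filtering and presence calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HitRecord:
    """One tabular-BLAST-style hit (outfmt-6-like)."""

    query_id: str
    subject_id: str
    kind: str  # "protein-vs-protein" | "nucleotide-vs-genome"
    evalue: float
    percent_identity: float
    query_coverage: float
    bitscore: float
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ConfigError("identity must be in [0,100]")
        if not 0.0 <= self.query_coverage <= 100.0:
            raise ConfigError("coverage must be in [0,100]")
        if self.evalue < 0:
            raise ConfigError("e-value must be >= 0")


def filter_hits(
    hits: Iterable[HitRecord],
    evalue_max: float = EVALUE_MAX,
    min_identity: float = MIN_IDENTITY,
    min_coverage: float = MIN_COVERAGE,
) -> list[HitRecord]:
    """Hits with e-value strictly below ``evalue_max`` and identity and
    query coverage at or above the minima; input order preserved."""
    return [
        h
        for h in hits
        if h.evalue < evalue_max
        and h.percent_identity >= min_identity
        and h.query_coverage >= min_coverage
    ]


@dataclass(frozen=True)
class Thresholds:
    evalue_max: float = EVALUE_MAX
    min_identity: float = MIN_IDENTITY
    min_coverage: float = MIN_COVERAGE
    fallback_coverage: float = FALLBACK_COVERAGE


@dataclass
class PresenceCall:
    """The +/-/M verdict for one R gene with its evidence trail."""

    gene_id: str
    verdict: str  # "+", "-", "M"
    orthologue: Optional[str] = None
    best_protein_hit: Optional[HitRecord] = None
    best_genome_hit: Optional[HitRecord] = None
    disagreement_flags: frozenset[str] = frozenset()


def _best(hits: Sequence[HitRecord], gene_id: str) -> Optional[HitRecord]:
    mine = [h for h in hits if h.query_id == gene_id]
    return max(mine, key=lambda h: h.bitscore) if mine else None


def call_presence(
    gene_id: str,
    orthologues: Mapping[str, str] | Iterable[str],
    protein_hits: Sequence[HitRecord],
    genome_hits: Sequence[HitRecord],
    thresholds: Thresholds = Thresholds(),
) -> PresenceCall:
    """Three-way presence call for one cloned R gene.

    Decision order: (1) a known orthologue marks the gene as a found
    candidate; (2) otherwise a best protein hit with query coverage above
    the 50% fallback does; (3) neither -> absent ("-").  A found candidate
    is present ("+") when its best protein hit passes the filtering
    thresholds with no disagreement, and mutated ("M") when it passes but a
    disagreement is recorded — a truncation/frameshift flag on the
    alignment, or the best genome (blastn-style) hit outscoring the protein
    hit.  A found candidate whose protein support fails the thresholds is
    also "M": the gene is evidenced but its protein is not intact.
    """
    if isinstance(orthologues, Mapping):
        ortho = orthologues.get(gene_id)
    else:
        ortho = gene_id if gene_id in set(orthologues) else None
    best_prot = _best(protein_hits, gene_id)
    best_geno = _best(genome_hits, gene_id)

    found = ortho is not None or (
        best_prot is not None
        and best_prot.query_coverage > thresholds.fallback_coverage
    )
    if not found:
        return PresenceCall(gene_id, "-", ortho, best_prot, best_geno)

    flags = set(best_prot.flags) if best_prot else set()
    if (
        best_prot is not None
        and best_geno is not None
        and best_geno.bitscore > best_prot.bitscore
    ):
        flags.add("superior_genome_hit")

    passes = best_prot is not None and bool(
        filter_hits(
            [best_prot],
            thresholds.evalue_max,
            thresholds.min_identity,
            thresholds.min_coverage,
        )
    )
    if passes and not flags:
        verdict = "+"
    else:
        if best_prot is None:
            flags.add("no_protein_hit")
        elif not passes:
            flags.add("below_thresholds")
        verdict = "M"
    return PresenceCall(
        gene_id, verdict, ortho, best_prot, best_geno, frozenset(flags)
    )


def call_presence_all(
    gene_ids: Sequence[str],
    orthologues: Mapping[str, str] | Iterable[str],
    protein_hits: Sequence[HitRecord],
    genome_hits: Sequence[HitRecord],
    thresholds: Thresholds = Thresholds(),
) -> list[PresenceCall]:
    return [
        call_presence(g, orthologues, protein_hits, genome_hits, thresholds)
        for g in gene_ids
    ]


# ---------------------------------------------------------------------------
# Chi-squared goodness of fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GofResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float


def chisq_gof(
    observed: Sequence[float], expected_proportions: Sequence[float]
) -> GofResult:
    """Pearson chi-squared goodness of fit of observed counts against
    expected proportions (no continuity correction); p-value from the
    upper tail of the chi-squared distribution with k-1 df."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.ndim != 1 or obs.size < 2 or obs.size != props.size:
        raise ConfigError("need matching count/proportion vectors of length >= 2")
    if (obs < 0).any():
        raise ConfigError("counts must be non-negative")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ConfigError("expected proportions must sum to 1")
    expected = obs.sum() * props
    if (expected <= 0).any():
        raise AnalysisError("degenerate expectation: zero expected cell")
    statistic, p_value = stats.chisquare(obs, f_exp=expected)
    return GofResult(
        statistic=float(statistic),
        degrees_of_freedom=obs.size - 1,
        p_value=float(p_value),
    )


# ---------------------------------------------------------------------------
# Positive-selection gene filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSGeneRow:
    gene_id: str
    description: str
    fdr: float
    n_positive_sites: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ConfigError("FDR must be in [0,1]")
        if self.n_positive_sites < 0:
            raise ConfigError("site count must be >= 0")


def select_by_fdr(rows: Sequence[PSGeneRow], alpha: float = FDR_ALPHA) -> list[PSGeneRow]:
    """Rows with FDR strictly below ``alpha`` (stable order)."""
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must be in (0,1)")
    return [r for r in rows if r.fdr < alpha]
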