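"""Genotype-table analytics: haplotype grouping and allele statistics.

Works on cultivar x SNP tables whose cells are homozygote letters (``"C"``),
slash-separated heterozygotes in lexicographic order (``"C/T"``) or missing
(``"."``).  Provides het-aware allele counts and minor-allele frequencies
(a heterozygote contributes 0.5 to each constituent allele), the half-integer
mismatch score used to compare cultivars against haplotype medoids,
informative-position extraction (positions where haplotype medoids differ),
a pamk-style k-medoids grouping with silhouette-based selection of k, and a
simplified coding-effect annotator for single-base substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .errors import AnalysisError, ConfigError, CoordinateError
from .genestruct import _CODON_TABLE, GeneModel, extract_cds

MISSING = "."

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}


def _alleles(cell: str) -> Optional[tuple[str, str]]:
    """A cell as an unordered allele pair; None when missing."""
    if cell == MISSING or cell == "" or cell is None:
        return None
    if "/" in cell:
        x, y = cell.split("/", 1)
        return (x, y)
    return (cell, cell)


# ---------------------------------------------------------------------------
# Allele statistics
# ---------------------------------------------------------------------------

@dataclass
class AlleleStats:
    position: str
    counts: dict[str, float]
    major_allele: Optional[str]
    minor_allele: Optional[str]
    maf: float  # percent, 0..50


def allele_stats(column: pd.Series, position: Optional[str] = None) -> AlleleStats:
    """Het-aware allele counts, major/minor allele and MAF for one SNP column.

    A heterozygote adds 0.5 to each of its alleles, so counts sum to the
    number of non-missing calls.  MAF is the minor count over the
    non-missing total, in percent.  Ties are broken lexicographically so
    output is deterministic.
    """
    counts: dict[str, float] = {}
    n = 0
    for cell in column:
        pair = _alleles(cell)
        if pair is None:
            continue
        n += 1
        for allele in pair:
            counts[allele] = counts.get(allele, 0.0) + 0.5
    if n == 0:
        raise AnalysisError(f"all calls missing at {position or column.name}")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    major = ranked[0][0]
    minor = ranked[1][0] if len(ranked) > 1 else None
    maf = 100.0 * ranked[1][1] / n if minor is not None else 0.0
    return AlleleStats(
        position=str(position or column.name),
        counts=counts,
        major_allele=major,
        minor_allele=minor,
        maf=maf,
    )


def informative_positions(medoids: Sequence[Sequence[str]]) -> list[int]:
    """0-based indices at which not all medoid allele strings agree."""
    if len(medoids) < 2:
        raise ConfigError("need at least two medoids")
    lengths = {len(m) for m in medoids}
    if len(lengths) != 1:
        raise ConfigError("medoid allele strings differ in length")
    return [
        j
        for j in range(lengths.pop())
        if len({m[j] for m in medoids}) > 1
    ]


# ---------------------------------------------------------------------------
# Mismatch scoring and distances
# ---------------------------------------------------------------------------

def _cell_mismatch(cell: str, ref: str) -> Optional[float]:
    """Half-integer mismatch of one call against another; None when either
    is missing.  Each call is an allele pair; the mismatch is the fraction
    of alleles without a counterpart on the other side (multiset overlap)."""
    a = _alleles(cell)
    b = _alleles(ref)
    if a is None or b is None:
        return None
    remaining = list(b)
    shared = 0
    for allele in a:
        if allele in remaining:
            remaining.remove(allele)
            shared += 1
    return 1.0 - shared / 2.0


def mismatch_score(
    cultivar: Sequence[str],
    reference: Sequence[str],
    positions: Optional[Sequence[int]] = None,
) -> float:
    """Sum of per-position mismatches of a cultivar against reference
    alleles: homozygous mismatch 1, heterozygote sharing one allele 0.5,
    missing positions skipped.  ``positions`` restricts scoring to a subset
    of 0-based indices (default: all)."""
    if len(cultivar) != len(reference):
        raise ConfigError("allele vectors differ in length")
    idx = range(len(cultivar)) if positions is None else positions
    total = 0.0
    for j in idx:
        m = _cell_mismatch(cultivar[j], reference[j])
        if m is not None:
            total += m
    return total


def _distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Mean per-position mismatch between all cultivar pairs,
    pairwise-complete over missing data."""
    cells = matrix.to_numpy(dtype=object)
    n, p = cells.shape
    pairs = [[_alleles(cells[i, j]) for j in range(p)] for i in range(n)]
    dist = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            num = 0.0
            den = 0
            for j in range(p):
                a, b = pairs[i][j], pairs[k][j]
                if a is None or b is None:
                    continue
                remaining = list(b)
                shared = 0
                for allele in a:
                    if allele in remaining:
                        remaining.remove(allele)
                        shared += 1
                num += 1.0 - shared / 2.0
                den += 1
            d = num / den if den else 1.0
            dist[i, k] = dist[k, i] = d
    return dist


# ---------------------------------------------------------------------------
# k-medoids haplotype grouping (pamk analog)
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeGrouping:
    k: int
    assignment: pd.Series  # cultivar -> group index 0..k-1
    medoid_ids: list[str]
    medoid_alleles: list[tuple[str, ...]]
    silhouette: float


def _pam(
    dist: np.ndarray, k: int, rng: np.random.Generator, n_restarts: int
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating k-medoids over a precomputed distance matrix; returns
    (labels, medoid indices) of the best restart by total cost."""
    n = dist.shape[0]
    best_cost = np.inf
    best: Optional[tuple[np.ndarray, np.ndarray]] = None
    for _ in range(n_restarts):
        medoids = rng.choice(n, size=k, replace=False)
        for _ in range(100):
            labels = np.argmin(dist[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(labels == c)
                if members.size == 0:
                    # re-seed an empty cluster on the farthest point
                    far = np.argmax(dist[np.arange(n), medoids[labels]])
                    new_medoids[c] = far
                    continue
                within = dist[np.ix_(members, members)].sum(axis=1)
                new_medoids[c] = members[np.argmin(within)]
            new_medoids = np.sort(new_medoids)
            if np.array_equal(new_medoids, np.sort(medoids)):
                break
            medoids = new_medoids
        labels = np.argmin(dist[:, medoids], axis=1)
        cost = dist[np.arange(n), medoids[labels]].sum()
        if cost < best_cost - 1e-12:
            best_cost = cost
            best = (labels, medoids)
    assert best is not None
    return best


def group_haplotypes(
    matrix: pd.DataFrame,
    k_max: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> HaplotypeGrouping:
    """Partition cultivars into haplotype groups by k-medoids over the
    allele-mismatch distance, choosing k in 2..k_max by maximal average
    silhouette width (ties toward smaller k).  Medoids are rows of the
    matrix.  When k equals the number of cultivars (all singletons) the
    silhouette is defined as 0."""
    n = len(matrix)
    if n < 2:
        raise ConfigError("need at least two cultivars")
    if k_max < 2:
        raise ConfigError("k_max must be >= 2")
    if k_max > n:
        raise ConfigError(f"k_max {k_max} exceeds the number of cultivars {n}")
    dist = _distance_matrix(matrix)
    rng = np.random.default_rng(seed)
    best: Optional[tuple[float, int, np.ndarray, np.ndarray]] = None
    for k in range(2, k_max + 1):
        labels, medoids = _pam(dist, k, rng, n_restarts)
        if len(set(labels.tolist())) < 2:
            continue
        if k == n:
            sil = 0.0
        else:
            sil = float(silhouette_score(dist, labels, metric="precomputed"))
        if best is None or sil > best[0] + 1e-12:
            best = (sil, k, labels, medoids)
    if best is None:
        raise AnalysisError("no valid grouping found")
    sil, k, labels, medoids = best
    cells = matrix.to_numpy(dtype=object)
    return HaplotypeGrouping(
        k=k,
        assignment=pd.Series(labels, index=matrix.index, name="group"),
        medoid_ids=[str(matrix.index[m]) for m in medoids],
        medoid_alleles=[tuple(cells[m, :]) for m in medoids],
        silhouette=sil,
    )


# ---------------------------------------------------------------------------
# Simplified SNP-effect annotation
# ---------------------------------------------------------------------------

@dataclass
class VariantEffect:
    position: int
    ref_allele: str
    alt_allele: str
    effect: str  # missense | synonymous | stop_gained | stop_lost | non_coding
    aa_change: Optional[str] = None  # Glu144Lys style
    aa_change_short: Optional[str] = None  # E144K style


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def annotate_snp(
    position: int,
    ref_allele: str,
    alt_allele: str,
    model: GeneModel,
    genome: str,
    flank: int = 2000,
) -> VariantEffect:
    """Predict the coding effect of a single-base substitution.

    Alleles are given on the forward genome strand.  Coding positions are
    located through the model's CDS segments (strand-aware), the affected
    codon substituted and translated; positions inside the locus or within
    ``flank`` bp of it but outside the CDS are non-coding; anything farther
    is out of range.
    """
    for allele in (ref_allele, alt_allele):
        if allele not in _COMP:
            raise ConfigError(f"allele must be a single base, got {allele!r}")
    loc = model.locus
    if not (loc.start - flank <= position <= loc.end + flank):
        raise CoordinateError(
            f"position {position} outside {loc.chrom}:{loc.start}-{loc.end} "
            f"+/- {flank}"
        )
    cds_pos = model.genomic_to_cds(position)
    if cds_pos is None:
        return VariantEffect(position, ref_allele, alt_allele, "non_coding")

    cds = extract_cds(genome, model)
    ref_base = ref_allele if loc.strand == "+" else _COMP[ref_allele]
    alt_base = alt_allele if loc.strand == "+" else _COMP[alt_allele]
    if cds[cds_pos - 1] != ref_base:
        raise AnalysisError(
            f"reference allele mismatch at {position}: CDS has "
            f"{cds[cds_pos - 1]}, expected {ref_base}"
        )
    codon_idx = (cds_pos - 1) // 3  # 0-based codon
    offset = (cds_pos - 1) % 3
    codon = cds[codon_idx * 3: codon_idx * 3 + 3]
    if len(codon) < 3:
        return VariantEffect(position, ref_allele, alt_allele, "non_coding")
    new_codon = codon[:offset] + alt_base + codon[offset + 1:]
    aa_ref = _CODON_TABLE[codon]
    aa_alt = _CODON_TABLE[new_codon]
    if aa_ref == aa_alt:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "stop_gained"
    elif aa_ref == "*":
        effect = "stop_lost"
    else:
        effect = "missense"
    pos_label = codon_idx + 1
    return VariantEffect(
        position,
        ref_allele,
        alt_allele,
        effect,
        aa_change=f"{_AA3[aa_ref]}{pos_label}{_AA3[aa_alt]}",
        aa_change_short=f"{aa_ref}{pos_label}{aa_alt}",
    )
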