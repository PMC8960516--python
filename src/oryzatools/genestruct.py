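"""Sequence and gene-model engine.

Coordinates are 1-based inclusive throughout (GFF3 convention), matching the
printed loci of the rice genomes this toolkit emulates (e.g. the *sd1* locus
``TN1_chr1:40,361,934-40,364,270``).  The module covers CDS extraction,
translation, affine-gap global pairwise alignment with deterministic
left-normalized gap placement, deletion characterization between orthologous
gene models (net deleted length, anchored bases interrupting the gap block,
coding vs intronic partition, frameshift junction and junction-codon effect)
and exon-boundary mapping through a protein alignment.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from Bio import Align

from .errors import (
    AlignmentError,
    AlphabetError,
    CoordinateError,
    ModelError,
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# Standard genetic code, stop rendered as "*".
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


# ---------------------------------------------------------------------------
# Intervals and gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CoordinateError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.start < 1:
            raise CoordinateError(f"interval start {self.start} < 1")
        if self.strand not in {"+", "-"}:
            raise CoordinateError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a 1-based inclusive interval (end - start + 1)."""
    return iv.length


@dataclass
class GeneModel:
    """Exon/CDS structure of a gene.

    ``exons`` and ``cds_segments`` are kept in transcription order: ascending
    genomic coordinates on the + strand, descending on the - strand.  Every
    CDS segment must be contained in an exon.
    """

    gene_id: str
    transcript_id: str
    locus: GenomicInterval
    exons: list[GenomicInterval]
    cds_segments: list[GenomicInterval]
    phase: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ModelError(f"phase must be 0/1/2, got {self.phase}")
        fwd = self.locus.strand == "+"
        ordered = sorted(self.exons, key=lambda e: e.start, reverse=not fwd)
        if [(e.start, e.end) for e in self.exons] != [(e.start, e.end) for e in ordered]:
            raise ModelError(f"{self.gene_id}: exons not in transcription order")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for prev, nxt in zip(genomic, genomic[1:]):
            if nxt.start <= prev.end:
                raise ModelError(f"{self.gene_id}: overlapping exons")
        for ex in self.exons:
            if ex.start < self.locus.start or ex.end > self.locus.end:
                raise ModelError(f"{self.gene_id}: exon outside locus")
        for cds in self.cds_segments:
            if not any(cds.start >= ex.start and cds.end <= ex.end for ex in self.exons):
                raise ModelError(
                    f"{self.gene_id}: CDS segment {cds.start}-{cds.end} not "
                    "contained in any exon"
                )

    @property
    def introns(self) -> list[GenomicInterval]:
        """Intervals between consecutive exons, in transcription order."""
        genomic = sorted(self.exons, key=lambda e: e.start)
        ivs = [
            GenomicInterval(self.locus.chrom, a.end + 1, b.start - 1, self.locus.strand)
            for a, b in zip(genomic, genomic[1:])
            if b.start - a.end > 1
        ]
        if self.locus.strand == "-":
            ivs = ivs[::-1]
        return ivs

    @property
    def cds_length(self) -> int:
        return sum(seg.length for seg in self.cds_segments)

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Map a 1-based CDS coordinate to its genomic coordinate."""
        if cds_pos < 1 or cds_pos > self.cds_length:
            raise CoordinateError(f"CDS position {cds_pos} outside 1..{self.cds_length}")
        offset = cds_pos
        for seg in self.cds_segments:  # transcription order
            if offset <= seg.length:
                if self.locus.strand == "+":
                    return seg.start + offset - 1
                return seg.end - offset + 1
            offset -= seg.length
        raise AssertionError("unreachable")

    def genomic_to_cds(self, genomic_pos: int) -> Optional[int]:
        """Map a genomic coordinate to a 1-based CDS coordinate, or None."""
        offset = 0
        for seg in self.cds_segments:
            if seg.start <= genomic_pos <= seg.end:
                if self.locus.strand == "+":
                    return offset + (genomic_pos - seg.start) + 1
                return offset + (seg.end - genomic_pos) + 1
            offset += seg.length
        return None


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_cds(genome: str, model: GeneModel) -> str:
    """Concatenated CDS of ``model`` read from ``genome`` (one chromosome).

    Segments are concatenated in transcription order; minus-strand models are
    reverse-complemented.
    """
    n = len(genome)
    segs = sorted(model.cds_segments, key=lambda s: s.start)
    for seg in segs:
        if seg.end > n:
            raise CoordinateError(
                f"{model.gene_id}: CDS segment {seg.start}-{seg.end} beyond "
                f"sequence length {n}"
            )
    raw = "".join(genome[seg.start - 1: seg.end] for seg in segs)
    if model.locus.strand == "-":
        return reverse_complement(raw)
    return raw


@dataclass(frozen=True)
class Translation:
    """Protein string plus any trailing incomplete codon (never padded)."""

    protein: str
    trailing: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.protein


def translate(cds: str) -> Translation:
    """Translate a CDS with the standard genetic code.

    Stop codons are rendered ``*``.  A trailing 1-2 nt partial codon is
    returned in ``trailing`` rather than silently dropped.  Ambiguity codes
    are rejected.
    """
    if len(cds) < 3:
        raise AlphabetError(f"CDS shorter than one codon ({len(cds)} nt)")
    seq = cds.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise AlphabetError(f"non-ACGT characters in CDS: {sorted(bad)}")
    n_full = len(seq) // 3 * 3
    protein = "".join(_CODON_TABLE[seq[i: i + 3]] for i in range(0, n_full, 3))
    return Translation(protein=protein, trailing=seq[n_full:])


# ---------------------------------------------------------------------------
# Pairwise global alignment (affine gaps)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap scoring; a gap of length L costs gap_open + (L-1)*gap_extend.

    Defaults target the near-identical-allele regime of cultivar gene
    comparisons: the mismatch penalty is deep enough (< open - extend - match)
    that a single matched base interrupting a long deletion stays matched
    instead of the two gap runs merging around it.
    """

    match: float = 2.0
    mismatch: float = -6.0
    gap_open: float = -8.0
    gap_extend: float = -2.0

    def score_pair(self, x: str, y: str) -> float:
        return self.match if x == y else self.mismatch

    def gap_cost(self, length: int) -> float:
        if length <= 0:
            return 0.0
        return self.gap_open + (length - 1) * self.gap_extend


@dataclass
class PairwiseAlignment:
    """A global alignment of two residue strings.

    ``columns`` maps every alignment column to 1-based source coordinates,
    ``None`` for gap columns.  De-gapped rows equal the inputs.
    """

    seq_a: str
    seq_b: str
    columns: list[tuple[Optional[int], Optional[int]]]
    score: float
    scoring: AlignScoring

    @property
    def row_a(self) -> str:
        return "".join("-" if a is None else self.seq_a[a - 1] for a, _ in self.columns)

    @property
    def row_b(self) -> str:
        return "".join("-" if b is None else self.seq_b[b - 1] for _, b in self.columns)

    @property
    def percent_identity(self) -> float:
        paired = [(a, b) for a, b in self.columns if a is not None and b is not None]
        if not paired:
            return 0.0
        same = sum(1 for a, b in paired if self.seq_a[a - 1] == self.seq_b[b - 1])
        return 100.0 * same / len(paired)

    @property
    def coverage_a(self) -> float:
        paired = sum(1 for a, b in self.columns if a is not None and b is not None)
        return 100.0 * paired / len(self.seq_a)

    @property
    def coverage_b(self) -> float:
        paired = sum(1 for a, b in self.columns if a is not None and b is not None)
        return 100.0 * paired / len(self.seq_b)


def _columns_from_indices(indices) -> list[tuple[Optional[int], Optional[int]]]:
    cols = []
    for ia, ib in zip(indices[0], indices[1]):
        cols.append(
            (int(ia) + 1 if ia >= 0 else None, int(ib) + 1 if ib >= 0 else None)
        )
    return cols


def _left_normalize(
    cols: list[tuple[Optional[int], Optional[int]]],
    seq_a: str,
    seq_b: str,
    scoring: AlignScoring,
) -> list[tuple[Optional[int], Optional[int]]]:
    """Slide gap runs leftward wherever score-neutral (canonical placement)."""
    cols = list(cols)
    changed = True
    while changed:
        changed = False
        i = 0
        n = len(cols)
        while i < n:
            a_i, b_i = cols[i]
            if a_i is not None and b_i is None:  # deletion run (gap in row b)
                j = i
                while j + 1 < n and cols[j + 1][0] is not None and cols[j + 1][1] is None:
                    j += 1
                if i > 0:
                    pa, pb = cols[i - 1]
                    if pa is not None and pb is not None:
                        last_a = cols[j][0]
                        if scoring.score_pair(
                            seq_a[last_a - 1], seq_b[pb - 1]
                        ) == scoring.score_pair(seq_a[pa - 1], seq_b[pb - 1]):
                            # move the aligned pair to the right end of the run
                            for k in range(i - 1, j):
                                cols[k] = (cols[k][0], None)
                            cols[j] = (last_a, pb)
                            changed = True
                i = j + 1
            elif a_i is None and b_i is not None:  # insertion run (gap in row a)
                j = i
                while j + 1 < n and cols[j + 1][0] is None and cols[j + 1][1] is not None:
                    j += 1
                if i > 0:
                    pa, pb = cols[i - 1]
                    if pa is not None and pb is not None:
                        last_b = cols[j][1]
                        if scoring.score_pair(
                            seq_a[pa - 1], seq_b[last_b - 1]
                        ) == scoring.score_pair(seq_a[pa - 1], seq_b[pb - 1]):
                            for k in range(i - 1, j):
                                cols[k] = (None, cols[k][1])
                            cols[j] = (pa, last_b)
                            changed = True
                i = j + 1
            else:
                i += 1
    return cols


def align_global(
    a: str, b: str, scoring: Optional[AlignScoring] = None
) -> PairwiseAlignment:
    """Optimal global alignment of two residue strings with affine gaps.

    Ties between co-optimal alignments are broken deterministically by
    left-normalizing gap placement (score-neutral gaps slide as far 5'/left
    as possible).
    """
    if not a or not b:
        raise AlignmentError("align_global requires two non-empty sequences")
    scoring = scoring or AlignScoring()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    aln = next(iter(aligner.align(a, b)))
    cols = _columns_from_indices(aln.indices)
    cols = _left_normalize(cols, a, b, scoring)
    return PairwiseAlignment(
        seq_a=a, seq_b=b, columns=cols, score=float(aln.score), scoring=scoring
    )


# ---------------------------------------------------------------------------
# Deletion events and characterization
# ---------------------------------------------------------------------------

@dataclass
class DeletionEvent:
    """A maximal run of reference-only columns, possibly interrupted by short
    runs of matched "anchored" bases (at most ``max_anchor_run`` in a row)."""

    col_start: int
    col_end: int
    deleted_ref_positions: list[int]
    anchored_ref_positions: list[int]

    @property
    def columns(self) -> int:
        return self.col_end - self.col_start + 1

    @property
    def deleted_bp(self) -> int:
        return len(self.deleted_ref_positions)

    @property
    def anchored_bases(self) -> int:
        return len(self.anchored_ref_positions)


def deletion_events(
    aln: PairwiseAlignment, max_anchor_run: int = 2
) -> list[DeletionEvent]:
    """Reference-only blocks of ``aln``, joining runs separated by short
    matched interruptions (the anchored-base rule)."""
    kinds: list[str] = []
    for a, b in aln.columns:
        if a is not None and b is None:
            kinds.append("D")
        elif a is None and b is not None:
            kinds.append("I")
        elif aln.seq_a[a - 1] == aln.seq_b[b - 1]:
            kinds.append("M")
        else:
            kinds.append("X")

    events: list[DeletionEvent] = []
    n = len(kinds)
    i = 0
    while i < n:
        if kinds[i] != "D":
            i += 1
            continue
        start = i
        deleted = []
        anchored = []
        j = i
        while j < n:
            if kinds[j] == "D":
                deleted.append(aln.columns[j][0])
                j += 1
            elif kinds[j] == "M":
                # only bridge if another D run follows within max_anchor_run
                run = 0
                k = j
                while k < n and kinds[k] == "M":
                    run += 1
                    k += 1
                if run <= max_anchor_run and k < n and kinds[k] == "D":
                    anchored.extend(aln.columns[m][0] for m in range(j, k))
                    j = k
                else:
                    break
            else:
                break
        events.append(
            DeletionEvent(
                col_start=start + 1,
                col_end=j,
                deleted_ref_positions=deleted,
                anchored_ref_positions=anchored,
            )
        )
        i = j
    return events


@dataclass
class DeletionReport:
    """Everything the deletion characterization reports about a gene pair."""

    genomic_deletion_bp: int = 0
    anchored_bases: int = 0
    gap_block_columns: int = 0
    cds_deletion_bp: int = 0
    intronic_deletion_bp: int = 0
    frameshift: bool = False
    frameshift_junction: Optional[int] = None
    junction_codon_effect: Optional[str] = None  # "preserved" | "changed"
    junction_amino_acids: Optional[tuple[str, str]] = None  # (ref, alt)

    def to_json(self) -> str:
        d = asdict(self)
        if d["junction_amino_acids"] is not None:
            d["junction_amino_acids"] = list(d["junction_amino_acids"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DeletionReport":
        d = json.loads(text)
        if d.get("junction_amino_acids") is not None:
            d["junction_amino_acids"] = tuple(d["junction_amino_acids"])
        return cls(**d)


def _gene_sequence(genome: str, model: GeneModel) -> str:
    loc = model.locus
    if loc.end > len(genome):
        raise CoordinateError(
            f"{model.gene_id}: locus end {loc.end} beyond sequence length {len(genome)}"
        )
    if loc.strand != "+":
        raise ModelError("deletion characterization expects forward-strand models")
    return genome[loc.start - 1: loc.end]


def characterize_deletion(
    ref_genome: str,
    ref_model: GeneModel,
    alt_genome: str,
    alt_model: GeneModel,
    scoring: Optional[AlignScoring] = None,
    max_anchor_run: int = 2,
) -> DeletionReport:
    """Characterize the deletion(s) distinguishing an alternative (derived)
    gene from its reference orthologue.

    The gene regions are globally aligned; maximal reference-only blocks are
    merged across matched interruptions of at most ``max_anchor_run`` columns
    (anchored bases).  The coding loss is measured on a second alignment of
    the two CDSs; reference coding positions absent from the derived CDS but
    whose genomic homologue survives inside a derived intron count as
    intronic, not deleted.  A frameshift is a coding loss not divisible by 3;
    its junction is the last derived CDS coordinate in frame with the
    reference, and the codon spanning the junction is translated on both
    sides.
    """
    if not ref_model.cds_segments or not alt_model.cds_segments:
        raise ModelError("both models need CDS annotation")
    scoring = scoring or AlignScoring()

    ref_gene = _gene_sequence(ref_genome, ref_model)
    alt_gene = _gene_sequence(alt_genome, alt_model)

    aln_g = align_global(ref_gene, alt_gene, scoring)
    if aln_g.percent_identity == 0.0:
        raise AlignmentError("no alignable region between the gene sequences")
    events_g = deletion_events(aln_g, max_anchor_run)

    report = DeletionReport()
    report.genomic_deletion_bp = sum(ev.deleted_bp for ev in events_g)
    report.anchored_bases = sum(ev.anchored_bases for ev in events_g)
    report.gap_block_columns = sum(ev.columns for ev in events_g)

    # Map ref gene-local position -> alt gene-local position for matched cols.
    ref_to_alt = {a: b for a, b in aln_g.columns if a is not None and b is not None}

    # Alt intron membership (gene-local coordinates).
    alt_off = alt_model.locus.start - 1
    alt_intron_pos: set[int] = set()
    for iv in alt_model.introns:
        alt_intron_pos.update(range(iv.start - alt_off, iv.end - alt_off + 1))

    ref_cds = extract_cds(ref_genome, ref_model)
    alt_cds = extract_cds(alt_genome, alt_model)
    aln_c = align_global(ref_cds, alt_cds, scoring)
    events_c = deletion_events(aln_c, max_anchor_run)

    ref_off = ref_model.locus.start - 1
    missing_cds_positions: list[int] = []  # ref CDS coordinates
    for ev in events_c:
        missing_cds_positions.extend(ev.deleted_ref_positions)

    intronic = 0
    for cds_pos in missing_cds_positions:
        gpos = ref_model.cds_to_genomic(cds_pos) - ref_off  # gene-local
        alt_pos = ref_to_alt.get(gpos)
        if alt_pos is not None and alt_pos in alt_intron_pos:
            intronic += 1
    report.intronic_deletion_bp = intronic
    report.cds_deletion_bp = len(missing_cds_positions) - intronic
    report.frameshift = report.cds_deletion_bp % 3 != 0

    if events_c:
        first = min(events_c, key=lambda ev: ev.col_start)
        alt_before = sum(
            1 for a, b in aln_c.columns[: first.col_start - 1] if b is not None
        )
        report.frameshift_junction = alt_before
        codon_idx = alt_before // 3 + 1  # codon spanning the junction
        r0, a0 = (codon_idx - 1) * 3, (codon_idx - 1) * 3
        ref_codon = ref_cds[r0: r0 + 3]
        alt_codon = alt_cds[a0: a0 + 3]
        if len(ref_codon) == 3 and len(alt_codon) == 3:
            aa_ref = _CODON_TABLE[ref_codon.upper()]
            aa_alt = _CODON_TABLE[alt_codon.upper()]
            report.junction_amino_acids = (aa_ref, aa_alt)
            report.junction_codon_effect = (
                "preserved" if aa_ref == aa_alt else "changed"
            )
    return report


def boundary_deletion_length(ref_boundary: int, alt_boundary: int) -> int:
    """Deletion length inferred from matching structural boundaries,
    e.g. (981, 599) -> 382."""
    if ref_boundary <= 0 or alt_boundary <= 0:
        raise CoordinateError("boundaries must be positive")
    if ref_boundary < alt_boundary:
        raise CoordinateError(
            f"reference boundary {ref_boundary} < derived boundary {alt_boundary}"
        )
    return ref_boundary - alt_boundary


def exon1_protein_span(exon1_cds_length: int) -> int:
    """Number of amino-acid positions encoded at least partially by exon 1
    (ceil(length/3)); 293 coding nt -> 98 aa."""
    if exon1_cds_length < 1:
        raise CoordinateError("exon 1 CDS length must be >= 1")
    return math.ceil(exon1_cds_length / 3)


# ---------------------------------------------------------------------------
# Exon mapping through a protein alignment
# ---------------------------------------------------------------------------

@dataclass
class ExonBoundary:
    """An internal exon boundary of one model projected onto the alignment."""

    model: str  # "a" | "b"
    exon_index: int  # 1-based, boundary after this exon
    cds_position: int
    protein_position: int
    column: int
    other_protein_position: Optional[int]


@dataclass
class ExonGapSpan:
    """Columns where one model has coding residues and the other has gaps."""

    missing_in: str  # "a" | "b": the model lacking coding counterpart
    col_start: int
    col_end: int
    other_protein_start: int
    other_protein_end: int


@dataclass
class ExonMap:
    boundaries: list[ExonBoundary]
    exon_gaps: list[ExonGapSpan]
    introns_a: list[GenomicInterval] = field(default_factory=list)
    introns_b: list[GenomicInterval] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "boundaries": [asdict(b) for b in self.boundaries],
                "exon_gaps": [asdict(g) for g in self.exon_gaps],
                "introns_a": [asdict(iv) for iv in self.introns_a],
                "introns_b": [asdict(iv) for iv in self.introns_b],
            },
            indent=2,
        )


def _boundaries_for(
    model: GeneModel, which: str, aln: PairwiseAlignment
) -> list[ExonBoundary]:
    col_of = {}
    other_at = {}
    for idx, (a, b) in enumerate(aln.columns, start=1):
        pos = a if which == "a" else b
        other = b if which == "a" else a
        if pos is not None:
            col_of[pos] = idx
            other_at[pos] = other
    out = []
    cum = 0
    plen = len(aln.seq_a if which == "a" else aln.seq_b)
    for i, seg in enumerate(model.cds_segments[:-1], start=1):
        cum += seg.length
        ppos = min(math.ceil(cum / 3), plen)
        out.append(
            ExonBoundary(
                model=which,
                exon_index=i,
                cds_position=cum,
                protein_position=ppos,
                column=col_of[ppos],
                other_protein_position=other_at[ppos],
            )
        )
    return out


def map_exons(
    aln: PairwiseAlignment, model_a: GeneModel, model_b: GeneModel
) -> ExonMap:
    """Project the exon boundaries of two gene models through an alignment of
    their translations; report exon-gap spans where one model has coding
    sequence and the other has alignment gaps."""
    for model, seq in ((model_a, aln.seq_a), (model_b, aln.seq_b)):
        n_aa = model.cds_length // 3
        if len(seq) not in (n_aa, n_aa - 1):  # translation may omit stop
            raise ModelError(
                f"{model.gene_id}: translation length {len(seq)} inconsistent "
                f"with CDS length {model.cds_length}"
            )
    boundaries = _boundaries_for(model_a, "a", aln) + _boundaries_for(
        model_b, "b", aln
    )
    gaps: list[ExonGapSpan] = []
    i = 0
    cols = aln.columns
    while i < len(cols):
        a, b = cols[i]
        if (a is None) != (b is None):
            missing = "a" if a is None else "b"
            j = i
            while j + 1 < len(cols) and (
                (cols[j + 1][0] is None) == (missing == "a")
                and (cols[j + 1][1] is None) == (missing == "b")
            ):
                j += 1
            other_positions = [
                (cols[k][1] if missing == "a" else cols[k][0]) for k in range(i, j + 1)
            ]
            gaps.append(
                ExonGapSpan(
                    missing_in=missing,
                    col_start=i + 1,
                    col_end=j + 1,
                    other_protein_start=other_positions[0],
                    other_protein_end=other_positions[-1],
                )
            )
            i = j + 1
        else:
            i += 1
    return ExonMap(
        boundaries=boundaries,
        exon_gaps=gaps,
        introns_a=model_a.introns,
        introns_b=model_b.introns,
    )
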