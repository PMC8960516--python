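"""Shared file I/O, run configuration and the umbrella pipeline.

Formats: FASTA (wrapped 60 columns), GFF3 (version 3 header, 1-based
inclusive, gene/mRNA/exon/CDS hierarchy with ID/Parent attributes),
tab-separated evidence and genotype tables with a header row and
"#"-prefixed comments, and JSON reports.  All readers validate and raise
:class:`~oryzatools.errors.FormatError` / ``ModelError`` with actionable
messages; all writers produce files their readers accept.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .errors import (
    AnalysisError,
    ConfigError,
    CoordinateError,
    FormatError,
    ModelError,
)
from .genestruct import (
    DeletionReport,
    GeneModel,
    GenomicInterval,
    characterize_deletion,
)
from .haplotypes import allele_stats, group_haplotypes, informative_positions, mismatch_score
from .rgenes import (
    DomainHit,
    GofResult,
    HitRecord,
    PresenceCall,
    Thresholds,
    call_presence_all,
    chisq_gof,
)

logger = logging.getLogger("oryzatools")

_VALID_BASES = set("ACGTN")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Parse a FASTA file into SeqRecords, uppercasing sequences.

    Rejects duplicate ids, empty sequences and characters outside ACGTN,
    naming the offending line.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
        seq = str(rec.seq)
        if seq != seq.upper():
            logger.info("%s: uppercased lowercase residues in %s", path, rec.id)
            seq = seq.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            lineno = _find_offending_line(path, bad)
            raise FormatError(
                f"{path}:{lineno}: invalid sequence character(s) "
                f"{sorted(bad)} in record {rec.id!r}"
            )
        rec.seq = Seq(seq)
    return records


def _find_offending_line(path: Path, bad: set[str]) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return i
    return 0


def write_fasta(records: Sequence[SeqRecord], path: str | Path, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}" + (f" {rec.description}" if rec.description
                                     and rec.description != rec.id else "") + "\n")
            seq = str(rec.seq)
            for i in range(0, len(seq), wrap):
                fh.write(seq[i: i + wrap] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 gene/mRNA/exon/CDS hierarchy into GeneModels (one per
    mRNA).  Exons come out in transcription order; structural violations
    (start > end, CDS outside exon) raise ModelError."""
    import gffutils

    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # malformed file
        raise FormatError(f"{path}: cannot parse GFF3 ({exc})") from exc

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        for mrna in db.children(gene, featuretype="mRNA"):
            try:
                strand = mrna.strand if mrna.strand in {"+", "-"} else "+"
                fwd = strand == "+"
                exons = sorted(
                    (
                        GenomicInterval(mrna.seqid, ex.start, ex.end, strand)
                        for ex in db.children(mrna, featuretype="exon")
                    ),
                    key=lambda iv: iv.start,
                    reverse=not fwd,
                )
                cds = sorted(
                    (
                        GenomicInterval(mrna.seqid, c.start, c.end, strand)
                        for c in db.children(mrna, featuretype="CDS")
                    ),
                    key=lambda iv: iv.start,
                    reverse=not fwd,
                )
                models.append(
                    GeneModel(
                        gene_id=gene.id,
                        transcript_id=mrna.id,
                        locus=GenomicInterval(mrna.seqid, gene.start, gene.end, strand),
                        exons=exons,
                        cds_segments=cds,
                    )
                )
            except CoordinateError as exc:
                raise ModelError(f"{path}: {gene.id}: {exc}") from exc
    if not models:
        raise FormatError(f"{path}: no gene/mRNA models found")
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            loc = m.locus
            fh.write(
                f"{loc.chrom}\toryzatools\tgene\t{loc.start}\t{loc.end}\t.\t"
                f"{loc.strand}\t.\tID={m.gene_id}\n"
            )
            fh.write(
                f"{loc.chrom}\toryzatools\tmRNA\t{loc.start}\t{loc.end}\t.\t"
                f"{loc.strand}\t.\tID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for i, ex in enumerate(sorted(m.exons, key=lambda e: e.start), 1):
                fh.write(
                    f"{loc.chrom}\toryzatools\texon\t{ex.start}\t{ex.end}\t.\t"
                    f"{loc.strand}\t.\tID={m.transcript_id}.exon{i};"
                    f"Parent={m.transcript_id}\n"
                )
            for i, c in enumerate(sorted(m.cds_segments, key=lambda s: s.start), 1):
                fh.write(
                    f"{loc.chrom}\toryzatools\tCDS\t{c.start}\t{c.end}\t.\t"
                    f"{loc.strand}\t{m.phase if i == 1 else '.'}\t"
                    f"ID={m.transcript_id}.cds{i};Parent={m.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# Tabular evidence and genotype I/O
# ---------------------------------------------------------------------------

_HIT_COLUMNS = ["qseqid", "sseqid", "kind", "pident", "qcovs", "evalue",
                "bitscore", "flags"]


def write_hits_tsv(hits: Sequence[HitRecord], path: str | Path) -> None:
    rows = [
        {
            "qseqid": h.query_id, "sseqid": h.subject_id, "kind": h.kind,
            "pident": h.percent_identity, "qcovs": h.query_coverage,
            "evalue": h.evalue, "bitscore": h.bitscore,
            "flags": ";".join(sorted(h.flags)) or ".",
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=_HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[HitRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    missing = set(_HIT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        flags = frozenset() if r["flags"] in {".", ""} else frozenset(
            r["flags"].split(";"))
        try:
            out.append(
                HitRecord(
                    r["qseqid"], r["sseqid"], r["kind"], float(r["evalue"]),
                    float(r["pident"]), float(r["qcovs"]),
                    float(r["bitscore"]), flags=flags,
                )
            )
        except (ValueError, ConfigError) as exc:
            raise FormatError(f"{path}: bad hit row for {r['qseqid']}: {exc}")
    return out


def write_ortho_tsv(orthologues: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(orthologues.items()), columns=["gene_id", "subject_id"]
    ).to_csv(path, sep="\t", index=False)


def read_ortho_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    if not {"gene_id", "subject_id"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns gene_id, subject_id")
    return dict(zip(df["gene_id"], df["subject_id"]))


def write_domains_tsv(hits: Sequence[DomainHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"target": h.domain_name, "query": h.protein_id,
             "i_evalue": h.evalue, "env_from": h.env_start,
             "env_to": h.env_end}
            for h in hits
        ],
        columns=["target", "query", "i_evalue", "env_from", "env_to"],
    ).to_csv(path, sep="\t", index=False)


def read_domains_tsv(path: str | Path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"target", "query", "i_evalue", "env_from", "env_to"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}")
    return [
        DomainHit(str(r["query"]), str(r["target"]), float(r["i_evalue"]),
                  int(r["env_from"]), int(r["env_to"]))
        for _, r in df.iterrows()
    ]


def write_genotypes_tsv(matrix: pd.DataFrame, path: str | Path,
                        seed: Optional[int] = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        matrix.to_csv(fh, sep="\t", index_label="cultivar")


def read_genotypes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str,
                     keep_default_na=False)
    if df.empty:
        raise FormatError(f"{path}: empty genotype matrix")
    return df


def write_calls_tsv(calls: Sequence[PresenceCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        evidence = {
            "orthologue": c.orthologue,
            "best_protein_hit": dataclasses.asdict(c.best_protein_hit)
            if c.best_protein_hit else None,
            "best_genome_hit": dataclasses.asdict(c.best_genome_hit)
            if c.best_genome_hit else None,
            "disagreement_flags": sorted(c.disagreement_flags),
        }
        for key in ("best_protein_hit", "best_genome_hit"):
            if evidence[key] is not None:
                evidence[key]["flags"] = sorted(evidence[key]["flags"])
        rows.append(
            {"gene_id": c.gene_id, "verdict": c.verdict,
             "evidence": json.dumps(evidence, sort_keys=True)}
        )
    pd.DataFrame(rows, columns=["gene_id", "verdict", "evidence"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration and report
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Umbrella configuration: thresholds, seed, output directory."""

    seed: int = 0
    out_dir: Optional[str] = None
    evalue_max: float = 1e-10
    min_identity: float = 70.0
    min_coverage: float = 70.0
    fallback_coverage: float = 50.0
    fdr_alpha: float = 0.05
    max_anchor_run: int = 2
    k_max: int = 6
    observed_counts: tuple[int, ...] = (69, 101)
    expected_proportions: tuple[float, ...] = (90 / 219, 129 / 219)
    verbosity: int = 0

    def validate(self) -> None:
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")
        if not 0 < self.fdr_alpha < 1:
            raise ConfigError("fdr_alpha must be in (0,1)")
        if self.max_anchor_run < 0:
            raise ConfigError("max_anchor_run must be >= 0")
        if self.k_max < 2:
            raise ConfigError("k_max must be >= 2")

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(self.evalue_max, self.min_identity,
                          self.min_coverage, self.fallback_coverage)


@dataclass
class Report:
    """Serializable record of one pipeline run."""

    version: str
    seed: int
    config: dict
    stages: dict
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Report":
        return cls(**json.loads(text))


def run_pipeline(config: RunConfig) -> Report:
    """Run the full demonstration pipeline on synthetic study material:
    generate both deletion scenarios, characterize them, call R-gene
    presence on planted evidence, group planted haplotypes, compute allele
    statistics, and run the orthologue-ratio goodness-of-fit test.  Every
    random draw derives from ``config.seed``; outputs are written under
    ``config.out_dir`` when set."""
    from .synthetic import (
        EvidenceScenarioConfig,
        GenotypeScenarioConfig,
        gen_genotype_matrix,
        gen_rgene_evidence,
        gen_sd1_pair,
        sd1_anchored_deletion_config,
        sd1_cds_deletion_config,
    )

    config.validate()
    stages: dict = {}

    # Stage 1: semidwarf deletion characterization on both scenarios.
    reports = {}
    scenarios = {
        "anchored_genomic": gen_sd1_pair(sd1_anchored_deletion_config(config.seed)),
        "cds_intronic": gen_sd1_pair(sd1_cds_deletion_config(config.seed)),
    }
    for name, sc in scenarios.items():
        rep = characterize_deletion(
            sc.ref_genome, sc.ref_model, sc.alt_genome, sc.alt_model,
            max_anchor_run=config.max_anchor_run,
        )
        reports[name] = json.loads(rep.to_json())
    stages["sd1_deletion"] = reports

    # Stage 2: presence/absence/mutated calls on planted evidence.
    ev = gen_rgene_evidence(EvidenceScenarioConfig.cycling(9, seed=config.seed))
    calls = call_presence_all(
        sorted(ev.truth), ev.orthologues, ev.protein_hits, ev.genome_hits,
        config.thresholds,
    )
    verdict_map = {"present": "+", "absent": "-", "mutated": "M"}
    concordant = sum(
        1 for c in calls if c.verdict == verdict_map[ev.truth[c.gene_id]])
    stages["rgene_calls"] = {
        "calls": {c.gene_id: c.verdict for c in calls},
        "truth_concordance": concordant / len(calls),
    }

    # Stage 3: haplotype grouping and allele statistics.
    matrix, truth_groups, haps = gen_genotype_matrix(
        GenotypeScenarioConfig(n_cultivars=60, n_positions=3, n_haplotypes=2,
                               seed=config.seed)
    )
    grouping = group_haplotypes(matrix, k_max=min(config.k_max, 5),
                                seed=config.seed)
    medoid_strings = ["".join(m) for m in grouping.medoid_alleles]
    stats_rows = {
        col: dataclasses.asdict(allele_stats(matrix[col]))
        for col in matrix.columns
    }
    stages["haplotypes"] = {
        "k": grouping.k,
        "silhouette": grouping.silhouette,
        "medoids": medoid_strings,
        "informative_positions": informative_positions(grouping.medoid_alleles),
        "mismatch_first_vs_medoid0": mismatch_score(
            list(matrix.iloc[0]), list(grouping.medoid_alleles[0])),
        "allele_stats": stats_rows,
    }

    # Stage 4: goodness-of-fit on the resistant/non-resistant orthologue ratio.
    gof = chisq_gof(config.observed_counts, config.expected_proportions)
    stages["gof"] = dataclasses.asdict(gof)

    # normalize through JSON so serializing and re-parsing yields an equal report
    report = Report(
        version=__version__,
        seed=config.seed,
        config=json.loads(json.dumps(dataclasses.asdict(config))),
        stages=json.loads(json.dumps(stages)),
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        write_calls_tsv(calls, out / "rgene_calls.tsv")
        write_genotypes_tsv(matrix, out / "genotypes.tsv", seed=config.seed)
        grouping.assignment.to_frame().to_csv(out / "haplotype_groups.tsv",
                                              sep="\t", index_label="cultivar")
        pd.DataFrame(
            [
                {"position": p, "major": s["major_allele"],
                 "minor": s["minor_allele"], "maf_percent": s["maf"]}
                for p, s in stats_rows.items()
            ]
        ).to_csv(out / "allele_stats.tsv", sep="\t", index=False)
        logger.info("report written to %s (seed=%d)", out, config.seed)
    return report
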