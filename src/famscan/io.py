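"""Readers/writers for the standard formats the pipeline consumes.

All genomic coordinates are 1-based inclusive (GFF3 convention) throughout
the package; any half-open arithmetic is internal to a function.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "GeneModel",
    "DomainHit",
    "ExpressionMatrix",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "read_domain_table",
    "read_expression_matrix",
    "read_qpcr_table",
    "reverse_complement",
]

_DNA_CHARS = set("ACGTUNRYSWKMBDHV-")
_PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """A named sequence, nucleotide or amino acid."""

    id: str
    sequence: str
    alphabet: str = "dna"  # {"dna", "protein"}

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence for {self.id!r} is empty")
        allowed = _DNA_CHARS if self.alphabet == "dna" else _PROTEIN_CHARS
        seq = self.sequence.upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"illegal {self.alphabet} character {ch!r} at position "
                    f"{pos} in record {self.id!r}")
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """One annotated gene with the exon/CDS layout of its chosen transcript."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        self.exons = sorted(self.exons)
        self.cds_segments = sorted(self.cds_segments)
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start > end")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e
        for s, e in self.cds_segments:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(
                    f"{self.gene_id}: CDS segment {s}-{e} outside any exon")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


_DOMAIN_ALIASES = {
    "LECTIN_LEGB": "Lectin_legB", "PF00139": "Lectin_legB",
    "B_LECTIN": "B_lectin", "PF01453": "B_lectin",
    "LECTIN_C": "Lectin_C", "PF00059": "Lectin_C",
    "KINASE": "kinase", "PKINASE": "kinase", "PF00069": "kinase",
    "PKINASE_TYR": "kinase", "PF07714": "kinase", "STYKC": "kinase",
    "S_TKC": "kinase",
    "TM": "TM", "TRANSMEMBRANE": "TM", "TMHMM": "TM",
    "SIGNAL_PEPTIDE": "signal_peptide", "SIGNALP": "signal_peptide",
    "SIGNAL": "signal_peptide",
    "EGF": "EGF", "PF00008": "EGF",
    "PAN": "PAN", "PAN_2": "PAN", "PF08276": "PAN", "PAN_AP": "PAN",
    "S_LOCUS": "S_locus", "S_LOCUS_GLYCOP": "S_locus", "PF00954": "S_locus",
}

LECTIN_DOMAINS = ("Lectin_legB", "B_lectin", "Lectin_C")


def normalize_domain(name: str) -> str:
    """Map a Pfam accession or model name onto the controlled vocabulary."""
    key = name.split(".")[0].upper()
    if key in _DOMAIN_ALIASES:
        return _DOMAIN_ALIASES[key]
    return f"other:{name}"


@dataclass
class DomainHit:
    """One domain/TM/signal annotation on a protein; the evidence unit
    for family identification."""

    protein_id: str
    domain: str
    evalue: float
    start: int
    end: int
    source: str = ""

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError(f"{self.protein_id}: negative e-value")
        if self.start > self.end:
            raise ValueError(
                f"{self.protein_id}: domain hit start {self.start} > end "
                f"{self.end}")


class ExpressionMatrix:
    """Gene x tissue FPKM grid, a thin wrapper over a pandas DataFrame."""

    def __init__(self, frame: pd.DataFrame):
        if frame.isna().any().any():
            raise ValueError("expression matrix has missing cells")
        if (frame.values < 0).any():
            raise ValueError("expression matrix has negative FPKM")
        self.frame = frame.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.frame.columns)


def read_fasta(path: str | os.PathLike, alphabet: str = "dna") -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords, preserving order.

    Raises on duplicate ids and on characters outside the declared alphabet.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq), alphabet))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def _feature_span(feats) -> list[tuple[int, int]]:
    return sorted((f.start, f.end) for f in feats)


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GFF3.

    When a gene carries several mRNAs the transcript with the longest total
    CDS is kept (the annotation source never names a canonical model; this
    convention is recorded in output metadata by the pipeline).
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    known_ids = {f.id for f in db.all_features()}
    for feat in db.all_features():
        for parent in feat.attributes.get("Parent", []):
            if parent not in known_ids:
                raise ValueError(
                    f"feature {feat.id!r} references unknown Parent "
                    f"{parent!r}")

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            mrnas = [gene]  # bare gene: take exon/CDS children directly
        best, best_cds = None, -1
        for mrna in mrnas:
            cds = _feature_span(db.children(mrna, featuretype="CDS"))
            total = sum(e - s + 1 for s, e in cds)
            if total > best_cds:
                best, best_cds = mrna, total
        exons = _feature_span(db.children(best, featuretype="exon"))
        cds = _feature_span(db.children(best, featuretype="CDS"))
        if not exons:
            exons = cds or [(gene.start, gene.end)]
        models.append(GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            start=gene.start, end=gene.end, exons=exons, cds_segments=cds))
    return models


def read_domain_table(path: str | os.PathLike,
                      dialect: str = "tsv") -> list[DomainHit]:
    """Read domain hits from an hmmscan ``--domtblout`` file or a generic
    TSV (columns: protein_id, domain, evalue, start, end[, source]).

    domtblout fields follow HMMER3's fixed column layout; the per-domain
    independent E-value (column 13) is used, and alignment coordinates are
    taken from the ``ali`` columns.
    """
    if dialect not in ("domtblout", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hits: list[DomainHit] = []
    if dialect == "domtblout":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 22:
                    raise ValueError(
                        f"{path}:{lineno}: unparseable domtblout row")
                try:
                    name = parts[0]
                    acc = parts[1]
                    protein = parts[3]
                    ievalue = float(parts[12])
                    start, end = int(parts[17]), int(parts[18])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: unparseable domtblout row "
                        f"({exc})") from None
                domain = normalize_domain(acc if acc != "-" else name)
                if domain.startswith("other:"):
                    domain = normalize_domain(name)
                hits.append(DomainHit(protein, domain, ievalue, start, end,
                                      source="domtblout"))
        return hits

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {col: i for i, col in enumerate(header)}
        required = ("protein_id", "domain", "evalue", "start", "end")
        for col in required:
            if col not in idx:
                raise ValueError(f"{path}: missing column {col!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                hits.append(DomainHit(
                    protein_id=parts[idx["protein_id"]],
                    domain=normalize_domain(parts[idx["domain"]]),
                    evalue=float(parts[idx["evalue"]]),
                    start=int(parts[idx["start"]]),
                    end=int(parts[idx["end"]]),
                    source=parts[idx["source"]] if "source" in idx and
                    len(parts) > idx["source"] else "tsv"))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable row "
                                 f"({exc})") from None
    return hits


def read_expression_matrix(path: str | os.PathLike) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(frame)


def write_expression_matrix(mat: ExpressionMatrix,
                            path: str | os.PathLike) -> None:
    mat.frame.to_csv(path, sep="\t", float_format="%.4f")


QPCR_COLUMNS = ["gene_id", "condition", "replicate", "ct_target",
                "ct_reference"]


def read_qpcr_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a qPCR Ct table (CSV: gene_id, condition, replicate,
    ct_target, ct_reference)."""
    df = pd.read_csv(path)
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing qPCR columns {missing}")
    bad = df[(df.ct_target <= 0) | (df.ct_target >= 45) |
             (df.ct_reference <= 0) | (df.ct_reference >= 45)]
    if len(bad):
        raise ValueError(f"{path}: Ct values outside (0, 45)")
    return df
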