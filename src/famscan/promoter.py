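"""Promoter extraction (1500 bp upstream of the translation start) and
IUPAC cis-element scanning against a user-supplied catalog.

The scanner replaces web-service catalogs with a local TSV of named IUPAC
patterns so runs are reproducible offline. Ubiquitous elements present in
essentially every plant promoter (CAAT-box, TATA-box, TATC-box) are
dropped by default.
"""
from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from .io import GeneModel, SeqRecord, reverse_complement

__all__ = [
    "MotifPattern", "MotifHit", "DEFAULT_EXCLUDE",
    "read_motif_catalog", "write_motif_catalog",
    "extract_upstream", "scan_motifs", "categorize_elements",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

CATEGORIES = ("light", "hormone", "stress", "development", "other")

#: elements ubiquitous in plant promoters, dropped from scan output
DEFAULT_EXCLUDE = frozenset({"CAAT-box", "TATA-box", "TATC-box"})


@dataclass
class MotifPattern:
    name: str
    iupac: str
    category: str

    def __post_init__(self):
        if not self.iupac:
            raise ValueError(f"motif {self.name!r}: empty pattern")
        self.iupac = self.iupac.upper()
        bad = [c for c in self.iupac if c not in IUPAC]
        if bad:
            raise ValueError(
                f"motif {self.name!r}: non-IUPAC characters {bad}")
        if self.category not in CATEGORIES:
            raise ValueError(f"motif {self.name!r}: unknown category "
                             f"{self.category!r}")

    def regex(self) -> re.Pattern:
        return re.compile("(?=(" + "".join(IUPAC[c] for c in self.iupac)
                          + "))")


@dataclass
class MotifHit:
    gene_id: str
    motif: str
    position: int  # 1-based offset within the promoter
    strand: str    # {"+", "-"}


def read_motif_catalog(path: str | os.PathLike) -> list[MotifPattern]:
    """Catalog TSV with header: name, iupac, category."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for col in ("name", "iupac", "category"):
            if col not in idx:
                raise ValueError(f"{path}: missing catalog column {col!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            out.append(MotifPattern(parts[idx["name"]], parts[idx["iupac"]],
                                    parts[idx["category"]]))
    return out


def write_motif_catalog(catalog: Iterable[MotifPattern],
                        path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("name\tiupac\tcategory\n")
        for m in catalog:
            fh.write(f"{m.name}\t{m.iupac}\t{m.category}\n")


def extract_upstream(model: GeneModel, genome: Mapping[str, SeqRecord] |
                     Iterable[SeqRecord], length: int = 1500) -> SeqRecord:
    """The ``length`` bp 5' of the translation start (first CDS base),
    strand-aware: minus-strand promoters are reverse-complemented so the
    returned sequence reads 5'->3' toward the gene. Truncated with a
    warning at chromosome ends.
    """
    if not isinstance(genome, Mapping):
        genome = {rec.id: rec for rec in genome}
    if model.chrom not in genome:
        raise KeyError(f"chromosome {model.chrom!r} missing from genome")
    chrom_seq = genome[model.chrom].sequence
    if not model.cds_segments:
        raise ValueError(f"{model.gene_id}: no CDS to anchor the promoter")
    if model.strand == "+":
        tss = model.cds_segments[0][0]
        start = max(1, tss - length)
        end = tss - 1
        seq = chrom_seq[start - 1:end]
    else:
        tss = model.cds_segments[-1][1]
        start = tss + 1
        end = min(len(chrom_seq), tss + length)
        seq = reverse_complement(chrom_seq[start - 1:end])
    if len(seq) < length:
        warnings.warn(
            f"{model.gene_id}: promoter truncated to {len(seq)} bp at the "
            f"chromosome end", stacklevel=2)
    if not seq:
        raise ValueError(f"{model.gene_id}: translation start at the very "
                         "chromosome edge, no upstream sequence")
    return SeqRecord(f"{model.gene_id}_promoter", seq, "dna")


def scan_motifs(promoter: SeqRecord, catalog: Iterable[MotifPattern],
                exclude: frozenset[str] | set[str] = DEFAULT_EXCLUDE
                ) -> list[MotifHit]:
    """Exact IUPAC matching of every catalog pattern on both strands at
    every offset (overlapping occurrences included); hits for excluded
    names are dropped. Positions are 1-based on the given promoter
    string; minus-strand hits are reported at the leftmost base of the
    match on that string.
    """
    gene_id = promoter.id.removesuffix("_promoter")
    seq = promoter.sequence.upper()
    hits: list[MotifHit] = []
    for motif in catalog:
        if motif.name in exclude:
            continue
        for m in motif.regex().finditer(seq):
            hits.append(MotifHit(gene_id, motif.name, m.start() + 1, "+"))
        rc_pattern = MotifPattern(motif.name,
                                  reverse_complement(motif.iupac),
                                  motif.category)
        for m in rc_pattern.regex().finditer(seq):
            hits.append(MotifHit(gene_id, motif.name, m.start() + 1, "-"))
    hits.sort(key=lambda h: (h.gene_id, h.position, h.motif, h.strand))
    return hits


def categorize_elements(hits: Iterable[MotifHit],
                        catalog: Iterable[MotifPattern]):
    """Per-gene and family-wide element counts per category.

    Returns (per_gene_types, per_gene_instances, family_types): the first
    two map gene_id -> category -> count of distinct element names /
    total hit instances; the third counts distinct element names per
    category over the whole family.
    """
    cat_of = {m.name: m.category for m in catalog}
    per_gene_names: dict[str, dict[str, set]] = {}
    per_gene_instances: dict[str, dict[str, int]] = {}
    family_names: dict[str, set] = {c: set() for c in CATEGORIES}
    for h in hits:
        if h.motif not in cat_of:
            raise KeyError(f"hit references unknown motif {h.motif!r}")
        cat = cat_of[h.motif]
        g = per_gene_names.setdefault(
            h.gene_id, {c: set() for c in CATEGORIES})
        g[cat].add(h.motif)
        inst = per_gene_instances.setdefault(
            h.gene_id, {c: 0 for c in CATEGORIES})
        inst[cat] += 1
        family_names[cat].add(h.motif)
    per_gene_types = {
        gid: {c: len(s) for c, s in cats.items()}
        for gid, cats in per_gene_names.items()}
    family_types = {c: len(s) for c, s in family_names.items()}
    return per_gene_types, per_gene_instances, family_types
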