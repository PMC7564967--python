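"""Physicochemical and gene-structure statistics for family members:
molecular weight, isoelectric point, CDS length, exon/intron counts.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.SeqUtils import molecular_weight as _bio_mw

from .io import GeneModel, SeqRecord

__all__ = [
    "ProteinProps", "GeneStructureStats", "molecular_weight",
    "isoelectric_point", "gene_structure", "family_structure_report",
    "BJELLQVIST_PKA",
]

#: Bjellqvist pKa set (ExPASy convention): ionizable side chains and termini.
BJELLQVIST_PKA = {
    "positive": {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98},
    "negative": {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
}

_X_PLACEHOLDER_DA = 110.0  # average residue mass stand-in for 'X'


def molecular_weight(seq: SeqRecord | str, allow_x: bool = False) -> float:
    """Average (not monoisotopic) protein mass in kilodaltons.

    Sum of average residue masses plus one water. Unknown residues raise;
    with ``allow_x`` an 'X' contributes a documented 110.0 Da placeholder.
    """
    s = seq.sequence if isinstance(seq, SeqRecord) else str(seq).upper()
    if not s:
        raise ValueError("empty protein sequence")
    if "-" in s:
        raise ValueError("gapped sequence passed to molecular_weight")
    n_x = s.count("X")
    if n_x and not allow_x:
        raise ValueError("unknown residue 'X' (enable allow_x to use a "
                         "110.0 Da placeholder)")
    core = s.replace("X", "")
    if not core:
        return (n_x * _X_PLACEHOLDER_DA + 18.0153) / 1000.0
    try:
        da = _bio_mw(core, seq_type="protein")
    except ValueError as exc:
        raise ValueError(f"unknown residue in protein sequence: {exc}")
    return (da + n_x * _X_PLACEHOLDER_DA) / 1000.0


def net_charge(seq: str, ph: float,
               pka: Mapping[str, Mapping[str, float]] = BJELLQVIST_PKA
               ) -> float:
    """Net charge of a peptide at a given pH (Henderson-Hasselbalch)."""
    pos = pka["positive"]
    neg = pka["negative"]
    charge = 1.0 / (1.0 + 10 ** (ph - pos["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (neg["Cterm"] - ph))
    for aa, pk in pos.items():
        if aa == "Nterm":
            continue
        charge += seq.count(aa) / (1.0 + 10 ** (ph - pk))
    for aa, pk in neg.items():
        if aa == "Cterm":
            continue
        charge -= seq.count(aa) / (1.0 + 10 ** (pk - ph))
    return charge


def isoelectric_point(seq: SeqRecord | str,
                      pka: Mapping[str, Mapping[str, float]] = BJELLQVIST_PKA,
                      tol: float = 1e-4) -> float:
    """pH at which the peptide's net charge is zero, by bisection on [0, 14]
    to |charge| < ``tol``. The termini are always ionizable, so the charge
    is positive at pH 0 and negative at pH 14 and a root always exists.
    """
    s = (seq.sequence if isinstance(seq, SeqRecord) else str(seq).upper())
    s = s.replace("-", "")
    if not s:
        raise ValueError("empty protein sequence")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(s, mid, pka)
        if abs(q) < tol and hi - lo < 1e-6:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@dataclass
class ProteinProps:
    protein_id: str
    length_aa: int
    mw_kda: float
    pi: float


def protein_props(seq: SeqRecord) -> ProteinProps:
    return ProteinProps(seq.id, len(seq.sequence.replace("-", "")),
                        molecular_weight(seq), isoelectric_point(seq))


@dataclass
class GeneStructureStats:
    gene_id: str
    n_exons: int
    n_introns: int
    cds_len_bp: int
    gene_len_bp: int


def gene_structure(model: GeneModel) -> GeneStructureStats:
    n_exons = len(model.exons)
    return GeneStructureStats(
        gene_id=model.gene_id,
        n_exons=n_exons,
        n_introns=max(n_exons - 1, 0),
        cds_len_bp=model.cds_length,
        gene_len_bp=model.length)


@dataclass
class FamilyStructureReport:
    n_genes: int
    cds_len_min: int
    cds_len_max: int
    mean_introns: float
    max_exons: int
    mw_min_kda: float | None = None
    mw_max_kda: float | None = None
    mw_min_id: str | None = None
    mw_max_id: str | None = None


def family_structure_report(stats: Iterable[GeneStructureStats],
                            props: Iterable[ProteinProps] | None = None
                            ) -> FamilyStructureReport:
    """Family-wide summary: CDS length extremes, mean intron count
    (2 decimals) and, when protein properties are supplied, the molecular
    weight extremes with their carrier ids."""
    stats = list(stats)
    if not stats:
        raise ValueError("no gene structures to summarize")
    report = FamilyStructureReport(
        n_genes=len(stats),
        cds_len_min=min(s.cds_len_bp for s in stats),
        cds_len_max=max(s.cds_len_bp for s in stats),
        mean_introns=round(sum(s.n_introns for s in stats) / len(stats), 2),
        max_exons=max(s.n_exons for s in stats))
    if props:
        props = list(props)
        lo = min(props, key=lambda p: p.mw_kda)
        hi = max(props, key=lambda p: p.mw_kda)
        report.mw_min_kda, report.mw_min_id = round(lo.mw_kda, 1), lo.protein_id
        report.mw_max_kda, report.mw_max_id = round(hi.mw_kda, 1), hi.protein_id
    return report
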