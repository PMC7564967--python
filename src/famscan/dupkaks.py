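"""Duplication-event detection, Nei-Gojobori (NG86) Ka/Ks, and
divergence dating.

Duplicate pairs are called from global protein alignments (coverage and
identity both strictly > 70%); pairs on one chromosome closer than 100 kb
with at most five intervening annotated genes are tandem, all others
dispersed. Ka and Ks come from the classic NG86 procedure: per-codon
synonymous-site fractions averaged between the two sequences, differences
averaged over all minimal mutational pathways (pathways through stop
codons excluded), and a Jukes-Cantor correction of the proportions.
Divergence time is T = Ks / 2r with r the synonymous substitution rate
per site per year (default 1.5e-8, the dicot clock).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import PairAlignment, align_pair
from .io import GeneModel, SeqRecord

__all__ = [
    "NgCounts", "DupEvent", "SaturationError",
    "find_duplicates", "classify_duplication", "ng_counts",
    "jukes_cantor", "kaks_pair", "divergence_time",
    "GENETIC_CODE", "STOP_CODONS",
]

_BASES = "TCAG"
_AMINO = ("FFLLSSSSYY**CC*W"
          "LLLLPPPPHHQQRRRR"
          "IIIMTTTTNNKKSSRR"
          "VVVVAAAADDEEGGGG")
#: standard nuclear genetic code (translation table 1)
GENETIC_CODE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOP_CODONS = {c for c, aa in GENETIC_CODE.items() if aa == "*"}


class SaturationError(ValueError):
    """Jukes-Cantor correction undefined: proportion at or past 3/4."""


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) for 0 <= p < 0.75."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} at or beyond JC saturation")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def synonymous_fraction(codon: str) -> float:
    """NG86 synonymous site count of one sense codon: at each of the three
    positions, the fraction of the three possible changes that preserve
    the amino acid (changes to stop codons count as nonsynonymous, so
    every codon contributes exactly 3 sites split between S and N)."""
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if GENETIC_CODE[mutant] == aa:
                s += 1.0 / 3.0
    return s


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over all minimal
    mutational pathways between two codons; pathways passing through a
    stop codon are excluded (unless every pathway does)."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    viable: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(diff):
        cur = codon_a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*" and nxt != codon_b:
                through_stop = True
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (blocked if through_stop else viable).append((sd, nd))
    pool = viable or blocked
    sd = sum(x for x, _ in pool) / len(pool)
    nd = sum(y for _, y in pool) / len(pool)
    return sd, nd


@dataclass
class NgCounts:
    S: float
    N: float
    Sd: float
    Nd: float
    n_codons: int

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S else 0.0

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N else 0.0


_AMBIG = set("NRYSWKMBDHV")


def _codon_ok(codon: str) -> bool:
    return ("-" not in codon and not (set(codon) & _AMBIG)
            and codon not in STOP_CODONS)


def ng_counts(cds_a: str, cds_b: str) -> NgCounts:
    """NG86 site and difference counts over a codon-aligned CDS pair.

    Codons containing gaps or ambiguity codes in either sequence are
    skipped, as are aligned stop codons; sites are averaged between the
    two sequences; differences are averaged over minimal pathways.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDS rows differ in length")
    if len(cds_a) % 3:
        raise ValueError("aligned CDS length not divisible by 3")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for k in range(0, len(cds_a), 3):
        ca, cb = cds_a[k:k + 3], cds_b[k:k + 3]
        if not (_codon_ok(ca) and _codon_ok(cb)):
            continue
        n_codons += 1
        s = 0.5 * (synonymous_fraction(ca) + synonymous_fraction(cb))
        S += s
        N += 3.0 - s
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no comparable codons (all gapped/ambiguous)")
    return NgCounts(S=S, N=N, Sd=Sd, Nd=Nd, n_codons=n_codons)


def _trim_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:].upper() in STOP_CODONS:
        return cds[:-3]
    return cds


def project_codon_alignment(cds_a: str, cds_b: str,
                            aln: PairAlignment) -> tuple[str, str]:
    """Thread two CDS onto their protein alignment: each residue column
    becomes its codon, each protein gap a '---'."""
    cds_a, cds_b = _trim_stop(cds_a.upper()), _trim_stop(cds_b.upper())
    for name, cds, row in ((aln.id_a, cds_a, aln.row_a),
                           (aln.id_b, cds_b, aln.row_b)):
        n_res = len(row.replace("-", ""))
        if len(cds) != 3 * n_res:
            raise ValueError(
                f"{name}: CDS length {len(cds)} != 3 x {n_res} aligned "
                "residues (after terminal stop trimming)")
        for k in range(0, len(cds), 3):
            if cds[k:k + 3] in STOP_CODONS:
                raise ValueError(f"{name}: internal stop codon at "
                                 f"position {k + 1}")
    out = []
    for cds, row in ((cds_a, aln.row_a), (cds_b, aln.row_b)):
        i, parts = 0, []
        for ch in row:
            if ch == "-":
                parts.append("---")
            else:
                parts.append(cds[3 * i:3 * i + 3])
                i += 1
        out.append("".join(parts))
    return out[0], out[1]


def kaks_pair(cds_a: SeqRecord | str, cds_b: SeqRecord | str,
              prot_aln: PairAlignment
              ) -> tuple[float, float, float | None]:
    """(Ka, Ks, omega) for one pair: codon alignment projected from the
    protein alignment, NG86 counting, Jukes-Cantor correction. omega is
    None when Ks = 0 (undefined ratio)."""
    sa = cds_a.sequence if isinstance(cds_a, SeqRecord) else cds_a
    sb = cds_b.sequence if isinstance(cds_b, SeqRecord) else cds_b
    row_a, row_b = project_codon_alignment(sa, sb, prot_aln)
    counts = ng_counts(row_a, row_b)
    ka = jukes_cantor(counts.pN)
    ks = jukes_cantor(counts.pS)
    omega = ka / ks if ks > 0 else None
    return ka, ks, omega


def divergence_time(ks: float, r: float = 1.5e-8) -> float:
    """Divergence time T = Ks / 2r, in million years."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    if r <= 0:
        raise ValueError("rate r must be positive")
    return ks / (2.0 * r) / 1e6


def find_duplicates(proteins: Sequence[SeqRecord], cov_min: float = 0.70,
                    id_min: float = 0.70) -> list[PairAlignment]:
    """All unordered pairs whose global protein alignment has coverage
    and identity both strictly above the thresholds."""
    out = []
    for a, b in itertools.combinations(proteins, 2):
        aln = align_pair(a, b)
        if aln.coverage > cov_min and aln.identity > id_min:
            out.append(aln)
    return out


@dataclass
class DupEvent:
    id_a: str
    id_b: str
    dup_class: str  # {"tandem", "dispersed"}
    gap_bp: int | None
    n_intervening: int | None
    identity: float
    coverage: float
    ka: float | None = None
    ks: float | None = None
    omega: float | None = None
    t_mya: float | None = None


def classify_duplication(pair: PairAlignment,
                         all_genes: Iterable[GeneModel],
                         protein_to_gene=None,
                         max_gap_bp: int = 100_000,
                         max_intervening: int = 5) -> DupEvent:
    """Tandem/dispersed call for one duplicate pair.

    Tandem means same chromosome, nearest gene boundaries < ``max_gap_bp``
    apart, and at most ``max_intervening`` annotated genes strictly between
    the two (counted strand-agnostically over the whole annotation).
    """
    lookup = {g.gene_id: g for g in all_genes}
    to_gene = protein_to_gene or (lambda pid: pid)
    ga_id, gb_id = to_gene(pair.id_a), to_gene(pair.id_b)
    for gid in (ga_id, gb_id):
        if gid not in lookup:
            raise KeyError(f"gene {gid!r} missing from the annotation")
    ga, gb = lookup[ga_id], lookup[gb_id]
    if ga.chrom != gb.chrom:
        return DupEvent(pair.id_a, pair.id_b, "dispersed", None, None,
                        pair.identity, pair.coverage)
    left, right = (ga, gb) if ga.start <= gb.start else (gb, ga)
    gap_bp = max(0, right.start - left.end - 1)
    intervening = sum(
        1 for g in lookup.values()
        if g.chrom == ga.chrom and g.gene_id not in (ga_id, gb_id)
        and g.start > left.end and g.end < right.start)
    tandem = gap_bp < max_gap_bp and intervening <= max_intervening
    return DupEvent(pair.id_a, pair.id_b, "tandem" if tandem else "dispersed",
                    gap_bp, intervening, pair.identity, pair.coverage)
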