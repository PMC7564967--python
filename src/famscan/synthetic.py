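"""Synthetic data with known truth for every pipeline stage.

The generator emulates the data a gene-family survey consumes: a toy
multi-chromosome genome with planted family members (lectin + TM + kinase
architectures), decoy genes with incomplete architectures, duplicate
pairs evolved to target Ka/Ks, tandem clusters with controlled gene
spacing, promoter cis-elements written into upstream sequence, a
three-level tissue FPKM matrix, and qPCR Ct tables with planted
fold-changes. Defaults mirror the published cucumber LecRLK family
survey: 46 members (23 G / 22 L / 1 C) over 7 chromosomes, CDS lengths
spanning 1803-2502 bp, a mean of 1.5 introns per gene (max 9 exons),
three duplicate pairs at the synonymous distances implied by divergence
times of 38.61 / 30.96 / 32.35 MYA at r = 1.5e-8, a 54-element promoter
catalog (24 light / 11 hormone / 9 stress / 6 development / 4 other),
expression groups of 7/12/27 genes with mean FPKM 18.01/6.48/1.29, and
20 up- / 38 down-regulation events across five treatments including an
88-fold ABA induction.

Every generator is a pure function of (config, seed).
"""
from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dupkaks import (GENETIC_CODE, STOP_CODONS, ng_counts,
                      synonymous_fraction)
from .io import reverse_complement
from .promoter import MotifPattern, write_motif_catalog

__all__ = [
    "SynthConfig", "DuplicateSpec", "generate_duplicate_pair",
    "generate_annotation", "generate_expression", "generate_qpcr",
    "generate_bundle", "translate_cds", "default_motif_catalog",
]

_SENSE_CODONS = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)
_CODONS_OF = {}
for _codon in _SENSE_CODONS:
    _CODONS_OF.setdefault(GENETIC_CODE[_codon], []).append(_codon)
_AMINO_ACIDS = sorted(_CODONS_OF)
_BASES = "ACGT"


def translate_cds(cds: str) -> str:
    """Translate a CDS (a terminal stop is allowed and dropped)."""
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    aas = []
    for k in range(0, len(cds), 3):
        aa = GENETIC_CODE[cds[k:k + 3]]
        if aa == "*":
            if k != len(cds) - 3:
                raise ValueError(f"internal stop codon at {k + 1}")
            break
        aas.append(aa)
    return "".join(aas)


@dataclass
class DuplicateSpec:
    """One planted duplicate pair: target synonymous/nonsynonymous
    distances and, for tandem pairs, the number of intervening genes."""
    ks: float
    ka: float
    tandem: bool
    n_intervening: int = 0


def _inv_jc(d: float) -> float:
    """Proportion p corresponding to a Jukes-Cantor distance d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


@dataclass
class SynthConfig:
    n_chromosomes: int = 7
    members_per_chromosome: tuple = (7, 2, 12, 6, 6, 6, 7)
    subfamily_sizes: tuple = (("G", 23), ("L", 22), ("C", 1))
    decoys_per_chromosome: int = 5
    fillers_per_chromosome: int = 12
    cds_length_range: tuple = (1803, 2502)
    intron_length_range: tuple = (100, 400)
    intergenic_range: tuple = (1700, 6000)
    duplicate_pairs: tuple = (
        DuplicateSpec(ks=1.1583, ka=0.0927, tandem=True, n_intervening=2),
        DuplicateSpec(ks=0.9288, ka=0.0743, tandem=False),
        DuplicateSpec(ks=0.9705, ka=0.0776, tandem=False),
    )
    promoter_length: int = 1500
    tissues: tuple = ("root", "hypocotyl", "cotyledon", "true_leaf", "stem",
                      "tendril", "female_flower", "male_flower", "ovary",
                      "peel")
    venn_tissues: tuple = ("root", "hypocotyl", "cotyledon", "true_leaf",
                           "tendril")
    group_means: tuple = (18.01, 6.48, 1.29)
    group_sizes: tuple = (7, 12, 27)
    fpkm_sigma: float = 0.25
    conditions: tuple = ("GA", "ABA", "NAA", "IAA", "cold")
    n_replicates: int = 3
    ct_noise_sd: float = 0.1

    def __post_init__(self):
        if sum(self.members_per_chromosome) != \
                sum(n for _, n in self.subfamily_sizes):
            raise ValueError("members_per_chromosome must sum to the "
                             "subfamily total")
        if len(self.members_per_chromosome) != self.n_chromosomes:
            raise ValueError("one member count per chromosome required")
        for spec in self.duplicate_pairs:
            # JC saturates at p >= 3/4; the planted *proportion* must stay
            # below saturation, the distance itself may exceed 0.75
            if _inv_jc(spec.ks) >= 0.75 or _inv_jc(spec.ka) >= 0.75:
                raise ValueError("duplicate target beyond JC saturation")


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random sense CDS: ATG + random codons + one stop.

    Amino acids are drawn uniformly and then a synonymous codon is
    picked, so the encoded protein has a balanced residue composition
    (uniform codon draws would be strongly arginine-biased).
    """
    if n_codons < 3:
        raise ValueError("CDS needs at least 3 codons")
    aas = rng.choice(_AMINO_ACIDS, size=n_codons - 2)
    body = [_CODONS_OF[aa][rng.integers(len(_CODONS_OF[aa]))]
            for aa in aas]
    return "ATG" + "".join(body) + "TGA"


def _syn_options(codon: str) -> list[str]:
    aa = GENETIC_CODE[codon]
    return [codon[:p] + b + codon[p + 1:]
            for p in range(3) for b in _BASES
            if b != codon[p] and
            GENETIC_CODE[codon[:p] + b + codon[p + 1:]] == aa]


def _nonsyn_options(codon: str) -> list[str]:
    aa = GENETIC_CODE[codon]
    return [codon[:p] + b + codon[p + 1:]
            for p in range(3) for b in _BASES
            if b != codon[p] and
            GENETIC_CODE[codon[:p] + b + codon[p + 1:]] not in ("*", aa)]


def generate_duplicate_pair(ks_target: float, ka_target: float,
                            n_codons: int, seed: int,
                            ancestral: str | None = None
                            ) -> tuple[str, str, dict]:
    """Evolve a duplicate CDS pair toward target Ks and Ka.

    An ancestral CDS of sense codons receives synonymous single-base
    substitutions on the expected proportion pS = inv-JC(Ks) of its
    synonymous sites, and nonsynonymous substitutions likewise, at most
    one substitution per codon so difference counting stays analytic; no
    internal stops are introduced. Deterministic given the seed.
    """
    if n_codons < 30:
        raise ValueError("need at least 30 codons")
    if _inv_jc(ks_target) >= 0.75 or _inv_jc(ka_target) >= 0.75:
        raise ValueError("target beyond JC saturation")
    rng = np.random.default_rng(seed)
    cds_a = ancestral if ancestral is not None else _random_cds(n_codons, rng)
    core = cds_a[:-3] if cds_a[-3:] in STOP_CODONS else cds_a
    codons = [core[k:k + 3] for k in range(0, len(core), 3)]
    s_sites = sum(synonymous_fraction(c) for c in codons)
    n_sites = 3 * len(codons) - s_sites
    p_s, p_n = _inv_jc(ks_target), _inv_jc(ka_target)
    order = list(rng.permutation(len(codons)))
    derived = list(codons)
    syn_done: list[int] = []
    nonsyn_done: list[int] = []

    def mutate(kind: str, want: int) -> None:
        done = syn_done if kind == "syn" else nonsyn_done
        options = _syn_options if kind == "syn" else _nonsyn_options
        while len(done) > want:      # revert surplus changes
            idx = done.pop()
            derived[idx] = codons[idx]
        for idx in order:
            if len(done) >= want:
                return
            if derived[idx] != codons[idx]:
                continue
            opts = options(codons[idx])
            if opts:
                derived[idx] = opts[rng.integers(len(opts))]
                done.append(idx)
        if len(done) < want:
            raise ValueError(
                f"infeasible targets: placed {len(syn_done)} synonymous "
                f"and {len(nonsyn_done)} nonsynonymous changes in "
                f"{len(codons)} codons")

    # first pass on ancestral site counts, then correct against the NG
    # counts of the evolved pair: substitutions shift the synonymous
    # site total, so the difference counts must track the averaged sites
    mutate("syn", int(round(p_s * s_sites)))
    mutate("nonsyn", int(round(p_n * n_sites)))
    for _ in range(8):
        c = ng_counts("".join(codons), "".join(derived))
        sd_want = int(round(p_s * c.S))
        nd_want = int(round(p_n * c.N))
        if sd_want == len(syn_done) and nd_want == len(nonsyn_done):
            break
        mutate("syn", sd_want)
        mutate("nonsyn", nd_want)
    stop = cds_a[-3:] if cds_a[-3:] in STOP_CODONS else ""
    cds_b = "".join(derived) + stop
    truth = {"ks_target": ks_target, "ka_target": ka_target,
             "sd_planted": len(syn_done), "nd_planted": len(nonsyn_done),
             "s_sites_ancestral": s_sites, "n_sites_ancestral": n_sites}
    return cds_a, cds_b, truth


# ---------------------------------------------------------------------------
# genome / annotation
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class _GenePlan:
    gene_id: str
    kind: str                    # member | decoy | filler
    chrom: int
    strand: str = "+"
    subfamily: str | None = None
    n_exons: int = 1
    cds: str = ""
    decoy_type: str | None = None
    has_signal: bool = False
    n_tm: int = 1
    has_egf: bool = False
    has_pan: bool = False
    has_s_locus: bool = False
    lectin_evalue: float = 1e-10
    reserved: bool = False       # keeps planted CDS-length extremes intact
    # filled during layout
    start: int = 0
    end: int = 0
    exons: list = field(default_factory=list)


_DECOY_TYPES = ("no_tm", "no_kinase", "no_lectin", "weak_lectin",
                "boundary_lectin", "unrelated")


def _member_plans(config: SynthConfig, rng: np.random.Generator
                  ) -> list[_GenePlan]:
    sizes = dict(config.subfamily_sizes)
    # subfamily layout: the single C first, then alternating L/G blocks so
    # both major types appear on most chromosomes
    labels = ["C"] * sizes.get("C", 0)
    l_left, g_left = sizes.get("L", 0), sizes.get("G", 0)
    while l_left or g_left:
        take = min(3, l_left)
        labels += ["L"] * take
        l_left -= take
        take = min(3, g_left)
        labels += ["G"] * take
        g_left -= take
    chroms = []
    for c, n in enumerate(config.members_per_chromosome, start=1):
        chroms += [c] * n
    lo, hi = config.cds_length_range
    plans = [
        _GenePlan(gene_id="", kind="member", chrom=chrom, subfamily=sub,
                  strand="+" if rng.random() < 0.5 else "-",
                  cds=_random_cds(int(rng.integers(lo // 3, hi // 3 + 1)),
                                  rng))
        for sub, chrom in zip(labels, chroms)]
    c_idxs = [i for i, p in enumerate(plans) if p.subfamily == "C"]
    g_idxs = [i for i, p in enumerate(plans) if p.subfamily == "G"]
    l_idxs = [i for i, p in enumerate(plans) if p.subfamily == "L"]
    # plant the CDS-length extremes: the C member (or first L) carries the
    # minimum, the last G the maximum; both stay out of duplicate pairs
    min_i = c_idxs[0] if c_idxs else l_idxs[0]
    max_i = g_idxs[-1] if g_idxs else l_idxs[-1]
    plans[min_i].cds = _random_cds(lo // 3, rng)
    plans[min_i].reserved = True
    plans[max_i].cds = _random_cds(hi // 3, rng)
    plans[max_i].reserved = True
    # exon counts: one 9-exon G, a 4-exon C, L-types hold 1-2 exons, the
    # remainder set so the family mean intron count is 1.5
    if c_idxs:
        plans[c_idxs[0]].n_exons = 4
    if g_idxs:
        plans[g_idxs[0]].n_exons = 9
        rest_g = g_idxs[1:]
        for i in rest_g[:20]:
            plans[i].n_exons = 3
        for i in rest_g[20:]:
            plans[i].n_exons = 2
    for i in l_idxs[:16]:
        plans[i].n_exons = 2
    for i in l_idxs[16:]:
        plans[i].n_exons = 1
    # architecture: G-type accessory domains (EGF/PAN/S-locus)
    for j, i in enumerate(g_idxs):
        p = plans[i]
        if j < 10:
            p.has_egf = p.has_pan = True
        elif j < 15:
            p.has_pan = True
        elif j < 22:
            p.has_egf = True
        p.has_s_locus = j < 12
    # signal peptides on 21 members, 3 TMs on 8
    for i in g_idxs[:10] + l_idxs[:11]:
        plans[i].has_signal = True
    for i in g_idxs[:4] + l_idxs[:4]:
        plans[i].n_tm = 3
    for p in plans:
        p.lectin_evalue = 10.0 ** -float(rng.integers(6, 31))
    return plans


def _apply_duplicates(config: SynthConfig, plans: list[_GenePlan],
                      rng: np.random.Generator) -> list[dict]:
    """Overwrite chosen same-subfamily member pairs' CDS with evolved
    duplicates; returns pair records with plan indices."""
    used: set[int] = set()

    def free(chrom: int, sub: str) -> list[int]:
        return [i for i, p in enumerate(plans)
                if p.chrom == chrom and p.subfamily == sub
                and i not in used and not p.reserved]

    chroms = sorted({p.chrom for p in plans})
    pairs = []
    cross_k = 0
    for spec in config.duplicate_pairs:
        ia = ib = None
        if spec.tandem:
            for c in chroms:
                for sub in ("G", "L"):
                    cand = free(c, sub)
                    if len(cand) >= 2:
                        ia, ib = cand[0], cand[1]
                        break
                if ia is not None:
                    break
        else:
            combos = [(c1, c2) for c1 in chroms for c2 in chroms if c1 < c2]
            for off in range(len(combos)):
                c1, c2 = combos[(cross_k + off) % len(combos)]
                for sub in ("L", "G"):
                    a_cand, b_cand = free(c1, sub), free(c2, sub)
                    if a_cand and b_cand:
                        ia, ib = a_cand[-1], b_cand[-1]
                        break
                if ia is not None:
                    cross_k += off + 1
                    break
        if ia is None:
            raise ValueError("cannot place duplicate pair: too few free "
                             "members")
        used.update((ia, ib))
        n_codons = len(plans[ia].cds) // 3
        seed = int(rng.integers(0, 2**31 - 1))
        cds_a, cds_b, truth = generate_duplicate_pair(
            spec.ks, spec.ka, n_codons, seed, ancestral=plans[ia].cds)
        plans[ia].cds = cds_a
        plans[ib].cds = cds_b
        pairs.append({"spec": dataclasses.asdict(spec), "idx_a": ia,
                      "idx_b": ib, **truth})
    return pairs


def _decoy_filler_plans(config: SynthConfig, rng: np.random.Generator
                        ) -> list[_GenePlan]:
    plans = []
    for chrom in range(1, config.n_chromosomes + 1):
        for d in range(config.decoys_per_chromosome):
            plans.append(_GenePlan(
                gene_id="", kind="decoy", chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                cds=_random_cds(int(rng.integers(300, 500)), rng),
                decoy_type=_DECOY_TYPES[d % len(_DECOY_TYPES)]))
        for _ in range(config.fillers_per_chromosome):
            plans.append(_GenePlan(
                gene_id="", kind="filler", chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                cds=_random_cds(int(rng.integers(200, 400)), rng)))
    return plans


def generate_annotation(config: SynthConfig, seed: int):
    """Build the toy genome: chromosome sequences, gene models, domain
    hits and the truth table.

    Returns (chromosomes, gff_rows, domain_rows, plans, truth):
    chromosomes maps name -> mutable uint8 array of sequence (so promoter
    plants can still be written), gff_rows are GFF3 lines, plans carry
    the per-gene layout.
    """
    rng = np.random.default_rng(seed)
    members = _member_plans(config, rng)
    pair_dicts = _apply_duplicates(config, members, rng)
    others = _decoy_filler_plans(config, rng)

    per_chrom: dict[int, list[_GenePlan]] = {
        c: [] for c in range(1, config.n_chromosomes + 1)}
    tandem_pairs = [(members[d["idx_a"]], members[d["idx_b"]],
                     spec.n_intervening)
                    for d, spec in zip(pair_dicts, config.duplicate_pairs)
                    if spec.tandem]
    held = {id(a) for a, _, _ in tandem_pairs} | \
        {id(b) for _, b, _ in tandem_pairs}
    for p in members:
        if id(p) not in held:
            per_chrom[p.chrom].append(p)
    for p in others:
        per_chrom[p.chrom].append(p)
    for c in per_chrom:
        lst = per_chrom[c]
        per_chrom[c] = [lst[i] for i in rng.permutation(len(lst))]
    # insert tandem pairs with exactly n_intervening genes between them
    for pa, pb, n_iv in tandem_pairs:
        lst = per_chrom[pa.chrom]
        between = [g for g in lst if g.kind == "filler"][:n_iv]
        if len(between) < n_iv:
            raise ValueError("not enough filler genes for the requested "
                             "intervening count")
        between_ids = {id(g) for g in between}
        rest = [g for g in lst if id(g) not in between_ids]
        cut = len(rest) // 2
        per_chrom[pa.chrom] = rest[:cut] + [pa] + between + [pb] + rest[cut:]

    chromosomes: dict[str, np.ndarray] = {}
    gff_rows: list[str] = []
    all_plans: list[_GenePlan] = []
    ilo, ihi = config.intron_length_range
    glo, ghi = config.intergenic_range
    glo = max(glo, config.promoter_length + 200)
    ghi = max(ghi, glo + 1)
    for c in range(1, config.n_chromosomes + 1):
        name = f"chr{c}"
        cursor = int(rng.integers(glo, ghi))
        writes = []  # (0-based start, genomic exon content)
        for gi, plan in enumerate(per_chrom[c], start=1):
            plan.gene_id = f"g{c}_{gi:03d}"
            cds_len = len(plan.cds)
            n_ex = plan.n_exons
            if n_ex == 1:
                exon_lens = [cds_len]
            else:
                cuts = sorted(rng.choice(np.arange(1, cds_len // 60),
                                         size=n_ex - 1, replace=False))
                bounds = [0] + [60 * int(x) for x in cuts] + [cds_len]
                exon_lens = [bounds[i + 1] - bounds[i] for i in range(n_ex)]
            genomic = plan.cds if plan.strand == "+" \
                else reverse_complement(plan.cds)
            pos, off, exons = cursor, 0, []
            for k, ln in enumerate(exon_lens):
                exons.append((pos, pos + ln - 1))
                writes.append((pos - 1, genomic[off:off + ln]))
                off += ln
                pos += ln
                if k < n_ex - 1:
                    pos += int(rng.integers(ilo, ihi))
            plan.start, plan.end = exons[0][0], exons[-1][1]
            plan.exons = exons
            all_plans.append(plan)
            mrna = f"{plan.gene_id}.1"
            gff_rows.append(
                f"{name}\tfamscan_synth\tgene\t{plan.start}\t{plan.end}"
                f"\t.\t{plan.strand}\t.\tID={plan.gene_id}")
            gff_rows.append(
                f"{name}\tfamscan_synth\tmRNA\t{plan.start}\t{plan.end}"
                f"\t.\t{plan.strand}\t.\tID={mrna};Parent={plan.gene_id}")
            cds_done = 0
            for s, e in exons:
                phase = (3 - cds_done % 3) % 3
                gff_rows.append(
                    f"{name}\tfamscan_synth\texon\t{s}\t{e}\t.\t"
                    f"{plan.strand}\t.\tParent={mrna}")
                gff_rows.append(
                    f"{name}\tfamscan_synth\tCDS\t{s}\t{e}\t.\t"
                    f"{plan.strand}\t{phase}\tID=cds_{mrna};Parent={mrna}")
                cds_done += e - s + 1
            cursor = plan.end + 1 + int(rng.integers(glo, ghi))
        total_len = cursor + int(rng.integers(glo, ghi))
        seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                         size=total_len)
        for start0, sub in writes:
            seq[start0:start0 + len(sub)] = \
                np.frombuffer(sub.encode(), dtype=np.uint8)
        chromosomes[name] = seq

    domain_rows = _domain_rows(all_plans)
    truth = {
        "members": {
            p.gene_id: {
                "subfamily": p.subfamily, "n_exons": p.n_exons,
                "cds_len": len(p.cds), "has_signal": p.has_signal,
                "n_tm": p.n_tm, "has_egf": p.has_egf, "has_pan": p.has_pan,
                "has_s_locus": p.has_s_locus, "chrom": f"chr{p.chrom}",
                "strand": p.strand}
            for p in all_plans if p.kind == "member"},
        "decoys": {p.gene_id: p.decoy_type for p in all_plans
                   if p.kind == "decoy"},
        "pairs": [
            {"gene_a": members[d["idx_a"]].gene_id,
             "gene_b": members[d["idx_b"]].gene_id,
             "tandem": spec.tandem,
             "n_intervening": spec.n_intervening if spec.tandem else None,
             "ks_target": spec.ks, "ka_target": spec.ka,
             "t_mya_target": spec.ks / (2 * 1.5e-8) / 1e6}
            for d, spec in zip(pair_dicts, config.duplicate_pairs)],
    }
    return chromosomes, gff_rows, domain_rows, all_plans, truth


def _domain_rows(plans: list[_GenePlan]) -> list[dict]:
    lectin_of = {"L": "Lectin_legB", "G": "B_lectin", "C": "Lectin_C"}
    rows = []

    def add(pid, domain, evalue, start, end):
        rows.append({"protein_id": pid, "domain": domain, "evalue": evalue,
                     "start": start, "end": end, "source": "synthetic"})

    for p in plans:
        if p.kind == "filler":
            continue
        pid = f"{p.gene_id}.1"
        plen = len(p.cds) // 3 - 1
        if p.kind == "member":
            if p.has_signal:
                add(pid, "signal_peptide", 0.0, 1, 24)
            add(pid, lectin_of[p.subfamily], p.lectin_evalue, 30,
                min(280, plen // 2))
            if p.has_egf:
                add(pid, "EGF", 1e-6, plen // 2 - 60, plen // 2 - 20)
            if p.has_pan:
                add(pid, "PAN", 1e-6, plen // 2 - 15, plen // 2 + 25)
            if p.has_s_locus:
                add(pid, "S_locus", 1e-8, 60, 200)
            tm0 = plen // 2 + 30
            for t in range(p.n_tm):
                add(pid, "TM", 0.0, tm0 + 25 * t, tm0 + 25 * t + 21)
            add(pid, "kinase", 1e-25, plen - min(260, plen // 3), plen - 10)
        else:
            t = p.decoy_type
            if t == "no_tm":
                add(pid, "B_lectin", 1e-12, 30, 150)
                add(pid, "kinase", 1e-20, plen - 120, plen - 5)
            elif t == "no_kinase":
                add(pid, "Lectin_legB", 1e-9, 30, 150)
                add(pid, "TM", 0.0, plen // 2, plen // 2 + 21)
            elif t == "no_lectin":
                add(pid, "kinase", 1e-22, plen - 120, plen - 5)
                add(pid, "TM", 0.0, 40, 61)
            elif t == "weak_lectin":
                add(pid, "Lectin_legB", 0.01, 30, 150)
                add(pid, "kinase", 1e-15, plen - 120, plen - 5)
                add(pid, "TM", 0.0, plen // 2, plen // 2 + 21)
            elif t == "boundary_lectin":
                # e-value exactly at the cutoff: the strict filter drops it
                add(pid, "B_lectin", 0.001, 30, 150)
                add(pid, "kinase", 1e-15, plen - 120, plen - 5)
                add(pid, "TM", 0.0, plen // 2, plen // 2 + 21)
            else:
                add(pid, "other:WD40", 1e-10, 10, max(11, min(plen - 1, 200)))
    return rows


# ---------------------------------------------------------------------------
# promoter catalog and plants
# ---------------------------------------------------------------------------

_CATEGORY_PLAN = (("light", 24), ("hormone", 11), ("stress", 9),
                  ("development", 6), ("other", 4))
#: canonical patterns for the named plant cis-elements in the catalog
_NAMED = {
    "light": [("G-box", "CACGTG"), ("Box-4", "ATTAAT"),
              ("GT1-motif", "GGTTAA"), ("MRE", "AACCTAA"),
              ("I-box", "GATAAGG")],
    "hormone": [("ABRE", "ACGTGGC"), ("ABRE2", "TACGTGT"),
                ("ABRE3", "CACGTAA"), ("TGA-element", "AACGAC"),
                ("ERE", "ATTTCAAA"), ("P-box", "CCTTTTG"),
                ("TCA-element", "TCAGAAGA")],
    "stress": [("LTR", "CCGAAA"), ("MBS", "CAACTG"),
               ("TC-rich", "ATTTTCTCCA")],
    "development": [("RY-element", "CATGCATG"), ("GCN4-motif", "TGAGTCA")],
    "other": [("circadian", "CAANNNNATC")],
}


def default_motif_catalog(rng: np.random.Generator) -> list[MotifPattern]:
    """A 54-element cis-element catalog over five categories (named plant
    elements first, filled up with random unique patterns), plus the
    ubiquitous CAAT/TATA boxes that the scanner excludes by default."""
    catalog: list[MotifPattern] = []
    seen: set[str] = set()
    for cat, n in _CATEGORY_PLAN:
        named = list(_NAMED.get(cat, []))[:n]
        for name, pat in named:
            seen.add(pat)
            catalog.append(MotifPattern(name, pat, cat))
        k = len(named)
        while k < n:
            length = int(rng.integers(6, 9))
            pat = "".join(rng.choice(list("ACGT"), size=length))
            if pat in seen:
                continue
            seen.add(pat)
            catalog.append(MotifPattern(f"{cat[:3].upper()}-{k + 1:02d}",
                                        pat, cat))
            k += 1
    catalog.append(MotifPattern("CAAT-box", "CCAAT", "other"))
    catalog.append(MotifPattern("TATA-box", "TATAAA", "other"))
    return catalog


def _concretize(iupac: str, rng: np.random.Generator) -> str:
    from .promoter import IUPAC
    out = []
    for ch in iupac:
        opts = IUPAC[ch].strip("[]")
        out.append(opts[int(rng.integers(len(opts)))] if len(opts) > 1
                   else opts)
    return "".join(out)


def _plant_promoters(config: SynthConfig, chromosomes, plans,
                     catalog: list[MotifPattern],
                     rng: np.random.Generator,
                     showcase: dict[str, str]) -> list[dict]:
    """Write catalog elements into member promoters; returns the planted
    hit list (gene_id, motif, 1-based promoter offset, hit strand)."""
    members = [p for p in plans if p.kind == "member"]
    scannable = [m for m in catalog
                 if m.name not in ("CAAT-box", "TATA-box", "TATC-box")]
    slots: dict[str, int] = {p.gene_id: 0 for p in members}
    plants: list[dict] = []

    def plant(plan: _GenePlan, motif: MotifPattern, strand: str):
        slot = slots[plan.gene_id]
        offset = 20 + 40 * slot
        concrete = _concretize(motif.iupac, rng)
        if offset + len(concrete) > config.promoter_length - 10:
            return
        slots[plan.gene_id] += 1
        # content of the promoter string at this offset
        prom_content = concrete if strand == "+" \
            else reverse_complement(concrete)
        # the promoter string reads toward the gene; map back to genome
        genome_content = prom_content if plan.strand == "+" \
            else reverse_complement(prom_content)
        L = len(genome_content)
        if plan.strand == "+":
            tss = plan.exons[0][0]
            g0 = (tss - config.promoter_length - 1) + (offset - 1)
        else:
            tss = plan.exons[-1][1]
            prom_end = tss + config.promoter_length
            g0 = prom_end - (offset - 1) - L
        chromosomes[f"chr{plan.chrom}"][g0:g0 + L] = \
            np.frombuffer(genome_content.encode(), dtype=np.uint8)
        plants.append({"gene_id": plan.gene_id, "motif": motif.name,
                       "position": offset, "strand": strand})

    by_id = {p.gene_id: p for p in members}
    # targeted plants echoing the treatment responses: three ABA elements
    # on the strongly ABA-induced gene, one on the ABA-repressed gene,
    # one auxin-responsive element on the IAA-repressed gene
    abres = [m for m in scannable if m.name.startswith("ABRE")]
    if showcase.get("aba_up") in by_id:
        for m in abres[:3]:
            plant(by_id[showcase["aba_up"]], m, "+")
    if showcase.get("aba_down") in by_id and abres:
        plant(by_id[showcase["aba_down"]], abres[0], "+")
    tga = [m for m in scannable if m.name == "TGA-element"]
    if showcase.get("iaa_down") in by_id and tga:
        plant(by_id[showcase["iaa_down"]], tga[0], "-")
    # every element planted in at least one promoter, round-robin
    for k, motif in enumerate(scannable):
        plan = members[k % len(members)]
        plant(plan, motif, "+" if k % 3 else "-")
        extra = members[(k * 7 + 3) % len(members)]
        if extra.gene_id != plan.gene_id:
            plant(extra, motif, "+")
    return plants


# ---------------------------------------------------------------------------
# expression and qPCR
# ---------------------------------------------------------------------------

def generate_expression(config: SynthConfig, member_ids: list[str],
                        seed: int) -> tuple[pd.DataFrame, dict]:
    """Three-level FPKM matrix with planted structure.

    Genes fall into groups (sizes and means from the config) drawn
    log-normally around the group mean (mean-corrected, so the arithmetic
    mean matches). With a large low group the generator also plants: 3
    silent genes, 5 tissue-specific genes, 2 genes with one zero tissue,
    a sub-threshold dip tissue for the remaining low-group genes, and 3
    middle-group genes dipping in one Venn tissue — so constitutive
    expression, Venn membership and expressed-in-all counts have exact
    known truth.
    """
    rng = np.random.default_rng(seed)
    tissues = list(config.tissues)
    sizes = list(config.group_sizes)
    if sum(sizes) != len(member_ids):
        raise ValueError("group sizes must sum to the member count")
    genes = list(member_ids)
    sigma = config.fpkm_sigma
    values = np.zeros((len(genes), len(tissues)))
    group_of: dict[str, int] = {}
    bounds = np.cumsum([0] + sizes)
    for g, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        mu = math.log(config.group_means[g]) - sigma ** 2 / 2.0
        values[lo:hi] = np.exp(rng.normal(mu, sigma,
                                          size=(hi - lo, len(tissues))))
        for i in range(lo, hi):
            group_of[genes[i]] = g + 1

    low = list(range(bounds[-2], bounds[-1]))
    g2 = list(range(bounds[-3], bounds[-2])) if len(sizes) >= 3 else []
    silent: list[int] = []
    spec_map: dict[str, str] = {}
    dippers: list[int] = []
    rich = len(low) >= 12 and len(g2) >= 3 and \
        len(config.venn_tissues) >= 3
    if rich:
        silent = low[:3]
        specific = low[3:8]
        specific_plan = ["root", "root", "cotyledon", "cotyledon",
                         "tendril"]
        specific_plan = [t if t in tissues else tissues[0]
                         for t in specific_plan]
        zero_extra = low[8:10]
        for i in silent:
            values[i, :] = 0.0
        for i, tis in zip(specific, specific_plan):
            spec_map[genes[i]] = tis
            values[i, :] = 0.0
            values[i, tissues.index(tis)] = 4.0 * float(
                np.exp(rng.normal(0, sigma)))
        for i in zero_extra:
            values[i, int(rng.integers(len(tissues)))] = 0.0
        for i in low[10:]:
            values[i, int(rng.integers(len(tissues)))] = float(
                rng.uniform(0.2, 0.8))
        venn_t = [tissues.index(t) for t in config.venn_tissues]
        dippers = g2[:3]
        values[dippers[0], venn_t[0]] = float(rng.uniform(0.3, 0.9))
        values[dippers[1], venn_t[1]] = float(rng.uniform(0.3, 0.9))
        values[dippers[2], venn_t[2]] = 1.2

    frame = pd.DataFrame(values, index=genes, columns=tissues)
    constitutive = [genes[i] for i in range(int(bounds[-2]))
                    if i not in dippers[:2]] if rich else None
    truth = {
        "group_of": group_of,
        "group_sizes": sizes,
        "group_means": list(config.group_means),
        "silent": [genes[i] for i in silent],
        "tissue_specific": spec_map,
        "constitutive": constitutive,
        "n_expressed_all_venn": (int(bounds[-2]) - 3) if rich else None,
    }
    return frame, truth


def generate_qpcr(config: SynthConfig, member_ids: list[str], seed: int
                  ) -> tuple[pd.DataFrame, dict]:
    """Ct tables with planted fold-changes.

    Per-treatment planted event counts follow the published tallies
    (GA 5 up / 3 down, ABA 8/8, NAA 6/14, IAA 1/8, cold 0/4: 20 up and
    38 down overall), including an 88-fold ABA induction, a 17-fold ABA
    repression and a 5-fold IAA repression; 15 genes respond to nothing.
    The reference gene is stable; the target Ct is shifted by
    -log2(fold) plus Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    genes = list(member_ids)
    base_counts = {"GA": (5, 3), "ABA": (8, 8), "NAA": (6, 14),
                   "IAA": (1, 8), "cold": (0, 4)}
    n_nr = 15 if len(genes) > 20 else max(0, len(genes) - 3)
    non_resp = genes[:n_nr]
    responders = genes[n_nr:]
    plan_counts = {}
    for c in config.conditions:
        ups, downs = base_counts.get(c, (1, 1))
        total = ups + downs
        if total > len(responders):  # small configs: scale the plan down
            scale = len(responders) / total
            ups = int(ups * scale)
            downs = len(responders) - ups
        plan_counts[c] = (ups, downs)
    fold = {(g, c): 1.0 for g in genes for c in config.conditions}
    showcase: dict[str, str] = {}
    r = 0

    def next_free(cond):
        nonlocal r
        for _ in range(len(responders)):
            g = responders[r % len(responders)]
            r += 1
            if fold[(g, cond)] == 1.0:
                return g
        raise RuntimeError("no free responder")

    for cond in config.conditions:
        ups, downs = plan_counts[cond]
        for u in range(ups):
            g = next_free(cond)
            if cond == "ABA" and u == 0:
                fold[(g, cond)] = 88.0
                showcase["aba_up"] = g
            else:
                fold[(g, cond)] = float(2.0 ** rng.uniform(1.0, 4.0))
        for d in range(downs):
            g = next_free(cond)
            if cond == "ABA" and d == 0:
                fold[(g, cond)] = 1.0 / 17.0
                showcase["aba_down"] = g
            elif cond == "IAA" and d == 0:
                fold[(g, cond)] = 1.0 / 5.0
                showcase["iaa_down"] = g
            else:
                fold[(g, cond)] = float(2.0 ** -rng.uniform(1.0, 4.0))

    rows = []
    sd = config.ct_noise_sd
    for g in genes:
        base = float(rng.uniform(24.0, 30.0))
        for cond in ("control",) + tuple(config.conditions):
            shift = 0.0 if cond == "control" else -math.log2(fold[(g, cond)])
            for rep in range(1, config.n_replicates + 1):
                rows.append({
                    "gene_id": g, "condition": cond, "replicate": rep,
                    "ct_target": base + shift + float(rng.normal(0, sd)),
                    "ct_reference": 20.0 + float(rng.normal(0, sd))})
    table = pd.DataFrame(rows)
    truth = {
        "fold_changes": {f"{g}|{c}": v for (g, c), v in fold.items()
                         if v != 1.0},
        "n_up_planted": sum(1 for v in fold.values() if v > 1.0),
        "n_down_planted": sum(1 for v in fold.values() if v < 1.0),
        "non_responders": non_resp,
        "showcase": showcase,
    }
    return table, truth


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

def generate_bundle(config: SynthConfig, outdir: str | os.PathLike,
                    seed: int) -> dict:
    """Emit the full synthetic input bundle to ``outdir``: genome.fa,
    annotation.gff3, domains.tsv, proteins.fa, cds.fa, motif_catalog.tsv,
    fpkm.tsv, qpcr.csv and truth.json.

    A pure function of (config, seed): two runs write byte-identical
    files. Returns the truth dictionary.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]
    chromosomes, gff_rows, domain_rows, plans, truth = \
        generate_annotation(config, sub_seeds[0])
    member_ids = sorted(p.gene_id for p in plans if p.kind == "member")

    fpkm, expr_truth = generate_expression(config, member_ids, sub_seeds[1])
    qpcr, qpcr_truth = generate_qpcr(config, member_ids, sub_seeds[2])

    cat_rng = np.random.default_rng(sub_seeds[3])
    catalog = default_motif_catalog(cat_rng)
    plants = _plant_promoters(config, chromosomes, plans, catalog, cat_rng,
                              qpcr_truth["showcase"])

    outdir = str(outdir)
    with open(os.path.join(outdir, "genome.fa"), "w") as fh:
        for name in sorted(chromosomes):
            fh.write(f">{name}\n")
            s = chromosomes[name].tobytes().decode()
            for i in range(0, len(s), 60):
                fh.write(s[i:i + 60] + "\n")
    with open(os.path.join(outdir, "annotation.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("\n".join(gff_rows) + "\n")
    with open(os.path.join(outdir, "domains.tsv"), "w") as fh:
        fh.write("protein_id\tdomain\tevalue\tstart\tend\tsource\n")
        for row in domain_rows:
            fh.write(f"{row['protein_id']}\t{row['domain']}\t"
                     f"{row['evalue']:g}\t{row['start']}\t{row['end']}\t"
                     f"{row['source']}\n")
    with open(os.path.join(outdir, "cds.fa"), "w") as fh, \
            open(os.path.join(outdir, "proteins.fa"), "w") as ph:
        for p in sorted((p for p in plans if p.kind != "filler"),
                        key=lambda q: q.gene_id):
            pid = f"{p.gene_id}.1"
            fh.write(f">{pid}\n")
            for i in range(0, len(p.cds), 60):
                fh.write(p.cds[i:i + 60] + "\n")
            prot = translate_cds(p.cds)
            ph.write(f">{pid}\n")
            for i in range(0, len(prot), 60):
                ph.write(prot[i:i + 60] + "\n")
    write_motif_catalog(catalog, os.path.join(outdir, "motif_catalog.tsv"))
    fpkm.to_csv(os.path.join(outdir, "fpkm.tsv"), sep="\t",
                float_format="%.4f", index_label="gene_id")
    qpcr.to_csv(os.path.join(outdir, "qpcr.csv"), index=False)

    truth.update({"expression": expr_truth, "qpcr": qpcr_truth,
                  "promoter_plants": plants,
                  "n_catalog_elements": sum(n for _, n in _CATEGORY_PLAN),
                  "category_counts": dict(_CATEGORY_PLAN)})
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
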