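"""Family identification by domain architecture and L/G/C subfamily
classification.

A protein is a candidate family member iff it carries, simultaneously, a
lectin-class domain (below the e-value cutoff), a kinase domain and a
transmembrane segment. The subfamily follows the lectin domain of the
best (lowest) e-value hit: legume lectin -> L, bulb/S-domain lectin -> G,
calcium-dependent lectin -> C.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .io import DomainHit, LECTIN_DOMAINS

__all__ = ["FamilyMember", "group_hits", "filter_candidates",
           "classify_subfamily", "classify_members", "architecture_summary"]

_SUBFAMILY_OF = {"Lectin_legB": "L", "B_lectin": "G", "Lectin_C": "C"}


@dataclass
class FamilyMember:
    gene_id: str
    protein_id: str
    subfamily: str  # {"L", "G", "C"}
    has_signal: bool
    n_tm: int
    has_egf: bool
    has_pan: bool
    has_s_locus: bool
    lectin_evalue: float


def group_hits(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    grouped: dict[str, list[DomainHit]] = defaultdict(list)
    for h in hits:
        grouped[h.protein_id].append(h)
    return dict(grouped)


def filter_candidates(hits: Iterable[DomainHit],
                      evalue_cutoff: float = 0.001) -> set[str]:
    """Protein ids retained by the identification filter: at least one
    lectin-class hit with e-value strictly below the cutoff, plus at
    least one kinase hit and one TM hit (presence only)."""
    retained = set()
    for pid, phits in group_hits(hits).items():
        domains = {h.domain for h in phits}
        has_lectin = any(h.domain in LECTIN_DOMAINS and
                         h.evalue < evalue_cutoff for h in phits)
        if has_lectin and "kinase" in domains and "TM" in domains:
            retained.add(pid)
    return retained


def classify_subfamily(protein_id: str, phits: list[DomainHit],
                       gene_id: str | None = None) -> FamilyMember:
    """Classify one retained protein from its hits.

    The subfamily follows the lectin class with the best (lowest)
    e-value; an exact tie between two lectin classes is refused and must
    be resolved manually.
    """
    lectins = [h for h in phits if h.domain in LECTIN_DOMAINS]
    if not lectins:
        raise ValueError(f"{protein_id}: no lectin-class hit to classify")
    best_e = min(h.evalue for h in lectins)
    best_classes = {h.domain for h in lectins if h.evalue == best_e}
    if len(best_classes) > 1:
        raise ValueError(
            f"{protein_id}: lectin classes {sorted(best_classes)} tie at "
            f"e-value {best_e}; manual resolution required")
    best = best_classes.pop()
    domains = [h.domain for h in phits]
    return FamilyMember(
        gene_id=gene_id or protein_id.rsplit(".", 1)[0],
        protein_id=protein_id,
        subfamily=_SUBFAMILY_OF[best],
        has_signal="signal_peptide" in domains,
        n_tm=domains.count("TM"),
        has_egf="EGF" in domains,
        has_pan="PAN" in domains,
        has_s_locus="S_locus" in domains,
        lectin_evalue=best_e)


def classify_members(hits: Iterable[DomainHit],
                     evalue_cutoff: float = 0.001) -> list[FamilyMember]:
    """Filter + classify in one pass; returns members sorted by gene id."""
    hits = list(hits)
    grouped = group_hits(hits)
    members = [classify_subfamily(pid, grouped[pid])
               for pid in filter_candidates(hits, evalue_cutoff)]
    members.sort(key=lambda m: m.gene_id)
    return members


def architecture_summary(members: Iterable[FamilyMember]) -> pd.DataFrame:
    """Counts of members per subfamily and architecture combination."""
    rows = []
    members = list(members)
    for sub in ("L", "G", "C"):
        in_sub = [m for m in members if m.subfamily == sub]
        rows.append({
            "subfamily": sub,
            "n_members": len(in_sub),
            "egf_and_pan": sum(m.has_egf and m.has_pan for m in in_sub),
            "egf_only": sum(m.has_egf and not m.has_pan for m in in_sub),
            "pan_only": sum(m.has_pan and not m.has_egf for m in in_sub),
            "neither": sum(not m.has_egf and not m.has_pan for m in in_sub),
            "with_signal": sum(m.has_signal for m in in_sub),
            "without_signal": sum(not m.has_signal for m in in_sub),
            "multi_tm": sum(m.n_tm > 1 for m in in_sub),
        })
    return pd.DataFrame(rows).set_index("subfamily")
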