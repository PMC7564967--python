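"""Protein alignment: global pairwise Needleman-Wunsch and a star
multiple alignment built from pairwise alignments.

Scoring follows the common gene-family workflow convention: BLOSUM62,
gap open 10, gap extend 0.5.
"""
from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .io import SeqRecord

__all__ = ["PairAlignment", "align_pair", "star_msa"]


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


@dataclass
class PairAlignment:
    """A global alignment of two proteins with its identity and coverage.

    identity = matches / aligned residue pairs (columns gapped in either
    sequence are excluded); coverage = aligned residue pairs / length of
    the longer sequence.
    """

    id_a: str
    id_b: str
    row_a: str
    row_b: str

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise ValueError("aligned rows differ in length")
        pairs = matches = 0
        for x, y in zip(self.row_a, self.row_b):
            if x != "-" and y != "-":
                pairs += 1
                if x == y:
                    matches += 1
        self.aligned_pairs = pairs
        self.identity = matches / pairs if pairs else 0.0
        longer = max(len(self.row_a.replace("-", "")),
                     len(self.row_b.replace("-", "")))
        self.coverage = pairs / longer if longer else 0.0


def align_pair(prot_a: SeqRecord, prot_b: SeqRecord) -> PairAlignment:
    """Globally align two protein sequences (BLOSUM62, open 10, extend 0.5)."""
    if not prot_a.sequence or not prot_b.sequence:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner().align(prot_a.sequence, prot_b.sequence)[0]
    return PairAlignment(prot_a.id, prot_b.id, str(aln[0]), str(aln[1]))


def _merge_onto_center(center: str, pairs: list[tuple[str, str, str]]
                       ) -> tuple[list[str], list[str]]:
    """Merge pairwise (center,row) alignments into one MSA by center
    coordinates ("once a gap, always a gap")."""
    n_res = len(center)
    # maximal insertion length at each of the n_res+1 slots between residues
    ins = [0] * (n_res + 1)
    parsed = []
    for _, c_row, s_row in pairs:
        slot, runs = 0, [0] * (n_res + 1)
        for c_ch in c_row:
            if c_ch == "-":
                runs[slot] += 1
            else:
                slot += 1
        for i, r in enumerate(runs):
            ins[i] = max(ins[i], r)
        parsed.append(runs)

    def expand(c_row: str, s_row: str, runs: list[int]) -> str:
        out: list[str] = []
        cols = list(zip(c_row, s_row))
        k = 0
        for slot in range(n_res + 1):
            # insertion block at this slot
            block = []
            while k < len(cols) and cols[k][0] == "-":
                block.append(cols[k][1])
                k += 1
            block += ["-"] * (ins[slot] - runs[slot])
            out.extend(block)
            if slot < n_res:
                out.append(cols[k][1])
                k += 1
        return "".join(out)

    rows = [expand(c, s, runs) for (_, c, s), runs in zip(pairs, parsed)]
    center_row = []
    for slot in range(n_res + 1):
        center_row.extend("-" * ins[slot])
        if slot < n_res:
            center_row.append(center[slot])
    return ["".join(center_row)], rows


def star_msa(records: list[SeqRecord]) -> tuple[list[str], list[str]]:
    """Multiple alignment by the star method: every sequence is aligned
    to a center sequence (the longest; ties broken by id) and the pairwise
    alignments are merged on center coordinates.

    Returns (ids, rows) in the input order.
    """
    if len(records) < 2:
        raise ValueError("need at least two sequences to align")
    center = min(records, key=lambda r: (-len(r.sequence), r.id))
    aligner = _aligner()
    pairs = []
    others = [r for r in records if r.id != center.id]
    for rec in others:
        aln = aligner.align(center.sequence, rec.sequence)[0]
        pairs.append((rec.id, str(aln[0]), str(aln[1])))
    if not pairs:  # all records identical id? guarded by read_fasta
        return [center.id], [center.sequence]
    center_rows, rows = _merge_onto_center(center.sequence, pairs)
    by_id = {rid: row for (rid, _, _), row in zip(pairs, rows)}
    by_id[center.id] = center_rows[0]
    ids = [r.id for r in records]
    return ids, [by_id[i] for i in ids]
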