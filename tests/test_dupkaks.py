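"""Nei-Gojobori counting, Jukes-Cantor correction, duplicate detection
and divergence dating."""
import itertools

import numpy as np
import pytest

from famscan.align import align_pair
from famscan.dupkaks import (SaturationError, classify_duplication,
                             divergence_time, find_duplicates,
                             jukes_cantor, kaks_pair, ng_counts,
                             synonymous_fraction)
from famscan.io import GeneModel, SeqRecord
from famscan.synthetic import generate_duplicate_pair, translate_cds

# ---------------------------------------------------------------------------
# independent oracle: genetic code from Biopython, exhaustive pathway
# enumeration written from scratch
# ---------------------------------------------------------------------------
from Bio.Data.CodonTable import standard_dna_table

_CODE = dict(standard_dna_table.forward_table)
for stop in standard_dna_table.stop_codons:
    _CODE[stop] = "*"
_BASES = "TCAG"


def oracle_sites(codon):
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            if _CODE[codon[:pos] + b + codon[pos + 1:]] == _CODE[codon]:
                s += 1 / 3
    return s


def oracle_diffs(ca, cb):
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    viable, blocked = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd, bad = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if _CODE[nxt] == "*" and nxt != cb:
                bad = True
            if _CODE[cur] == _CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if bad else viable).append((sd, nd))
    pool = viable or blocked
    return (sum(x for x, _ in pool) / len(pool),
            sum(y for _, y in pool) / len(pool))


SENSE = sorted(c for c, aa in _CODE.items() if aa != "*")


class TestNgCounts:
    def test_identical_cds(self):
        c = ng_counts("ATGAAA", "ATGAAA")
        assert c.Sd == 0 and c.Nd == 0

    def test_single_twofold_codon(self):
        # TTT vs TTC: silent third-position change
        c = ng_counts("TTT", "TTC")
        assert c.Sd == 1 and c.Nd == 0
        assert c.S == pytest.approx(1 / 3)
        assert c.N == pytest.approx(8 / 3)

    def test_sites_conserved(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 6))
            a = "".join(rng.choice(SENSE, size=n))
            b = "".join(rng.choice(SENSE, size=n))
            c = ng_counts(a, b)
            assert c.S + c.N == pytest.approx(3 * c.n_codons, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = "".join(rng.choice(SENSE, size=3))
            b = "".join(rng.choice(SENSE, size=3))
            ca, cb = ng_counts(a, b), ng_counts(b, a)
            assert (ca.S, ca.N, ca.Sd, ca.Nd) == (cb.S, cb.N, cb.Sd, cb.Nd)

    def test_matches_exhaustive_pathway_oracle(self):
        """Random <=3-codon sense pairs: sites and pathway-averaged
        differences equal independent enumeration exactly."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(1, 4))
            a = "".join(rng.choice(SENSE, size=n))
            b = "".join(rng.choice(SENSE, size=n))
            c = ng_counts(a, b)
            exp_s = sum(0.5 * (oracle_sites(a[k:k + 3]) +
                               oracle_sites(b[k:k + 3]))
                        for k in range(0, 3 * n, 3))
            exp_sd = exp_nd = 0.0
            for k in range(0, 3 * n, 3):
                sd, nd = oracle_diffs(a[k:k + 3], b[k:k + 3])
                exp_sd += sd
                exp_nd += nd
            assert c.S == pytest.approx(exp_s, abs=1e-12)
            assert c.Sd == pytest.approx(exp_sd, abs=1e-12)
            assert c.Nd == pytest.approx(exp_nd, abs=1e-12)

    def test_gapped_and_ambiguous_codons_skipped(self):
        c = ng_counts("TTT---AAA", "TTCNNNAAA")
        assert c.n_codons == 2

    def test_all_codons_skipped_is_error(self):
        with pytest.raises(ValueError):
            ng_counts("---", "TTT")

    def test_agrees_with_biopython_ng86(self):
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        a, b, _ = generate_duplicate_pair(0.3, 0.1, 300, seed=5)
        a, b = a[:-3], b[:-3]
        c = ng_counts(a, b)
        dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        assert jukes_cantor(c.pN) == pytest.approx(dn, abs=1e-9)
        assert jukes_cantor(c.pS) == pytest.approx(ds, abs=1e-9)


class TestJukesCantor:
    def test_closed_form_spot_checks(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.1) == pytest.approx(0.107326, abs=1e-6)
        assert jukes_cantor(0.5) == pytest.approx(0.823959, abs=1e-6)

    def test_saturation(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.75)
        with pytest.raises(ValueError):
            jukes_cantor(-0.01)


class TestKaKsPair:
    def _pair(self, ks, ka, n=400, seed=9):
        a, b, _ = generate_duplicate_pair(ks, ka, n, seed=seed)
        ra = SeqRecord("a", translate_cds(a), "protein")
        rb = SeqRecord("b", translate_cds(b), "protein")
        return a, b, align_pair(ra, rb)

    def test_identical_cds(self):
        a, b, aln = self._pair(0.0, 0.0)
        ka, ks, omega = kaks_pair(a, b, aln)
        assert ka == 0.0 and ks == 0.0 and omega is None

    def test_synonymous_only_changes(self):
        a, b, aln = self._pair(0.3, 0.0)
        assert translate_cds(a) == translate_cds(b)
        ka, ks, _ = kaks_pair(a, b, aln)
        assert ka == 0.0 and ks > 0.2

    def test_length_mismatch_names_offender(self):
        a, b, aln = self._pair(0.1, 0.05)
        with pytest.raises(ValueError, match="a"):
            kaks_pair(a[:-6], b, aln)

    def test_internal_stop_rejected(self):
        a, b, aln = self._pair(0.0, 0.0, n=40)
        bad = a[:30] + "TGA" + a[33:]
        with pytest.raises(ValueError, match="stop"):
            kaks_pair(bad, b, aln)

    @pytest.mark.parametrize("ks_true", [0.1, 0.3, 0.5])
    def test_ks_recovery_within_ten_percent(self, ks_true):
        """Median relative error of Ks over 20 simulated 500-codon pairs
        stays within 10% at each divergence level."""
        errs = []
        for seed in range(20):
            a, b, aln = self._pair(ks_true, 0.2 * ks_true, n=500,
                                   seed=1000 + seed)
            _, ks, _ = kaks_pair(a, b, aln)
            errs.append(abs(ks - ks_true) / ks_true)
        assert np.median(errs) <= 0.10


class TestDuplicateCalling:
    def test_strict_thresholds(self):
        # identical pair is found; sub-threshold coverage is not
        long = "MKVLWAALLVTFLAGCQAKVEQAVETEPEPELRQQTEWQSGQRWELALGRFWDYLRWVQT" * 3
        recs = [SeqRecord("a", long, "protein"),
                SeqRecord("b", long, "protein"),
                SeqRecord("c", long[:int(len(long) * 0.69)], "protein")]
        pairs = find_duplicates(recs)
        found = {frozenset((p.id_a, p.id_b)) for p in pairs}
        assert frozenset(("a", "b")) in found
        assert frozenset(("a", "c")) not in found  # coverage 0.69 < 0.70

    def _genes(self, chrom_b="chr1", start_b=50_000, intervening=2):
        genes = [GeneModel("ga", "chr1", "+", 1000, 3000,
                           exons=[(1000, 3000)],
                           cds_segments=[(1000, 3000)]),
                 GeneModel("gb", chrom_b, "+", start_b, start_b + 2000,
                           exons=[(start_b, start_b + 2000)],
                           cds_segments=[(start_b, start_b + 2000)])]
        for i in range(intervening):
            s = 5000 + 3000 * i
            genes.append(GeneModel(f"f{i}", "chr1", "-", s, s + 1000,
                                   exons=[(s, s + 1000)],
                                   cds_segments=[(s, s + 1000)]))
        return genes

    def _pair(self):
        rec = SeqRecord("x", "MKVLWAALLVTFLAGCQAKV" * 10, "protein")
        aln = align_pair(rec, SeqRecord("y", rec.sequence, "protein"))
        aln.id_a, aln.id_b = "ga", "gb"
        return aln

    def test_tandem_within_gap_and_intervening_limits(self):
        ev = classify_duplication(self._pair(), self._genes())
        assert ev.dup_class == "tandem"
        assert ev.n_intervening == 2
        assert ev.gap_bp == 50_000 - 3000 - 1

    def test_different_chromosomes_dispersed(self):
        ev = classify_duplication(self._pair(),
                                  self._genes(chrom_b="chr2"))
        assert ev.dup_class == "dispersed"

    def test_too_many_intervening_forces_dispersed(self):
        genes = self._genes(start_b=80_000, intervening=7)
        ev = classify_duplication(self._pair(), genes)
        assert ev.dup_class == "dispersed"
        assert ev.n_intervening == 7

    def test_gap_beyond_100kb_dispersed(self):
        ev = classify_duplication(self._pair(),
                                  self._genes(start_b=150_000,
                                              intervening=0))
        assert ev.dup_class == "dispersed"

    def test_missing_gene_is_error(self):
        with pytest.raises(KeyError):
            classify_duplication(self._pair(), self._genes()[:1])


class TestDivergenceTime:
    def test_zero_and_closed_form(self):
        assert divergence_time(0.0) == 0.0
        assert divergence_time(0.3) == pytest.approx(10.0)
        assert divergence_time(1.1583) == pytest.approx(38.61)

    def test_bad_rate(self):
        with pytest.raises(ValueError):
            divergence_time(0.3, r=0.0)
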