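"""Pileup construction and the diploid SNV caller."""

import math

import numpy as np
import pytest

import xenomix as xm
from xenomix.align import AlignmentRecord
from xenomix.readsim import SimulatedRead
from xenomix.variants import PileupColumn


def mkread(seq, rid, qual=40):
    return SimulatedRead(rid, seq, np.full(len(seq), qual))


def mkrec(rid, pos, cigar, chrom="chr1", strand="+"):
    return AlignmentRecord(rid, f"human:{chrom}", pos, strand, 0, 60, cigar, True, True)


@pytest.fixture(scope="module")
def reference():
    return xm.generate_ancestor(300, 1, 0.5, seed=301, name="human")


class TestPileup:
    def test_empty(self, reference):
        assert list(xm.pileup([], {}, reference)) == []

    def test_three_error_free_reads(self, reference):
        seq = reference.seq("chr1")
        reads, recs = {}, []
        for i, start in enumerate((10, 20, 30)):
            r = mkread(seq[start : start + 50], f"h:chr1_{start}_+_0_{i}")
            reads[r.read_id] = r
            recs.append(mkrec(r.read_id, start, "50M"))
        cols = {c.pos: c for c in xm.pileup(recs, reads, reference)}
        col = cols[35]  # covered by all three reads
        assert col.depth == 3
        assert col.base_counts == {seq[35]: 3}

    def test_hand_built_toy_counts(self, reference):
        """5 reads over one position, one with a planted mismatch."""
        seq = reference.seq("chr1")
        target = 100
        ref_base = seq[target]
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref_base]
        reads, recs = {}, []
        for i in range(5):
            start = target - 20 - i
            s = seq[start : start + 40]
            if i == 0:
                off = target - start
                s = s[:off] + alt + s[off + 1 :]
            r = mkread(s, f"h:chr1_{start}_+_0_{i}")
            reads[r.read_id] = r
            recs.append(mkrec(r.read_id, start, "40M"))
        cols = {c.pos: c for c in xm.pileup(recs, reads, reference)}
        assert cols[target].base_counts == {ref_base: 4, alt: 1}

    def test_deletion_and_insertion_cigar_handling(self, reference):
        seq = reference.seq("chr1")
        # read skips reference bases 60..61 (deletion)
        del_read = mkread(seq[50:60] + seq[62:82], "h:chr1_50_+_0_0")
        # read carries a 3-base insertion after 5 aligned bases
        ins_read = mkread(seq[150:155] + "AAA" + seq[155:170], "h:chr1_150_+_0_1")
        reads = {r.read_id: r for r in (del_read, ins_read)}
        recs = [
            mkrec(del_read.read_id, 50, "10M2D20M"),
            mkrec(ins_read.read_id, 150, "5M3I15M"),
        ]
        cols = {c.pos: c for c in xm.pileup(recs, reads, reference)}
        assert 60 not in cols and 61 not in cols  # deleted: no observation
        assert cols[62].base_counts == {seq[62]: 1}
        assert cols[155].base_counts == {seq[155]: 1}  # insertion skipped
        assert cols[169].base_counts == {seq[169]: 1}

    def test_reverse_strand_bases(self, reference):
        seq = reference.seq("chr1")
        window = seq[200:240]
        rc = window.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        r = mkread(rc, "h:chr1_200_-_0_0")
        recs = [mkrec(r.read_id, 200, "40M", strand="-")]
        cols = {c.pos: c for c in xm.pileup(recs, {r.read_id: r}, reference)}
        assert cols[210].base_counts == {seq[210]: 1}

    def test_inconsistent_cigar_names_read(self, reference):
        r = mkread("ACGTACGTAC", "h:chr1_0_+_0_0")
        with pytest.raises(ValueError, match="h:chr1_0_"):
            list(xm.pileup([mkrec(r.read_id, 0, "99M")], {r.read_id: r}, reference))


def column(ref, alt, n_ref, n_alt, qual=30.0):
    counts = {}
    quals = {}
    if n_ref:
        counts[ref] = n_ref
        quals[ref] = qual
    if n_alt:
        counts[alt] = n_alt
        quals[alt] = qual
    return PileupColumn("chr1", 0, ref, counts, quals)


def brute_force_qual(ref, alt, n_ref, n_alt, qual):
    """Posterior-of-hom-ref quality from explicit per-observation products."""
    e = 10 ** (-qual / 10)

    def p_obs(base, g):
        return sum((1 - e if base == a else e / 3) for a in g) / len(g)
    liks = {}
    for g in (("r", "r"), ("r", "a"), ("a", "a")):
        lik = 1.0
        for _ in range(n_ref):
            lik *= p_obs("r", g)
        for _ in range(n_alt):
            lik *= p_obs("a", g)
        liks[g] = lik
    post_rr = liks[("r", "r")] / sum(liks.values())
    return -10 * math.log10(post_rr)


class TestCallSnvs:
    def test_all_ref_no_call(self):
        calls = xm.call_snvs([column("A", "T", 30, 0)])
        assert calls == []

    def test_hom_alt_matches_brute_force_likelihood(self):
        calls = xm.call_snvs([column("A", "T", 0, 30)])
        (call,) = calls
        assert call.genotype == "hom_alt" and call.alt_allele == "T"
        expected = brute_force_qual("A", "T", 0, 30, 30.0)
        assert call.qual > 100  # far above the QUAL>=13 threshold
        assert call.qual == pytest.approx(expected, rel=1e-6)

    def test_balanced_het(self):
        (call,) = xm.call_snvs([column("A", "G", 15, 15)])
        assert call.genotype == "het"
        expected = brute_force_qual("A", "G", 15, 15, 30.0)
        assert call.qual == pytest.approx(expected, rel=1e-6)

    def test_min_depth_respected(self):
        assert xm.call_snvs([column("A", "T", 1, 1)], min_depth=3) == []
        assert len(xm.call_snvs([column("A", "T", 1, 2)], min_depth=3)) == 1

    def test_qual_monotone_in_alt_depth(self):
        quals = []
        for n_alt in range(2, 28):
            calls = xm.call_snvs([column("A", "T", 30 - n_alt, n_alt)])
            if calls:
                quals.append(calls[0].qual)
            else:
                # below the calling threshold only at the lowest alt depths
                assert not quals
        assert len(quals) >= 15
        assert quals == sorted(quals)

    def test_most_frequent_alt_wins(self):
        col = PileupColumn(
            "chr1", 5, "A", {"A": 10, "T": 6, "G": 2}, {"A": 30.0, "T": 30.0, "G": 30.0}
        )
        (call,) = xm.call_snvs([col])
        assert call.alt_allele == "T"


class TestFilterCalls:
    def _call(self, qual):
        return xm.VariantCall("chr1", 0, "A", "T", "het", qual)

    def test_boundary_inclusive(self):
        kept = xm.filter_calls([self._call(13.0), self._call(12.9)], min_qual=13)
        assert len(kept) == 1 and kept[0].qual == 13.0

    def test_empty(self):
        assert xm.filter_calls([], 13) == []


class TestPhred:
    def test_paper_value_q13(self):
        assert xm.phred_to_error_prob(13) == pytest.approx(0.05012, abs=5e-6)

    @pytest.mark.parametrize("q,p", [(0, 1.0), (10, 0.1), (20, 0.01)])
    def test_known_values(self, q, p):
        assert xm.phred_to_error_prob(q) == pytest.approx(p)

    def test_roundtrip_identity(self):
        for q in np.linspace(0.5, 60, 25):
            assert xm.prob_to_phred(xm.phred_to_error_prob(q)) == pytest.approx(
                q, abs=1e-9
            )


class TestVcfIO:
    def test_roundtrip(self, reference, tmp_path):
        calls = [
            xm.VariantCall("chr1", 9, "A", "T", "het", 42.5),
            xm.VariantCall("chr1", 99, "G", "C", "hom_alt", 13.0),
        ]
        path = tmp_path / "calls.vcf"
        xm.write_vcf(calls, reference, path)
        text = path.read_text()
        assert text.startswith("##fileformat=VCFv4.2")
        assert "\t10\t" in text  # 0-based 9 -> 1-based 10
        back = xm.read_vcf(path)
        assert [(c.chrom, c.pos, c.ref_allele, c.alt_allele, c.genotype) for c in back] == [
            ("chr1", 9, "A", "T", "het"),
            ("chr1", 99, "G", "C", "hom_alt"),
        ]
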