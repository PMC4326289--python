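"""Seed-and-extend aligner: scoring, uniqueness, SAM round-trips."""

import numpy as np
import pytest

import xenomix as xm
from oracles import cigar_score, oracle_best_score, revcomp
from xenomix.align import AlignParams, is_successful, seed_offsets, unmapped_record
from xenomix.readsim import SimulatedRead


def mkread(seq, rid="q:chr1_0_+_0_0"):
    return SimulatedRead(rid, seq, np.full(len(seq), 40))


@pytest.fixture(scope="module")
def genome():
    return xm.generate_ancestor(8000, 1, 0.45, seed=101, name="ref")


@pytest.fixture(scope="module")
def index(genome):
    return xm.build_index(genome, 15)


class TestIndex:
    def test_k_too_small(self, genome):
        with pytest.raises(ValueError):
            xm.build_index(genome, 4)

    def test_empty_genome_set(self):
        idx = xm.build_index([], 15)
        assert idx.n_kmers == 0

    def test_duplicate_genome_names(self, genome):
        with pytest.raises(ValueError):
            xm.build_index([genome, genome], 15)

    def test_positions_reproduce_their_kmer(self):
        g = xm.generate_ancestor(500, 1, 0.5, seed=102, name="g")
        idx = xm.build_index(g, 10)
        for kmer, hits in idx.positions().items():
            for rid, pos in hits:
                name, arr = idx.refs[rid]
                assert arr[pos : pos + 10].tobytes() == kmer

    def test_union_index_equals_union_of_parts(self):
        a = xm.generate_ancestor(400, 1, 0.5, seed=103, name="A")
        b = xm.generate_ancestor(400, 1, 0.5, seed=104, name="B")
        union = xm.build_index([a, b], 12)
        parts = {}
        for idx in (xm.build_index(a, 12), xm.build_index(b, 12)):
            for kmer, hits in idx.positions().items():
                parts.setdefault(kmer, set()).update(
                    (idx.ref_name(rid), pos) for rid, pos in hits
                )
        merged = {
            kmer: {(union.ref_name(rid), pos) for rid, pos in hits}
            for kmer, hits in union.positions().items()
        }
        assert merged == parts


class TestAlignRead:
    def test_exact_unique_substring(self, genome, index):
        read = mkread(genome.seq("chr1")[1000:1100])
        rec = xm.align_read(read, index)
        assert rec.mapped and rec.unique
        assert (rec.pos, rec.strand, rec.cigar) == (1000, "+", "100M")
        assert rec.score == 100 and rec.mapq == 60

    def test_planted_duplication_tie(self):
        seq = xm.generate_ancestor(3000, 1, 0.5, seed=105).seq("chr1")
        dup = seq[:400] + seq[1000:1100] + seq[400:1000] + seq[1000:]
        g = xm.Genome("dup", {"chr1": dup})
        idx = xm.build_index(g, 15)
        rec = xm.align_read(mkread(seq[1000:1080]), idx)
        assert not rec.mapped and not rec.unique and rec.mapq == 0

    def test_read_shorter_than_k(self, index):
        rec = xm.align_read(mkread("ACGTACGT"), index)
        assert not rec.mapped and rec.reason == "read shorter than k"

    def test_unalignable_read(self, index):
        rec = xm.align_read(mkread("AC" * 30), index)
        assert not rec.mapped

    def test_reverse_complement_symmetry(self, genome, index):
        fwd = genome.seq("chr1")[2000:2100]
        r1 = xm.align_read(mkread(fwd), index)
        r2 = xm.align_read(mkread(revcomp(fwd)), index)
        assert (r1.pos, r2.pos) == (2000, 2000)
        assert {r1.strand, r2.strand} == {"+", "-"}
        assert r1.score == r2.score

    def test_mismatch_and_gap_scoring(self, genome, index):
        base = genome.seq("chr1")[3000:3100]
        one_mm = "T" if base[50] != "T" else "A"
        rec = xm.align_read(mkread(base[:50] + one_mm + base[51:]), index)
        assert rec.score == 97  # 99 matches - 2 for the mismatch
        with_del = base[:50] + base[52:] + genome.seq("chr1")[3100:3102]
        rec = xm.align_read(mkread(with_del), index)
        assert "D" in rec.cigar
        assert rec.score == 100 - 4 - 2  # full-length match minus 2-base deletion

    def test_score_monotone_in_extra_mismatches(self, genome, index):
        seq = genome.seq("chr1")[4000:4100]
        prev = xm.align_read(mkread(seq), index).score
        read = list(seq)
        rng = np.random.default_rng(106)
        for i in rng.choice(100, size=6, replace=False):
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
            score = xm.align_read(mkread("".join(read)), index).score
            assert score <= prev
            prev = score

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(107)
        p = AlignParams()
        for _ in range(20):
            ref = "".join(rng.choice(list("ACGT"), 600))
            idx = xm.build_index(xm.Genome("g", {"c": ref}), p.k)
            start = int(rng.integers(0, 500))
            read = list(ref[start : start + 80])
            for i in rng.choice(len(read) - 10, size=int(rng.integers(0, 3))):
                read[i + 5] = str(rng.choice(list("ACGT")))
            read = "".join(read)
            if rng.random() < 0.5:
                read = revcomp(read)
            rec = xm.align_read(mkread(read), idx, p)
            best, _ = oracle_best_score(read, ref)
            assert rec.mapped
            assert rec.score == best
            assert cigar_score(read, ref, rec.pos, rec.strand, rec.cigar) == best


class TestSuccessCriterion:
    def test_score_floor(self):
        p = AlignParams()
        rec = unmapped_record("x")
        assert not is_successful(rec, 100, p)
        good = xm.AlignmentRecord("x", "g:c", 0, "+", 60, 60, "100M", True, True)
        assert is_successful(good, 100, p)
        weak = xm.AlignmentRecord("x", "g:c", 0, "+", 59, 60, "100M", True, True)
        assert not is_successful(weak, 100, p)

    def test_seed_offsets(self):
        assert seed_offsets(100, 15) == [0, 25, 50, 75]
        assert seed_offsets(50, 15) == [0, 12, 24]


class TestSamIO:
    def test_roundtrip(self, genome, index, tmp_path):
        reads = [
            mkread(genome.seq("chr1")[i : i + 100], f"q:chr1_{i}_+_0_{i}")
            for i in (100, 700, 1500)
        ]
        recs = list(xm.align_reads(reads, index).values())
        recs.append(unmapped_record("q:chr1_0_+_0_99"))
        path = tmp_path / "out.sam"
        xm.emit_sam(recs, index.ref_lengths(), path, reads={r.read_id: r for r in reads})
        back = xm.ingest_sam(path)
        by_id = {r.read_id: r for r in back}
        for rec in recs:
            got = by_id[rec.read_id]
            assert got.mapped == rec.mapped
            if rec.mapped:
                assert (got.ref_name, got.pos, got.strand) == (
                    rec.ref_name, rec.pos, rec.strand
                )
                assert got.cigar == rec.cigar and got.score == rec.score
                assert got.mapq == rec.mapq and got.unique == rec.unique

    def test_one_based_pos_conversion(self, tmp_path):
        sam = tmp_path / "t.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:g:chr1\tLN:500\n"
            "r1\t0\tg:chr1\t101\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n"
        )
        (rec,) = xm.ingest_sam(sam)
        assert rec.pos == 100

    def test_unmapped_only(self, tmp_path):
        sam = tmp_path / "u.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:g:chr1\tLN:500\n"
            "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n"
        )
        recs = xm.ingest_sam(sam)
        assert len(recs) == 1 and not recs[0].mapped

    def test_unknown_reference_rejected(self, tmp_path):
        sam = tmp_path / "bad.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:alien:chr9\tLN:100\n"
            "r1\t0\talien:chr9\t1\t60\t4M\t*\t0\t0\tACGT\t*\n"
        )
        with pytest.raises(ValueError, match="not in registry"):
            xm.ingest_sam(sam, known_refs={"human:chr1": 500})
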