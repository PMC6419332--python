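"""Chain parsing, coordinate mapping and variant lifting."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import refconcord.chain_liftover as cl
from refconcord import synthetic_data as sd
from refconcord.variants import SNVRecord
from conftest import make_pair

IDENTITY = "chain 1000 srcA 100 + 0 100 tgtA 100 + 0 100 1\n100\n"


class TestParseChain:
    def test_identity_chain(self):
        cs = cl.parse_chain(IDENTITY)
        assert len(cs.chains) == 1
        chain = cs.chains[0]
        assert chain.blocks == [cl.ChainBlock(100)]
        assert (chain.source_name, chain.target_name) == ("srcA", "tgtA")
        assert cs.source_sequence_sizes == {"srcA": 100}

    def test_two_block_chain_requires_consistent_spans(self):
        good = "chain 1000 srcA 100 + 0 100 tgtA 100 + 0 90 1\n40 10 0\n50\n"
        cs = cl.parse_chain(good)
        assert [b.size for b in cs.chains[0].blocks] == [40, 50]
        bad = "chain 1000 srcA 100 + 0 100 tgtA 100 + 0 100 5\n40 10 0\n50\n"
        with pytest.raises(cl.ChainFormatError, match="chain 5"):
            cl.parse_chain(bad)

    def test_empty_stream_gives_empty_chainset(self):
        cs = cl.parse_chain("")
        assert cs.chains == [] and cs.source_sequence_sizes == {}

    @pytest.mark.parametrize("text", [
        "chain 1000 srcA 100 + 0 100 tgtA 100 +\n100\n",  # short header
        "chain 1000 srcA 100 - 0 100 tgtA 100 + 0 100 1\n100\n",  # src strand
        "40 10 0\n",  # data before header
        "chain x srcA 100 + 0 100 tgtA 100 + 0 100 1\n100\n",  # non-numeric
        "chain 1000 srcA 100 + 0 100 tgtA 100 + 0 100 1\n100\n"
        "chain 1000 srcA 100 + 0 100 tgtA 90 + 0 90 2\n90\n",  # size conflict
        "chain 1000 srcA 100 + 0 100 tgtA 100 + 0 100 1\n40 10 0\n",  # truncated
    ])
    def test_malformed_text_raises(self, text):
        with pytest.raises(cl.ChainFormatError):
            cl.parse_chain(text)

    def test_writer_roundtrip_reproduces_chainset(self, small_pair):
        for cs in (small_pair.chain_fwd, small_pair.chain_rev):
            buf = io.StringIO()
            cl.write_chain(cs, buf)
            reparsed = cl.parse_chain(buf.getvalue())
            assert reparsed.chains == cs.chains
            assert reparsed.source_sequence_sizes == cs.source_sequence_sizes
            assert reparsed.target_sequence_sizes == cs.target_sequence_sizes


def _single_chain(score=100, src=("srcA", 1000, 0, 100),
                  tgt=("tgtA", 1000, "+", 50, 150), chain_id=1, blocks=None):
    name, size, start, end = src
    tname, tsize, strand, tstart, tend = tgt
    return cl.Chain(score=score, source_name=name, source_size=size,
                    source_start=start, source_end=end, target_name=tname,
                    target_size=tsize, target_strand=strand,
                    target_start=tstart, target_end=tend,
                    blocks=blocks or [cl.ChainBlock(end - start)],
                    chain_id=chain_id)


def _index(*chains):
    src_sizes = {c.source_name: c.source_size for c in chains}
    tgt_sizes = {c.target_name: c.target_size for c in chains}
    return cl.ChainIndex(cl.ChainSet(list(chains), src_sizes, tgt_sizes))


class TestMapPosition:
    def test_plus_strand_offset(self):
        idx = _index(_single_chain())
        status, mapped = idx.map_position("srcA", 10)
        assert status == cl.CONVERTED
        assert (mapped.target_pos, mapped.strand) == (60, "+")

    def test_minus_strand_local_coordinates(self):
        chain = _single_chain(tgt=("tgtA", 200, "-", 0, 100),
                              src=("srcA", 1000, 0, 100))
        idx = _index(chain)
        status, mapped = idx.map_position("srcA", 10)
        assert status == cl.CONVERTED
        assert mapped.target_pos == 200 - 1 - 10 == 189
        assert mapped.strand == "-"

    def test_gap_vs_absent_chain(self):
        chain = _single_chain(src=("srcA", 1000, 0, 100),
                              tgt=("tgtA", 1000, "+", 0, 90),
                              blocks=[cl.ChainBlock(40, 10, 0), cl.ChainBlock(50)])
        idx = _index(chain)
        assert idx.map_position("srcA", 45)[0] == cl.UNMAPPED_IN_GAP
        assert idx.map_position("srcA", 500)[0] == cl.UNMAPPED_NO_CHAIN
        assert idx.map_position("nope", 5)[0] == cl.UNMAPPED_NO_CHAIN

    def test_equal_score_disagreeing_chains_multimap(self):
        a = _single_chain(score=5, chain_id=1)
        b = _single_chain(score=5, chain_id=2, tgt=("tgtA", 1000, "+", 300, 400))
        assert _index(a, b).map_position("srcA", 10)[0] == cl.REJECTED_MULTIMAP

    def test_highest_score_chain_wins(self):
        a = _single_chain(score=5, chain_id=1)
        b = _single_chain(score=9, chain_id=2, tgt=("tgtA", 1000, "+", 300, 400))
        status, mapped = _index(a, b).map_position("srcA", 10)
        assert status == cl.CONVERTED and mapped.target_pos == 310
        assert mapped.chain_id == 2

    def test_exhaustive_oracle_agreement(self):
        """Index queries equal a linear walk of all blocks at every base."""
        pair = make_pair(length=10_000, seed=13)
        idx = cl.ChainIndex(pair.chain_fwd)
        tgt, strand, span = sd.exhaustive_truth_map(
            pair.chain_fwd, pair.source_name, pair.source_length)
        for pos in range(pair.source_length):
            status, mapped = idx.map_position(pair.source_name, pos)
            if tgt[pos] >= 0:
                assert status == cl.CONVERTED
                assert mapped.target_pos == tgt[pos]
                assert mapped.strand == ("+" if strand[pos] == 1 else "-")
            elif span[pos]:
                assert status == cl.UNMAPPED_IN_GAP
            else:
                assert status == cl.UNMAPPED_NO_CHAIN


class TestLiftVariant:
    def test_plus_strand_alleles_unchanged(self):
        idx = _index(_single_chain())
        seqs = {"tgtA": "N" * 60 + "A" + "N" * 939}
        snv = SNVRecord("srcA", 10, "A", "G", "0/1", 12)
        res = cl.lift_variant(idx, snv, seqs)
        assert res.converted and (res.lifted_ref, res.lifted_alt) == ("A", "G")
        assert res.mapped.target_pos == 60

    def test_minus_strand_complements_alleles(self):
        chain = _single_chain(tgt=("tgtA", 200, "-", 0, 100))
        idx = _index(chain)
        good = {"tgtA": "N" * 189 + "T" + "N" * 10}
        res = cl.lift_variant(idx, SNVRecord("srcA", 10, "A", "G", "1/1"), good)
        assert res.converted and (res.lifted_ref, res.lifted_alt) == ("T", "C")
        bad = {"tgtA": "N" * 200}
        res = cl.lift_variant(idx, SNVRecord("srcA", 10, "A", "G", "1/1"), bad)
        assert res.status == cl.REJECTED_REF_MISMATCH

    def test_ref_mismatch_keep_mode(self):
        idx = _index(_single_chain())
        seqs = {"tgtA": "C" * 1000}
        snv = SNVRecord("srcA", 10, "A", "G", "0/1")
        assert cl.lift_variant(idx, snv, seqs).status == cl.REJECTED_REF_MISMATCH
        kept = cl.lift_variant(idx, snv, seqs, on_ref_mismatch="keep")
        assert kept.converted

    def test_missing_target_sequence_is_hard_error(self):
        idx = _index(_single_chain())
        with pytest.raises(KeyError):
            cl.lift_variant(idx, SNVRecord("srcA", 10, "A", "G", "0/1"), {})

    def test_genotype_carried_through(self, small_pair, small_bundle):
        idx = cl.ChainIndex(small_pair.chain_fwd)
        converted, _, _ = cl.lift_records(idx, small_bundle.source_records,
                                          small_pair.target_sequences)
        by_src = {res.source.sort_key: moved for moved, res in converted}
        for rec in small_bundle.source_records:
            if rec.sort_key in by_src:
                assert by_src[rec.sort_key].genotype == rec.genotype
                assert by_src[rec.sort_key].depth == rec.depth


class TestLiftCallset:
    def test_identity_chain_converts_everything(self, identity_pair, tmp_path):
        bundle = sd.simulate_callsets(identity_pair, 500,
                                      sd.DiscordanceSpec(seed=5))
        sd.write_fixture(bundle, tmp_path)
        tally = cl.lift_callset(tmp_path / "source.vcf", tmp_path / "fwd.chain",
                                tmp_path / "target.fa",
                                tmp_path / "conv.vcf", tmp_path / "rej.vcf")
        assert tally.n_input == tally.n_converted == 500
        assert tally.n_rejected == 0

    def test_partition_and_reject_annotation(self, fixture_dir, tmp_path):
        tally = cl.lift_callset(fixture_dir / "source.vcf",
                                fixture_dir / "fwd.chain",
                                fixture_dir / "target.fa",
                                tmp_path / "conv.vcf", tmp_path / "rej.vcf")
        assert tally.n_input == 1000
        assert tally.n_converted == 950
        assert tally.n_input == tally.n_converted + tally.n_rejected
        import pysam
        with pysam.VariantFile(str(tmp_path / "rej.vcf")) as vcf:
            statuses = [rec.info["LSTAT"] for rec in vcf]
        assert len(statuses) == tally.n_rejected
        assert set(statuses) <= set(cl.REJECT_STATUSES)
        with pysam.VariantFile(str(tmp_path / "conv.vcf")) as vcf:
            positions = [(rec.contig, rec.start) for rec in vcf]
            assert all("SRC" in rec.info for rec in vcf)
        assert positions == sorted(positions)

    def test_direction_mismatch_detected(self, fixture_dir, tmp_path):
        with pytest.raises(ValueError, match="direction"):
            cl.lift_callset(fixture_dir / "target.vcf", fixture_dir / "fwd.chain",
                            fixture_dir / "target.fa",
                            tmp_path / "c.vcf", tmp_path / "r.vcf")


class TestRoundTrip:
    def test_forward_then_reverse_restores_variants(self, small_pair, small_bundle):
        """Bidirectionally covered variants survive a forward+reverse lift
        exactly, including double complementation across inverted blocks."""
        fwd = cl.ChainIndex(small_pair.chain_fwd)
        rev = cl.ChainIndex(small_pair.chain_rev)
        converted, _, _ = cl.lift_records(fwd, small_bundle.source_records,
                                          small_pair.target_sequences)
        assert any(res.mapped.strand == "-" for _, res in converted)
        back, rejects, _ = cl.lift_records(rev, [m for m, _ in converted],
                                           small_pair.source_sequences)
        assert not rejects
        covered = [r for r in small_bundle.source_records
                   if small_pair.truth_tgt[r.pos] >= 0]
        assert sorted(m for m, _ in back) == sorted(covered)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n_del=st.integers(0, 3),
       n_ins=st.integers(0, 3), n_inv=st.integers(0, 2))
def test_mapping_matches_truth_on_random_pairs(seed, n_del, n_ins, n_inv):
    """Property: on random edit scripts, indexed mapping equals the truth
    map on a systematic sample of source positions."""
    pair = make_pair(length=6000, seed=seed, n_deletions=n_del,
                     n_insertions=n_ins, n_inversions=n_inv, edit_len=(50, 300))
    idx = cl.ChainIndex(pair.chain_fwd)
    for pos in range(0, pair.source_length, 17):
        status, mapped = idx.map_position(pair.source_name, pos)
        if pair.truth_tgt[pos] >= 0:
            assert status == cl.CONVERTED
            assert mapped.target_pos == pair.truth_tgt[pos]
        else:
            assert status in (cl.UNMAPPED_IN_GAP, cl.UNMAPPED_NO_CHAIN)
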