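"""Genome ingestion: FASTA parsing, base encoding, chunking, blacklists and the
HDF5 container round trip."""

import h5py
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromacast.errors import DataError
from chromacast.genome import (
    Blacklist,
    GenomeSequence,
    chunk_genome,
    encode_base,
    encode_sequence,
    filter_chunks,
    load_blacklist,
    read_container,
    read_fasta,
    reverse_complement_matrix,
    write_container,
)

CHANNEL_OF = {"C": 0, "A": 1, "T": 2, "G": 3}


def decode_matrix(matrix, pad_mask):
    """Inverse of encode_sequence over real (pad-masked True) rows."""
    out = []
    for row in matrix[pad_mask]:
        if np.allclose(row, 0.25):
            out.append("N")
        else:
            out.append("CATG"[int(np.argmax(row))])
    return "".join(out)


class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n")
        records = read_fasta(p)
        assert len(records) == 1
        assert records[0] == GenomeSequence("chr1", 4, "ACGT")

    def test_multi_record_uppercased_and_ordered(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">a\nacgt\n>b\nNNNN\n")
        records = read_fasta(p)
        assert [r.seq_id for r in records] == ["a", "b"]
        assert [r.residues for r in records] == ["ACGT", "NNNN"]

    def test_wrapped_lines(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">a\n" + "ACGTT\n" * 4)
        assert read_fasta(p)[0].residues == "ACGTT" * 4

    def test_duplicate_header_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">a\nAC\n>a\nGT\n")
        with pytest.raises(DataError, match="duplicate"):
            read_fasta(p)

    @pytest.mark.parametrize("content", ["", "ACGT\n>a\nAC\n"])
    def test_malformed_or_empty_rejected(self, tmp_path, content):
        p = tmp_path / "g.fa"
        p.write_text(content)
        with pytest.raises(DataError):
            read_fasta(p)


class TestEncoding:
    @pytest.mark.parametrize("residue,channel", list(CHANNEL_OF.items()))
    def test_unit_vectors_in_channel_order(self, residue, channel):
        vec = encode_base(residue)
        assert vec[channel] == 1.0 and vec.sum() == 1.0

    def test_n_is_uniform_and_sums_to_one(self):
        assert np.allclose(encode_base("N"), 0.25)
        # every real-base row sums to 1 under the ambiguity rule
        assert np.allclose(encode_sequence("ACGTN").sum(axis=1), 1.0)

    def test_lowercase_accepted(self):
        assert np.array_equal(encode_base("c"), encode_base("C"))

    def test_illegal_symbol_named_in_error(self):
        with pytest.raises(DataError, match="'X'"):
            encode_base("X")
        with pytest.raises(DataError, match="'R'"):
            encode_sequence("ACGRT")

    def test_encode_sequence_matches_per_base(self, rng):
        residues = "".join(rng.choice(list("ACGTN"), size=64))
        expected = np.stack([encode_base(r) for r in residues])
        assert np.array_equal(encode_sequence(residues), expected)


class TestChunking:
    def test_padding_count_on_50kb_sequence(self, rng):
        seq = GenomeSequence("s", 50_000, "".join(rng.choice(list("ACGT"), size=50_000)))
        chunks = chunk_genome(seq, 21_384)
        assert len(chunks) == 3
        assert (chunks[2].start, chunks[2].end) == (42_768, 50_000)
        assert int((~chunks[2].pad_mask).sum()) == 14_152
        assert all(c.pad_mask.all() for c in chunks[:2])
        # padded rows are exactly the zero vector
        assert np.all(chunks[2].matrix[~chunks[2].pad_mask] == 0.0)

    def test_exact_length_single_chunk(self):
        seq = GenomeSequence("s", 8, "ACGTACGT")
        (chunk,) = chunk_genome(seq, 8)
        assert chunk.pad_mask.all() and not chunk.is_gap

    def test_all_n_chunk_is_gap(self):
        seq = GenomeSequence("s", 8, "N" * 8)
        (chunk,) = chunk_genome(seq, 8)
        assert chunk.is_gap

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            chunk_genome(GenomeSequence("s", 4, "ACGT"), 0)

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=80))
    @settings(max_examples=60, deadline=None)
    def test_tiling_reconstructs_sequence(self, residues):
        L = 16
        seq = GenomeSequence("s", len(residues), residues)
        chunks = chunk_genome(seq, L)
        rebuilt = "".join(decode_matrix(c.matrix, c.pad_mask) for c in chunks)
        assert rebuilt == residues
        # non-overlapping tiles covering [0, len)
        assert [c.start for c in chunks] == list(range(0, len(residues), L))

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=80))
    @settings(max_examples=60, deadline=None)
    def test_strand_duality(self, residues):
        L = 16
        seq = GenomeSequence("s", len(residues), residues)
        plus = chunk_genome(seq, L, "+")
        minus = chunk_genome(seq, L, "-")
        for p, m in zip(plus, minus):
            assert np.array_equal(m.matrix, reverse_complement_matrix(p.matrix))
            assert np.array_equal(m.pad_mask, p.pad_mask[::-1])
            assert m.is_gap == p.is_gap

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_gap_rule(self, residues):
        seq = GenomeSequence("s", len(residues), residues)
        for chunk in chunk_genome(seq, 8):
            window = residues[chunk.start:chunk.end]
            assert chunk.is_gap == all(r == "N" for r in window)


class TestFilterAndBlacklist:
    def test_blacklisted_chunks_removed_in_order(self, rng):
        seqs = [GenomeSequence(f"s{i}", 8, "ACGTACGT") for i in range(5)]
        chunks = [c for s in seqs for c in chunk_genome(s, 8)]
        chunks += chunk_genome(GenomeSequence("scaf", 16, "ACGTACGTACGTACGT"), 8)
        out = filter_chunks(chunks, Blacklist(frozenset({"scaf"})))
        assert len(out) == 5
        assert [c.seq_id for c in out] == [f"s{i}" for i in range(5)]

    def test_empty_blacklist_is_identity(self):
        chunks = chunk_genome(GenomeSequence("s", 8, "ACGTACGT"), 8)
        assert filter_chunks(chunks, Blacklist()) == chunks

    def test_gap_retained_when_not_dropping(self):
        chunks = chunk_genome(GenomeSequence("s", 16, "ACGTACGT" + "N" * 8), 8)
        assert len(filter_chunks(chunks, Blacklist(), drop_gaps=False)) == 2
        assert len(filter_chunks(chunks, Blacklist(), drop_gaps=True)) == 1

    def test_plain_list(self, tmp_path):
        p = tmp_path / "bl.txt"
        p.write_text("scaf_12\nchrM\n")
        assert load_blacklist(p).seq_ids == {"scaf_12", "chrM"}

    def test_jsonl_mitochondrion_and_unplaced(self, tmp_path):
        p = tmp_path / "report.jsonl"
        p.write_text(
            '{"sequence_name": "chrM", "assigned_molecule_location_type": "Mitochondrion", "role": "assembled-molecule"}\n'
            '{"sequence_name": "chr1", "assigned_molecule_location_type": "Chromosome", "role": "assembled-molecule"}\n'
            '{"sequence_name": "scaf9", "assigned_molecule_location_type": "Chromosome", "role": "unplaced-scaffold"}\n'
        )
        assert load_blacklist(p).seq_ids == {"chrM", "scaf9"}

    def test_empty_file_empty_blacklist(self, tmp_path):
        p = tmp_path / "bl.txt"
        p.write_text("")
        assert len(load_blacklist(p)) == 0

    def test_unparseable_line_reports_number(self, tmp_path):
        p = tmp_path / "report.jsonl"
        p.write_text('{"sequence_name": "chrM"}\n{broken\n')
        with pytest.raises(DataError, match=":2"):
            load_blacklist(p)


class TestContainer:
    def _toy(self, rng):
        seq = GenomeSequence("chr1", 12, "ACGTNNACGTAC")
        chunks = chunk_genome(seq, 8, "+") + chunk_genome(seq, 8, "-")
        tracks = {"atac": rng.poisson(2.0, size=(len(chunks), 8)).astype(float)}
        return [seq], chunks, tracks

    def test_round_trip_bitwise(self, tmp_path, rng):
        genome, chunks, tracks = self._toy(rng)
        path = tmp_path / "c.h5"
        write_container(path, genome, chunks, tracks, Blacklist(frozenset({"chrX"})))
        cont = read_container(path)
        assert cont.subseq_len == 8
        assert cont.seq_lengths == {"chr1": 12}
        for orig, read in zip(chunks, cont.chunks):
            assert np.array_equal(orig.matrix.astype(np.float32), read.matrix)
            assert np.array_equal(orig.pad_mask, read.pad_mask)
            assert (orig.seq_id, orig.start, orig.end, orig.strand, orig.is_gap) == (
                read.seq_id, read.start, read.end, read.strand, read.is_gap)
        assert np.array_equal(cont.tracks["atac"], tracks["atac"].astype(np.float32))

    def test_missing_coverage_is_prediction_only(self, tmp_path, rng):
        genome, chunks, _ = self._toy(rng)
        path = tmp_path / "c.h5"
        write_container(path, genome, chunks, tracks=None)
        cont = read_container(path)
        assert cont.prediction_only

    def test_schema_mismatch_rejected(self, tmp_path, rng):
        genome, chunks, tracks = self._toy(rng)
        path = tmp_path / "c.h5"
        write_container(path, genome, chunks, tracks)
        with h5py.File(path, "r+") as f:
            f.attrs["schema_version"] = "other-schema-9"
        with pytest.raises(DataError, match="schema"):
            read_container(path)

    def test_corrupted_file_errors(self, tmp_path):
        path = tmp_path / "c.h5"
        path.write_bytes(b"this is not hdf5")
        with pytest.raises(DataError):
            read_container(path)

    def test_track_shape_mismatch_rejected(self, tmp_path, rng):
        genome, chunks, _ = self._toy(rng)
        with pytest.raises(DataError, match="shape"):
            write_container(tmp_path / "c.h5", genome, chunks,
                            {"atac": np.zeros((1, 8))})
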