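import numpy as np
import pytest
from hypothesis import given, strategies as st

from matsec.seqio import (
    AA20,
    FastaParseError,
    LabelError,
    SequenceRecord,
    Window,
    extract_window,
    hobohm2_reduce,
    pairwise_identity,
    read_fasta,
    read_labels,
    window_from_position,
    write_fasta,
)
from .conftest import rng_for


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_parses_entries_in_order(self, tmp_path):
        p = _write(tmp_path, "a.fasta", ">a\nMKT\n>b\nACD\n")
        recs = read_fasta(p)
        assert [(r.id, r.seq) for r in recs] == [("a", "MKT"), ("b", "ACD")]

    def test_uppercases_and_strips_stop_symbol(self, tmp_path):
        p = _write(tmp_path, "a.fasta", ">a\nmkt*\n")
        assert read_fasta(p)[0].seq == "MKT"

    def test_rejects_sequence_before_header(self, tmp_path):
        p = _write(tmp_path, "bad.fasta", "MKT\n>a\nACD\n")
        with pytest.raises(FastaParseError, match="line 1"):
            read_fasta(p)

    def test_rejects_empty_file(self, tmp_path):
        with pytest.raises(FastaParseError):
            read_fasta(_write(tmp_path, "empty.fasta", ""))

    def test_roundtrip_with_writer(self, tmp_path):
        recs = [SequenceRecord("x", "MKT" * 30), SequenceRecord("y", "ACDEF")]
        p = tmp_path / "rt.fasta"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in recs]


class TestReadLabels:
    def test_attaches_labels_and_cleavage(self, tmp_path):
        p = _write(tmp_path, "l.tsv", "p1\tsecretory\t21\nc1\tcytoplasmic\t\n")
        recs = [SequenceRecord("p1", "M" * 50), SequenceRecord("c1", "M" * 40)]
        out = read_labels(p, recs)
        assert out[0].label == "secretory" and out[0].cleavage_pos == 21
        assert out[1].label == "cytoplasmic" and out[1].cleavage_pos is None

    def test_unknown_label_token(self, tmp_path):
        p = _write(tmp_path, "l.tsv", "p2\tsecreted\t20\n")
        with pytest.raises(LabelError, match="secreted"):
            read_labels(p, [SequenceRecord("p2", "M" * 50)])

    def test_duplicate_id(self, tmp_path):
        p = _write(tmp_path, "l.tsv", "p1\tsecretory\t5\np1\tsecretory\t6\n")
        with pytest.raises(LabelError, match="duplicate"):
            read_labels(p, [SequenceRecord("p1", "M" * 50)])

    def test_unmatched_ids_warn(self, tmp_path):
        p = _write(tmp_path, "l.tsv", "ghost\tcytoplasmic\t\n")
        with pytest.warns(UserWarning, match="ghost"):
            read_labels(p, [SequenceRecord("p1", "M" * 10)])


class TestRecordInvariants:
    def test_cytoplasmic_cannot_have_cleavage(self):
        with pytest.raises(ValueError):
            SequenceRecord("c", "M" * 30, "cytoplasmic", 5)

    def test_cleavage_must_be_inside_sequence(self):
        with pytest.raises(ValueError):
            SequenceRecord("s", "M" * 10, "secretory", 10)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            SequenceRecord("e", "")


class TestExtractWindow:
    def test_mature_coordinates(self):
        seq = "".join(AA20[i % 20] for i in range(120))
        rec = SequenceRecord("s", seq, "secretory", 21)
        w = extract_window(rec, "mature", 80)
        assert w.start_pos == 24
        assert w.residues == seq[23:103]
        assert not w.short

    def test_suffix_padding(self):
        w = extract_window(SequenceRecord("s", "MKT"), "preprotein", 5)
        assert w.residues == "MKT--"
        assert w.short  # fewer than 20 real residues

    def test_mature_without_cleavage_is_error(self):
        with pytest.raises(ValueError, match="cleavage"):
            extract_window(SequenceRecord("c", "M" * 50, "cytoplasmic"), "mature", 10)

    @given(st.integers(min_value=1, max_value=60), st.integers(min_value=5, max_value=90))
    def test_length_exact_for_any_valid_input(self, cp, W):
        rec = SequenceRecord("s", "A" * 61, "secretory", cp)
        for kind in ("preprotein", "mature"):
            assert len(extract_window(rec, kind, W).residues) == W

    def test_padding_must_be_suffix(self):
        with pytest.raises(ValueError):
            Window("x", "mature", "AC-DE", 1)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        s = "ACDEFGHIKL" * 5
        assert pairwise_identity(s, s) == 100.0

    def test_single_mismatch_over_ten(self):
        assert pairwise_identity("ACDEFGHIKL", "ACDEFGHIKV") == pytest.approx(90.0)

    def test_disjoint_alphabets(self):
        assert pairwise_identity("AAAAAAAAAA", "VVVVVVVVVV") == 0.0

    def test_only_first_span_residues_compared(self):
        a = "A" * 100 + "W" * 50
        b = "A" * 100 + "Y" * 50
        assert pairwise_identity(a, b, span=100) == 100.0

    def test_symmetry_on_random_pairs(self):
        rng = rng_for("identity-symmetry")
        for _ in range(20):
            a = "".join(rng.choice(list(AA20), size=rng.integers(10, 60)))
            b = "".join(rng.choice(list(AA20), size=rng.integers(10, 60)))
            assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))


def _random_family(rng, n_clusters=3, per_cluster=3, length=60):
    """Sequences grouped into mutation clusters (high within-cluster identity)."""
    out = []
    for c in range(n_clusters):
        base = rng.choice(list(AA20), size=length)
        for m in range(per_cluster):
            seq = base.copy()
            k = rng.integers(0, 10)  # up to ~17% mutations
            pos = rng.choice(length, size=k, replace=False)
            seq[pos] = rng.choice(list(AA20), size=k)
            out.append(SequenceRecord(f"c{c}m{m}", "".join(seq)))
    return out


class TestHobohm:
    def test_worked_three_sequence_example(self):
        # A and B are near-identical; C is unrelated.  A<->B is the only edge,
        # both have one neighbour, the tie-break removes the later one (B).
        base = "ACDEFGHIKLMNPQRSTVWY" * 3
        a = SequenceRecord("A", base)
        b = SequenceRecord("B", base[:-1] + "A")
        c = SequenceRecord("C", "".join("WY"[i % 2] for i in range(60)))
        kept = hobohm2_reduce([a, b, c], cutoff=40)
        assert [r.id for r in kept] == ["A", "C"]

    def test_dissimilar_set_unchanged(self):
        rng = rng_for("hobohm-dissimilar")
        recs = [
            SequenceRecord(f"r{i}", "".join(rng.choice(list(AA20), size=80)))
            for i in range(6)
        ]
        kept = hobohm2_reduce(recs, cutoff=90)
        assert [r.id for r in kept] == [r.id for r in recs]

    def test_idempotent_and_no_pair_above_cutoff(self):
        rng = rng_for("hobohm-idempotent")
        recs = _random_family(rng)
        kept = hobohm2_reduce(recs, cutoff=40)
        for i, x in enumerate(kept):
            for y in kept[i + 1 :]:
                assert pairwise_identity(x.seq, y.seq) <= 40
        again = hobohm2_reduce(kept, cutoff=40)
        assert [r.id for r in again] == [r.id for r in kept]

    def test_classes_reduced_separately(self):
        base = "ACDEFGHIKLMNPQRSTVWY" * 3
        sec = SequenceRecord("s1", base, "secretory", 20)
        cyt = SequenceRecord("c1", base, "cytoplasmic")
        kept = hobohm2_reduce([sec, cyt], cutoff=40)
        assert {r.id for r in kept} == {"s1", "c1"}


def test_window_from_position_matches_manual_slice():
    rec = SequenceRecord("s", "".join(AA20[i % 20] for i in range(100)))
    w = window_from_position(rec, "mature", 30, 11)
    assert w.residues == rec.seq[10:40]
    assert w.start_pos == 11
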