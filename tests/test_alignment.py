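import string

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regraft.alignment import (
    Alignment,
    AlignmentError,
    map_to_reference,
    mask_columns,
    read_alignment,
    write_alignment,
)

AA = "ARNDCQEGHILKMFPSTWYV"


def make_aln(tmp_path, text, name="a.fasta"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadWrite:
    def test_fasta_parse(self, tmp_path):
        p = make_aln(tmp_path, ">t1\nMK-V\n>t2\nmkav\n")
        aln = read_alignment(p)
        assert aln.taxa == ("t1", "t2")
        assert aln.rows == ("MK-V", "MKAV")  # lowercase uppercased
        assert aln.n_sites == 4

    def test_normalisation_of_dot_and_question(self, tmp_path):
        p = make_aln(tmp_path, ">t1\nM.K?\n>t2\nMKAV\n")
        aln = read_alignment(p)
        assert aln.rows[0] == "M-KX"

    def test_ragged_rows_error_names_taxon(self, tmp_path):
        p = make_aln(tmp_path, ">t1\nMKAV\n>bad\nMKAVL\n")
        with pytest.raises(AlignmentError, match="bad"):
            read_alignment(p)

    def test_duplicate_labels_error(self, tmp_path):
        p = make_aln(tmp_path, ">t1\nMKAV\n>t1\nMKAV\n")
        with pytest.raises(AlignmentError, match="t1"):
            read_alignment(p)

    def test_illegal_character_error_reports_position(self, tmp_path):
        p = make_aln(tmp_path, ">t1\nMK1V\n>t2\nMKAV\n")
        with pytest.raises(AlignmentError, match="t1.*column 2"):
            read_alignment(p)

    @pytest.mark.parametrize("fmt", ["fasta", "phylip"])
    def test_round_trip_identity(self, tmp_path, fmt, rng):
        taxa = tuple(f"taxon_{i}" for i in range(6))
        rows = tuple(
            "".join(rng.choice(list(AA + "-X"), size=40)) for _ in taxa
        )
        aln = Alignment(taxa, rows)
        p = tmp_path / f"rt.{fmt}"
        write_alignment(aln, p, fmt)
        back = read_alignment(p, fmt)
        assert back == aln

    def test_phylip_interleaved_accepted(self, tmp_path):
        text = " 2 8\nalpha  MKAV\nbeta   MKAL\n\nVAKM\nLAKM\n"
        p = make_aln(tmp_path, text, "x.phy")
        aln = read_alignment(p, "phylip")
        assert aln.n_sites == 8
        assert aln.row("alpha") == "MKAVVAKM"


class TestMask:
    def test_all_gap_column_dropped(self):
        aln = Alignment(("a", "b", "c"), ("M-", "K-", "V-"))
        masked, mask = mask_columns(aln, max_gap_fraction=0.5)
        assert masked.rows == ("M", "K", "V")
        assert mask.kept == (0,)

    def test_identity_when_threshold_permissive(self):
        aln = Alignment(("a", "b"), ("M-X", "KAV"))
        masked, mask = mask_columns(aln, max_gap_fraction=1.0, drop_ambiguous=False)
        assert masked == aln
        assert mask.kept == (0, 1, 2)

    def test_kept_count_matches_independent_scan(self, rng):
        taxa = tuple(f"t{i}" for i in range(10))
        rows = tuple("".join(rng.choice(list(AA + "--X"), size=50)) for _ in taxa)
        aln = Alignment(taxa, rows)
        frac = 0.3
        masked, mask = mask_columns(aln, max_gap_fraction=frac, drop_ambiguous=True)
        expected = [
            j
            for j in range(50)
            if sum(r[j] == "-" for r in rows) / 10 <= frac
            and not any(r[j] == "X" for r in rows)
        ]
        assert list(mask.kept) == expected
        assert masked.n_sites == len(expected)

    def test_idempotent_at_same_threshold(self, rng):
        taxa = tuple(f"t{i}" for i in range(5))
        rows = tuple("".join(rng.choice(list(AA + "--"), size=30)) for _ in taxa)
        once, mask1 = mask_columns(Alignment(taxa, rows), 0.3)
        twice, mask2 = mask_columns(once, 0.3)
        assert twice == once
        assert mask2.kept == tuple(range(once.n_sites))

    def test_error_when_everything_removed(self):
        aln = Alignment(("a", "b"), ("--", "--"))
        with pytest.raises(AlignmentError, match="threshold|max_gap"):
            mask_columns(aln, max_gap_fraction=0.4)

    def test_mask_tsv_round_trip(self, tmp_path):
        aln = Alignment(("a", "b", "c"), ("M-A", "K-A", "V-A"))
        _, mask = mask_columns(aln, 0.5)
        p = tmp_path / "mask.tsv"
        mask.to_tsv(p)
        from regraft.alignment import ColumnMask

        assert ColumnMask.from_tsv(p) == mask


class TestReferenceMap:
    def test_basic_mapping(self):
        aln = Alignment(("ref", "o"), ("M-KV", "MAKV"))
        assert map_to_reference(aln, "ref") == [1, None, 2, 3]

    def test_all_gap_reference(self):
        aln = Alignment(("ref", "o"), ("---", "MKV"))
        assert map_to_reference(aln, "ref") == [None, None, None]

    def test_unknown_taxon(self):
        aln = Alignment(("a",), ("MKV",))
        with pytest.raises(AlignmentError, match="nope"):
            map_to_reference(aln, "nope")

    def test_matches_cumulative_count_oracle(self, rng):
        row = "".join(rng.choice(list(AA + "---"), size=80))
        aln = Alignment(("ref",), (row,))
        got = map_to_reference(aln, "ref")
        count = 0
        for j, ch in enumerate(row):
            if ch == "-":
                assert got[j] is None
            else:
                count += 1
                assert got[j] == count
        # exactly one distinct position per non-gap residue
        assert len({g for g in got if g is not None}) == sum(c != "-" for c in row)


@settings(max_examples=25, deadline=None)
@given(
    n_taxa=st.integers(2, 6),
    n_sites=st.integers(1, 30),
    data=st.data(),
)
def test_round_trip_property(tmp_path_factory, n_taxa, n_sites, data):
    """write∘read is the identity for random valid alignments, both formats."""
    taxa = tuple(f"t{i}" for i in range(n_taxa))
    alphabet = AA + "-X"
    rows = tuple(
        "".join(
            data.draw(st.sampled_from(alphabet)) for _ in range(n_sites)
        )
        for _ in taxa
    )
    aln = Alignment(taxa, rows)
    tmp = tmp_path_factory.mktemp("rt")
    for fmt in ("fasta", "phylip"):
        p = tmp / f"x.{fmt}"
        write_alignment(aln, p, fmt)
        assert read_alignment(p, fmt) == aln
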