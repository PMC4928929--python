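"""Evolutionary-rate and gene-age computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnevo import CladeProfile, column_rate, gene_age, gene_er, load_annotation
from grnevo.evo_annotation import (
    UninformativeColumnError,
    ages_from_profile,
    load_clade_profile,
    write_annotation,
)


@pytest.mark.parametrize(
    "column, span, convention, expected",
    [
        (list("AAA"), 2.0, "distinct_minus_one", 0.0),
        (list("AAA"), 2.0, "distinct", 0.5),
        (list("ALS-"), 3.0, "distinct", 1.0),
        (list("ALSX"), 3.0, "distinct", 1.0),  # ambiguity chars excluded
        (list("AL"), 4.0, "distinct_minus_one", 0.25),
    ],
)
def test_column_rate_examples(column, span, convention, expected):
    assert column_rate(column, span, convention) == pytest.approx(expected)


def test_column_rate_all_gap_is_uninformative():
    with pytest.raises(UninformativeColumnError):
        column_rate(list("--X"), 2.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from("ACDEFGHIKLMNPQRSTVWY-"), min_size=2, max_size=20),
       st.randoms(use_true_random=False))
def test_column_rate_invariant_under_permutation(column, rnd):
    if all(c == "-" for c in column):
        return
    shuffled = list(column)
    rnd.shuffle(shuffled)
    assert column_rate(column, 3.0) == column_rate(shuffled, 3.0)


def _write_alignment(tmp_path, seqs):
    p = tmp_path / "aln.fasta"
    p.write_text("".join(f">s{i}\n{s}\n" for i, s in enumerate(seqs)))
    return p


def _write_tree(tmp_path, newick="(s0:1.0,s1:1.0);"):
    p = tmp_path / "tree.nwk"
    p.write_text(newick + "\n")
    return p


class TestGeneEr:
    def test_fully_conserved_zero_under_minus_one(self, tmp_path):
        aln = _write_alignment(tmp_path, ["AA", "AA"])
        tree = _write_tree(tmp_path)
        assert gene_er(aln, tree, convention="distinct_minus_one") == 0.0

    def test_mean_of_column_rates(self, tmp_path):
        # span 2.0; column 1 {A,A} -> 1/2 = 0.5, column 2 {A,L} -> 2/2 = 1.0
        aln = _write_alignment(tmp_path, ["AA", "AL"])
        tree = _write_tree(tmp_path)
        assert gene_er(aln, tree, convention="distinct") == pytest.approx(0.75)

    def test_matches_per_column_brute_force(self, tmp_path):
        rng = np.random.default_rng(11)
        ntax, ncol = 12, 40
        seqs = ["".join(rng.choice(list("ACDEFG-"), size=ncol)) for _ in range(ntax)]
        aln = _write_alignment(tmp_path, seqs)
        newick = "(" + ",".join(f"s{i}:0.25" for i in range(ntax)) + ");"
        tree = _write_tree(tmp_path, newick)
        span = ntax * 0.25
        expected = []
        for j in range(ncol):
            residues = {s[j] for s in seqs} - {"-"}
            if len([s[j] for s in seqs if s[j] != "-"]) >= 2 and residues:
                expected.append(len(residues) / span)
        assert gene_er(aln, tree) == pytest.approx(np.mean(expected))

    def test_duplicated_sequences_do_not_change_rate(self, tmp_path):
        seqs = ["ALSK", "AVSK", "GLTK"]
        tree3 = _write_tree(tmp_path, "(s0:1.0,(s1:0.5,s2:0.5):0.5);")
        er1 = gene_er(_write_alignment(tmp_path, seqs), tree3)
        er2 = gene_er(_write_alignment(tmp_path, seqs + seqs), tree3)
        assert er1 == er2

    def test_all_gap_alignment_errors(self, tmp_path):
        aln = _write_alignment(tmp_path, ["--", "--"])
        tree = _write_tree(tmp_path)
        with pytest.raises(ValueError, match="informative"):
            gene_er(aln, tree)


class TestGeneAge:
    def _profile(self, vec):
        return CladeProfile(clades=[f"c{i}" for i in range(13)],
                            presence={"X": np.array(vec, dtype=bool)})

    def test_present_everywhere_is_oldest(self):
        assert gene_age(self._profile([True] * 13), "X") == 0

    def test_human_only_is_youngest(self):
        vec = [False] * 12 + [True]
        assert gene_age(self._profile(vec), "X") == 12

    def test_minimum_present_index(self):
        vec = [i in (3, 7, 12) for i in range(13)]
        assert gene_age(self._profile(vec), "X") == 3

    def test_adding_older_presence_monotone(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            vec = rng.random(13) < 0.3
            vec[12] = True
            age = gene_age(self._profile(list(vec)), "X")
            older = list(vec)
            k = int(rng.integers(0, 13))
            older[k] = True
            assert gene_age(self._profile(older), "X") <= age

    def test_missing_gene_keyerror(self):
        with pytest.raises(KeyError, match="Y"):
            gene_age(self._profile([True] * 13), "Y")


class TestAnnotationIO:
    def test_load_and_merge(self, tmp_path):
        (tmp_path / "er.tsv").write_text("gene\ter\nfoo\t0.5\nbar\t1.25\n")
        (tmp_path / "age.tsv").write_text("gene\tage\nFOO\t3\nbaz\t12\n")
        ann = load_annotation(tmp_path / "er.tsv", tmp_path / "age.tsv")
        assert ann.er["FOO"] == 0.5 and ann.age["FOO"] == 3
        assert "BAR" in ann.er and "BAR" not in ann.age  # partial genes retained
        assert "BAZ" in ann.age and "BAZ" not in ann.er

    def test_non_numeric_value_names_line(self, tmp_path):
        p = tmp_path / "er.tsv"
        p.write_text("gene\ter\na\t0.1\nb\toops\n")
        with pytest.raises(ValueError, match="line 3"):
            load_annotation(er_path=p)

    def test_empty_file_gives_empty_annotation(self, tmp_path):
        p = tmp_path / "er.tsv"
        p.write_text("")
        ann = load_annotation(er_path=p)
        assert len(ann) == 0

    def test_write_read_round_trip(self, tmp_path):
        from grnevo import EvoAnnotation

        ann = EvoAnnotation(er={"A": 0.125, "B": 2.5}, age={"A": 0, "B": 12})
        write_annotation(ann, tmp_path / "er.tsv", tmp_path / "age.tsv")
        back = load_annotation(tmp_path / "er.tsv", tmp_path / "age.tsv")
        assert back.er == ann.er and back.age == ann.age

    def test_clade_profile_round_trip(self, tmp_path):
        header = "gene\t" + "\t".join(f"c{i}" for i in range(13))
        row1 = "g1\t" + "\t".join("1" for _ in range(13))
        row2 = "g2\t" + "\t".join("1" if i >= 5 else "0" for i in range(13))
        (tmp_path / "clades.tsv").write_text(f"{header}\n{row1}\n{row2}\n")
        prof = load_clade_profile(tmp_path / "clades.tsv")
        assert ages_from_profile(prof) == {"G1": 0, "G2": 5}
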