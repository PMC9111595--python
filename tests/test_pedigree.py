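import numpy as np
import pandas as pd
import pytest

from qolped.pedigree import (
    COLUMNS,
    ParseError,
    Pedigree,
    ValidationError,
    classify_pairs,
    kinship_coefficient,
    read_pedigree,
    relatedness_matrices,
    write_pedigree,
)
from conftest import gene_drop_phi, make_ped


class TestIO:
    def test_minimal_family_reads(self, tmp_path):
        p = tmp_path / "ped.tsv"
        p.write_text(
            "\t".join(COLUMNS) + "\n"
            "f1\tfa\t\t\tM\t\t\t50\t8\t53\t7\t0\n"
            "f1\tmo\t\t\tF\t\t\t48\t7\t51\t6\t0\n"
            "f1\tt1\tfa\tmo\tF\tmz1\t\t20\t6\t23\t5\t0\n"
            "f1\tt2\tfa\tmo\tF\tmz1\t\t20\t9\t23\t8\t0\n"
        )
        ped = read_pedigree(p)
        assert len(ped) == 4
        assert ped.n_families == 1
        assert ped.df["mz_group"].notna().sum() == 2

    def test_female_father_rejected(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text(
            ",".join(COLUMNS) + "\n"
            "f1,fa,,,F,,,50,8,53,7,0\n"
            "f1,kid,fa,,M,,,20,6,23,5,0\n"
        )
        with pytest.raises(ValidationError):
            read_pedigree(p)

    def test_unknown_parent_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            make_ped([("f1", "kid", "ghost", None, "M", None, None, 20, 6, 23, 5, 0)])

    def test_phenotype_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            make_ped([("f1", "a", None, None, "M", None, None, 20, 11, 23, 5, 0)])

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("\t".join(COLUMNS) + "\nf1\tonly_two_fields\n")
        with pytest.raises(ParseError, match="line 2"):
            read_pedigree(p)

    def test_writer_round_trip_bit_identical(self, dz_family, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_pedigree(dz_family, p1)
        ped2 = read_pedigree(p1)
        write_pedigree(ped2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert ped2.df.equals(dz_family.df)


class TestKinship:
    def test_textbook_coefficients(self, mz_family):
        assert kinship_coefficient(mz_family, "fa", "t1") == 0.25
        assert kinship_coefficient(mz_family, "t1", "s1") == 0.25  # full sibs
        assert kinship_coefficient(mz_family, "t1", "t2") == 0.5  # MZ merge
        assert kinship_coefficient(mz_family, "fa", "mo") == 0.0
        assert kinship_coefficient(mz_family, "t1", "t1") == 0.5

    def test_symmetry(self, three_gen_family):
        ids = list(three_gen_family.df["person_id"])
        for i in ids:
            for j in ids:
                assert kinship_coefficient(three_gen_family, i, j) == pytest.approx(
                    kinship_coefficient(three_gen_family, j, i)
                )

    def test_relatives_through_mz_twins(self, three_gen_family):
        # child of one MZ twin vs the co-twin: genetic parent-offspring
        assert kinship_coefficient(three_gen_family, "c1", "t2") == 0.25
        # children of MZ sisters: genetic half sibs
        assert kinship_coefficient(three_gen_family, "c1", "c2") == 0.125

    def test_different_families_raise(self, dz_family):
        two = make_ped(
            [tuple(r) for r in dz_family.df.itertuples(index=False)]
            + [("f2", "x", None, None, "M", None, None, 30, 5, 33, 5, 0)]
        )
        with pytest.raises(Exception, match="different families"):
            kinship_coefficient(two, "fa", "x")

    def test_matches_gene_dropping(self, three_gen_family):
        """Recursive kinship agrees with a Monte-Carlo gene-dropping
        estimate within 3 standard errors on every pair."""
        mc = gene_drop_phi(three_gen_family, "g1", n_rep=20_000, seed=11)
        for (i, j), (phat, se) in mc.items():
            phi = kinship_coefficient(three_gen_family, i, j)
            assert abs(phi - phat) <= max(3 * se, 1e-12), (i, j, phi, phat)


class TestRelatednessMatrices:
    def test_nuclear_family_values(self, dz_family):
        rel = relatedness_matrices(dz_family, "f1")
        idx = {p: k for k, p in enumerate(rel.member_order)}
        A, D, H = rel.additive, rel.dominance, rel.household
        assert A[idx["fa"], idx["t1"]] == 0.5
        assert A[idx["t1"], idx["t2"]] == 0.5
        assert A[idx["fa"], idx["mo"]] == 0.0
        assert D[idx["t1"], idx["t2"]] == 0.25
        assert D[idx["fa"], idx["t1"]] == 0.0
        assert D[idx["fa"], idx["mo"]] == 0.0
        assert H[idx["fa"], idx["mo"]] == 1.0
        assert H[idx["fa"], idx["t1"]] == 0.0
        assert np.all(np.diag(A) == 1) and np.all(np.diag(D) == 1)

    def test_mz_pair_all_ones(self):
        ped = make_ped([
            ("f1", "t1", None, None, "F", "m", None, 20, 6, 23, 5, 0),
            ("f1", "t2", None, None, "F", "m", None, 20, 7, 23, 6, 0),
        ])
        rel = relatedness_matrices(ped, "f1")
        assert np.array_equal(rel.additive, np.ones((2, 2)))
        assert np.array_equal(rel.dominance, np.ones((2, 2)))

    def test_additive_entries_canonical_and_psd(self, three_gen_family):
        rel = relatedness_matrices(three_gen_family, "g1")
        allowed = {0.0, 0.125, 0.25, 0.5, 1.0}
        assert set(np.round(rel.additive, 10).ravel()) <= allowed
        assert np.linalg.eigvalsh(rel.additive).min() >= -1e-10
        assert np.linalg.eigvalsh(rel.dominance).min() >= -1e-10
        # household blocks are at most spouse pairs
        off = rel.household - np.eye(len(rel.member_order))
        assert off.sum(axis=0).max() <= 1


class TestClassifyPairs:
    def test_hand_built_family_labels(self, mz_family):
        pairs = classify_pairs(mz_family)
        lab = {
            tuple(sorted((a, b))): t
            for a, b, t in pairs.itertuples(index=False)
        }
        assert lab[("fa", "mo")] == "spouse"
        assert lab[("t1", "t2")] == "MZF"
        assert lab[("s1", "t1")] == "sister-sister"  # twin x non-twin sister
        assert lab[("mo", "t1")] == "mother-daughter"
        assert lab[("fa", "s1")] == "father-daughter"

    def test_dz_twins_vs_ordinary_sibs(self, dz_family):
        pairs = classify_pairs(dz_family)
        types = dict(
            zip(zip(pairs["id1"], pairs["id2"]), pairs["relationship_type"])
        )
        assert types[("t1", "t2")] == "DZM"  # co-born: identical recorded age

    def test_parent_stored_first(self, dz_family):
        pairs = classify_pairs(dz_family)
        po = pairs[pairs["relationship_type"].str.startswith(("mother", "father"))]
        assert set(po["id1"]) <= {"fa", "mo"}

    def test_partition_counts(self, three_gen_family):
        pairs = classify_pairs(three_gen_family)
        n = len(three_gen_family)
        assert len(pairs) == n * (n - 1) // 2
        assert pairs["relationship_type"].isin(
            [
                "spouse", "MZF", "brother-sister", "mother-daughter", "mother-son",
                "father-daughter", "father-son", "other", "sister-sister",
            ]
        ).all()
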