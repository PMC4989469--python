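"""Tree/trait I/O, pruning geometry, and iterative tip matching."""

import numpy as np
import pytest

from ploidyshift import (
    TimeTree,
    TraitRecord,
    match_tips,
    prune_to,
    read_trait_table,
    read_tree_set,
    write_trait_table,
    write_tree_set,
)
from ploidyshift.tree import MissingBranchLengthError
from ploidyshift.tree_io import MatchConflictError, TraitTableError, TreeFormatError

from conftest import random_tree


class TestTreeReading:
    def test_minimal_newick(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B:1):0;\n")
        trees = read_tree_set(p)
        assert len(trees) == 1
        t = trees[0]
        assert sorted(t.tip_labels) == ["A", "B"]
        assert np.allclose(sorted(t.blen[: t.n_tips]), [1.0, 1.0])

    def test_nexus_translate_equivalent_to_newick(self, tmp_path):
        nexus = (
            "#NEXUS\nBEGIN TAXA;\nDIMENSIONS NTAX=3;\nTAXLABELS Aa Bb Cc;\nEND;\n"
            "BEGIN TREES;\nTRANSLATE 1 Aa, 2 Bb, 3 Cc;\n"
            "TREE one = ((1:1.0,2:1.0):0.5,3:1.5);\nEND;\n"
        )
        p1 = tmp_path / "t.nex"
        p1.write_text(nexus)
        p2 = tmp_path / "t.nwk"
        p2.write_text("((Aa:1.0,Bb:1.0):0.5,Cc:1.5);\n")
        t_nex = read_tree_set(p1)[0]
        t_nwk = read_tree_set(p2)[0]
        assert sorted(t_nex.tip_labels) == sorted(t_nwk.tip_labels)
        for a in t_nex.tip_labels:
            for b in t_nex.tip_labels:
                ia, ib = t_nex.tip_index(a), t_nex.tip_index(b)
                ja, jb = t_nwk.tip_index(a), t_nwk.tip_index(b)
                assert t_nex.patristic(ia, ib) == pytest.approx(t_nwk.patristic(ja, jb))

    def test_round_trip_identity_on_tree_set(self, tmp_path):
        trees = [random_tree(10, seed=s) for s in range(20)]
        p = tmp_path / "set.nwk"
        write_tree_set(trees, p)
        back = read_tree_set(p)
        assert len(back) == 20
        for a, b in zip(trees, back):
            assert a.tip_labels == b.tip_labels or sorted(a.tip_labels) == sorted(b.tip_labels)
            for u in a.tip_labels:
                for v in a.tip_labels:
                    da = a.patristic(a.tip_index(u), a.tip_index(v))
                    db = b.patristic(b.tip_index(u), b.tip_index(v))
                    assert db == pytest.approx(da, rel=1e-9)

    def test_unparseable_file_raises_format_error(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A:1,B:1\n")
        with pytest.raises(TreeFormatError):
            read_tree_set(p)

    def test_missing_branch_lengths_fatal(self, tmp_path):
        p = tmp_path / "nolen.nwk"
        p.write_text("((A,B),C);\n")
        with pytest.raises(MissingBranchLengthError):
            read_tree_set(p)


class TestPruning:
    def test_keep_all_is_identity(self):
        t = random_tree(12, seed=1)
        p = prune_to(t, t.tip_labels)
        assert sorted(p.tip_labels) == sorted(t.tip_labels)
        for a in t.tip_labels:
            for b in t.tip_labels:
                assert p.patristic(p.tip_index(a), p.tip_index(b)) == pytest.approx(
                    t.patristic(t.tip_index(a), t.tip_index(b))
                )

    def test_path_length_conservation_cherry(self):
        t = TimeTree.from_newick("((A:1,B:1):1,C:2);")
        p = prune_to(t, ["A", "C"])
        assert sorted(p.tip_labels) == ["A", "C"]
        assert p.blen[p.tip_index("A")] == pytest.approx(2.0)
        assert p.blen[p.tip_index("C")] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", [0, 7, 21])
    def test_patristic_distances_preserved(self, seed):
        t = random_tree(50, seed=seed)
        rng = np.random.default_rng(seed)
        keep = list(rng.choice(t.tip_labels, size=20, replace=False))
        p = prune_to(t, keep)
        for i in range(0, 20, 3):
            for j in range(i + 1, 20, 3):
                a, b = keep[i], keep[j]
                assert p.patristic(p.tip_index(a), p.tip_index(b)) == pytest.approx(
                    t.patristic(t.tip_index(a), t.tip_index(b)), rel=1e-9
                )

    def test_depths_preserved(self):
        t = random_tree(30, seed=5)
        keep = t.tip_labels[:7]
        p = prune_to(t, keep)
        for lab in keep:
            assert p.depths()[p.tip_index(lab)] == pytest.approx(
                t.depths()[t.tip_index(lab)], rel=1e-9
            )

    def test_too_few_labels(self):
        t = random_tree(5, seed=0)
        with pytest.raises(ValueError):
            prune_to(t, t.tip_labels[:1])


def _rec(taxon, system="diplodiploid", **kw):
    return TraitRecord(taxon=taxon, system=system, **kw)


class TestMatching:
    def test_exact_species_matches(self):
        t = TimeTree.from_newick("((Aa_x:1,Bb_y:1):1,Cc_z:2);")
        table = [_rec("Aa x", count_2n=10), _rec("Bb y", count_2n=12)]
        ds = match_tips(t, table)
        assert ds.tree.n_tips == 2
        assert set(ds.traits["match_level"]) == {"species"}

    def test_genus_collapse(self):
        t = TimeTree.from_newick(
            "(((Gg_a:1,Gg_b:1):0.5,Gg_c:1.5):0.5,(Hh_a:1,Ii_a:1):1);"
        )
        table = [
            _rec("Gg something", genus="Gg", count_2n=14, system="haplodiploid"),
            _rec("Hh a", count_2n=20),
            _rec("Ii a", count_2n=22),
        ]
        ds = match_tips(t, table)
        assert ds.tree.n_tips == 3
        row = ds.traits[ds.traits["match_level"] == "genus"].iloc[0]
        assert row["taxon"].lower() == "gg"
        assert row["system"] == "haplodiploid"
        # collapsed tip ends at the genus crown depth (stem retained)
        orig_crown_depth = 0.5  # the MRCA of (Gg_a, Gg_b, Gg_c) sits at depth 0.5
        tip_depth = ds.tree.depths()[ds.tree.tip_index(row["taxon"])]
        assert tip_depth == pytest.approx(orig_crown_depth)

    def test_family_collapse(self):
        # two tips identified only to family level on the tree
        t = TimeTree.from_newick("((FamA_sp1:1,FamA_sp2:1):1,(Hh_a:1.5,Ii_a:1.5):0.5);")
        table = [
            _rec("Hh a", count_2n=20),
            _rec("Ii a", count_2n=22),
            _rec("Other sp", genus="Other", family="FamA", count_2n=8),
            _rec("Other2 sp", genus="Other2", family="FamA", count_2n=10),
        ]
        ds = match_tips(t, table)
        fam_rows = ds.traits[ds.traits["match_level"] == "family"]
        assert len(fam_rows) == 1
        assert fam_rows.iloc[0]["count_2n"] == pytest.approx(9.0)

    def test_mean_count_over_records(self):
        t = TimeTree.from_newick("((Aa_x:1,Bb_y:1):1,Cc_z:2);")
        table = [
            _rec("Aa x", count_2n=14),
            _rec("Aa x", count_2n=16),
            _rec("Bb y", count_2n=12),
        ]
        ds = match_tips(t, table)
        row = ds.traits[ds.traits["taxon"] == "Aa_x"].iloc[0]
        assert row["count_2n"] == pytest.approx(15.0)
        assert row["n_records"] == 2

    def test_conflicting_system_is_error(self):
        t = TimeTree.from_newick("((Aa_x:1,Bb_y:1):1,Cc_z:2);")
        table = [
            _rec("Aa x", system="diplodiploid"),
            _rec("Aa x", system="haplodiploid"),
            _rec("Bb y"),
        ]
        with pytest.raises(MatchConflictError, match="Aa_x"):
            match_tips(t, table)

    def test_no_overlap_is_error(self):
        t = TimeTree.from_newick("(A_a:1,B_b:1);")
        with pytest.raises(ValueError):
            match_tips(t, [_rec("Zz z")])

    def test_match_is_idempotent(self):
        t = random_tree(12, seed=4)
        table = [_rec(lab, count_2n=10 + i) for i, lab in enumerate(t.tip_labels[:9])]
        ds1 = match_tips(t, table)
        recs = [
            TraitRecord(taxon=r["taxon"], system=r["system"], count_2n=r["count_2n"])
            for _, r in ds1.traits.iterrows()
        ]
        ds2 = match_tips(ds1.tree, recs)
        assert ds2.tree.n_tips == ds1.tree.n_tips
        assert list(ds2.traits["taxon"]) == list(ds1.traits["taxon"])
        assert np.allclose(ds2.traits["count_2n"], ds1.traits["count_2n"])


class TestTraitTable:
    def test_round_trip(self, tmp_path):
        recs = [
            _rec("Aa x", count_2n=12, infraorder="IO1", family="F1", genus="Aa",
                 sex_determination="XY"),
            _rec("Bb y", system="haplodiploid"),
        ]
        p = tmp_path / "traits.csv"
        write_trait_table(recs, p)
        back = read_trait_table(p)
        assert [r.taxon for r in back] == ["Aa x", "Bb y"]
        assert back[0].count_2n == 12
        assert back[1].count_2n is None
        assert back[0].sex_determination == "XY"

    def test_validation_errors(self):
        with pytest.raises(TraitTableError):
            TraitRecord(taxon="X", system="parthenogenetic")
        with pytest.raises(TraitTableError):
            TraitRecord(taxon="X", system="diplodiploid", count_2n=300)
        with pytest.raises(TraitTableError):
            TraitRecord(taxon="X", system="diplodiploid", sex_determination="ZW")
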