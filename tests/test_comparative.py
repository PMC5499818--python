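from itertools import product

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ribocub import (
    TRNAPool,
    canberra_distance,
    codons_lacking_trna,
    cognate_codon,
    concordance_percent,
    distance_matrix,
    favourite_concordance,
    gc_stats,
    load_species_trna_summary,
    ols_regression,
    species_summary,
    upgma,
)
from ribocub.comparative import mean_rscu, read_trna_tsv, write_trna_tsv
from ribocub.rscu import CodonCountTable, CodonWindow, compute_rscu

from conftest import random_count_table

ALL_CODONS = ["".join(p) for p in product("ACGT", repeat=3)]


class TestCognateCodon:
    @pytest.mark.parametrize("anticodon, codon", [
        ("TTT", "AAA"),
        ("AGC", "GCT"),
        ("CAT", "ATG"),  # the Met initiator anticodon
    ])
    def test_reverse_complement(self, anticodon, codon):
        assert cognate_codon(anticodon) == codon

    def test_involution(self):
        for c in ALL_CODONS:
            assert cognate_codon(cognate_codon(c)) == c

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            cognate_codon("AUG")


class TestCodonsLackingTRNA:
    def test_empty_pool_lacks_all_59(self, code):
        assert len(codons_lacking_trna(TRNAPool({}))) == 59

    def test_full_pool_lacks_none(self):
        pool = TRNAPool({a: 1 for a in ALL_CODONS})
        assert codons_lacking_trna(pool) == set()

    def test_single_missing_anticodon(self):
        pool = TRNAPool({a: 1 for a in ALL_CODONS if a != "AGC"})
        assert codons_lacking_trna(pool) == {"GCT"}

    def test_antitone_in_pool(self, code):
        rng = np.random.default_rng(0)
        copies = {a: int(rng.integers(0, 3)) for a in ALL_CODONS}
        before = codons_lacking_trna(TRNAPool(copies))
        copies[rng.choice([a for a, n in copies.items() if n == 0])] = 5
        after = codons_lacking_trna(TRNAPool(copies))
        assert after <= before


def build_concordance_fixture(code, n_discordant=3, n_pref_lacking=2):
    """Preferred map + pool where exactly 18−n_discordant amino acids concord
    and n_pref_lacking of the discordant preferred codons lack tRNA."""
    preferred, copies = {}, {}
    for i, aa in enumerate(code.degenerate_aas):
        synonyms = code.synonyms(aa)
        preferred[aa] = synonyms[0]
        discordant = i >= len(code.degenerate_aas) - n_discordant
        lacking = discordant and i >= len(code.degenerate_aas) - n_pref_lacking
        for j, c in enumerate(synonyms):
            if j == 0:
                copies[cognate_codon(c)] = 0 if lacking else (1 if discordant else 10)
            elif j == 1:
                copies[cognate_codon(c)] = 10 if discordant else 1
            else:
                copies[cognate_codon(c)] = 1
    return preferred, TRNAPool(copies)


class TestFavouriteConcordance:
    def test_full_concordance(self, code):
        preferred, pool = build_concordance_fixture(code, n_discordant=0, n_pref_lacking=0)
        result = favourite_concordance(preferred, pool)
        assert result.n_concordant == 18 and result.n_fav_lacking == 0

    def test_constructed_fifteen_of_eighteen(self, code):
        preferred, pool = build_concordance_fixture(code)
        result = favourite_concordance(preferred, pool)
        assert result.n_concordant == 15
        assert result.n_fav_lacking == 2

    def test_empty_pool_degenerate_all_tie_at_zero(self, code):
        preferred, _ = build_concordance_fixture(code, 0, 0)
        result = favourite_concordance(preferred, TRNAPool({}))
        assert result.n_concordant == 18 and result.n_fav_lacking == 18

    def test_missing_amino_acids_non_concordant(self, code):
        preferred, pool = build_concordance_fixture(code, 0, 0)
        del preferred["F"]
        result = favourite_concordance(preferred, pool)
        assert result.n_concordant == 17 and result.missing_aas == ("F",)


class TestOLSRegression:
    def test_perfect_line(self):
        points = {"a": (0, 0), "b": (1, 1), "c": (2, 2)}
        fit = ols_regression(points)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self):
        df = load_species_trna_summary()
        points = {r.species: (r.total_trnas, r.n_lacking) for r in df.itertuples()}
        fit = ols_regression(points, exclude=["H. capsulatum"])
        # closed-form least squares, independent of the implementation path
        kept = [(x, y) for s, (x, y) in points.items() if s != "H. capsulatum"]
        x, y = np.array(kept, dtype=float).T
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert fit.slope == pytest.approx(slope, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ols_regression({"a": (0, 0), "b": (1, 1)})

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            ols_regression({"a": (1, 0), "b": (1, 1), "c": (1, 2)})


class TestCanberra:
    @pytest.mark.parametrize("x, y, expected", [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 0], [0, 1], 2.0),
        ([1, 3], [3, 1], 1.0),
        ([0, 1], [0, 2], 1 / 3),  # 0/0 term contributes nothing
    ])
    def test_examples(self, x, y, expected):
        assert canberra_distance(x, y) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            canberra_distance([1, 2], [1, 2, 3])

    def test_against_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.integers(0, 10, size=(2, 12)).astype(float)
            brute = sum(
                abs(a - b) / (abs(a) + abs(b))
                for a, b in zip(x, y) if abs(a) + abs(b) > 0
            )
            assert canberra_distance(x, y) == pytest.approx(brute)


def tree_clusters(dendrogram):
    """Internal nodes as {frozenset(leaves): height} for comparison."""
    out = {}

    def walk(node):
        if node.is_leaf:
            return frozenset([node.name])
        leaves = frozenset().union(*(walk(c) for c in node.children))
        out[leaves] = node.height
        return leaves

    walk(dendrogram.root)
    return out


def scipy_clusters(d, labels):
    Z = linkage(squareform(d, checks=False), method="average")
    members = {i: frozenset([labels[i]]) for i in range(len(labels))}
    out = {}
    for k, (i, j, dist, _) in enumerate(Z):
        merged = members[int(i)] | members[int(j)]
        members[len(labels) + k] = merged
        out[merged] = dist / 2
    return out


class TestUPGMA:
    def test_two_leaves(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        tree = upgma(d, ["A", "B"])
        assert tree.root.height == pytest.approx(1.5)
        assert sorted(c.name for c in tree.root.children) == ["A", "B"]

    def test_three_leaf_hand_example(self):
        d = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float)
        tree = upgma(d, ["A", "B", "C"])
        clusters = tree_clusters(tree)
        assert clusters[frozenset("AB")] == pytest.approx(1.0)
        assert clusters[frozenset("ABC")] == pytest.approx(4.0)

    def test_identical_rows_merge_in_label_order(self):
        d = np.full((3, 3), 6.0) - 6.0 * np.eye(3)
        tree = upgma(d, ["C", "A", "B"])
        clusters = tree_clusters(tree)
        assert clusters[frozenset("AB")] == pytest.approx(3.0)
        assert clusters[frozenset("ABC")] == pytest.approx(3.0)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            upgma(np.array([[0, 1], [2, 0]], dtype=float), ["A", "B"])

    def test_ultrametric_and_newick_round_trip(self):
        import skbio

        rng = np.random.default_rng(3)
        x = rng.random((6, 4))
        d, labels = distance_matrix({f"s{i}": x[i] for i in range(6)})
        tree = upgma(d, labels)
        assert tree.is_ultrametric()
        parsed = skbio.TreeNode.read([tree.to_newick()])
        assert sorted(t.name for t in parsed.tips()) == sorted(labels)
        # depths survive the Newick round trip
        depths = tree.leaf_depths()
        for tip in parsed.tips():
            assert tip.accumulate_to_ancestor(parsed) == pytest.approx(depths[tip.name])

    def test_agrees_with_scipy_average_linkage(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            d = squareform(rng.random(10))  # 5x5 symmetric
            labels = list("ABCDE")
            mine = tree_clusters(upgma(d, labels))
            ref = scipy_clusters(d, labels)
            assert set(mine) == set(ref)
            for k in ref:
                assert mine[k] == pytest.approx(ref[k])


class TestGCStats:
    def preferred_ending(self, code, n_gc):
        pref = {}
        for i, aa in enumerate(code.degenerate_aas):
            synonyms = code.synonyms(aa)
            want_gc = i < n_gc
            pref[aa] = next(
                (c for c in synonyms if (c[-1] in "GC") == want_gc), synonyms[0]
            )
        return pref

    @pytest.mark.parametrize("n_gc, expected", [(18, 100.0), (0, 0.0), (9, 50.0)])
    def test_lastbase_percent(self, code, n_gc, expected):
        pref = self.preferred_ending(code, n_gc)
        # every degenerate aa has both G/C- and A/T-ending synonyms
        assert all((pref[aa][-1] in "GC") == (i < n_gc)
                   for i, aa in enumerate(code.degenerate_aas))
        _, lastbase = gc_stats("ACGT", pref)
        assert lastbase == pytest.approx(expected)

    def test_genome_gc_percent(self, code):
        pref = self.preferred_ending(code, 18)
        gc, _ = gc_stats({"c1": "GGCC", "c2": "AATT"}, pref)
        assert gc == pytest.approx(50.0)

    def test_empty_sequences_rejected(self, code):
        with pytest.raises(ValueError):
            gc_stats("NNN", self.preferred_ending(code, 0))


class TestSpeciesSummary:
    @pytest.mark.parametrize("n, expected", [(15, 83.3), (9, 50.0), (0, 0.0)])
    def test_percentage_formatting(self, n, expected):
        assert concordance_percent(n) == expected

    def test_assembled_row(self, code):
        preferred, pool = build_concordance_fixture(code)
        summary = species_summary("test_sp", preferred, pool, gc_sequences="GGCCAATT")
        assert summary.n_concordant == 15
        assert summary.concordance_percent == 83.3
        assert summary.total_trnas == pool.total
        assert summary.n_lacking == len(codons_lacking_trna(pool))
        assert summary.genome_gc_percent == pytest.approx(50.0)
        row = summary.to_row()
        assert row["species"] == "test_sp" and row["n_fav_lacking"] == 2


def test_trna_tsv_round_trip(tmp_path):
    pool = TRNAPool({"AAA": 3, "AGC": 0, "CAT": 7})
    path = tmp_path / "trna.tsv"
    write_trna_tsv(pool, path)
    assert read_trna_tsv(path).copies == pool.copies


def test_trna_tsv_sums_isodecoders(tmp_path):
    path = tmp_path / "trna.tsv"
    path.write_text("anticodon\tcopy_count\nAGC\t2\nAGC\t3\n")
    assert read_trna_tsv(path).copies == {"AGC": 5}


def test_mean_rscu_averages_defined_codons(code):
    rng = np.random.default_rng(5)
    vectors = [compute_rscu(random_count_table(rng)) for _ in range(3)]
    mean = mean_rscu(vectors)
    codon = code.analysis_codons[0]
    defined = [v.values[codon] for v in vectors if codon in v.values]
    if defined:
        assert mean.values[codon] == pytest.approx(np.mean(defined))
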