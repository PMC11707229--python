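"""Contiguity, degree of synteny, and ubiTUV architecture classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import rel_entr

from quinrep.annotation import AnnotatedGenome, GeneFeature
from quinrep.synteny import (
    SyntenyParams,
    TripletOccurrence,
    bernoulli_relative_entropy,
    class_counts,
    classify_ubiTUV_architecture,
    contiguity_score,
    enumerate_triplet_occurrences,
    intergenic_distance,
    proximity_threshold,
    synteny_degree_matrix,
)

L = 100_000


def feat(start, end, strand="+", tag="x", label="", replicon="r", gid="g", length=L):
    return GeneFeature(gid, replicon, length, start, end, strand, tag, label)


def genome(gid, spec):
    """spec: list of (label, start, end, strand[, replicon])."""
    feats = []
    for i, item in enumerate(spec):
        label, start, end, strand = item[:4]
        repl = item[4] if len(item) > 4 else "r"
        feats.append(
            GeneFeature(gid, repl, L, start, end, strand, f"{gid}_{i}", label)
        )
    return AnnotatedGenome(gid, feats)


class TestIntergenicDistance:
    def test_boundary_500_not_contiguous(self):
        a, b = feat(100, 400), feat(901, 1500)
        assert intergenic_distance(a, b) == 500  # not < 500: NOT contiguous

    def test_499_contiguous(self):
        a, b = feat(100, 400), feat(900, 1500)
        assert intergenic_distance(a, b) == 499

    def test_overlap_is_zero(self):
        assert intergenic_distance(feat(100, 400), feat(300, 600)) == 0

    def test_symmetric(self):
        a, b = feat(100, 400), feat(900, 1500)
        assert intergenic_distance(a, b) == intergenic_distance(b, a)

    def test_different_replicons_not_comparable(self):
        a = feat(100, 400, replicon="r1")
        b = feat(100, 400, replicon="r2")
        assert intergenic_distance(a, b) is None

    def test_circular_wraparound(self):
        a = feat(1, 400)
        b = feat(L - 200, L)
        assert intergenic_distance(a, b) == L - 601
        assert intergenic_distance(a, b, circular=True) == 0  # adjacent over origin


class TestProximityThreshold:
    @pytest.mark.parametrize(
        "length,expected", [(5_000_000, 50_000), (500_000, 5_000), (1_000_000, 10_000)]
    )
    def test_printed_values(self, length, expected):
        assert proximity_threshold(length, 0.02) == expected

    def test_linearity_in_p(self):
        assert proximity_threshold(1_000_000, 0.04) == 2 * proximity_threshold(
            1_000_000, 0.02
        )


class TestSyntenyDegree:
    def test_zero_at_f_equals_p(self):
        assert bernoulli_relative_entropy(0.02, 0.02) == 0.0

    def test_full_proximity_is_log_inverse_p(self):
        assert bernoulli_relative_entropy(1.0, 0.02) == pytest.approx(
            math.log(50), abs=1e-12
        )

    def test_equals_bernoulli_kl_on_grid(self):
        for f in np.linspace(0, 1, 21):
            for p in (0.01, 0.02, 0.1, 0.5, 0.9):
                oracle = float(rel_entr(f, p) + rel_entr(1 - f, 1 - p))
                assert bernoulli_relative_entropy(f, p) == pytest.approx(
                    oracle, abs=1e-12
                )

    def test_strictly_increasing_above_p(self):
        grid = np.linspace(0.02, 1.0, 50)
        vals = [bernoulli_relative_entropy(f, 0.02) for f in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_matrix_f_and_denominator(self):
        # 3 genomes with both genes; proximal in 2 (d(L=1e5, p=0.02) = 1000)
        genomes = [
            genome("g1", [("a", 100, 700, "+"), ("b", 1200, 1800, "+")]),  # gap 499
            genome("g2", [("a", 100, 700, "+"), ("b", 1500, 2100, "+")]),  # gap 799
            genome("g3", [("a", 100, 700, "+"), ("b", 50_000, 50_600, "+")]),  # far
            genome("g4", [("a", 100, 700, "+")]),  # no b: out of denominator
        ]
        df = synteny_degree_matrix(genomes, SyntenyParams(p=0.02))
        row = df[(df.gene_i == "a") & (df.gene_j == "b")].iloc[0]
        assert row.n == 3
        assert row.f == pytest.approx(2 / 3)
        assert row.D == pytest.approx(bernoulli_relative_entropy(2 / 3, 0.02))

    def test_different_replicons_not_proximal(self):
        genomes = [
            genome("g1", [("a", 100, 700, "+", "r1"), ("b", 800, 1400, "+", "r2")])
        ]
        df = synteny_degree_matrix(genomes)
        row = df.iloc[0]
        assert row.n == 1 and row.f == 0.0

    def test_never_cooccurring_pair_has_empty_denominator(self):
        genomes = [
            genome("g1", [("a", 100, 700, "+")]),
            genome("g2", [("b", 100, 700, "+")]),
        ]
        df = synteny_degree_matrix(genomes)
        row = df.iloc[0]
        assert row.n == 0 and np.isnan(row.D)


class TestContiguityScore:
    def build(self, n_i, n_j, n_both_adjacent):
        genomes = []
        k = 0
        for _ in range(n_both_adjacent):  # both, adjacent
            genomes.append(genome(f"g{k}", [("i", 100, 700, "+"), ("j", 900, 1500, "+")]))
            k += 1
        for _ in range(n_j - n_both_adjacent):  # both, far apart
            genomes.append(
                genome(f"g{k}", [("i", 100, 700, "+"), ("j", 60_000, 60_600, "+")])
            )
            k += 1
        for _ in range(n_i - n_j):  # i only
            genomes.append(genome(f"g{k}", [("i", 100, 700, "+")]))
            k += 1
        return genomes

    def test_printed_definition(self):
        genomes = self.build(10, 8, 4)
        assert contiguity_score("i", "j", genomes) == pytest.approx(0.5)

    def test_always_adjacent_scores_one(self):
        assert contiguity_score("i", "j", self.build(5, 5, 5)) == 1.0

    def test_never_adjacent_scores_zero(self):
        assert contiguity_score("i", "j", self.build(5, 5, 0)) == 0.0

    def test_missing_gene_reports_no_edge(self):
        assert contiguity_score("i", "zz", self.build(3, 3, 1)) is None

    def test_infinite_gap_cutoff_makes_all_copresent_pairs_contiguous(self):
        genomes = self.build(10, 8, 3)
        assert contiguity_score("i", "j", genomes, gap_max=10**9) == 1.0


def _mirror(spec):
    """Reverse-complement a genome spec across the replicon."""
    out = []
    for label, start, end, strand, *rest in [tuple(s) + ("r",)[:0] for s in spec]:
        ns, ne = L - end + 1, L - start + 1
        out.append((label, ns, ne, "+" if strand == "-" else "-"))
    return out


class TestArchitectures:
    def occ(self, spec, gid="g"):
        g = genome(gid, spec)
        return TripletOccurrence(
            gid,
            g.genes_with_label("ubiT")[0],
            g.genes_with_label("ubiU")[0],
            g.genes_with_label("ubiV")[0],
        )

    CLASS1 = [("ubiT", 1, 600, "+"), ("ubiU", 700, 2000, "+"), ("ubiV", 2050, 3300, "+")]
    CLASS2 = [("ubiU", 700, 2000, "+"), ("ubiV", 2050, 3300, "+"), ("ubiT", 3400, 4000, "+")]
    CLASS3 = [("ubiT", 100, 700, "-"), ("ubiU", 850, 2000, "+"), ("ubiV", 2050, 3300, "+")]
    CLASS4 = [("ubiT", 100, 700, "+"), ("ubiU", 40_700, 42_000, "+"), ("ubiV", 42_050, 43_300, "+")]

    @pytest.mark.parametrize(
        "spec,expected",
        [(CLASS1, "1"), (CLASS2, "2"), (CLASS3, "3"), (CLASS4, "4")],
        ids=["T-upstream", "T-downstream", "T-divergent", "T-distant"],
    )
    def test_geometries(self, spec, expected):
        assert classify_ubiTUV_architecture(self.occ(spec)).class_label == expected

    @pytest.mark.parametrize(
        "spec", [CLASS1, CLASS2, CLASS3, CLASS4],
        ids=["T-upstream", "T-downstream", "T-divergent", "T-distant"],
    )
    def test_reverse_complement_invariance(self, spec):
        fwd = classify_ubiTUV_architecture(self.occ(spec)).class_label
        rev = classify_ubiTUV_architecture(self.occ(_mirror(spec))).class_label
        assert fwd == rev

    def test_translation_invariance(self):
        shifted = [(lab, s + 5000, e + 5000, st) for lab, s, e, st in self.CLASS3]
        assert classify_ubiTUV_architecture(self.occ(shifted)).class_label == "3"

    def test_uv_not_adjacent_is_other(self):
        spec = [
            ("ubiT", 1, 600, "+"),
            ("ubiU", 700, 2000, "+"),
            ("ubiV", 3000, 4300, "+"),  # gap 999 >= 500
        ]
        assert classify_ubiTUV_architecture(self.occ(spec)).class_label == "other"

    def test_uv_wrong_order_is_other(self):
        spec = [
            ("ubiV", 700, 2000, "+"),
            ("ubiU", 2050, 3300, "+"),
            ("ubiT", 3400, 4000, "+"),
        ]
        assert classify_ubiTUV_architecture(self.occ(spec)).class_label == "other"

    def test_convergent_downstream_t_is_other(self):
        spec = [
            ("ubiU", 700, 2000, "+"),
            ("ubiV", 2050, 3300, "+"),
            ("ubiT", 3400, 4000, "-"),
        ]
        assert classify_ubiTUV_architecture(self.occ(spec)).class_label == "other"

    def test_t_on_other_replicon_is_class4(self):
        g = genome(
            "g",
            [
                ("ubiT", 100, 700, "+", "plasmid"),
                ("ubiU", 700, 2000, "+"),
                ("ubiV", 2050, 3300, "+"),
            ],
        )
        occ = TripletOccurrence(
            "g",
            g.genes_with_label("ubiT")[0],
            g.genes_with_label("ubiU")[0],
            g.genes_with_label("ubiV")[0],
        )
        assert classify_ubiTUV_architecture(occ).class_label == "4"


class TestEnumeration:
    def test_single_copy_single_occurrence(self):
        g = genome("g", TestArchitectures.CLASS1)
        arch, report = enumerate_triplet_occurrences([g])
        assert len(arch) == 1 and report.iloc[0]["class"] == "1"

    def test_two_copy_sets_two_occurrences(self):
        spec = TestArchitectures.CLASS1 + [
            ("ubiT", 50_001, 50_600, "+"),
            ("ubiU", 50_700, 52_000, "+"),
            ("ubiV", 52_050, 53_300, "+"),
        ]
        g = genome("g", spec)
        arch, report = enumerate_triplet_occurrences([g])
        assert len(arch) == 2
        assert class_counts(arch) == {"1": 2}
        # grouping keeps each cassette together
        for a in arch:
            assert a.gap_uv is not None and a.gap_uv < 500

    def test_incomplete_triplet_reported_not_classified(self):
        g = genome("g", [("ubiU", 700, 2000, "+"), ("ubiV", 2050, 3300, "+")])
        arch, report = enumerate_triplet_occurrences([g])
        assert arch == []
        assert report.iloc[0]["class"] == "incomplete"

    def test_planted_class_frequencies_recovered_exactly(self, small_dataset, small_genomes):
        arch, _ = enumerate_triplet_occurrences(small_genomes)
        got = class_counts(arch)
        expected = small_dataset.truth.architectures["class"].value_counts().to_dict()
        assert got == expected


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    start1=st.integers(1, 5000),
    len1=st.integers(1, 2000),
    gap=st.integers(0, 3000),
    len2=st.integers(1, 2000),
)
def test_distance_translation_invariant_and_symmetric(start1, len1, gap, len2):
    a = feat(start1, start1 + len1 - 1)
    b = feat(start1 + len1 + gap, start1 + len1 + gap + len2 - 1)
    d = intergenic_distance(a, b)
    assert d == gap
    assert intergenic_distance(b, a) == d
    shift = 1234
    a2 = feat(a.start + shift, a.end + shift)
    b2 = feat(b.start + shift, b.end + shift)
    assert intergenic_distance(a2, b2) == d
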