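"""Annotation I/O: GFF3/domtblout parsing, hit filtering, genome selection."""

import random

import pytest

from quinrep.annotation import (
    GeneFeature,
    GenomeMetadata,
    HitFilterPolicy,
    ProfileHit,
    build_annotated_genome,
    filter_hits,
    mimag_filter,
    read_gff3,
    read_hit_table,
    resolve_best_profile,
    select_one_genome_per_species,
)


def make_hit(**kw):
    base = dict(
        protein_id="p1",
        genome_id="g1",
        profile_name="ubiU",
        bit_score=100.0,
        i_evalue=1e-10,
        aln_from=1,
        aln_to=180,
        seq_length=200,
        ga_threshold=None,
    )
    base.update(kw)
    return ProfileHit(**base)


class TestGff3:
    def test_direct_field_mapping(self, tmp_path):
        p = tmp_path / "g.gff"
        p.write_text(
            "##gff-version 3\n"
            "##sequence-region repl1 1 5000\n"
            "repl1\t.\tCDS\t100\t400\t.\t+\t.\tID=a1;locus_tag=a1\n"
        )
        feats = read_gff3(p, genome_id="g")
        assert len(feats) == 1
        f = feats[0]
        assert (f.start, f.end, f.strand, f.locus_tag) == (100, 400, "+", "a1")
        assert f.replicon_length == 5000

    def test_multiple_replicons(self, tmp_path):
        p = tmp_path / "g.gff"
        p.write_text(
            "##gff-version 3\n"
            "##sequence-region r1 1 5000\n"
            "##sequence-region r2 1 3000\n"
            "r1\t.\tCDS\t100\t400\t.\t+\t.\tID=a\n"
            "r1\t.\tCDS\t600\t900\t.\t-\t.\tID=b\n"
            "r2\t.\tCDS\t10\t310\t.\t+\t.\tID=c\n"
        )
        feats = read_gff3(p)
        assert len(feats) == 3
        assert {f.replicon_id for f in feats} == {"r1", "r2"}

    def test_feature_past_replicon_end_rejected(self, tmp_path):
        p = tmp_path / "g.gff"
        p.write_text(
            "##sequence-region r1 1 500\n" "r1\t.\tCDS\t100\t600\t.\t+\t.\tID=a\n"
        )
        with pytest.raises(ValueError, match=":2:"):
            read_gff3(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "g.gff"
        p.write_text("##sequence-region r1 1 500\nr1\tonly-three\tcolumns\n")
        with pytest.raises(ValueError, match=":2:"):
            read_gff3(p)

    def test_synthetic_round_trip(self, small_dataset):
        """Features read back from generated GFF3 match the planted genes."""
        gid = small_dataset.genome_ids[0]
        feats = read_gff3(small_dataset.gff_dir / f"{gid}.gff", genome_id=gid)
        assert feats, "generator wrote no features"
        assert all(f.genome_id == gid for f in feats)
        assert all(1 <= f.start <= f.end <= f.replicon_length for f in feats)


class TestHitTable:
    def test_coverage_and_row_count(self, tmp_path, small_dataset):
        gid = small_dataset.genome_ids[0]
        hits = read_hit_table(small_dataset.hits_dir / f"{gid}.domtbl", genome_id=gid)
        truth = small_dataset.truth.hits
        expected = truth[truth.genome_id == gid]
        assert len(hits) == len(expected)
        by_key = {(h.protein_id, h.profile_name): h for h in hits}
        for row in expected.itertuples():
            h = by_key[(row.protein_id, row.profile_name)]
            assert h.aln_from == row.aln_from and h.aln_to == row.aln_to
            assert h.coverage == pytest.approx(
                (row.aln_to - row.aln_from + 1) / row.seq_length
            )

    def test_comment_lines_skipped(self, tmp_path):
        rows = [
            "ubiU - 200 prot1 - 200 1e-20 55.0 0.0 1 1 1e-20 1e-20 55.0 0.0 1 200 10 109 10 109 0.99 -",
        ] * 4
        p = tmp_path / "t.domtbl"
        p.write_text("# a comment\n# another\n" + "\n".join(rows) + "\n")
        hits = read_hit_table(p)
        assert len(hits) == 4
        assert hits[0].coverage == pytest.approx(0.5)  # (109-10+1)/200

    def test_negative_evalue_rejected(self, tmp_path):
        p = tmp_path / "t.domtbl"
        p.write_text(
            "ubiU - 200 prot1 - 200 1e-20 55.0 0.0 1 1 1e-20 -1e-20 55.0 0.0 1 200 10 109 10 109 0.99 -\n"
        )
        with pytest.raises(ValueError, match="negative"):
            read_hit_table(p)

    def test_missing_columns_is_parse_error(self, tmp_path):
        p = tmp_path / "t.domtbl"
        p.write_text("ubiU - 200 prot1\n")
        with pytest.raises((ValueError, IndexError)):
            read_hit_table(p)


class TestFilterHits:
    @pytest.mark.parametrize(
        "ga,bit,iev,cov,kept",
        [
            (25.0, 30.0, 1.0, 0.2, True),  # above GA wins outright
            (25.0, 20.0, 1e-30, 0.9, False),  # below GA loses outright
            (None, 100.0, 1e-5, 0.6, True),  # e-value + coverage rule
            (None, 100.0, 1e-2, 0.9, False),  # good coverage cannot rescue e-value
            (None, 100.0, 5e-4, 0.3, False),  # good e-value cannot rescue coverage
            (None, 100.0, 1e-3, 0.6, False),  # e-value bound is strict
            (None, 100.0, 1e-4, 0.5, False),  # coverage bound is strict
        ],
    )
    def test_retention_rule(self, ga, bit, iev, cov, kept):
        aln_to = int(cov * 1000)
        hit = make_hit(
            ga_threshold=ga, bit_score=bit, i_evalue=iev,
            aln_from=1, aln_to=aln_to, seq_length=1000,
        )
        assert (filter_hits([hit]) == [hit]) is kept

    def test_five_hit_toy_table(self):
        hits = [
            make_hit(protein_id="a", ga_threshold=25, bit_score=30),
            make_hit(protein_id="b", ga_threshold=25, bit_score=26),
            make_hit(protein_id="c", i_evalue=1e-6, aln_to=120),
            make_hit(protein_id="d", i_evalue=0.01, aln_to=190),
            make_hit(protein_id="e", ga_threshold=40, bit_score=12),
        ]
        kept = filter_hits(hits)
        assert [h.protein_id for h in kept] == ["a", "b", "c"]

    def test_idempotent_and_order_preserving(self):
        rng = random.Random(0)
        hits = [
            make_hit(
                protein_id=f"p{i}",
                ga_threshold=rng.choice([None, 25.0]),
                bit_score=rng.uniform(0, 60),
                i_evalue=10 ** rng.uniform(-10, 0),
                aln_to=rng.randint(50, 200),
            )
            for i in range(60)
        ]
        once = filter_hits(hits)
        assert filter_hits(once) == once
        assert once == [h for h in hits if h in once]

    def test_reductase_policy_ignores_ga(self):
        hit = make_hit(ga_threshold=25.0, bit_score=30.0, i_evalue=1e-4, aln_to=180)
        assert filter_hits([hit], HitFilterPolicy.reductase()) == []
        hit2 = make_hit(ga_threshold=25.0, bit_score=3.0, i_evalue=1e-6, aln_to=180)
        assert filter_hits([hit2], HitFilterPolicy.reductase()) == [hit2]


class TestResolveBestProfile:
    def test_lowest_ievalue_wins(self):
        hits = [
            make_hit(profile_name="ubiU", i_evalue=1e-40),
            make_hit(profile_name="ubiV", i_evalue=1e-6),
        ]
        assert resolve_best_profile(hits)["p1"].profile_name == "ubiU"

    def test_single_hit(self):
        h = make_hit()
        assert resolve_best_profile([h]) == {"p1": h}

    def test_tie_breaks_lexicographically_and_order_independent(self):
        hits = [
            make_hit(profile_name="ubiV", i_evalue=1e-6),
            make_hit(profile_name="ubiU", i_evalue=1e-6),
            make_hit(protein_id="p2", profile_name="menB", i_evalue=1e-9),
        ]
        fwd = resolve_best_profile(hits)
        rev = resolve_best_profile(list(reversed(hits)))
        assert fwd["p1"].profile_name == "ubiU"
        assert {k: v.profile_name for k, v in fwd.items()} == {
            k: v.profile_name for k, v in rev.items()
        }


class TestGenomeSelection:
    def meta(self, gid, sp, cat, comp=99.0, cont=1.0):
        return GenomeMetadata(gid, sp, cat, comp, cont)

    def test_reference_beats_others(self):
        records = [
            self.meta("g1", "s1", "other"),
            self.meta("g2", "s1", "reference"),
            self.meta("g3", "s1", "other"),
        ]
        assert select_one_genome_per_species(records, seed=0) == {"s1": "g2"}

    def test_single_genome_species(self):
        assert select_one_genome_per_species([self.meta("g9", "s", "other")], 5) == {
            "s": "g9"
        }

    def test_seeded_choice_reproducible_and_order_independent(self):
        records = [self.meta(f"g{i}", "s1", "other") for i in range(3)]
        pick = select_one_genome_per_species(records, seed=42)
        assert pick == select_one_genome_per_species(records[::-1], seed=42)
        assert select_one_genome_per_species(records, seed=42) == pick

    def test_one_genome_per_species(self):
        records = [
            self.meta(f"g{i}", f"s{i % 4}", "representative") for i in range(12)
        ]
        chosen = select_one_genome_per_species(records, seed=1)
        assert sorted(chosen) == ["s0", "s1", "s2", "s3"]


class TestMimag:
    @pytest.mark.parametrize(
        "comp,cont,kept",
        [(95, 2, True), (90, 2, False), (91, 5, False), (90.1, 4.9, True)],
    )
    def test_strict_boundaries(self, comp, cont, kept):
        m = GenomeMetadata("g", "s", "other", comp, cont)
        assert (mimag_filter([m]) == ["g"]) is kept

    def test_missing_values_rejected(self):
        m = GenomeMetadata("g", "s", "other", None, 1.0)
        assert mimag_filter([m]) == []

    def test_six_record_table(self):
        vals = [(95, 2), (90, 2), (99, 5), (91, 4.9), (100, 0), (50, 1)]
        records = [
            GenomeMetadata(f"g{i}", f"s{i}", "other", c, x)
            for i, (c, x) in enumerate(vals)
        ]
        assert mimag_filter(records) == ["g0", "g3", "g4"]


class TestBuildAnnotatedGenome:
    def feats(self):
        return [
            GeneFeature("g", "r", 10_000, 100, 700, "+", f"t{i}") for i in range(3)
        ]

    def feats_spread(self):
        return [
            GeneFeature("g", "r", 10_000, 100 + 1000 * i, 700 + 1000 * i, "+", f"t{i}")
            for i in range(3)
        ]

    def test_partial_labelling(self):
        g = build_annotated_genome(self.feats_spread(), {"t0": "ubiU", "t2": "ubiV"})
        assert g.labels == {"ubiU", "ubiV"}
        assert sum(1 for f in g.features if not f.gene_label) == 1

    def test_paralogs_flagged_multi_copy(self):
        g = build_annotated_genome(self.feats_spread(), {"t0": "ubiU", "t1": "ubiU"})
        assert g.multi_copy_labels == {"ubiU"}
        assert len(g.genes_with_label("ubiU")) == 2

    def test_unknown_locus_tag_raises_with_offenders(self):
        with pytest.raises(ValueError, match="missing_tag"):
            build_annotated_genome(self.feats_spread(), {"missing_tag": "ubiU"})

    def test_synthetic_labels_match_planted_truth(self, small_dataset, small_genomes):
        truth = small_dataset.truth.hits
        for g in small_genomes:
            expected = truth[(truth.genome_id == g.genome_id) & truth.is_true]
            assert g.label_counts() == expected.profile_name.value_counts().to_dict()
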