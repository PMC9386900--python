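import pytest

from conftest import make_record
from lemnomics.annotation import (
    AnnotationDB,
    best_hit_per_species,
    filter_hits,
    merge_eggnog,
    taxon_summary,
    transfer_go,
)
from lemnomics.homology import HomologyHit


def hit(
    query="q1",
    subject="R1",
    species="plant_sp1",
    taxon="plant",
    identity=80.0,
    similarity=80.0,
    length=50,
    coverage=90.0,
    score=100.0,
):
    return HomologyHit(
        query_id=query,
        subject_id=subject,
        subject_species=species,
        subject_taxon_group=taxon,
        percent_identity=identity,
        percent_similarity=similarity,
        alignment_length=length,
        percent_query_alignment=coverage,
        score=score,
    )


class TestFilterHits:
    def test_short_alignment_removed(self):
        assert filter_hits([hit(length=19)]) == []
        assert len(filter_hits([hit(length=20)])) == 1

    def test_weak_similarity_removed(self):
        assert filter_hits([hit(similarity=34.9)]) == []
        assert len(filter_hits([hit(similarity=35.0)])) == 1

    def test_non_plant_top_hit_removes_whole_gene(self):
        # q1: plant top hit, non-plant secondary; q2: bacterial top hit
        hits = [
            hit("q1", "P1", taxon="plant", length=25, similarity=80, score=100),
            hit("q1", "B1", taxon="bacteria", length=30, similarity=60, score=90),
            hit("q2", "B2", taxon="bacteria", length=40, similarity=90, score=100),
            hit("q2", "P2", taxon="plant", length=40, similarity=50, score=80),
        ]
        kept = filter_hits(hits)
        assert [h.subject_id for h in kept] == ["P1"]

    def test_empty_in_empty_out(self):
        assert filter_hits([]) == []

    def test_idempotent(self):
        hits = [
            hit("q1", "P1", score=100),
            hit("q1", "P2", score=90, similarity=30),
            hit("q2", "B1", taxon="bacteria", score=100),
        ]
        once = filter_hits(hits)
        assert filter_hits(once) == once


class TestBestHitPerSpecies:
    def test_highest_coverage_wins(self):
        hits = [hit(subject="R1", coverage=80), hit(subject="R2", coverage=95)]
        best = best_hit_per_species(hits)
        assert best[("q1", "plant_sp1")].subject_id == "R2"

    def test_coverage_tie_broken_by_score_then_id(self):
        hits = [
            hit(subject="R1", coverage=90, score=50),
            hit(subject="R2", coverage=90, score=60),
        ]
        assert best_hit_per_species(hits)[("q1", "plant_sp1")].subject_id == "R2"
        hits = [
            hit(subject="R2", coverage=90, score=50),
            hit(subject="R1", coverage=90, score=50),
        ]
        assert best_hit_per_species(hits)[("q1", "plant_sp1")].subject_id == "R1"

    def test_one_entry_per_species(self):
        hits = [hit(species=f"plant_sp{i}") for i in (1, 2, 3)]
        assert len(best_hit_per_species(hits)) == 3


class TestTransferGo:
    def test_union_of_best_hit_go_sets(self):
        best = {
            ("g1", "plant_sp1"): hit(subject="R1", species="plant_sp1"),
            ("g1", "plant_sp2"): hit(subject="R2", species="plant_sp2"),
        }
        records = {
            "R1": make_record("R1", go=("GO:0000001", "GO:0000002")),
            "R2": make_record("R2", go=("GO:0000002", "GO:0000003")),
        }
        db = transfer_go(best, records)
        assert db.genes["g1"].go_terms == {"GO:0000001", "GO:0000002", "GO:0000003"}
        assert db.genes["g1"].sources == {"homology"}

    def test_empty_go_set_still_annotates_gene(self):
        best = {("g1", "plant_sp1"): hit(subject="R1")}
        db = transfer_go(best, {"R1": make_record("R1")})
        assert "g1" in db
        assert db.genes["g1"].go_terms == set()

    def test_descriptor_from_overall_best_hit(self):
        best = {
            ("g1", "plant_sp1"): hit(subject="R1", species="plant_sp1", coverage=80),
            ("g1", "plant_sp2"): hit(subject="R2", species="plant_sp2", coverage=95),
        }
        records = {"R1": make_record("R1"), "R2": make_record("R2")}
        assert transfer_go(best, records).genes["g1"].descriptor == "protein R2"

    def test_no_duplicate_terms_and_bounded_size(self):
        best = {
            ("g1", f"plant_sp{i}"): hit(subject=f"R{i}", species=f"plant_sp{i}")
            for i in range(1, 4)
        }
        records = {
            f"R{i}": make_record(f"R{i}", go=("GO:0000001", f"GO:000000{i + 1}"))
            for i in range(1, 4)
        }
        terms = transfer_go(best, records).genes["g1"].go_terms
        assert len(terms) == len(set(terms))
        assert len(terms) <= sum(len(r.go_terms) for r in records.values())


class TestMergeEggnog:
    def _eggnog(self, tmp_path, rows, header=None):
        header = header or ["query", "seed_ortholog", "Description", "GOs"]
        path = tmp_path / "eggnog.annotations"
        lines = ["## eggNOG-mapper style output", "#" + "\t".join(header)]
        lines += ["\t".join(r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    def _homology_db(self):
        best = {("g1", "plant_sp1"): hit(query="g1", subject="R1")}
        return transfer_go(best, {"R1": make_record("R1", go=("GO:0000001",))})

    def test_union_with_homology_terms(self, tmp_path):
        path = self._eggnog(tmp_path, [["g1", "R9", "desc", "GO:0000001,GO:0000002"]])
        merged = merge_eggnog(self._homology_db(), path)
        assert merged.genes["g1"].go_terms == {"GO:0000001", "GO:0000002"}
        assert merged.genes["g1"].sources == {"homology", "eggnog"}

    def test_gene_only_in_eggnog_is_added(self, tmp_path):
        path = self._eggnog(tmp_path, [["g2", "R9", "desc", "GO:0000005"]])
        merged = merge_eggnog(self._homology_db(), path)
        assert merged.genes["g2"].go_terms == {"GO:0000005"}
        assert merged.genes["g2"].sources == {"eggnog"}

    def test_dash_go_cell_contributes_nothing(self, tmp_path):
        path = self._eggnog(tmp_path, [["g2", "R9", "desc", "-"]])
        merged = merge_eggnog(self._homology_db(), path)
        assert merged.genes["g2"].go_terms == set()

    def test_merge_content_is_order_independent(self, tmp_path):
        path = self._eggnog(tmp_path, [["g1", "R9", "desc", "GO:0000002"]])
        via_homology_first = merge_eggnog(self._homology_db(), path)
        via_eggnog_first = merge_eggnog(AnnotationDB(), path)
        for g1 in via_eggnog_first.genes.values():
            g1.go_terms |= self._homology_db().genes["g1"].go_terms
        assert (
            via_homology_first.genes["g1"].go_terms
            == via_eggnog_first.genes["g1"].go_terms
        )

    def test_non_plant_seed_ortholog_filtered_with_metadata(self, tmp_path):
        path = self._eggnog(tmp_path, [["g2", "B1", "desc", "GO:0000005"]])
        meta = {"B1": make_record("B1", taxon="bacteria", species="bact_sp1")}
        merged = merge_eggnog(self._homology_db(), path, db_metadata=meta)
        assert "g2" not in merged


class TestTaxonSummary:
    def test_fraction_arithmetic(self):
        hits = [
            hit(query=f"g{i}", taxon="plant", species="plant_sp1") for i in range(199)
        ] + [hit(query="g199", taxon="bacteria", species="bact_sp1")]
        summary = taxon_summary(hits)
        assert summary.counts == {"plant": 199, "bacteria": 1}
        assert summary.percents == {"plant": 99.5, "bacteria": 0.5}

    def test_top_hit_decides_taxon(self):
        hits = [
            hit(query="g1", subject="B1", taxon="bacteria", score=100),
            hit(query="g1", subject="P1", taxon="plant", score=90),
        ]
        assert taxon_summary(hits).counts == {"bacteria": 1}

    def test_empty(self):
        summary = taxon_summary([])
        assert summary.counts == {} and summary.fractions == {}

    def test_fractions_sum_to_one(self):
        hits = [hit(query=f"g{i}", taxon=t) for i, t in enumerate(
            ["plant"] * 5 + ["bacteria"] * 3 + ["fungi"] * 2
        )]
        assert sum(taxon_summary(hits).fractions.values()) == pytest.approx(1.0)


def test_annotation_db_round_trip(tmp_path):
    best = {
        ("g1", "plant_sp1"): hit(query="g1", subject="R1"),
        ("g2", "plant_sp2"): hit(query="g2", subject="R2", species="plant_sp2"),
    }
    records = {
        "R1": make_record("R1", go=("GO:0000001", "GO:0000002")),
        "R2": make_record("R2", go=("GO:0000003",)),
    }
    db = transfer_go(best, records)
    db.write(tmp_path / "annodb")
    back = AnnotationDB.read(tmp_path / "annodb")
    assert back.gene_to_go() == db.gene_to_go()
    assert back.genes["g1"].descriptor == db.genes["g1"].descriptor
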