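"""Five-key ordering, cross-organism commonality, biofluid overlap, reports."""

import random

import pytest

from phoscross.model import (
    CandidateHit,
    MatchMetrics,
    PeptideWindow,
    PhosphoSite,
)
from phoscross.ranker import (
    annotate_biofluids,
    common_across_organisms,
    rank_hits,
    read_presence_list,
    write_report,
)


def make_hit(accession="P00001", metrics=(5, 2, 3, 5), mw=15000,
             gene="GENE1", taxon=9606, seed_id="S129", position=50,
             entry_name=None):
    n_exact, n_similar, es, eos = metrics
    return CandidateHit(
        seed_id=seed_id,
        accession=accession,
        entry_name=entry_name or f"{gene}_HUMAN",
        gene_name=gene,
        organism_taxon=taxon,
        site=PhosphoSite(position, "S", "phosphoserine"),
        window=PeptideWindow("EAYEMPSEEGYQD", position),
        metrics=MatchMetrics(n_exact, n_similar, es, eos),
        mw_da=mw,
    )


class TestRankHits:
    def test_longer_exact_stretch_ranks_first(self):
        lo = make_hit("P00001", metrics=(5, 2, 3, 5))
        hi = make_hit("P00002", metrics=(5, 2, 5, 5))
        ranked = rank_hits([lo, hi])
        assert [h.accession for h in ranked] == ["P00002", "P00001"]
        assert [h.rank for h in ranked] == [1, 2]

    def test_metric_ties_broken_by_ascending_weight(self):
        heavy = make_hit("P00001", mw=60000)
        light = make_hit("P00002", mw=14000)
        assert [h.mw_da for h in rank_hits([heavy, light])] == [14000, 60000]

    def test_weight_direction_is_configurable(self):
        heavy = make_hit("P00001", mw=60000)
        light = make_hit("P00002", mw=14000)
        ranked = rank_hits([heavy, light], mw_ascending=False)
        assert [h.mw_da for h in ranked] == [60000, 14000]

    def test_singleton_gets_rank_one(self):
        assert rank_hits([make_hit()])[0].rank == 1

    def test_five_keys_applied_in_order(self):
        hits = [
            make_hit("P1", metrics=(6, 0, 4, 4)),
            make_hit("P2", metrics=(5, 3, 4, 6)),
            make_hit("P3", metrics=(7, 1, 4, 6)),
            make_hit("P4", metrics=(7, 2, 4, 6)),
        ]
        ranked = rank_hits(hits)
        # eos desc first among stretch ties, then n_exact desc, then n_similar desc
        assert [h.accession for h in ranked] == ["P4", "P3", "P2", "P1"]

    def test_permutation_invariance_and_multiset_conservation(self):
        rng = random.Random(3)
        hits = []
        for i in range(40):
            ne = rng.randint(0, 10)
            ns = rng.randint(0, 13 - ne)
            es = rng.randint(0, ne)
            eos = rng.randint(es, min(13, ne + ns))
            hits.append(make_hit(f"P{i:05d}", metrics=(ne, ns, es, eos),
                                 mw=rng.choice([12000, 15000, 60000])))
        baseline = rank_hits(hits)
        for trial in range(5):
            shuffled = hits[:]
            rng.shuffle(shuffled)
            again = rank_hits(shuffled)
            assert [h.accession for h in again] == \
                [h.accession for h in baseline]
            assert [h.rank for h in again] == list(range(1, 41))
        assert sorted(h.accession for h in baseline) == \
            sorted(h.accession for h in hits)

    def test_input_not_mutated(self):
        h = make_hit()
        rank_hits([h])
        assert h.rank is None


class TestCommonality:
    def test_case_folded_gene_identity(self):
        human = {"S129": [make_hit(gene="SNCA")]}
        mouse = {"S129": [make_hit("O55042", gene="Snca", taxon=10090)]}
        result = common_across_organisms(human, mouse)
        assert result.per_seed["S129"] == {"SNCA"}
        assert result.size("S129") == 1

    def test_disjoint_gene_sets(self):
        human = {"S129": [make_hit(gene="NEFL")]}
        mouse = {"S129": [make_hit(gene="Gfap", taxon=10090)]}
        assert common_across_organisms(human, mouse).size("S129") == 0

    def test_intersection_by_hand(self):
        human = {"S129": [make_hit("P1", gene="NEFL"),
                          make_hit("P2", gene="SNCA")]}
        mouse = {"S129": [make_hit("P3", gene="Nefl", taxon=10090)]}
        result = common_across_organisms(human, mouse)
        assert result.per_seed["S129"] == {"NEFL"}

    def test_entry_name_stem_fallback(self):
        human = {"Y125": [make_hit(gene="", entry_name="SYUA_HUMAN")]}
        mouse = {"Y125": [make_hit(gene="", entry_name="SYUA_MOUSE",
                                   taxon=10090)]}
        assert common_across_organisms(human, mouse).per_seed["Y125"] == {"SYUA"}

    def test_union_reported_alongside_per_seed(self):
        human = {"S129": [make_hit(gene="NEFL")],
                 "Y125": [make_hit(gene="SNCA")]}
        mouse = {"S129": [make_hit(gene="Snca", taxon=10090)],
                 "Y125": [make_hit(gene="Nefl", taxon=10090)]}
        result = common_across_organisms(human, mouse)
        assert result.size("S129") == 0 and result.size("Y125") == 0
        assert result.union == {"SNCA", "NEFL"}


class TestBiofluidOverlap:
    def test_printed_percentage_pairs(self):
        """The overlap arithmetic reproduces the published count pairs:
        59 of 123 candidates in plasma -> 47.97%; 27 of 59 -> 45.76%."""
        proteins = [f"G{i}" for i in range(123)]
        summary = annotate_biofluids(proteins, set(proteins[:59]), "plasma")
        assert summary.total == 123 and summary.present == 59
        assert round(summary.percentage, 2) == 47.97
        summary = annotate_biofluids([f"G{i}" for i in range(59)],
                                     {f"G{i}" for i in range(27)}, "plasma")
        assert round(summary.percentage, 2) == 45.76

    def test_empty_presence_list(self):
        summary = annotate_biofluids(["A", "B"], set(), "csf")
        assert summary.present == 0 and summary.percentage == 0.0

    def test_empty_hit_set_reports_zero(self):
        summary = annotate_biofluids([], {"SNCA"}, "plasma")
        assert summary.total == 0 and summary.percentage == 0.0

    def test_proteins_deduplicated_across_seeds(self):
        hits = [make_hit(gene="SNCA", seed_id="S129"),
                make_hit(gene="SNCA", seed_id="Y125")]
        summary = annotate_biofluids(hits, {"SNCA"}, "plasma")
        assert summary.total == 1 and summary.present == 1

    def test_accession_then_gene_matching(self):
        hit = make_hit("P37840", gene="SNCA")
        assert annotate_biofluids([hit], {"P37840"}, "x").present == 1
        assert annotate_biofluids([hit], {"snca"}, "x").present == 1
        assert annotate_biofluids([hit], {"OTHER"}, "x").present == 0

    def test_presence_list_parsing(self, tmp_path):
        path = tmp_path / "plasma.txt"
        path.write_text("# plasma proteins\nSNCA\np37840  # aSyn\n\nNEFL\n")
        assert read_presence_list(path) == {"SNCA", "P37840", "NEFL"}


class TestWriteReport:
    def test_file_count_and_order(self, tmp_path):
        ranked = {"S129": rank_hits([make_hit("P2", mw=2), make_hit("P1", mw=1)]),
                  "Y125": []}
        paths = write_report(ranked, [], tmp_path / "out")
        names = sorted(p.name for p in paths)
        assert names == ["hits_S129.tsv", "hits_Y125.tsv",
                         "manifest.txt", "summary.tsv"]
        lines = (tmp_path / "out" / "hits_Y125.tsv").read_text().splitlines()
        assert len(lines) == 1  # header only
        rows = (tmp_path / "out" / "hits_S129.tsv").read_text().splitlines()
        assert rows[1].split("\t")[1] == "P1"  # rank order preserved

    def test_reports_are_byte_identical_across_runs(self, tmp_path):
        ranked = {"S129": rank_hits([make_hit(f"P{i}", mw=1000 + i)
                                     for i in range(5)])}
        summaries = [annotate_biofluids(["A", "B", "C"], {"A"}, "plasma")]
        write_report(ranked, summaries, tmp_path / "a", {"k": "v"})
        write_report(ranked, summaries, tmp_path / "b", {"k": "v"})
        for name in ["hits_S129.tsv", "summary.tsv", "manifest.txt"]:
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_unwritable_destination_errors_before_output(self, tmp_path):
        blocker = tmp_path / "file"
        blocker.write_text("x")
        with pytest.raises(OSError):
            write_report({"S129": []}, [], blocker / "sub")
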