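"""Mapper color file, Venn region counts, and the output bundle."""

import itertools
import json
import random

import pytest

from metorigin.enrichment import pathway_enrichment, pathway_universe
from metorigin.errors import ConfigError
from metorigin.origin import SourceSet, build_source, classify_origins
from metorigin.report import make_mapper_file, make_venn, write_bundle


def make_source(label, compounds, kos=frozenset()):
    return SourceSet(label=label, ko_ids=set(kos), producible_compounds=set(compounds))


class TestMapperFile:
    def test_detected_microbiome_only_compound_gets_blue_orange(self):
        sources = [
            make_source("microbiome", {"C00246"}, kos={"K00929"}),
            make_source("host", set(), kos={"K11111"}),
        ]
        table = classify_origins(sources, detected={"C00246"})
        lines = make_mapper_file(table, sources)
        assert "C00246 blue,orange" in lines
        assert "K00929 blue" in lines
        assert "K11111 yellow" in lines

    def test_empty_origin_table_gives_empty_file(self):
        sources = [make_source("a", set()), make_source("b", set())]
        table = classify_origins(sources)
        assert make_mapper_file(table, sources) == []

    def test_all_both_no_detection(self):
        shared = {"C00001", "C00002"}
        sources = [make_source("a", shared, kos={"K00001"}),
                   make_source("b", shared, kos={"K00001"})]
        table = classify_origins(sources)
        lines = make_mapper_file(table, sources)
        compound_lines = [l for l in lines if l.startswith("C")]
        assert compound_lines == ["C00001 green", "C00002 green"]
        assert "K00001 green" in lines

    def test_more_than_two_sources_refused(self):
        sources = [make_source(l, set()) for l in "abc"]
        table = classify_origins(sources)
        with pytest.raises(ConfigError, match="two sources"):
            make_mapper_file(table, sources)

    def test_palette_override(self):
        sources = [make_source("m", {"C00001"}), make_source("h", set())]
        table = classify_origins(sources)
        lines = make_mapper_file(table, sources, palette={"source1": "#0000cd"})
        assert lines[0] == "C00001 #0000cd"

    def test_entity_ids_subset_of_table_and_sources(self, synth_bundle):
        _, _, db = synth_bundle
        kos = sorted(db.orthologs)
        sources = [build_source("m", kos[:15], db), build_source("h", kos[10:25], db)]
        table = classify_origins(sources, detected=set(list(db.compounds)[:10]))
        allowed = set(table.rows) | sources[0].ko_ids | sources[1].ko_ids
        for line in make_mapper_file(table, sources):
            assert line.split()[0] in allowed


class TestVenn:
    def test_three_region_counts_from_spec_example(self):
        sources = [make_source("A", {"C1", "C3"}), make_source("B", {"C2", "C3"})]
        venn = make_venn(None, sources, detected={"C1", "C2", "C3", "C4"})
        assert venn.region_counts["detected&A"] == 1
        assert venn.region_counts["detected&B"] == 1
        assert venn.region_counts["detected&A&B"] == 1
        assert venn.region_counts["detected"] == 1
        assert venn.region_counts["A"] == 0 and venn.region_counts["B"] == 0

    def test_disjoint_sets_have_empty_intersections(self):
        venn = make_venn(None, [make_source("A", {"C1"}), make_source("B", {"C2"})])
        assert venn.region_counts == {"A": 1, "B": 1, "A&B": 0}

    def test_region_counts_sum_to_union(self):
        rng = random.Random(2)
        pool = [f"C{i:05d}" for i in range(30)]
        for _ in range(20):
            a, b, d = (set(rng.sample(pool, rng.randint(0, 20))) for _ in range(3))
            venn = make_venn(None, [make_source("A", a), make_source("B", b)], detected=d)
            assert venn.union_size == len(a | b | d)

    def test_counts_equal_brute_force_membership_tally(self):
        rng = random.Random(3)
        pool = [f"C{i:05d}" for i in range(25)]
        for _ in range(15):
            named = {l: set(rng.sample(pool, rng.randint(0, 15))) for l in "ABC"}
            venn = make_venn(
                None, [make_source(l, s) for l, s in named.items()]
            )
            for r in range(1, 4):
                for combo in itertools.combinations("ABC", r):
                    expected = 0
                    for element in pool:
                        inside = {l for l in "ABC" if element in named[l]}
                        if inside == set(combo):
                            expected += 1
                    assert venn.region_counts["&".join(combo)] == expected

    def test_regions_biject_with_origin_categories(self):
        rng = random.Random(4)
        pool = [f"C{i:05d}" for i in range(40)]
        for _ in range(10):
            a = set(rng.sample(pool, rng.randint(0, 25)))
            b = set(rng.sample(pool, rng.randint(0, 25)))
            d = set(rng.sample(pool, rng.randint(1, 30)))
            sources = [make_source("m", a), make_source("h", b)]
            table = classify_origins(sources, detected=d)
            venn = make_venn(table, sources, detected=d)
            counts = table.category_counts(detected_only=True)
            assert venn.region_counts["detected&m"] == counts.get("m_only", 0)
            assert venn.region_counts["detected&h"] == counts.get("h_only", 0)
            assert venn.region_counts["detected&m&h"] == counts.get("both", 0)
            assert venn.region_counts["detected"] == counts.get("neither", 0)

    def test_figure_rendered_for_three_sets(self, tmp_path):
        figure = tmp_path / "venn.png"
        make_venn(
            None,
            [make_source("A", {"C1"}), make_source("B", {"C2"})],
            detected={"C1"},
            figure_path=figure,
        )
        assert figure.exists() and figure.stat().st_size > 0

    def test_four_sets_emit_counts_without_figure(self, tmp_path):
        figure = tmp_path / "venn.png"
        venn = make_venn(
            None,
            [make_source(l, {f"C{l}"}) for l in "ABCD"],
            figure_path=figure,
        )
        assert len(venn.region_counts) == 2**4 - 1
        assert not figure.exists()


class TestWriteBundle:
    def run_bundle(self, synth_bundle, outdir, detected=True):
        _, truth, db = synth_bundle
        kos = sorted(db.orthologs)
        sources = [build_source("microbiome", kos[:15], db),
                   build_source("host", kos[10:25], db)]
        detected_set = (
            set(sorted(sources[0].producible_compounds)[:8]) | {"C99999"}
            if detected else None
        )
        table = classify_origins(sources, detected=detected_set, db=db)
        universe = pathway_universe(db)
        queries = (
            {c: table.compounds_in_category(c, detected_only=True)
             for c in table.categories() if c != "neither"}
            if detected else {s.label: s.producible_compounds for s in sources}
        )
        enrichment = {
            name: pathway_enrichment(q, db, universe) for name, q in queries.items() if q
        }
        return write_bundle(
            outdir, table, enrichment, sources, detected=detected_set, db=db,
            run_metadata={"seed": 1},
        )

    def test_manifest_lists_exactly_the_written_files(self, synth_bundle, tmp_path):
        manifest = self.run_bundle(synth_bundle, tmp_path / "out")
        on_disk = {
            p.name for p in (tmp_path / "out").iterdir() if p.name != "manifest.json"
        }
        assert set(manifest["files"]) == on_disk

    def test_reruns_are_byte_identical_for_text_outputs(self, synth_bundle, tmp_path):
        self.run_bundle(synth_bundle, tmp_path / "a")
        self.run_bundle(synth_bundle, tmp_path / "b")
        for path_a in (tmp_path / "a").iterdir():
            if path_a.suffix == ".png":
                continue
            assert path_a.read_bytes() == (tmp_path / "b" / path_a.name).read_bytes()

    def test_run_without_detection_notes_omission(self, synth_bundle, tmp_path):
        manifest = self.run_bundle(synth_bundle, tmp_path / "out", detected=False)
        assert manifest["detection_supplied"] is False
        assert "note" in manifest
        written = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert written["note"] == manifest["note"]
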