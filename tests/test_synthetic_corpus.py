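"""Generator contracts: ontology shape, exact counts, round-trip I/O."""

import json

import pytest

from tcmaid import synthetic_corpus as sc


class TestBuildOntology:
    def test_single_disease_single_syndrome_forced(self):
        onto = sc.build_ontology(1, 1, 1, seed=3)
        assert onto.disease_to_syndromes == {"D000": ("S000",)}

    def test_deterministic_for_fixed_seed(self):
        a = sc.build_ontology(5, 8, 3, seed=42)
        b = sc.build_ontology(5, 8, 3, seed=42)
        assert a == b

    def test_many_to_many_by_exhaustive_scan(self):
        # 4 diseases x ~2 syndromes out of 3: pigeonhole or forced sharing
        onto = sc.build_ontology(4, 3, 2, seed=0)
        seen = {}
        for d, syns in onto.disease_to_syndromes.items():
            assert len(syns) >= 1
            for s in syns:
                seen.setdefault(s, set()).add(d)
        assert any(len(ds) >= 2 for ds in seen.values())

    @pytest.mark.parametrize("args", [(0, 1, 1), (1, 0, 1), (2, 2, 0.5)])
    def test_invalid_counts_rejected(self, args):
        with pytest.raises(ValueError):
            sc.build_ontology(*args, seed=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_invariants_hold_across_seeds(self, seed):
        onto = sc.build_ontology(6, 10, 2.5, seed=seed)
        onto.validate()


class TestGenerateCorpus:
    def test_exact_per_class_counts(self):
        onto = sc.build_ontology(2, 4, 2, seed=1)
        a, b = onto.disease_ids
        cfg = sc.GenConfig(onto, {a: 5, b: 7}, seed=2)
        notes = sc.generate_corpus(cfg)
        assert len(notes) == 12
        assert sum(1 for n in notes if n.disease == a) == 5

    def test_exact_violation_counts(self):
        onto = sc.build_ontology(2, 4, 2, seed=1)
        cfg = sc.GenConfig(
            onto, {d: 10 for d in onto.disease_ids},
            qc_violations={"missing_page": 2}, seed=3,
        )
        notes = sc.generate_corpus(cfg)
        flagged = [n for n in notes if "missing_page" in n.qc_flags]
        assert len(flagged) == 2
        for n in flagged:
            assert "admission" not in n.sections or "discharge" not in n.sections

    def test_violations_exceeding_total_rejected(self):
        onto = sc.build_ontology(1, 1, 1, seed=1)
        cfg = sc.GenConfig(onto, {"D000": 2}, qc_violations={"missing_page": 3}, seed=0)
        with pytest.raises(ValueError):
            sc.generate_corpus(cfg)

    def test_severe_imbalance_histogram(self):
        # the kind of skew a hospital corpus shows: 2180/1913/109/584
        onto = sc.build_ontology(4, 8, 2, seed=5)
        wanted = dict(zip(onto.disease_ids, (2180, 1913, 109, 584)))
        notes = sc.generate_corpus(sc.GenConfig(onto, wanted, seed=6))
        got = {}
        for n in notes:
            got[n.disease] = got.get(n.disease, 0) + 1
        assert got == wanted

    def test_spans_lie_inside_sections_and_do_not_overlap(self, noisy_corpus):
        _, notes = noisy_corpus
        for n in notes:
            by_sec = {}
            for s in n.spans:
                assert 0 <= s.start < s.end <= len(n.sections[s.section])
                by_sec.setdefault(s.section, []).append((s.start, s.end))
            for spans in by_sec.values():
                spans.sort()
                for (a0, a1), (b0, _) in zip(spans, spans[1:]):
                    assert a1 <= b0

    def test_duration_adjacent_to_its_symptom(self, small_corpus):
        _, notes = small_corpus
        for n in notes[:20]:
            cc = [s for s in n.spans if s.section == "chief_complaint"]
            cc.sort(key=lambda s: s.start)
            for prev, cur in zip(cc, cc[1:]):
                if cur.etype == "duration":
                    assert prev.etype == "symptom"
                    assert cur.start == prev.end + 1  # single joining space

    def test_label_consistency(self, noisy_corpus):
        cfg, notes = noisy_corpus
        for n in notes:
            assert n.disease in cfg.ontology.disease_ids
            if not n.qc_flags:
                assert n.syndrome in cfg.ontology.disease_to_syndromes[n.disease]

    def test_disjoint_symptom_lexica_without_noise(self, small_corpus):
        cfg, notes = small_corpus
        assert cfg.synonym_noise == 0
        per_disease = {}
        for n in notes:
            canon = {s.canonical for s in n.spans if s.etype == "symptom"}
            per_disease.setdefault(n.disease, set()).update(canon)
        diseases = list(per_disease)
        for i, a in enumerate(diseases):
            for b in diseases[i + 1 :]:
                assert per_disease[a].isdisjoint(per_disease[b])

    def test_deterministic_files_for_fixed_config(self, tmp_path, small_ontology):
        def gen(path):
            cfg = sc.GenConfig(
                small_ontology, {d: 5 for d in small_ontology.disease_ids},
                seed=9, synonym_noise=0.3, fullwidth_prob=0.3,
            )
            sc.write_corpus(sc.generate_corpus(cfg), path)

        gen(tmp_path / "a")
        gen(tmp_path / "b")
        for fname in ("notes.jsonl", "annotations.bio"):
            assert (tmp_path / "a" / fname).read_bytes() == (tmp_path / "b" / fname).read_bytes()


class TestCorpusIO:
    def test_empty_corpus_round_trips(self, tmp_path):
        sc.write_corpus([], tmp_path / "c")
        assert sc.read_corpus(tmp_path / "c") == []

    def test_round_trip_identity(self, tmp_path, noisy_corpus):
        _, notes = noisy_corpus
        sc.write_corpus(notes, tmp_path / "c")
        assert sc.read_corpus(tmp_path / "c") == notes
        lines = (tmp_path / "c" / "notes.jsonl").read_text().splitlines()
        assert len(lines) == len(notes)

    def test_malformed_line_names_line_number(self, tmp_path):
        bad = tmp_path / "notes.jsonl"
        bad.write_text('{"id": "a", "sections": {}, "spans": [], "disease": "d", '
                       '"syndrome": "s", "qc_flags": []}\nnot json\n')
        with pytest.raises(sc.CorpusFormatError, match="line 2"):
            sc.read_corpus(bad)

    def test_ontology_round_trip(self, tmp_path, small_ontology):
        sc.write_ontology(small_ontology, tmp_path / "o.json")
        assert sc.read_ontology(tmp_path / "o.json") == small_ontology


class TestBioFormat:
    def test_two_token_span_tagged_b_then_i(self, tmp_path):
        note = sc.AnnotatedNote(
            "n1", {"chief_complaint": "ab cd 3days"},
            [sc.Span("chief_complaint", 0, 5, "symptom", "ab-cd"),
             sc.Span("chief_complaint", 6, 11, "duration", "3days")],
            "D", "S",
        )
        sc.write_bio([note], tmp_path / "x.bio")
        blocks = sc.read_bio(tmp_path / "x.bio")
        assert blocks[0]["tags"] == ["B-symptom", "I-symptom", "B-duration"]

    def test_one_block_per_nonempty_section(self, tmp_path, small_corpus):
        _, notes = small_corpus
        sc.write_bio(notes[:3], tmp_path / "x.bio")
        blocks = sc.read_bio(tmp_path / "x.bio")
        expected = sum(1 for n in notes[:3] for t in n.sections.values() if t.strip())
        assert len(blocks) == expected
        text = (tmp_path / "x.bio").read_text()
        for line in text.splitlines():
            if line and not line.startswith("#"):
                assert len(line.split("\t")) == 2

    def test_malformed_bio_line_reported(self, tmp_path):
        (tmp_path / "x.bio").write_text("tok\tB-symptom\ntok extra cols\n")
        with pytest.raises(sc.CorpusFormatError, match="line 2"):
            sc.read_bio(tmp_path / "x.bio")

    def test_spans_to_tags_round_trip_with_decode(self, small_corpus):
        from tcmaid.ner import decode_entities

        _, notes = small_corpus
        for n in notes[:10]:
            for section, text in n.sections.items():
                spans = [s for s in n.spans if s.section == section]
                toks, tags = sc.spans_to_tags(text, spans)
                decoded = decode_entities(toks, tags)
                toklist = sc.tokenize(text)
                rebuilt = {
                    (toklist[a][1], toklist[b - 1][2], t) for a, b, t in decoded
                }
                assert rebuilt == {(s.start, s.end, s.etype) for s in spans}
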