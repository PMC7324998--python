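"""Shared fixtures: small seeded synthetic corpora built at test time."""

import pytest

from tcmaid import features as ft
from tcmaid import synthetic_corpus as sc


@pytest.fixture(scope="session")
def small_ontology():
    return sc.build_ontology(3, 6, 2.0, seed=1)


@pytest.fixture(scope="session")
def small_corpus(small_ontology):
    """Clean separable corpus: 3 diseases x 25 notes, no noise, no violations."""
    cfg = sc.GenConfig(
        small_ontology,
        {d: 25 for d in small_ontology.disease_ids},
        seed=7,
    )
    notes = sc.generate_corpus(cfg)
    return cfg, notes


@pytest.fixture(scope="session")
def noisy_corpus(small_ontology):
    """Corpus with synonym noise, full-width mixing and planted QC violations."""
    cfg = sc.GenConfig(
        small_ontology,
        {d: 20 for d in small_ontology.disease_ids},
        qc_violations={"missing_page": 2, "inconsistent": 2, "nonstandard_complaint": 2},
        seed=13,
        synonym_noise=0.2,
        fullwidth_prob=0.3,
        placeholder_prob=0.4,
    )
    notes = sc.generate_corpus(cfg)
    return cfg, notes


@pytest.fixture(scope="session")
def small_lexicon(small_corpus):
    cfg, _ = small_corpus
    return ft.StandardLexicon(cfg.lexicon.surface_to_canonical())
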