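"""Seeded generation of annotated synthetic EHR corpora.

Real admission notes from a TCM hospital cannot be shipped, so this module
builds corpora with the statistical structure the rest of the pipeline
assumes: sectioned notes, entity spans (symptom, duration, tongue quality,
pulse, history), a many-to-many disease/syndrome ontology, severe class
imbalance, duration-qualified symptom mentions, full-width/half-width
character mixing, synonym variation, and planted quality-control
violations.  Notes are language-neutral token sequences drawn from a
generated lexicon; every note carries gold spans and gold disease/syndrome
labels, so supervised training of every downstream stage is possible
offline.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SECTION_NAMES",
    "QC_MISSING_PAGE",
    "QC_INCONSISTENT",
    "QC_NONSTANDARD_COMPLAINT",
    "Span",
    "Ontology",
    "Lexicon",
    "GenConfig",
    "AnnotatedNote",
    "build_ontology",
    "build_lexicon",
    "generate_corpus",
    "write_corpus",
    "read_corpus",
    "write_ontology",
    "read_ontology",
    "write_bio",
    "read_bio",
    "tokenize",
    "spans_to_tags",
    "CorpusFormatError",
]

#: Predefined note sections, in canonical order.
SECTION_NAMES = (
    "chief_complaint",
    "present_illness",
    "medical_history",
    "family_history",
    "physical_exam",
    "tongue",
    "pulse",
    "admission",
    "discharge",
)

QC_MISSING_PAGE = "missing_page"
QC_INCONSISTENT = "inconsistent"
QC_NONSTANDARD_COMPLAINT = "nonstandard_complaint"
QC_KINDS = (QC_MISSING_PAGE, QC_INCONSISTENT, QC_NONSTANDARD_COMPLAINT)

ENTITY_TYPES = ("symptom", "duration", "tongue_quality", "pulse", "history")

_TOKEN_RE = re.compile(r"\S+")

# ASCII '!'..'~' <-> full-width forms U+FF01..U+FF5E (1:1, length preserving).
_TO_FULLWIDTH = {cp: cp - 0x21 + 0xFF01 for cp in range(0x21, 0x7F)}


class CorpusFormatError(ValueError):
    """Raised when a corpus file cannot be parsed; names the line number."""


@dataclass(frozen=True)
class Span:
    """Entity span, 0-based half-open character offsets within one section."""

    section: str
    start: int
    end: int
    etype: str
    canonical: str

    def to_list(self) -> list:
        return [self.section, self.start, self.end, self.etype, self.canonical]

    @staticmethod
    def from_list(obj: list) -> "Span":
        section, start, end, etype, canonical = obj
        return Span(section, int(start), int(end), etype, canonical)


@dataclass(frozen=True)
class Ontology:
    """Disease and syndrome inventory with a many-to-many mapping."""

    disease_ids: tuple[str, ...]
    syndrome_ids: tuple[str, ...]
    disease_to_syndromes: dict[str, tuple[str, ...]]

    def validate(self) -> None:
        for d in self.disease_ids:
            syns = self.disease_to_syndromes.get(d, ())
            if not syns:
                raise ValueError(f"disease {d!r} maps to no syndrome")
            unknown = set(syns) - set(self.syndrome_ids)
            if unknown:
                raise ValueError(f"disease {d!r} maps to unknown syndromes {unknown}")


@dataclass
class Lexicon:
    """Surface forms per entity type.

    ``symptom_surfaces`` maps canonical symptom id -> list of surface forms
    (the first is the canonical surface; later entries are synonym
    variants).  Symptom canonicals are organized per disease: a disease has
    ``core`` symptoms shared by all of its syndromes plus a disjoint
    ``signature`` symptom set per (disease, syndrome) pair, so that with
    synonym noise 0 different diseases use disjoint symptom lexica.
    """

    symptom_surfaces: dict[str, list[str]]
    core_symptoms: dict[str, list[str]]  # disease -> canonical ids
    signature_symptoms: dict[str, dict[str, list[str]]]  # disease -> syndrome -> ids
    tongue_qualities: list[str]
    pulses: list[str]
    history_items: list[str]
    fillers: list[str]

    def surface_to_canonical(self) -> dict[str, str]:
        """Total synonym map (includes identity for canonical surfaces)."""
        out: dict[str, str] = {}
        for canon, surfaces in self.symptom_surfaces.items():
            for s in surfaces:
                out[s] = canon
        for term in self.tongue_qualities + self.pulses + self.history_items:
            out[term] = term
        return out

    def to_json(self) -> dict:
        return {
            "symptom_surfaces": self.symptom_surfaces,
            "core_symptoms": self.core_symptoms,
            "signature_symptoms": self.signature_symptoms,
            "tongue_qualities": self.tongue_qualities,
            "pulses": self.pulses,
            "history_items": self.history_items,
            "fillers": self.fillers,
        }

    @staticmethod
    def from_json(obj: dict) -> "Lexicon":
        return Lexicon(**obj)


@dataclass
class GenConfig:
    """Everything :func:`generate_corpus` needs, seed included."""

    ontology: Ontology
    per_class_counts: dict[str, int]
    qc_violations: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    lexicon: Lexicon | None = None
    max_note_tokens: int = 120
    synonym_noise: float = 0.0  # P(symptom surface is a synonym variant)
    fullwidth_prob: float = 0.0  # P(token rendered in full-width code points)
    placeholder_prob: float = 0.0  # P(non-text placeholder in an entity-free section)
    max_duration_days: int = 14

    def validate(self) -> None:
        self.ontology.validate()
        for d, c in self.per_class_counts.items():
            if c < 0:
                raise ValueError(f"negative note count for {d!r}")
            if d not in self.ontology.disease_ids:
                raise ValueError(f"unknown disease {d!r} in per_class_counts")
        for kind, c in self.qc_violations.items():
            if kind not in QC_KINDS:
                raise ValueError(f"unknown QC violation kind {kind!r}")
            if c < 0:
                raise ValueError("negative QC violation count")
        if sum(self.qc_violations.values()) > sum(self.per_class_counts.values()):
            raise ValueError("more QC violations requested than notes")


@dataclass
class AnnotatedNote:
    note_id: str
    sections: dict[str, str]
    spans: list[Span]
    disease: str
    syndrome: str
    qc_flags: frozenset[str] = frozenset()

    def to_json(self) -> dict:
        return {
            "id": self.note_id,
            "sections": self.sections,
            "spans": [s.to_list() for s in self.spans],
            "disease": self.disease,
            "syndrome": self.syndrome,
            "qc_flags": sorted(self.qc_flags),
        }

    @staticmethod
    def from_json(obj: dict) -> "AnnotatedNote":
        return AnnotatedNote(
            note_id=obj["id"],
            sections=dict(obj["sections"]),
            spans=[Span.from_list(s) for s in obj["spans"]],
            disease=obj["disease"],
            syndrome=obj["syndrome"],
            qc_flags=frozenset(obj["qc_flags"]),
        )


# ---------------------------------------------------------------------------
# ontology


def build_ontology(
    n_diseases: int,
    n_syndromes: int,
    mean_syndromes_per_disease: float,
    seed: int,
) -> Ontology:
    """Random many-to-many disease/syndrome map, deterministic per seed.

    Each disease draws a syndrome-set size around the requested mean
    (clipped to [1, n_syndromes]) and samples that many syndromes without
    replacement.  If no syndrome ends up shared between two diseases (and
    sharing is possible), one is forced, so the map is genuinely
    many-to-many whenever ``n_diseases >= 2``.
    """
    if n_diseases < 1 or n_syndromes < 1:
        raise ValueError("n_diseases and n_syndromes must be >= 1")
    if mean_syndromes_per_disease < 1:
        raise ValueError("mean_syndromes_per_disease must be >= 1")
    rng = np.random.default_rng(seed)
    diseases = tuple(f"D{i:03d}" for i in range(n_diseases))
    syndromes = tuple(f"S{i:03d}" for i in range(n_syndromes))
    mapping: dict[str, tuple[str, ...]] = {}
    for d in diseases:
        k = int(np.clip(round(rng.normal(mean_syndromes_per_disease, 1.0)), 1, n_syndromes))
        chosen = rng.choice(n_syndromes, size=k, replace=False)
        mapping[d] = tuple(syndromes[i] for i in sorted(chosen))
    if n_diseases >= 2:
        seen: set[str] = set()
        shared = False
        for d in diseases:
            if shared:
                break
            for s in mapping[d]:
                if s in seen:
                    shared = True
                    break
                seen.add(s)
        if not shared:
            d0, d1 = diseases[0], diseases[1]
            mapping[d1] = tuple(sorted(set(mapping[d1]) | {mapping[d0][0]}))
    onto = Ontology(diseases, syndromes, mapping)
    onto.validate()
    return onto


def build_lexicon(
    ontology: Ontology,
    seed: int,
    n_core: int = 4,
    n_signature: int = 3,
    n_synonyms: int = 2,
    two_token_frac: float = 0.3,
) -> Lexicon:
    """Derive a disjoint-by-disease symptom lexicon from an ontology.

    About ``two_token_frac`` of canonical symptom surfaces contain an
    internal space so their spans cover two tokens (exercising I- tags).
    """
    rng = np.random.default_rng(seed)
    symptom_surfaces: dict[str, list[str]] = {}
    core: dict[str, list[str]] = {}
    signature: dict[str, dict[str, list[str]]] = {}

    def register(canon: str) -> None:
        if rng.random() < two_token_frac:
            head, tail = canon.split("-", 1)
            surface = f"{head} {tail}"
        else:
            surface = canon
        surfaces = [surface]
        for v in range(n_synonyms):
            surfaces.append(f"{canon}~v{v}")
        symptom_surfaces[canon] = surfaces

    for d in ontology.disease_ids:
        core[d] = [f"sym-{d}c{j}" for j in range(n_core)]
        for c in core[d]:
            register(c)
        signature[d] = {}
        for s in ontology.disease_to_syndromes[d]:
            ids = [f"sym-{d}{s}x{j}" for j in range(n_signature)]
            signature[d][s] = ids
            for c in ids:
                register(c)

    return Lexicon(
        symptom_surfaces=symptom_surfaces,
        core_symptoms=core,
        signature_symptoms=signature,
        tongue_qualities=[f"tongue-q{i}" for i in range(6)],
        pulses=[f"pulse-p{i}" for i in range(5)],
        history_items=[f"hx-item{i}" for i in range(8)],
        fillers=[f"w{i}" for i in range(15)],
    )


# ---------------------------------------------------------------------------
# note assembly


class _SectionBuilder:
    """Accumulates tokens and records entity spans at character offsets."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.pos = 0
        self.spans: list[tuple[int, int, str, str]] = []

    def add(self, token: str, etype: str | None = None, canonical: str | None = None) -> None:
        if self.parts:
            self.pos += 1  # joining space
        start = self.pos
        self.parts.append(token)
        self.pos += len(token)
        if etype is not None:
            self.spans.append((start, self.pos, etype, canonical or token))

    def text(self) -> str:
        return " ".join(self.parts)


def _pick(rng: np.random.Generator, items: list[str]) -> str:
    return items[int(rng.integers(len(items)))]


def _symptom_surface(rng: np.random.Generator, lex: Lexicon, canon: str, noise: float) -> str:
    surfaces = lex.symptom_surfaces[canon]
    if noise > 0 and len(surfaces) > 1 and rng.random() < noise:
        return surfaces[1 + int(rng.integers(len(surfaces) - 1))]
    return surfaces[0]


def _fullwidth(text: str) -> str:
    return text.translate(_TO_FULLWIDTH)


def _apply_fullwidth(note: AnnotatedNote, rng: np.random.Generator, prob: float) -> None:
    """Map whole tokens to full-width forms; 1:1 code points keep spans valid."""
    if prob <= 0:
        return
    for name, text in note.sections.items():
        if not text:
            continue
        out = []
        last = 0
        for m in _TOKEN_RE.finditer(text):
            out.append(text[last : m.start()])
            tok = m.group()
            out.append(_fullwidth(tok) if rng.random() < prob else tok)
            last = m.end()
        out.append(text[last:])
        note.sections[name] = "".join(out)


def _build_note(
    rng: np.random.Generator,
    cfg: GenConfig,
    note_id: str,
    disease: str,
    syndrome: str,
) -> AnnotatedNote:
    lex = cfg.lexicon
    assert lex is not None
    sig = lex.signature_symptoms[disease][syndrome]
    core = lex.core_symptoms[disease]
    sections: dict[str, str] = {}
    spans: list[Span] = []
    sex = "M" if rng.random() < 0.5 else "F"
    age = int(rng.integers(18, 90))

    def emit(name: str, b: _SectionBuilder) -> None:
        sections[name] = b.text()
        spans.extend(Span(name, s, e, t, c) for s, e, t, c in b.spans)

    def add_symptom(b: _SectionBuilder, canon: str, with_duration: bool) -> None:
        surface = _symptom_surface(rng, lex, canon, cfg.synonym_noise)
        toks = surface.split(" ")
        if len(toks) == 1:
            b.add(surface, "symptom", canon)
        else:
            # multi-token surface: one span covering the joined tokens
            if b.parts:
                b.pos += 1
            start = b.pos
            for i, t in enumerate(toks):
                if i:
                    b.pos += 1
                b.parts.append(t)
                b.pos += len(t)
            b.spans.append((start, b.pos, "symptom", canon))
        if with_duration:
            days = int(rng.integers(1, cfg.max_duration_days + 1))
            b.add(f"{days}days", "duration", f"{days}days")

    # chief complaint: 1-2 signature symptoms, duration-qualified
    b = _SectionBuilder()
    n_sig = 1 + int(rng.integers(2))
    for canon in rng.choice(np.array(sig, dtype=object), size=min(n_sig, len(sig)), replace=False):
        add_symptom(b, str(canon), with_duration=True)
    emit("chief_complaint", b)

    # present illness: core + signature mix, fillers between entities
    b = _SectionBuilder()
    b.add(_pick(rng, lex.fillers))
    for canon in [_pick(rng, core), _pick(rng, sig)]:
        add_symptom(b, canon, with_duration=rng.random() < 0.5)
        if rng.random() < 0.5:
            b.add(_pick(rng, lex.fillers))
    emit("present_illness", b)

    # medical history: history items + an old symptom with long duration
    b = _SectionBuilder()
    b.add(_pick(rng, lex.history_items), "history")
    if rng.random() < 0.5:
        b.add(_pick(rng, lex.fillers))
        add_symptom(b, _pick(rng, core), with_duration=True)
    emit("medical_history", b)

    b = _SectionBuilder()
    if rng.random() < 0.5:
        b.add(_pick(rng, lex.history_items), "history")
    else:
        b.add(_pick(rng, lex.fillers))
    emit("family_history", b)

    # physical exam: non-entity observations (may host placeholders)
    b = _SectionBuilder()
    for _ in range(2 + int(rng.integers(3))):
        b.add(_pick(rng, lex.fillers))
    if cfg.placeholder_prob > 0 and rng.random() < cfg.placeholder_prob:
        b.add(f"[[img:{int(rng.integers(100))}]]")
    emit("physical_exam", b)

    b = _SectionBuilder()
    for q in rng.choice(np.array(lex.tongue_qualities, dtype=object), size=1 + int(rng.integers(2)), replace=False):
        b.add(str(q), "tongue_quality")
    emit("tongue", b)

    b = _SectionBuilder()
    b.add(_pick(rng, lex.pulses), "pulse")
    emit("pulse", b)

    for page in ("admission", "discharge"):
        b = _SectionBuilder()
        b.add(f"disease={disease}")
        b.add(f"sex={sex}")
        b.add(f"age={age}")
        b.add(_pick(rng, lex.fillers))
        emit(page, b)

    note = AnnotatedNote(note_id, sections, spans, disease, syndrome)
    _apply_fullwidth(note, rng, cfg.fullwidth_prob)
    return note


_KV_RE = re.compile(r"(\w+)=(\S+)")


def _plant_violation(note: AnnotatedNote, kind: str, rng: np.random.Generator) -> None:
    if kind == QC_MISSING_PAGE:
        page = "admission" if rng.random() < 0.5 else "discharge"
        del note.sections[page]
        note.spans = [s for s in note.spans if s.section != page]
    elif kind == QC_INCONSISTENT:
        text = note.sections["discharge"]
        m = _KV_RE.search(text)
        # flip the sex field between pages
        if "sex=M" in text:
            note.sections["discharge"] = text.replace("sex=M", "sex=F")
        else:
            note.sections["discharge"] = text.replace("sex=F", "sex=M")
        assert m is not None
    elif kind == QC_NONSTANDARD_COMPLAINT:
        note.spans = [s for s in note.spans if s.section != "chief_complaint"]
        note.sections["chief_complaint"] = "feels unwell lately"
    else:  # pragma: no cover
        raise ValueError(f"unknown violation kind {kind!r}")
    note.qc_flags = note.qc_flags | {kind}


def generate_corpus(config: GenConfig) -> list[AnnotatedNote]:
    """Generate the corpus described by ``config``.

    Per-disease note counts match ``per_class_counts`` exactly and exactly
    the configured number of notes carry each QC violation kind (at most
    one violation per note).  Deterministic for a fixed config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.lexicon is None:
        config.lexicon = build_lexicon(config.ontology, int(rng.integers(2**31)))

    notes: list[AnnotatedNote] = []
    i = 0
    for disease in config.ontology.disease_ids:
        count = config.per_class_counts.get(disease, 0)
        syndromes = config.ontology.disease_to_syndromes[disease]
        for _ in range(count):
            syndrome = syndromes[int(rng.integers(len(syndromes)))]
            notes.append(_build_note(rng, config, f"note{i:06d}", disease, syndrome))
            i += 1

    n_viol = sum(config.qc_violations.values())
    if n_viol:
        victims = rng.choice(len(notes), size=n_viol, replace=False)
        it = iter(victims)
        for kind in QC_KINDS:
            for _ in range(config.qc_violations.get(kind, 0)):
                _plant_violation(notes[int(next(it))], kind, rng)
    return notes


# ---------------------------------------------------------------------------
# I/O: JSONL notes, JSON ontology, CoNLL-style BIO annotations


def write_corpus(notes: list[AnnotatedNote], path: str | Path) -> None:
    """Write ``notes.jsonl`` and ``annotations.bio`` under directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "notes.jsonl", "w", encoding="utf-8") as fh:
        for note in notes:
            fh.write(json.dumps(note.to_json(), ensure_ascii=False) + "\n")
    write_bio(notes, path / "annotations.bio")


def read_corpus(path: str | Path) -> list[AnnotatedNote]:
    path = Path(path)
    fname = path / "notes.jsonl" if path.is_dir() else path
    notes = []
    with open(fname, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                notes.append(AnnotatedNote.from_json(json.loads(line)))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise CorpusFormatError(f"{fname}: malformed note on line {lineno}: {exc}") from exc
    return notes


def write_ontology(ontology: Ontology, path: str | Path) -> None:
    obj = {
        "disease_ids": list(ontology.disease_ids),
        "syndrome_ids": list(ontology.syndrome_ids),
        "disease_to_syndromes": {d: list(s) for d, s in ontology.disease_to_syndromes.items()},
    }
    Path(path).write_text(json.dumps(obj, indent=1) + "\n", encoding="utf-8")


def read_ontology(path: str | Path) -> Ontology:
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    onto = Ontology(
        tuple(obj["disease_ids"]),
        tuple(obj["syndrome_ids"]),
        {d: tuple(s) for d, s in obj["disease_to_syndromes"].items()},
    )
    onto.validate()
    return onto


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Whitespace tokenization with character offsets (token, start, end)."""
    return [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def spans_to_tags(text: str, spans: list[Span] | list[tuple[int, int, str]]) -> tuple[list[str], list[str]]:
    """BIO-encode the spans of one section. Returns (tokens, tags)."""
    toks = tokenize(text)
    tags = ["O"] * len(toks)
    norm = []
    for s in spans:
        if isinstance(s, Span):
            norm.append((s.start, s.end, s.etype))
        else:
            norm.append((s[0], s[1], s[2]))
    for start, end, etype in norm:
        first = True
        for i, (_, ts, te) in enumerate(toks):
            if ts >= start and te <= end:
                tags[i] = ("B-" if first else "I-") + etype
                first = False
    return [t[0] for t in toks], tags


def write_bio(notes: list[AnnotatedNote], path: str | Path) -> None:
    """CoNLL-style two-column file: token TAB tag, blank line per section."""
    with open(path, "w", encoding="utf-8") as fh:
        for note in notes:
            for section, text in note.sections.items():
                if not text:
                    continue
                toks, tags = spans_to_tags(text, [s for s in note.spans if s.section == section])
                if not toks:
                    continue
                fh.write(f"# note={note.note_id} section={section}\n")
                for tok, tag in zip(toks, tags):
                    fh.write(f"{tok}\t{tag}\n")
                fh.write("\n")


def read_bio(path: str | Path) -> list[dict]:
    """Read a BIO file back into blocks: {note_id, section, tokens, tags}."""
    blocks: list[dict] = []
    cur: dict | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("# "):
                meta = dict(m.groups() for m in re.finditer(r"(\w+)=(\S+)", line))
                cur = {"note_id": meta.get("note"), "section": meta.get("section"), "tokens": [], "tags": []}
                blocks.append(cur)
                continue
            if not line.strip():
                cur = None
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusFormatError(f"{path}: malformed BIO line {lineno}: {line!r}")
            if cur is None:
                cur = {"note_id": None, "section": None, "tokens": [], "tags": []}
                blocks.append(cur)
            cur["tokens"].append(parts[0])
            cur["tags"].append(parts[1])
    return blocks
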