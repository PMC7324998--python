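"""Note normalization, sectioning, quality control, balancing, partitioning.

Mirrors the intake stage of a hospital-EHR pipeline: full-width characters
are folded to half-width, non-text components (image placeholders) are
stripped, freestyle text is divided into predefined sections, notes with
missing or inconsistent admission/discharge pages or a non-standard chief
complaint are excluded, classes are balanced by down-sampling and
synthetic-minority oversampling, and the corpus is split 8:1:1.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .synthetic_corpus import AnnotatedNote, SECTION_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "SectionedNote",
    "QCReport",
    "QCConfig",
    "normalize_width",
    "strip_nontext",
    "split_sections",
    "preprocess_note",
    "qc_filter",
    "balance_classes",
    "partition",
]

# Full-width ASCII block U+FF01..U+FF5E -> '!'..'~'; ideographic space -> ' '.
_FULL_TO_HALF = {cp: cp - 0xFF01 + 0x21 for cp in range(0xFF01, 0xFF5F)}
_FULL_TO_HALF[0x3000] = 0x20

_PLACEHOLDER_RE = re.compile(r"\[\[[^\]]*\]\]")
_KV_RE = re.compile(r"(\w+)=(\S+)")

#: A standard chief complaint states symptoms with durations.
STANDARD_COMPLAINT_RE = re.compile(r"\d+\s*(day|month|year)s?\b")


@dataclass
class SectionedNote:
    note_id: str
    sections: dict[str, str]


@dataclass
class QCReport:
    kept: list[str]
    discarded: list[tuple[str, str]]  # (note_id, reason)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    def to_json(self) -> dict:
        return {"kept": self.kept, "discarded": [list(d) for d in self.discarded]}


@dataclass
class QCConfig:
    """Which admission/discharge fields must agree, and the complaint pattern."""

    consistency_fields: tuple[str, ...] = ("disease", "sex", "age")
    complaint_pattern: re.Pattern = STANDARD_COMPLAINT_RE
    required_pages: tuple[str, ...] = ("admission", "discharge")


def normalize_width(text: str) -> str:
    """Fold full-width (full-angle) code points to their half-width forms.

    Length preserving and idempotent; character spans computed on the raw
    text remain valid on the normalized text.
    """
    return text.translate(_FULL_TO_HALF)


def strip_nontext(note: AnnotatedNote | SectionedNote) -> AnnotatedNote | SectionedNote:
    """Remove embedded non-text placeholders (``[[...]]``) from every section.

    Surrounding text runs keep their order; runs are re-joined on single
    spaces where a placeholder was removed.
    """
    for name, text in note.sections.items():
        if "[[" not in text:
            continue
        cleaned = _PLACEHOLDER_RE.sub(" ", text)
        note.sections[name] = re.sub(r"\s{2,}", " ", cleaned).strip()
    return note


def split_sections(raw_text: str, header_spec: list[str] | None = None) -> SectionedNote:
    """Divide one freestyle note into predefined sections.

    ``header_spec`` lists the recognizable section markers (rendered in the
    text as ``[name]``).  Every character of the input is assigned to
    exactly one section; text before the first marker goes to a
    ``preamble`` section.  A duplicated marker concatenates with a logged
    warning.  Missing sections are simply absent.
    """
    headers = list(header_spec) if header_spec is not None else list(SECTION_NAMES)
    pattern = re.compile("|".join(re.escape(f"[{h}]") for h in headers))
    sections: dict[str, str] = {}
    matches = list(pattern.finditer(raw_text))
    pre = raw_text[: matches[0].start()] if matches else raw_text
    if pre.strip():
        sections["preamble"] = pre.strip()
    for i, m in enumerate(matches):
        name = m.group()[1:-1]
        end = matches[i + 1].start() if i + 1 < len(matches) else len(raw_text)
        body = raw_text[m.end() : end].strip()
        if name in sections:
            logger.warning("duplicated section marker [%s]; concatenating", name)
            sections[name] = (sections[name] + " " + body).strip()
        else:
            sections[name] = body
    return SectionedNote(note_id="", sections=sections)


def preprocess_note(note: AnnotatedNote) -> AnnotatedNote:
    """Width-normalize and strip non-text content, in place."""
    strip_nontext(note)
    for name, text in note.sections.items():
        note.sections[name] = normalize_width(text)
    return note


def _page_fields(text: str) -> dict[str, str]:
    return {m.group(1): m.group(2) for m in _KV_RE.finditer(text)}


def qc_filter(
    notes: list[AnnotatedNote | SectionedNote],
    config: QCConfig | None = None,
) -> QCReport:
    """Partition notes into kept and discarded with a recorded reason.

    A note is discarded iff it (a) lacks an admission or discharge page
    (``incomplete``), (b) has a configured field differing between the two
    pages (``inconsistent``), or (c) has no chief complaint matching the
    standard symptom-with-duration pattern (``nonstandard_complaint``).
    The first failing rule, in that order, is the recorded reason.
    """
    cfg = config or QCConfig()
    kept: list[str] = []
    discarded: list[tuple[str, str]] = []
    for note in notes:
        nid = note.note_id
        sections = note.sections
        if any(not sections.get(p, "").strip() for p in cfg.required_pages):
            discarded.append((nid, "incomplete"))
            continue
        adm = _page_fields(sections["admission"])
        dis = _page_fields(sections["discharge"])
        if any(adm.get(f) != dis.get(f) for f in cfg.consistency_fields):
            discarded.append((nid, "inconsistent"))
            continue
        if not cfg.complaint_pattern.search(sections.get("chief_complaint", "")):
            discarded.append((nid, "nonstandard_complaint"))
            continue
        kept.append(nid)
    return QCReport(kept=kept, discarded=discarded)


def balance_classes(
    X: np.ndarray,
    y: np.ndarray,
    target_per_class: int,
    seed: int,
    k_neighbors: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Bring every class to exactly ``target_per_class`` records.

    Classes above target are reduced by uniform sampling without
    replacement; classes below target are augmented with synthetic-minority
    oversampling: a new vector is ``x + u * (neighbor - x)`` with
    ``u ~ Uniform(0, 1)`` and the neighbor drawn among the ``k_neighbors``
    nearest same-class points.  Deterministic for a fixed seed.
    """
    if target_per_class < 1:
        raise ValueError("target_per_class must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    out_X: list[np.ndarray] = []
    out_y: list[np.ndarray] = []
    for cls in sorted(np.unique(y).tolist()):
        Xc = X[y == cls]
        n = len(Xc)
        if n > target_per_class:
            idx = rng.choice(n, size=target_per_class, replace=False)
            Xb = Xc[np.sort(idx)]
        elif n == target_per_class:
            Xb = Xc
        else:
            if n < 2:
                raise ValueError(
                    f"class {cls!r} has {n} record(s); oversampling interpolation undefined"
                )
            k = min(k_neighbors, n - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
            _, nbr = nn.kneighbors(Xc)  # column 0 is the point itself
            n_new = target_per_class - n
            base = rng.integers(n, size=n_new)
            pick = rng.integers(1, k + 1, size=n_new)
            u = rng.random(size=(n_new, 1))
            neigh = Xc[nbr[base, pick]]
            synth = Xc[base] + u * (neigh - Xc[base])
            Xb = np.vstack([Xc, synth])
        out_X.append(Xb)
        out_y.append(np.full(len(Xb), cls, dtype=y.dtype))
    return np.vstack(out_X), np.concatenate(out_y)


def partition(
    ids: list[str],
    seed: int,
    strata: list | None = None,
    ratios: tuple[int, int, int] = (8, 1, 1),
) -> tuple[list[str], list[str], list[str]]:
    """Split ids into (train, val, test), stratified, deterministic.

    Validation and test each get ``floor(N * r / sum(ratios))`` ids (with
    the default 8:1:1 that is ``floor(N/10)`` each); the remainder goes to
    train.  Allocation across strata follows largest-remainder rounding so
    the global sizes are exact and each stratum is split as evenly as the
    floors allow.
    """
    if not ids:
        raise ValueError("cannot partition an empty id list")
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    N = len(ids)
    total = sum(ratios)
    n_val = N * ratios[1] // total
    n_test = N * ratios[2] // total
    labels = list(strata) if strata is not None else ["_all"] * N
    if len(labels) != N:
        raise ValueError("strata must align with ids")

    rng = np.random.default_rng(seed)
    by_label: dict = {}
    for i, lab in enumerate(labels):
        by_label.setdefault(lab, []).append(ids[i])
    for lab in by_label:
        members = by_label[lab]
        order = rng.permutation(len(members))
        by_label[lab] = [members[i] for i in order]

    def allocate(want: int, sizes: dict) -> dict:
        quota = {lab: sizes[lab] * want / N for lab in sizes}
        base = {lab: int(np.floor(q)) for lab, q in quota.items()}
        short = want - sum(base.values())
        order = sorted(sizes, key=lambda lab: (-(quota[lab] - base[lab]), str(lab)))
        for lab in order[:short]:
            base[lab] += 1
        return base

    sizes = {lab: len(m) for lab, m in by_label.items()}
    val_n = allocate(n_val, sizes)
    rem = {lab: sizes[lab] - val_n[lab] for lab in sizes}
    # allocate test from what's left, still exact globally
    quota = {lab: min(rem[lab], sizes[lab] * n_test / N) for lab in sizes}
    base = {lab: int(np.floor(q)) for lab, q in quota.items()}
    short = n_test - sum(base.values())
    order = sorted(sizes, key=lambda lab: (-(quota[lab] - base[lab]), str(lab)))
    while short > 0:
        progressed = False
        for lab in order:
            if short > 0 and base[lab] < rem[lab]:
                base[lab] += 1
                short -= 1
                progressed = True
        if not progressed:  # pragma: no cover - sum(rem) >= n_test always
            break
    test_n = base

    train: list[str] = []
    val: list[str] = []
    test: list[str] = []
    for lab in sorted(by_label, key=str):
        members = by_label[lab]
        nv, nt = val_n[lab], test_n[lab]
        val.extend(members[:nv])
        test.extend(members[nv : nv + nt])
        train.extend(members[nv + nt :])
    return train, val, test
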