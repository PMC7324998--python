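"""Weighted feature vectors from structured records.

Entity surfaces are standardized against a synonym dictionary, mentions of
the same canonical term across sections are merged (split-and-join), each
duration-qualified symptom is expanded into a bare term plus a
symptom-with-duration compound term, and every term receives a recency
weight: with N total time units, an occurrence n units in the past weighs
(N - n)/N, so the most recent mention weighs 1 and one N units old weighs
0 (the weight grid itself is weight(k) = k/N, built from weight(0) = 0 by
adding a constant increment 1/N).  Per-term weighted sums above a
threshold become the coordinates of a fixed-length vector over a feature
index frozen on the training split.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .ner import StructuredRecord

logger = logging.getLogger(__name__)

__all__ = [
    "StandardLexicon",
    "TimeWeightScheme",
    "FeatureGroup",
    "FeatureVector",
    "standardize",
    "parse_duration_days",
    "split_and_join",
    "expand_symptom_time",
    "time_weight",
    "weighted_sum",
    "select_and_vectorize",
    "record_groups",
    "build_feature_index",
    "vectorize_record",
    "cnn_tokens",
]

_DURATION_RE = re.compile(r"(\d+)\s*(day|month|year)s?", re.IGNORECASE)
_UNIT_DAYS = {"day": 1, "month": 30, "year": 365}


@dataclass
class StandardLexicon:
    """Surface form -> canonical term id (total on configured synonyms)."""

    mapping: dict[str, str]

    def __contains__(self, term: str) -> bool:
        return term in self.mapping


@dataclass(frozen=True)
class TimeWeightScheme:
    """Affine recency weights over N time units (unit: day by default).

    ``weight(k) = k / N`` for k = 0..N: starts at 0, rises by a constant
    increment 1/N per unit, reaches 1.
    """

    N: int = 365

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")

    @property
    def increment(self) -> float:
        return 1.0 / self.N

    def weight(self, k: int) -> float:
        if not 0 <= k <= self.N:
            raise ValueError(f"weight index {k} outside [0, {self.N}]")
        return k / self.N


@dataclass
class FeatureGroup:
    """One canonical feature term with its (section, distance) occurrences."""

    term: str
    occurrences: list[tuple[str, int | None]] = field(default_factory=list)


@dataclass
class FeatureVector:
    index: dict[str, int]
    values: np.ndarray


def standardize(term: str, lexicon: StandardLexicon) -> str:
    """Map a surface form to its canonical term; unknown forms pass through."""
    canon = lexicon.mapping.get(term)
    if canon is None:
        logger.info("no standard form for %r; kept verbatim", term)
        return term
    return canon


def parse_duration_days(surface: str | None) -> int | None:
    """'3days' / '2 months' / '1year' -> days; None if unparseable."""
    if not surface:
        return None
    m = _DURATION_RE.search(surface)
    if not m:
        logger.info("unparseable duration %r", surface)
        return None
    return int(m.group(1)) * _UNIT_DAYS[m.group(2).lower()]


def time_weight(n: int, scheme: TimeWeightScheme) -> float:
    """Recency weight of an occurrence ``n`` time units in the past.

    Distance 0 (now) -> 1.0; distance N -> 0.0; affine in between.
    """
    if not 0 <= n <= scheme.N:
        raise ValueError(f"time distance {n} outside [0, {scheme.N}]")
    return scheme.weight(scheme.N - n)


def weighted_sum(group: FeatureGroup, scheme: TimeWeightScheme) -> float:
    """Sum of recency weights over a group's occurrences.

    Occurrences with no time stamp contribute weight 1 (treated as
    current); distances are clipped at N, i.e. anything older than the
    horizon weighs 0.
    """
    total = 0.0
    for _section, dist in group.occurrences:
        if dist is None:
            total += 1.0
        else:
            total += time_weight(min(dist, scheme.N), scheme)
    return total


def split_and_join(
    record: StructuredRecord, lexicon: StandardLexicon
) -> dict[str, list[tuple[str, str | None]]]:
    """Merge same-canonical entities across sections.

    Returns canonical id -> list of (section, duration surface or None);
    one group per distinct canonical id, retaining every occurrence.
    """
    groups: dict[str, list[tuple[str, str | None]]] = {}
    for ent in record.entities:
        canon = standardize(ent.surface, lexicon)
        groups.setdefault(canon, []).append((ent.section, ent.duration))
    return groups


def expand_symptom_time(pairs: list[tuple[str, str | None]]) -> list[str]:
    """Expand (symptom, duration) pairs into feature terms.

    Each symptom yields its bare term; a paired symptom additionally
    yields the compound ``symptom|duration`` term, in input order with the
    bare term first.
    """
    out: list[str] = []
    for symptom, duration in pairs:
        out.append(symptom)
        if duration is not None:
            out.append(f"{symptom}|{duration}")
    return out


def record_groups(
    record: StructuredRecord,
    lexicon: StandardLexicon,
    scheme: TimeWeightScheme,
) -> list[FeatureGroup]:
    """All feature groups of one record: bare, compound and non-symptom terms.

    A duration-qualified symptom mention contributes a dated occurrence to
    its bare group and one to its compound group; undated mentions (and
    tongue/pulse/history entities) contribute timeless occurrences.
    """
    merged = split_and_join(record, lexicon)
    groups: dict[str, FeatureGroup] = {}

    def occ(term: str, section: str, dist: int | None) -> None:
        groups.setdefault(term, FeatureGroup(term)).occurrences.append((section, dist))

    for canon, occurrences in merged.items():
        for section, duration in occurrences:
            dist = parse_duration_days(duration)
            occ(canon, section, dist)
            if duration is not None:
                terms = expand_symptom_time([(canon, duration)])
                for term in terms[1:]:
                    occ(term, section, dist)
    return list(groups.values())


def select_and_vectorize(
    sums: dict[str, float],
    index: dict[str, int],
    tau: float = 0.0,
) -> FeatureVector:
    """Weighted sums above ``tau`` become vector coordinates; rest are 0.

    Terms absent from the (training-frozen) index are dropped with a log
    entry.  Permutation-stable: the result depends only on the sums.
    """
    values = np.zeros(len(index))
    for term, s in sums.items():
        pos = index.get(term)
        if pos is None:
            logger.info("feature %r not in index; dropped", term)
            continue
        if s > tau:
            values[pos] = s
    return FeatureVector(index, values)


def build_feature_index(
    records: list[StructuredRecord],
    lexicon: StandardLexicon,
    scheme: TimeWeightScheme,
) -> dict[str, int]:
    """Feature term -> position, frozen on the training corpus vocabulary."""
    terms: set[str] = set()
    for rec in records:
        for g in record_groups(rec, lexicon, scheme):
            terms.add(g.term)
    return {t: i for i, t in enumerate(sorted(terms))}


def vectorize_record(
    record: StructuredRecord,
    lexicon: StandardLexicon,
    scheme: TimeWeightScheme,
    index: dict[str, int],
    tau: float = 0.0,
) -> FeatureVector:
    groups = record_groups(record, lexicon, scheme)
    sums = {g.term: weighted_sum(g, scheme) for g in groups}
    return select_and_vectorize(sums, index, tau)


def cnn_tokens(record: StructuredRecord, lexicon: StandardLexicon) -> list[str]:
    """Entity token sequence for the disease classifier, in note order.

    The classifier consumes the extracted named entities and their
    relationships: each entity's canonical term, with the compound
    symptom-with-duration term following a paired symptom.
    """
    out: list[str] = []
    for ent in record.entities:
        canon = standardize(ent.surface, lexicon)
        out.append(canon)
        if ent.duration is not None:
            out.append(f"{canon}|{ent.duration}")
    return out
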