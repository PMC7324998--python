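"""End-to-end orchestration and evaluation.

Ties the stages together: preprocessing and quality control, entity
recognition, feature vectorization, disease top-k classification and
per-disease syndrome voting; computes top-k disease accuracy, per-disease
syndrome accuracy tables and system-level joint accuracy (disease AND
syndrome simultaneously correct).

System top-k uses the gold disease's syndrome model only when the gold
disease appears within the top-k disease predictions; otherwise the case
counts as incorrect.  This makes system top-k <= disease top-k by
construction, matching the ordering the scores must satisfy.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import disease_classifier as dc
from . import features as ft
from . import ner as nermod
from . import preprocess as pp
from . import syndrome_ensemble as se
from .synthetic_corpus import AnnotatedNote, Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "TrainedSystem",
    "TrainConfig",
    "topk_accuracy",
    "system_accuracy",
    "train_system",
    "run_pipeline",
    "save_system",
    "load_system",
]


@dataclass
class EvalReport:
    disease_topk: dict[int, float]
    system_topk: dict[int, float]
    syndrome_table: dict[str, dict[str, float]]  # disease -> kind/integration -> acc
    n_cases: int

    def to_json(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "disease_topk": {str(k): v for k, v in sorted(self.disease_topk.items())},
            "system_topk": {str(k): v for k, v in sorted(self.system_topk.items())},
            "syndrome_table": self.syndrome_table,
        }

    def syndrome_table_frame(self):
        """Table-style view (one row per disease, one column per learner)."""
        import pandas as pd

        return pd.DataFrame(self.syndrome_table).T.sort_index()


def topk_accuracy(ranked: list[list[str]], gold: list[str], k: int) -> float:
    """Fraction of cases whose gold label is among the first k predictions."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not ranked:
        raise ValueError("empty evaluation set")
    if len(ranked) != len(gold):
        raise ValueError("predictions and gold labels must align")
    hits = sum(1 for r, g in zip(ranked, gold) if g in r[:k])
    return hits / len(gold)


def system_accuracy(
    disease_ranked: list[list[str]],
    syndrome_top1: list[str | None],
    gold_pairs: list[tuple[str, str]],
    k: int,
) -> float:
    """Joint accuracy: gold disease within top-k AND gold syndrome predicted.

    ``syndrome_top1[i]`` is the top syndrome from the gold disease's model
    (None when unavailable).
    """
    if not gold_pairs:
        return 0.0
    hits = 0
    for ranked, syn, (gd, gs) in zip(disease_ranked, syndrome_top1, gold_pairs):
        if gd in ranked[:k] and syn == gs:
            hits += 1
    return hits / len(gold_pairs)


# ---------------------------------------------------------------------------
# training orchestration


@dataclass
class TrainedSystem:
    """Everything needed to run the pipeline on new notes."""

    ontology: Ontology
    lexicon: ft.StandardLexicon
    scheme: ft.TimeWeightScheme
    ner_model: nermod.NerModel
    feature_index: dict[str, int]
    cnn: dc.TextCnn
    registry: se.Registry
    tau: float = 0.0
    meta: dict = field(default_factory=dict)


@dataclass
class TrainConfig:
    seed: int = 0
    time_units: int = 365
    tau: float = 0.0
    ner_hyperparams: dict = field(default_factory=dict)
    ner_max_train_notes: int | None = 400
    cnn: dc.TextCnnConfig | None = None
    learner_specs: list[se.BaseLearnerSpec] | None = None
    balance_target: int | None = None  # per-disease target for CNN training
    qc: pp.QCConfig = field(default_factory=pp.QCConfig)
    lexicon: ft.StandardLexicon | None = None  # synonym dictionary


def _drop_rare_syndromes(disease: str, X: np.ndarray, y: np.ndarray):
    """A syndrome seen once cannot be learned; drop its records (logged)."""
    labs, counts = np.unique(y, return_counts=True)
    rare = set(labs[counts < 2].tolist())
    if rare and len(labs) - len(rare) >= 1:
        logger.info("disease %s: dropping rare syndromes %s from training", disease, sorted(rare))
        keep = ~np.isin(y, sorted(rare))
        return X[keep], y[keep]
    return X, y


def _note_record(
    note: AnnotatedNote,
    ner_model: nermod.NerModel | None,
    use_gold_spans: bool,
) -> nermod.StructuredRecord:
    if use_gold_spans:
        spans = note.spans
    else:
        assert ner_model is not None
        spans = nermod.predict_spans(ner_model, note)
    return nermod.structure(note, spans)


def train_system(
    corpus: list[AnnotatedNote],
    config: TrainConfig | None = None,
) -> tuple[TrainedSystem, dict]:
    """Train every stage on a QC-filtered, partitioned corpus.

    Returns the trained system plus a dict with the id splits and the QC
    report.  Gold annotations train the tagger; downstream stages consume
    the tagger's own output, so recognition errors propagate realistically.
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)

    notes = [pp.preprocess_note(n) for n in corpus]
    qc = pp.qc_filter(notes, cfg.qc)
    by_id = {n.note_id: n for n in notes}
    kept = [by_id[i] for i in qc.kept]
    logger.info("QC kept %d of %d notes", len(kept), len(notes))
    if not kept:
        raise ValueError("no notes survive quality control")

    train_ids, val_ids, test_ids = pp.partition(
        [n.note_id for n in kept], seed=int(rng.integers(2**31)),
        strata=[n.disease for n in kept],
    )
    train = [by_id[i] for i in train_ids]
    val = [by_id[i] for i in val_ids]

    # 1. NER
    ner_train = train[: cfg.ner_max_train_notes] if cfg.ner_max_train_notes else train
    ner_val = val[: max(1, len(val) // 2)]
    ner_model, trace = nermod.fit(
        ner_train, ner_val, cfg.ner_hyperparams, seed=int(rng.integers(2**31))
    )
    logger.info("NER val F1 trace: %s", trace)

    # ontology + synonym lexicon are part of the system's standing knowledge
    onto_diseases = tuple(sorted({n.disease for n in kept}))
    onto_syndromes = tuple(sorted({n.syndrome for n in kept}))
    d2s: dict[str, tuple[str, ...]] = {}
    for n in kept:
        d2s.setdefault(n.disease, ())
        if n.syndrome not in d2s[n.disease]:
            d2s[n.disease] = tuple(sorted({*d2s[n.disease], n.syndrome}))
    ontology = Ontology(onto_diseases, onto_syndromes, d2s)
    lexicon = cfg.lexicon or ft.StandardLexicon({})
    scheme = ft.TimeWeightScheme(cfg.time_units)

    # 2. features from the tagger's own spans
    train_records = [_note_record(n, ner_model, use_gold_spans=False) for n in train]
    val_records = [_note_record(n, ner_model, use_gold_spans=False) for n in val]
    index = ft.build_feature_index(train_records, lexicon, scheme)

    # 3. disease classifier over entity token sequences
    cnn_cfg = cfg.cnn or dc.TextCnnConfig(
        L=16, d=32, n_filters=32, seed=int(rng.integers(2**31)), epochs=20
    )
    cnn_train = [(ft.cnn_tokens(r, lexicon), n.disease) for r, n in zip(train_records, train)]
    cnn_val = [(ft.cnn_tokens(r, lexicon), n.disease) for r, n in zip(val_records, val)]
    if cfg.balance_target:
        # token sequences cannot be interpolated: resample to the target count
        # (without replacement above it, with replacement below it)
        bal_rng = np.random.default_rng(int(rng.integers(2**31)))
        by_cls: dict[str, list[tuple[list[str], str]]] = {}
        for item in cnn_train:
            by_cls.setdefault(item[1], []).append(item)
        cnn_train = []
        for d in sorted(by_cls):
            items = by_cls[d]
            take = bal_rng.choice(len(items), size=cfg.balance_target, replace=len(items) < cfg.balance_target)
            cnn_train.extend(items[i] for i in take)
    cnn = dc.fit(cnn_train, cnn_val, cnn_cfg)

    # 4. per-disease syndrome ensembles on (optionally balanced) vectors
    Xtr = np.stack(
        [ft.vectorize_record(r, lexicon, scheme, index, cfg.tau).values for r in train_records]
    )
    registry_models: dict[str, se.IntegratedModel] = {}
    diseases = np.array([n.disease for n in train])
    syndromes = np.array([n.syndrome for n in train])
    for d in ontology.disease_ids:
        mask = diseases == d
        if not mask.any():
            continue
        Xd, yd = _drop_rare_syndromes(d, Xtr[mask], syndromes[mask])
        registry_models[d] = se.fit_integrated(
            d, Xd, yd, cfg.learner_specs, seed=int(rng.integers(2**31))
        )
    registry = se.Registry(registry_models)

    system = TrainedSystem(ontology, lexicon, scheme, ner_model, index, cnn, registry, cfg.tau)
    splits = {"train": train_ids, "val": val_ids, "test": test_ids, "qc": qc}
    return system, splits


# ---------------------------------------------------------------------------
# inference + evaluation


def run_pipeline(
    notes: list[AnnotatedNote],
    system: TrainedSystem,
    ks: tuple[int, ...] = (1, 3, 5),
    run_dir: str | Path | None = None,
    syndrome_folds: int = 5,
    eval_seed: int = 0,
) -> tuple[list[dict], EvalReport]:
    """Run preprocessing, NER, features, disease top-k and syndrome voting.

    Returns per-note predictions and an :class:`EvalReport`.  With a
    ``run_dir``, every intermediate artifact (predictions, report,
    manifest) is written there.
    """
    if not notes:
        report = EvalReport({k: 0.0 for k in ks}, {k: 0.0 for k in ks}, {}, 0)
        if run_dir is not None:
            _write_run(run_dir, [], report, system)
        return [], report

    notes = [pp.preprocess_note(n) for n in notes]
    kmax = max(ks)
    predictions: list[dict] = []
    disease_ranked: list[list[str]] = []
    gold_pairs: list[tuple[str, str]] = []
    gold_syn_top1: list[str | None] = []
    vectors: list[np.ndarray] = []

    for note in notes:
        record = _note_record(note, system.ner_model, use_gold_spans=False)
        tokens = ft.cnn_tokens(record, system.lexicon)
        vec = ft.vectorize_record(record, system.lexicon, system.scheme, system.feature_index, system.tau)
        pred = dc.predict_topk(system.cnn, tokens, kmax)
        ranked_diseases = [d for d, _ in pred.ranked]
        top_disease = ranked_diseases[0]
        if top_disease in system.registry:
            syn_ranked = se.predict_syndrome(vec.values, top_disease, system.registry)
        else:
            syn_ranked = []
        if note.disease in system.registry:
            gold_model_syn = se.predict_syndrome(vec.values, note.disease, system.registry)
            gold_syn_top1.append(gold_model_syn[0][0])
        else:
            gold_syn_top1.append(None)
        vectors.append(vec.values)
        disease_ranked.append(ranked_diseases)
        gold_pairs.append((note.disease, note.syndrome))
        predictions.append(
            {
                "id": note.note_id,
                "diseases": [[d, p] for d, p in pred.ranked],
                "syndromes": [[s, int(v), c] for s, v, c in syn_ranked],
            }
        )

    gold_diseases = [d for d, _ in gold_pairs]
    disease_topk = {k: topk_accuracy(disease_ranked, gold_diseases, k) for k in ks}
    system_topk = {k: system_accuracy(disease_ranked, gold_syn_top1, gold_pairs, k) for k in ks}

    # per-disease syndrome accuracy table (5-fold CV on this evaluation set)
    X = np.stack(vectors)
    table: dict[str, dict[str, float]] = {}
    diseases = np.array(gold_diseases)
    syndromes = np.array([s for _, s in gold_pairs])
    for d in sorted(set(gold_diseases)) if syndrome_folds >= 2 else []:
        mask = diseases == d
        yd = syndromes[mask]
        classes, counts = np.unique(yd, return_counts=True)
        if len(classes) > 1 and counts.min() < 2:
            logger.warning("disease %s: a syndrome has a single record; skipping CV table row", d)
            continue
        try:
            table[d] = se.evaluate_models(X[mask], yd, folds=syndrome_folds, seed=eval_seed)
        except ValueError as exc:
            logger.warning("disease %s: %s", d, exc)

    report = EvalReport(disease_topk, system_topk, table, len(notes))
    if run_dir is not None:
        _write_run(run_dir, predictions, report, system)
    return predictions, report


def save_system(system: TrainedSystem, path: str | Path) -> None:
    """Persist a trained system to a directory (models + JSON sidecars)."""
    import joblib

    from .synthetic_corpus import write_ontology

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    system.ner_model.save(path / "ner.npz")
    system.cnn.save(path / "cnn.npz")
    joblib.dump(system.registry, path / "registry.joblib")
    write_ontology(system.ontology, path / "ontology.json")
    sidecar = {
        "lexicon": system.lexicon.mapping,
        "feature_index": system.feature_index,
        "time_units": system.scheme.N,
        "tau": system.tau,
        "meta": system.meta,
    }
    (path / "system.json").write_text(json.dumps(sidecar, indent=1) + "\n", encoding="utf-8")


def load_system(path: str | Path) -> TrainedSystem:
    import joblib

    from .synthetic_corpus import read_ontology

    path = Path(path)
    sidecar = json.loads((path / "system.json").read_text(encoding="utf-8"))
    return TrainedSystem(
        ontology=read_ontology(path / "ontology.json"),
        lexicon=ft.StandardLexicon(sidecar["lexicon"]),
        scheme=ft.TimeWeightScheme(sidecar["time_units"]),
        ner_model=nermod.NerModel.load(path / "ner.npz"),
        feature_index=sidecar["feature_index"],
        cnn=dc.TextCnn.load(path / "cnn.npz"),
        registry=joblib.load(path / "registry.joblib"),
        tau=sidecar["tau"],
        meta=sidecar.get("meta", {}),
    )


def _write_run(run_dir: str | Path, predictions: list[dict], report: EvalReport, system: TrainedSystem) -> None:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    with open(run_dir / "predictions.jsonl", "w", encoding="utf-8") as fh:
        for p in predictions:
            fh.write(json.dumps(p) + "\n")
    (run_dir / "report.json").write_text(json.dumps(report.to_json(), indent=1) + "\n", encoding="utf-8")
    if report.syndrome_table:
        report.syndrome_table_frame().to_csv(run_dir / "syndrome_table.csv")
    manifest = {
        "n_cases": report.n_cases,
        "feature_index_size": len(system.feature_index),
        "diseases": list(system.ontology.disease_ids),
        "content_hash": hashlib.sha256(
            json.dumps([p for p in predictions]).encode()
        ).hexdigest(),
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n", encoding="utf-8")
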