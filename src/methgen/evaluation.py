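"""Classifier-based evaluation of methylome generators.

The protocol: split the real data 70/30 stratified by cancer type, fit the
generators (CVAE and/or beta benchmark) on the 70%, train multi-class
classifiers (decision tree, Gaussian naive Bayes, random forest,
k-nearest-neighbour, SVM) on the 30%, generate a fixed number of samples
per cancer type from each generator, and ask the classifiers to recover
the intended type.  A generated sample counts as correct iff it is
classified as the condition it was generated for.  The whole loop is
repeated with fresh splits and generation seeds, yielding one accuracy
distribution per (classifier, generator).

Also provided: per-condition one-vs-rest AUC from classifier scores, and a
joint 3-D t-SNE embedding of real and generated samples for visual cluster
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .benchmark import fit_table, sample_benchmark
from .cvae import CVAEConfig, train_cvae, generate
from .io import BetaMatrix, ConditionVector
from .preprocess import chunk_cpgs

__all__ = [
    "EvalReport",
    "EvaluationError",
    "CLASSIFIER_TAGS",
    "split_data",
    "train_classifiers",
    "evaluate_generated",
    "one_vs_rest_auc",
    "embed_tsne",
    "compare_generators",
]

CLASSIFIER_TAGS = ("DT", "NB", "RF", "KNN", "SVM")


class EvaluationError(ValueError):
    pass


@dataclass
class EvalReport:
    """Per-(classifier, generator) metrics over repetitions.

    ``records`` holds one row per (repetition, classifier, generator) with
    overall accuracy, per-condition accuracy, a confusion matrix over
    ``conditions`` (rows = intended, columns = predicted) and per-condition
    one-vs-rest AUC (NaN where undefined).
    """

    conditions: list[str]
    records: list[dict] = field(default_factory=list)
    train_fraction: float = 0.7
    seed: int | None = None
    notes: dict = field(default_factory=dict)

    def add(self, *, repetition: int, classifier: str, generator: str,
            confusion: np.ndarray, per_condition_auc: dict[str, float]) -> None:
        confusion = np.asarray(confusion)
        total = confusion.sum()
        acc = float(np.trace(confusion) / total) if total else float("nan")
        per_cond = {}
        for i, c in enumerate(self.conditions):
            row = confusion[i].sum()
            per_cond[c] = float(confusion[i, i] / row) if row else float("nan")
        self.records.append(
            {
                "repetition": repetition,
                "classifier": classifier,
                "generator": generator,
                "accuracy": acc,
                "per_condition_accuracy": per_cond,
                "confusion": confusion,
                "per_condition_auc": per_condition_auc,
            }
        )

    def accuracy_table(self) -> pd.DataFrame:
        """One row per record: repetition, classifier, generator, accuracy."""
        return pd.DataFrame(
            [
                {k: r[k] for k in ("repetition", "classifier", "generator",
                                   "accuracy")}
                for r in self.records
            ]
        )

    def mean_accuracy(self, classifier: str, generator: str) -> float:
        vals = [
            r["accuracy"]
            for r in self.records
            if r["classifier"] == classifier and r["generator"] == generator
        ]
        if not vals:
            raise KeyError((classifier, generator))
        return float(np.mean(vals))

    def pooled_confusion(self, classifier: str, generator: str) -> np.ndarray:
        mats = [
            r["confusion"]
            for r in self.records
            if r["classifier"] == classifier and r["generator"] == generator
        ]
        if not mats:
            raise KeyError((classifier, generator))
        return np.sum(mats, axis=0)


def split_data(
    m: BetaMatrix,
    labels: ConditionVector,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[tuple[BetaMatrix, ConditionVector], tuple[BetaMatrix, ConditionVector]]:
    """Stratified random split into (generator-train, classifier-train).

    Default 70% for fitting the generators, 30% for the classifiers.
    Partitions are disjoint, exhaustive, and per-condition proportions are
    within one sample of the target fraction.
    """
    if not (0.0 < train_fraction < 1.0):
        raise EvaluationError("train_fraction must lie in (0, 1)")
    if labels.n_samples != m.n_samples:
        raise EvaluationError("labels not aligned to matrix")
    rng = np.random.default_rng(seed)
    idx = labels.indices()
    part_a: list[int] = []
    part_b: list[int] = []
    for ci, cond in enumerate(labels.vocabulary):
        rows = np.flatnonzero(idx == ci)
        if rows.size < 2:
            raise EvaluationError(
                f"condition {cond!r} has {rows.size} sample(s); need >= 2 to split"
            )
        rows = rng.permutation(rows)
        n_a = int(round(train_fraction * rows.size))
        n_a = min(max(n_a, 1), rows.size - 1)
        part_a.extend(rows[:n_a])
        part_b.extend(rows[n_a:])
    part_a.sort()
    part_b.sort()
    return (
        (m.subset_samples(part_a), labels.subset(part_a)),
        (m.subset_samples(part_b), labels.subset(part_b)),
    )


def _make_classifier(tag: str, seed: int):
    if tag == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if tag == "NB":
        return GaussianNB()
    if tag == "RF":
        return RandomForestClassifier(random_state=seed)
    if tag == "KNN":
        return KNeighborsClassifier()
    if tag == "SVM":
        return SVC(random_state=seed)  # ovr decision_function for scores
    raise EvaluationError(
        f"unknown classifier tag {tag!r}; available: {list(CLASSIFIER_TAGS)}"
    )


@dataclass
class _FittedClassifiers:
    models: dict[str, object]
    classes: list[str]
    cpg_ids: list[str]

    def scores(self, tag: str, X: np.ndarray) -> np.ndarray:
        """Per-condition scores aligned to self.classes (for one-vs-rest AUC)."""
        model = self.models[tag]
        if hasattr(model, "predict_proba"):
            s = model.predict_proba(X)
        else:
            s = model.decision_function(X)
            if s.ndim == 1:  # binary: expand to two columns
                s = np.column_stack([-s, s])
        order = [list(model.classes_).index(c) for c in self.classes]
        return s[:, order]


def train_classifiers(
    train: BetaMatrix,
    labels: ConditionVector,
    algorithms: Sequence[str] = CLASSIFIER_TAGS,
    seed: int = 0,
) -> _FittedClassifiers:
    """Fit the requested multi-class models (library defaults, fixed seeds)."""
    if labels.n_conditions < 2:
        raise EvaluationError("need >= 2 conditions to train classifiers")
    X = train.values
    y = np.array(labels.labels)
    models = {}
    for tag in algorithms:
        clf = _make_classifier(tag, seed)
        clf.fit(X, y)
        models[tag] = clf
    return _FittedClassifiers(
        models=models, classes=list(labels.vocabulary), cpg_ids=list(train.cpg_ids)
    )


def one_vs_rest_auc(
    scores: np.ndarray, intended: Sequence[str], conditions: Sequence[str]
) -> dict[str, float]:
    """Per-condition one-vs-rest AUC (rank-based, midrank ties).

    ``scores[i, k]`` is sample i's score for ``conditions[k]``; a sample is
    a positive for its intended condition and a negative for the rest.
    Conditions without both positives and negatives get NaN.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise EvaluationError("scores must be finite")
    intended = list(intended)
    out: dict[str, float] = {}
    for k, cond in enumerate(conditions):
        pos = np.array([lab == cond for lab in intended])
        if pos.all() or not pos.any():
            out[cond] = float("nan")
            continue
        out[cond] = float(roc_auc_score(pos.astype(int), scores[:, k]))
    return out


def evaluate_generated(
    classifiers: _FittedClassifiers,
    generated: Sequence[tuple[BetaMatrix, str]] | Callable[[int], list],
    repetitions: int = 1,
    seed: int = 0,
) -> EvalReport:
    """Classify generated samples against their intended condition.

    ``generated`` is either a list of ``(BetaMatrix, intended_condition)``
    pairs (evaluated once) or a callable ``seed -> list`` invoked with a
    fresh child seed per repetition.
    """
    report = EvalReport(conditions=list(classifiers.classes), seed=seed)
    if callable(generated):
        child = np.random.SeedSequence(seed).generate_state(repetitions)
        batches = [generated(int(s % (2**31))) for s in child]
    else:
        batches = [list(generated)]
    for rep, batch in enumerate(batches):
        _evaluate_batch(report, classifiers, batch, rep, generator="generator")
    return report


def _evaluate_batch(
    report: EvalReport,
    classifiers: _FittedClassifiers,
    batch: Sequence[tuple[BetaMatrix, str]],
    repetition: int,
    generator: str,
) -> None:
    conds = report.conditions
    cond_index = {c: i for i, c in enumerate(conds)}
    Xs, intended = [], []
    for mat, cond in batch:
        if list(mat.cpg_ids) != classifiers.cpg_ids:
            diff = set(mat.cpg_ids) ^ set(classifiers.cpg_ids)
            raise EvaluationError(
                f"generated CpGs differ from classifier CpGs: {sorted(diff)[:5]}..."
            )
        Xs.append(mat.values)
        intended.extend([cond] * mat.n_samples)
    X = np.concatenate(Xs, axis=0)
    for tag, model in classifiers.models.items():
        pred = model.predict(X)
        confusion = np.zeros((len(conds), len(conds)), dtype=int)
        for lab, p in zip(intended, pred):
            confusion[cond_index[lab], cond_index[p]] += 1
        auc = one_vs_rest_auc(classifiers.scores(tag, X), intended, conds)
        report.add(
            repetition=repetition,
            classifier=tag,
            generator=generator,
            confusion=confusion,
            per_condition_auc=auc,
        )


def embed_tsne(
    real: BetaMatrix,
    generated: Sequence[tuple[BetaMatrix, str]] = (),
    real_labels: ConditionVector | None = None,
    dims: int = 3,
    seed: int = 0,
    perplexity: float = 30.0,
) -> pd.DataFrame:
    """Joint t-SNE of real and generated samples (default 3-D).

    Returns one coordinate row per sample with ``source`` ("real" or
    "generated") and ``condition`` provenance columns.
    """
    Xs = [real.values]
    source = ["real"] * real.n_samples
    condition = (
        list(real_labels.labels) if real_labels is not None else [""] * real.n_samples
    )
    ids = list(real.sample_ids)
    for mat, cond in generated:
        Xs.append(mat.values)
        source.extend(["generated"] * mat.n_samples)
        condition.extend([cond] * mat.n_samples)
        ids.extend(mat.sample_ids)
    X = np.concatenate(Xs, axis=0)
    if X.shape[0] <= perplexity:
        raise EvaluationError(
            f"{X.shape[0]} samples is too few for perplexity {perplexity}; "
            "pass a smaller perplexity"
        )
    emb = TSNE(
        n_components=dims, random_state=seed, perplexity=perplexity, init="pca"
    ).fit_transform(X)
    out = pd.DataFrame(emb, columns=[f"tsne{d + 1}" for d in range(dims)])
    out.insert(0, "sample_id", ids)
    out["source"] = source
    out["condition"] = condition
    return out


def compare_generators(
    data: BetaMatrix,
    labels: ConditionVector,
    generators: Sequence[str] = ("cvae", "benchmark"),
    n_generated_per_condition: int = 100,
    repetitions: int = 10,
    seed: int = 0,
    train_fraction: float = 0.7,
    cvae_config: CVAEConfig | None = None,
    algorithms: Sequence[str] = CLASSIFIER_TAGS,
    chunk_size: int = 10000,
    min_n: int = 3,
    redraw_split: bool = True,
    redraw_generation: bool = True,
) -> EvalReport:
    """Run the full generator-comparison protocol.

    Per repetition: stratified 70/30 split; fit the requested generators on
    the 70%; train classifiers on the 30%; generate
    ``n_generated_per_condition`` samples per cancer type per generator;
    classify and record metrics.  By default both the split and the
    generation are re-drawn each repetition (``redraw_split`` /
    ``redraw_generation`` pin them).

    ``data`` must be preprocessed (no missing values).
    """
    if np.isnan(data.values).any():
        raise EvaluationError("data contains missing values; preprocess first")
    for g in generators:
        if g not in ("cvae", "benchmark"):
            raise EvaluationError(f"unknown generator {g!r}")
    report = EvalReport(
        conditions=list(labels.vocabulary),
        train_fraction=train_fraction,
        seed=seed,
        notes={
            "n_generated_per_condition": n_generated_per_condition,
            "repetitions": repetitions,
            "redraw_split": redraw_split,
            "redraw_generation": redraw_generation,
        },
    )
    base = np.random.SeedSequence(seed)
    rep_seeds = [int(s % (2**31)) for s in base.generate_state(3 * repetitions)]
    for rep in range(repetitions):
        split_seed = rep_seeds[3 * rep] if redraw_split else rep_seeds[0]
        fit_seed = rep_seeds[3 * rep + 1]
        gen_seed = rep_seeds[3 * rep + 2] if redraw_generation else rep_seeds[2]
        (gen_train, gen_labels), (clf_train, clf_labels) = split_data(
            data, labels, train_fraction, seed=split_seed
        )
        classifiers = train_classifiers(clf_train, clf_labels, algorithms, seed=fit_seed)
        for gname in generators:
            if gname == "cvae":
                cfg = cvae_config if cvae_config is not None else CVAEConfig()
                cfg = CVAEConfig(**{**cfg.__dict__, "seed": fit_seed})
                chunked = chunk_cpgs(gen_train, chunk_size)
                state = train_cvae(chunked, gen_labels, cfg)
                batch = [
                    (generate(state, cond, n_generated_per_condition,
                              seed=gen_seed + ci), cond)
                    for ci, cond in enumerate(labels.vocabulary)
                ]
            else:
                table = fit_table(gen_train, gen_labels, min_n=min_n)
                batch = [
                    (sample_benchmark(table, cond, n_generated_per_condition,
                                      seed=gen_seed + ci), cond)
                    for ci, cond in enumerate(labels.vocabulary)
                ]
            _evaluate_batch(report, classifiers, batch, rep, generator=gname)
    return report
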