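"""Random-forest link classification, cross-validation and ranking.

The classifier consumes, per (circRNA, disease) pair, the concatenation of
the two AANE node embeddings and the DCAE hidden vector of the pair's fused
feature vector.  Cross-validation is stratified at the pair level; in the
default ``fold_safe`` mode every label-derived quantity (GIP and Jaccard
similarities, fusion, embeddings, the autoencoder) is recomputed from the
training fold's association matrix with test-pair entries zeroed, so no
test label leaks into the features.  ``paper_faithful`` computes features
once from the full matrix, reproducing the common (leaky) protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from . import aane as aane_mod
from . import dcae as dcae_mod
from .core_io import AssociationMatrix, DiseaseDAG, ExpressionTable, LabeledPairSet
from .fusion import fuse, pair_features
from .similarity import SemanticParams, SimilarityBundle, build_bundle, dss1, dss2, jaccard, gip_kernel


@dataclass
class ClassifierConfig:
    """Random-forest settings: 100 trees, 20% of features per split."""

    n_trees: int = 100
    max_feature_fraction: float = 0.2
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.max_feature_fraction <= 1):
            raise ValueError("max_feature_fraction must be in (0, 1]")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class PipelineHyper:
    """Hyperparameters of the feature-construction stack used inside CV.

    Sized for desk-scale synthetic data; all fields are overridable.
    """

    variance_kept: float = 0.95
    aane_dim: int = 4
    aane_lambda: float = 0.5
    aane_rho: float = 5.0
    aane_iters: int = 30
    dcae: dcae_mod.DcaeConfig = field(
        default_factory=lambda: dcae_mod.DcaeConfig(hidden_dim=4, epochs=200)
    )
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    ablation: str = "full"  # full | no_aane | no_dcae | neither
    semantic: SemanticParams = field(default_factory=SemanticParams)
    se_mode: str = "standard"
    gip_literal: bool = False


@dataclass
class EvalReport:
    per_fold: list[dict]
    mean: dict
    roc: tuple[np.ndarray, np.ndarray] | None = None
    confusion: dict | None = None


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def metrics(labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> dict:
    """ACC, Sen, F1, MCC (with square-rooted denominator), AUC and confusion.

    Degenerate denominators (single-class labels, empty positive set, ...)
    yield metric value 0 with a warning rather than an exception.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    calls = (scores >= threshold).astype(int)
    tp = int(np.sum((calls == 1) & (labels == 1)))
    fn = int(np.sum((calls == 0) & (labels == 1)))
    tn = int(np.sum((calls == 0) & (labels == 0)))
    fp = int(np.sum((calls == 1) & (labels == 0)))
    out = confusion_metrics(tp, fn, tn, fp)
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class labels; AUC set to 0", stacklevel=2)
        out["AUC"] = 0.0
        out["roc"] = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
    else:
        out["AUC"] = float(roc_auc_score(labels, scores))
        fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
        out["roc"] = (fpr, tpr)
    return out


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Threshold metrics from raw confusion counts."""
    total = tp + fn + tn + fp
    acc = (tp + tn) / total if total else 0.0
    sen = tp / (tp + fn) if tp + fn else _warn_zero("Sen")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else _warn_zero("F1")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    else:
        mcc = _warn_zero("MCC")
    return {"ACC": acc, "Sen": sen, "F1": f1, "MCC": float(mcc),
            "TP": tp, "FN": fn, "TN": tn, "FP": fp}


def _warn_zero(name: str) -> float:
    warnings.warn(f"degenerate denominator; {name} set to 0", stacklevel=3)
    return 0.0


# ---------------------------------------------------------------------------
# feature assembly / classifier
# ---------------------------------------------------------------------------

def assemble_features(
    pairs: LabeledPairSet,
    aane_c: np.ndarray | None,
    aane_d: np.ndarray | None,
    dcae_hidden: np.ndarray | None,
    ablation: str = "full",
    raw_fv: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pair feature table under the requested ablation.

    full = [aane_c(i) | aane_d(j) | dcae_hidden(pair)]; no_aane drops the
    embeddings, no_dcae drops the hidden vector (keeping embeddings),
    neither = the raw fused feature vector FV.
    """
    idx_c = np.array([i for i, _, _ in pairs.pairs], dtype=int)
    idx_d = np.array([j for _, j, _ in pairs.pairs], dtype=int)
    if ablation == "full":
        return np.hstack([aane_c[idx_c], aane_d[idx_d], dcae_hidden])
    if ablation == "no_aane":
        return np.asarray(dcae_hidden)
    if ablation == "no_dcae":
        return np.hstack([aane_c[idx_c], aane_d[idx_d]])
    if ablation == "neither":
        return np.asarray(raw_fv)
    raise ValueError(f"unknown ablation {ablation!r}")


def fit_predict(
    train_X: np.ndarray, train_y: np.ndarray, test_X: np.ndarray, cfg: ClassifierConfig | None = None
) -> np.ndarray:
    """Fit the random forest and return positive-class scores in [0, 1]."""
    cfg = cfg or ClassifierConfig()
    train_y = np.asarray(train_y, dtype=int)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.max_feature_fraction,
        random_state=cfg.seed,
        n_jobs=1,
    )
    clf.fit(train_X, train_y)
    return clf.predict_proba(test_X)[:, 1]


# ---------------------------------------------------------------------------
# per-fold feature construction
# ---------------------------------------------------------------------------

def _am_from_labels(template: AssociationMatrix, pairs: LabeledPairSet, labels: np.ndarray) -> np.ndarray:
    am = np.zeros_like(template.AM)
    for (i, j, _), y in zip(pairs.pairs, labels):
        if y == 1:
            am[i, j] = 1
    return am


def build_fold_features(
    am_matrix: np.ndarray,
    fixed: SimilarityBundle,
    train_pairs: LabeledPairSet,
    test_pairs: LabeledPairSet,
    hyper: PipelineHyper,
    seed: int,
):
    """Label-derived similarities + fusion + AANE + DCAE for one fold.

    ``fixed`` supplies the label-independent matrices (DSS1/DSS2/SE and the
    coverage masks); GIP and Jaccard are recomputed from ``am_matrix``.
    Returns (train feature table, test feature table).
    """
    if am_matrix.sum() == 0:
        raise ValueError("training association matrix is empty")
    bundle = SimilarityBundle(
        DSS1=fixed.DSS1, DSS2=fixed.DSS2,
        GD=gip_kernel(am_matrix, "disease", literal=hyper.gip_literal),
        JD=jaccard(am_matrix, "disease"),
        GC=gip_kernel(am_matrix, "circRNA", literal=hyper.gip_literal),
        SE=fixed.SE,
        JC=jaccard(am_matrix, "circRNA"),
        semantic_mask=fixed.semantic_mask,
        expression_mask=fixed.expression_mask,
    )
    fused = fuse(bundle, variance_kept=hyper.variance_kept)
    need_aane = hyper.ablation in ("full", "no_dcae")
    need_dcae = hyper.ablation in ("full", "no_aane")
    emb_c = emb_d = None
    if need_aane:
        emb_c = aane_mod.embed_nodes(
            fused.CM, fused.CS, d=hyper.aane_dim, lambda_=hyper.aane_lambda,
            rho=hyper.aane_rho, max_iter=hyper.aane_iters, seed=seed,
        )
        emb_d = aane_mod.embed_nodes(
            fused.DM, fused.DS, d=hyper.aane_dim, lambda_=hyper.aane_lambda,
            rho=hyper.aane_rho, max_iter=hyper.aane_iters, seed=seed + 1,
        )
    fv_train = pair_features(fused.CM, fused.DM, train_pairs)
    fv_test = pair_features(fused.CM, fused.DM, test_pairs)
    hid_train = hid_test = None
    if need_dcae:
        model, out = dcae_mod.train(fv_train, replace(hyper.dcae, seed=seed + 2))
        hid_train = out.hidden
        hid_test = model.encode(fv_test)
    X_train = assemble_features(train_pairs, emb_c, emb_d, hid_train, hyper.ablation, fv_train)
    X_test = assemble_features(test_pairs, emb_c, emb_d, hid_test, hyper.ablation, fv_test)
    return X_train, X_test


# ---------------------------------------------------------------------------
# cross-validation, sweep, ranking
# ---------------------------------------------------------------------------

def cross_validate(
    am: AssociationMatrix,
    dag: DiseaseDAG | None,
    expr: ExpressionTable | None,
    pairs: LabeledPairSet,
    k: int = 5,
    hyper: PipelineHyper | None = None,
    leakage_mode: str = "fold_safe",
    seed: int = 0,
    permute_labels: bool = False,
) -> EvalReport:
    """Stratified pair-level k-fold cross-validation of the full stack.

    ``permute_labels`` shuffles the pair labels once before splitting (a
    negative control: features built from permuted labels carry no signal,
    so AUC should sit near 0.5).
    """
    if leakage_mode not in ("fold_safe", "paper_faithful"):
        raise ValueError("leakage_mode must be 'fold_safe' or 'paper_faithful'")
    hyper = hyper or PipelineHyper()
    labels = pairs.labels.copy()
    if permute_labels:
        labels = np.random.default_rng(seed + 77).permutation(labels)
    fixed = build_bundle(am, dag, expr, hyper.semantic, hyper.se_mode, hyper.gip_literal)
    am_full = _am_from_labels(am, pairs, labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    idx = np.arange(len(pairs))
    per_fold = []
    rocs = []
    conf = {"TP": 0, "FN": 0, "TN": 0, "FP": 0}
    for fold, (tr, te) in enumerate(skf.split(idx, labels)):
        train_pairs = LabeledPairSet(
            [(pairs.pairs[i][0], pairs.pairs[i][1], int(labels[i])) for i in tr]
        )
        test_pairs = LabeledPairSet(
            [(pairs.pairs[i][0], pairs.pairs[i][1], int(labels[i])) for i in te]
        )
        if leakage_mode == "fold_safe":
            am_fold = am_full.copy()
            for i in te:  # zero the test-pair cells, positive or not
                am_fold[pairs.pairs[i][0], pairs.pairs[i][1]] = 0
        else:
            am_fold = am_full
        X_tr, X_te = build_fold_features(
            am_fold, fixed, train_pairs, test_pairs, hyper, seed=seed * 1000 + fold
        )
        cfg = replace(hyper.classifier, seed=seed * 1000 + fold)
        scores = fit_predict(X_tr, train_pairs.labels, X_te, cfg)
        rep = metrics(test_pairs.labels, scores, hyper.classifier.threshold)
        rocs.append(rep.pop("roc"))
        for key in conf:
            conf[key] += rep[key]
        per_fold.append(rep)
    mean = {
        key: float(np.mean([f[key] for f in per_fold]))
        for key in ("ACC", "Sen", "F1", "MCC", "AUC")
    }
    return EvalReport(per_fold=per_fold, mean=mean, roc=rocs[0], confusion=conf)


def sweep_max_feature(
    values: list[float],
    am: AssociationMatrix,
    dag: DiseaseDAG | None,
    expr: ExpressionTable | None,
    pairs: LabeledPairSet,
    k: int = 5,
    hyper: PipelineHyper | None = None,
    seed: int = 0,
) -> tuple[list[tuple[float, float]], float]:
    """Mean CV AUC per max_feature_fraction value; returns (table, argmax)."""
    hyper = hyper or PipelineHyper()
    table = []
    for v in values:
        h = replace(hyper, classifier=replace(hyper.classifier, max_feature_fraction=v))
        rep = cross_validate(am, dag, expr, pairs, k=k, hyper=h, seed=seed)
        table.append((v, rep.mean["AUC"]))
    best = max(table, key=lambda t: t[1])[0]
    return table, best


def rank_candidates(
    am: AssociationMatrix,
    dag: DiseaseDAG | None,
    expr: ExpressionTable | None,
    pairs: LabeledPairSet,
    hyper: PipelineHyper | None = None,
    seed: int = 0,
    top: int | None = 20,
) -> list[tuple[str, str, float]]:
    """Score every unlabeled zero cell with a model trained on all labels.

    Returns (circRNA id, disease id, score) in descending score order, ties
    broken lexicographically; labeled pairs never appear.
    """
    hyper = hyper or PipelineHyper()
    fixed = build_bundle(am, dag, expr, hyper.semantic, hyper.se_mode, hyper.gip_literal)
    labeled = {(i, j) for i, j, _ in pairs.pairs}
    cand = [
        (i, j)
        for i in range(am.m)
        for j in range(am.n)
        if am.AM[i, j] == 0 and (i, j) not in labeled
    ]
    cand_pairs = LabeledPairSet([(i, j, 0) for i, j in cand])
    X_tr, X_cand = build_fold_features(
        _am_from_labels(am, pairs, pairs.labels), fixed, pairs, cand_pairs, hyper, seed
    )
    scores = fit_predict(X_tr, pairs.labels, X_cand, replace(hyper.classifier, seed=seed))
    rows = sorted(
        zip((am.circ_ids[i] for i, _ in cand), (am.disease_ids[j] for _, j in cand), scores),
        key=lambda r: (-r[2], r[0], r[1]),
    )
    return rows[:top] if top else rows
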