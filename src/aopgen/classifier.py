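"""Binary antioxidant-activity classifier with fivefold cross-validation.

Architecture: embedding -> 1-D convolution (valid padding, ReLU) -> global
max-pooling over positions -> layer normalization -> dense sigmoid output.
Trained with binary cross-entropy and Adam.  The k fold models trained during
stratified cross-validation are all kept and used together at prediction
time; a candidate peptide passes the consensus filter only if every fold
model scores it at or above the confidence threshold (0.99 by default).

Metrics (accuracy, precision, MCC from the confusion matrix at 0.5, AUC-ROC
as the Mann-Whitney rank statistic with ties counted 1/2) are computed per
held-out fold and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import _nn
from .seqdata import DEFAULT_VOCAB, AminoAcidVocabulary, PeptideCorpus


@dataclass
class ClfConfig:
    embed_dim: int = 64
    conv_filters: int = 64
    conv_kernel_len: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 50
    k_folds: int = 5
    seed: int = 0
    threshold: float = 0.5  # decision threshold for accuracy/precision
    vocab: AminoAcidVocabulary = field(default_factory=lambda: DEFAULT_VOCAB)

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.conv_kernel_len < 1:
            raise ValueError("conv_kernel_len must be >= 1")


@dataclass
class FoldMetrics:
    accuracy: float
    precision: float
    auc_roc: float
    mcc: float
    tp: int
    fp: int
    tn: int
    fn: int
    mcc_degenerate: bool = False  # zero denominator, MCC defined as 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class FoldModel:
    params: _nn.Params
    fold_index: int
    config: ClfConfig


@dataclass
class ClassifierEnsemble:
    models: list[FoldModel]
    fold_assignment: np.ndarray  # record index -> held-out fold
    metrics: list[FoldMetrics]
    config: ClfConfig

    @property
    def mean_metrics(self) -> dict[str, float]:
        return {
            name: float(np.mean([getattr(m, name) for m in self.metrics]))
            for name in ("accuracy", "precision", "auc_roc", "mcc")
        }


# ---------------------------------------------------------------------------
# Metrics

def compute_metrics(labels, scores, threshold: float = 0.5) -> FoldMetrics:
    """Confusion-matrix metrics at ``threshold`` plus rank-based AUC-ROC.

    accuracy = (TP+TN)/n; precision = TP/(TP+FP);
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), 0 when the
    denominator vanishes; AUC from the Mann-Whitney statistic with tied
    scores contributing 1/2.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    n = y.size
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (tp * tn - fp * fn) / np.sqrt(denom)
    n_pos = int((y == 1).sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        auc = float("nan")
    else:
        ranks = rankdata(s)  # average ranks -> ties count 1/2
        auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return FoldMetrics(
        accuracy=float(accuracy), precision=float(precision), auc_roc=float(auc),
        mcc=float(mcc), tp=tp, fp=fp, tn=tn, fn=fn, mcc_degenerate=bool(degenerate),
    )


# ---------------------------------------------------------------------------
# Network

def _pad_ids(corpus: PeptideCorpus, vocab: AminoAcidVocabulary, min_len: int) -> np.ndarray:
    seqs = corpus.sequences
    T = max(max((len(s) for s in seqs), default=1), min_len)
    ids = np.full((len(seqs), T), vocab.pad_id, dtype=np.int64)
    for i, s in enumerate(seqs):
        ids[i, :len(s)] = [vocab.index_of(ch) for ch in s]
    return ids


def _init_clf_params(cfg: ClfConfig, rng: np.random.Generator) -> _nn.Params:
    params: _nn.Params = {}
    emb_vocab = len(cfg.vocab.residues) + 1  # residues + pad
    for name, sub in (
        ("embedding", _nn.embedding_init(rng, emb_vocab, cfg.embed_dim)),
        ("conv", _nn.conv1d_init(rng, cfg.conv_kernel_len, cfg.embed_dim, cfg.conv_filters)),
        ("norm", _nn.layernorm_init(cfg.conv_filters)),
        ("output", _nn.dense_init(rng, cfg.conv_filters, 1)),
    ):
        for k, v in sub.items():
            params[f"{name}/{k}"] = v
    return params


def _clf_forward(params: _nn.Params, ids: np.ndarray):
    X = _nn.embedding_forward(params, "embedding", ids)
    C = _nn.conv1d_forward(params, "conv", X)
    A = np.maximum(C, 0.0)
    arg = A.argmax(axis=1)
    M = np.take_along_axis(A, arg[:, None, :], axis=1)[:, 0, :]
    N, ln_cache = _nn.layernorm_forward(params, "norm", M)
    logit = _nn.dense_forward(params, "output", N)[:, 0]
    p = _nn.sigmoid(logit)
    return p, (X, C, A, arg, M, N, ln_cache)


def _clf_loss_and_grads(params: _nn.Params, ids: np.ndarray, y: np.ndarray):
    p, (X, C, A, arg, M, N, ln_cache) = _clf_forward(params, ids)
    loss, dlogit = _nn.bce_loss(p, y)
    grads = _nn.zero_grads(params)
    dN = _nn.dense_backward(params, grads, "output", N, dlogit[:, None])
    dM = _nn.layernorm_backward(params, grads, "norm", ln_cache, dN)
    dA = np.zeros_like(A)
    np.put_along_axis(dA, arg[:, None, :], dM[:, None, :], axis=1)
    dC = dA * (C > 0)
    dX = _nn.conv1d_backward(params, grads, "conv", X, dC)
    _nn.embedding_backward(grads, "embedding", ids, dX)
    return loss, grads


ALL_CLF_LAYERS = {"embedding", "conv", "norm", "output"}


def _train_single(ids: np.ndarray, y: np.ndarray, cfg: ClfConfig, seed: int) -> _nn.Params:
    rng = np.random.default_rng(seed)
    params = _init_clf_params(cfg, rng)
    opt = _nn.Adam(params, lr=cfg.learning_rate)
    n = len(y)
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            _, grads = _clf_loss_and_grads(params, ids[idx], y[idx])
            opt.step(params, grads, ALL_CLF_LAYERS)
    return params


def train_cv(corpus: PeptideCorpus, config: ClfConfig | None = None) -> ClassifierEnsemble:
    """Stratified k-fold training; every record is held out exactly once."""
    cfg = config or ClfConfig()
    labels = corpus.labels
    if any(l not in (0, 1) for l in labels):
        raise ValueError("corpus must be fully labeled with binary activity (0/1)")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("corpus must contain both classes")
    ids = _pad_ids(corpus, cfg.vocab, cfg.conv_kernel_len)
    skf = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True, random_state=cfg.seed)
    fold_assignment = np.full(len(y), -1, dtype=int)
    models: list[FoldModel] = []
    metrics: list[FoldMetrics] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(ids, y)):
        if len(np.unique(y[test_idx])) < 2:
            raise ValueError(f"fold {fold} holds out a single class")
        fold_assignment[test_idx] = fold
        params = _train_single(ids[train_idx], y[train_idx], cfg, seed=cfg.seed + fold)
        scores, _ = _clf_forward(params, ids[test_idx])
        metrics.append(compute_metrics(y[test_idx], scores, threshold=cfg.threshold))
        models.append(FoldModel(params=params, fold_index=fold, config=cfg))
    return ClassifierEnsemble(models=models, fold_assignment=fold_assignment,
                              metrics=metrics, config=cfg)


def predict_ensemble(ensemble: ClassifierEnsemble, corpus: PeptideCorpus) -> np.ndarray:
    """Per-sequence probability from each fold model: array of shape (n, k)."""
    cfg = ensemble.config
    ids = _pad_ids(corpus, cfg.vocab, cfg.conv_kernel_len)
    cols = [_clf_forward(m.params, ids)[0] for m in ensemble.models]
    return np.column_stack(cols)


def consensus_filter(
    corpus: PeptideCorpus, predictions: np.ndarray, threshold: float = 0.99
) -> tuple[PeptideCorpus, np.ndarray]:
    """Keep sequences unanimously scored >= threshold by every fold model."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape[0] != len(corpus):
        raise ValueError("one prediction row per corpus record required")
    accepted = predictions.min(axis=1) >= threshold
    kept = PeptideCorpus(
        [corpus[i] for i in range(len(corpus)) if accepted[i]],
        name=corpus.name + "/consensus",
    )
    return kept, accepted


def save_ensemble(ensemble: ClassifierEnsemble, path: str) -> None:
    """Persist fold models as a named-tensor archive + plain-text sidecar."""
    import json

    base = path[:-4] if path.endswith(".npz") else path
    tensors = {}
    for m in ensemble.models:
        for k, v in m.params.items():
            tensors[f"fold{m.fold_index}/{k}"] = v
    np.savez(base + ".npz", **tensors, fold_assignment=ensemble.fold_assignment)
    cfg = ensemble.config
    sidecar = {
        "embed_dim": cfg.embed_dim, "conv_filters": cfg.conv_filters,
        "conv_kernel_len": cfg.conv_kernel_len, "learning_rate": cfg.learning_rate,
        "batch_size": cfg.batch_size, "epochs": cfg.epochs, "k_folds": cfg.k_folds,
        "seed": cfg.seed, "threshold": cfg.threshold,
        "metrics": [vars(m) for m in ensemble.metrics],
    }
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_ensemble(path: str) -> ClassifierEnsemble:
    import json

    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        sc = json.load(fh)
    cfg = ClfConfig(
        embed_dim=sc["embed_dim"], conv_filters=sc["conv_filters"],
        conv_kernel_len=sc["conv_kernel_len"], learning_rate=sc["learning_rate"],
        batch_size=sc["batch_size"], epochs=sc["epochs"], k_folds=sc["k_folds"],
        seed=sc["seed"], threshold=sc["threshold"],
    )
    with np.load(base + ".npz") as npz:
        fold_assignment = npz["fold_assignment"].copy()
        models = []
        for fold in range(cfg.k_folds):
            prefix = f"fold{fold}/"
            params = {
                k[len(prefix):]: npz[k].copy() for k in npz.files if k.startswith(prefix)
            }
            models.append(FoldModel(params=params, fold_index=fold, config=cfg))
    metrics = [FoldMetrics(**m) for m in sc["metrics"]]
    return ClassifierEnsemble(models=models, fold_assignment=fold_assignment,
                              metrics=metrics, config=cfg)


def metrics_table(ensemble: ClassifierEnsemble) -> "pandas.DataFrame":
    """Per-fold + average metrics on the percent scale, one row per model."""
    import pandas as pd

    rows = []
    for i, m in enumerate(ensemble.metrics, start=1):
        rows.append({"model": f"fold {i}", "accuracy_pct": 100 * m.accuracy,
                     "precision_pct": 100 * m.precision, "auc_roc_pct": 100 * m.auc_roc,
                     "mcc_pct": 100 * m.mcc})
    mean = ensemble.mean_metrics
    rows.append({"model": "average", "accuracy_pct": 100 * mean["accuracy"],
                 "precision_pct": 100 * mean["precision"],
                 "auc_roc_pct": 100 * mean["auc_roc"], "mcc_pct": 100 * mean["mcc"]})
    return pd.DataFrame(rows)
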