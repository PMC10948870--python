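"""Character-level recurrent generative model for peptide sequences.

The network is an embedding layer feeding two stacked GRU layers and a dense
softmax projection over the full token vocabulary (20 residues plus
pad/begin/end), trained with sparse categorical cross-entropy and Adam under
teacher forcing.  Transfer learning follows a fixed freezing contract: the
embedding and the first GRU keep the general-peptide representation learned
during base training, while the second GRU and the output projection are
re-trained on the smaller antioxidant corpus.

Training checkpoints every epoch on validation loss and returns the best
checkpoint; sampling is autoregressive multinomial decoding from the
temperature-scaled softmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import _nn
from .seqdata import (
    DEFAULT_VOCAB,
    AminoAcidVocabulary,
    PeptideCorpus,
    PeptideRecord,
    detokenize,
    tokenize,
)

LAYERS = ("embedding", "gru1", "gru2", "output")


@dataclass
class GenConfig:
    embed_dim: int = 64
    recurrent_units: int = 128
    max_sample_len: int = 8
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    vocab: AminoAcidVocabulary = field(default_factory=lambda: DEFAULT_VOCAB)

    def __post_init__(self):
        if self.embed_dim <= 0 or self.recurrent_units <= 0:
            raise ValueError("embed_dim and recurrent_units must be positive")
        if self.max_sample_len < 1:
            raise ValueError("max_sample_len must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class GenModelState:
    params: _nn.Params
    trainability: dict[str, bool]
    config: GenConfig

    def copy(self) -> "GenModelState":
        return GenModelState(
            params=_nn.clone_params(self.params),
            trainability=dict(self.trainability),
            config=self.config,
        )

    @property
    def trainable_prefixes(self) -> set[str]:
        return {k for k, v in self.trainability.items() if v}


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0  # 1-based; 0 means no epoch improved on nothing (empty log)
    seed: int = 0


def build_model(config: GenConfig) -> GenModelState:
    """Initialise all four layer groups (all trainable) with a seeded RNG."""
    rng = np.random.default_rng(config.seed)
    V = config.vocab.size
    params: _nn.Params = {}
    for name, sub in (
        ("embedding", _nn.embedding_init(rng, V, config.embed_dim)),
        ("gru1", _nn.gru_init(rng, config.embed_dim, config.recurrent_units)),
        ("gru2", _nn.gru_init(rng, config.recurrent_units, config.recurrent_units)),
        ("output", _nn.dense_init(rng, config.recurrent_units, V)),
    ):
        for k, v in sub.items():
            params[f"{name}/{k}"] = v
    return GenModelState(params=params, trainability={l: True for l in LAYERS}, config=config)


def apply_transfer_protocol(model: GenModelState) -> GenModelState:
    """Freeze embedding + first GRU; leave second GRU + output trainable."""
    out = model.copy()
    out.trainability = {"embedding": False, "gru1": False, "gru2": True, "output": True}
    return out


def _batch_arrays(corpus: PeptideCorpus, vocab: AminoAcidVocabulary):
    """Tokenize a corpus into padded input/target/mask arrays.

    Inputs are [bos, s...]; targets the sequence shifted left, ending in eos;
    pad positions are masked out of the loss.
    """
    toks = [tokenize(r, vocab) for r in corpus]
    T = max(len(t) for t in toks) - 1
    n = len(toks)
    X = np.full((n, T), vocab.pad_id, dtype=np.int64)
    Y = np.full((n, T), vocab.pad_id, dtype=np.int64)
    M = np.zeros((n, T), dtype=bool)
    for i, t in enumerate(toks):
        L = len(t) - 1
        X[i, :L] = t[:-1]
        Y[i, :L] = t[1:]
        M[i, :L] = True
    return X, Y, M


def _forward(params: _nn.Params, X: np.ndarray):
    E = _nn.embedding_forward(params, "embedding", X)
    H1, c1 = _nn.gru_forward(params, "gru1", E)
    H2, c2 = _nn.gru_forward(params, "gru2", H1)
    logits = _nn.dense_forward(params, "output", H2)
    return logits, (E, H1, c1, H2, c2)


def _loss_and_grads(params: _nn.Params, X, Y, M):
    logits, (E, H1, c1, H2, c2) = _forward(params, X)
    loss, dlogits = _nn.masked_softmax_xent(logits, Y, M)
    grads = _nn.zero_grads(params)
    dH2 = _nn.dense_backward(params, grads, "output", H2, dlogits)
    dH1 = _nn.gru_backward(params, grads, "gru2", H1, c2, dH2)
    dE = _nn.gru_backward(params, grads, "gru1", E, c1, dH1)
    _nn.embedding_backward(grads, "embedding", X, dE)
    return loss, grads


def corpus_loss(model: GenModelState, corpus: PeptideCorpus) -> float:
    """Mean per-token cross-entropy of a corpus under the model."""
    X, Y, M = _batch_arrays(corpus, model.config.vocab)
    logits, _ = _forward(model.params, X)
    lp = _nn.log_softmax(logits)
    picked = np.take_along_axis(lp, Y[..., None], axis=-1)[..., 0]
    return float(-(picked * M).sum() / max(int(M.sum()), 1))


def train(
    model: GenModelState,
    train_corpus: PeptideCorpus,
    val_corpus: PeptideCorpus,
    epochs: int,
    learning_rate: float | None = None,
) -> tuple[GenModelState, TrainLog]:
    """Teacher-forced training with per-epoch validation-loss checkpointing.

    Only layers marked trainable are updated; the returned state is the
    checkpoint from the epoch with minimum validation loss.  ``epochs=0``
    returns an unchanged copy.
    """
    if len(train_corpus) == 0:
        raise ValueError("training corpus is empty")
    if len(val_corpus) == 0:
        raise ValueError("validation corpus is empty")
    cfg = model.config
    state = model.copy()
    log = TrainLog(seed=cfg.seed)
    if epochs == 0:
        return state, log
    lr = cfg.learning_rate if learning_rate is None else learning_rate
    opt = _nn.Adam(state.params, lr=lr)
    rng = np.random.default_rng(cfg.seed)
    Xtr, Ytr, Mtr = _batch_arrays(train_corpus, cfg.vocab)
    n = len(train_corpus)
    best = None
    best_loss = np.inf
    trainable = state.trainable_prefixes
    for epoch in range(1, epochs + 1):
        perm = rng.permutation(n)
        losses = []
        weights = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            Xb, Yb, Mb = Xtr[idx], Ytr[idx], Mtr[idx]
            # trim shared trailing padding for speed
            T = int(Mb.any(axis=0).sum())
            loss, grads = _loss_and_grads(state.params, Xb[:, :T], Yb[:, :T], Mb[:, :T])
            opt.step(state.params, grads, trainable)
            losses.append(loss)
            weights.append(int(Mb.sum()))
        log.train_loss.append(float(np.average(losses, weights=weights)))
        vl = corpus_loss(state, val_corpus)
        log.val_loss.append(vl)
        if vl < best_loss:
            best_loss = vl
            best = _nn.clone_params(state.params)
            log.best_epoch = epoch
    state.params = best
    return state, log


def next_token_distribution(model: GenModelState, prefix: str) -> np.ndarray:
    """Probability distribution over the next token given a residue prefix."""
    vocab = model.config.vocab
    ids = [vocab.bos_id] + [vocab.index_of(ch) for ch in prefix.upper()]
    logits, _ = _forward(model.params, np.asarray([ids]))
    return _nn.softmax(logits[0, -1])


def sequence_log_likelihood(model: GenModelState, record: PeptideRecord) -> float:
    """Sum of log-probabilities of each observed token, end marker included."""
    vocab = model.config.vocab
    toks = tokenize(record, vocab)
    X = np.asarray([toks[:-1]])
    Y = np.asarray([toks[1:]])
    logits, _ = _forward(model.params, X)
    lp = _nn.log_softmax(logits)
    return float(np.take_along_axis(lp, Y[..., None], axis=-1).sum())


def sample(
    model: GenModelState,
    n: int,
    max_len: int | None = None,
    temperature: float = 1.0,
    seed: int = 0,
) -> PeptideCorpus:
    """Autoregressively sample ``n`` non-empty sequences of length <= max_len.

    Decoding starts from the begin token; pad and begin tokens are masked out
    of emission.  ``temperature=0`` is greedy argmax decoding.  Sequences that
    terminate immediately (length 0) are resampled.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    cfg = model.config
    max_len = cfg.max_sample_len if max_len is None else max_len
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    vocab = cfg.vocab
    rng = np.random.default_rng(seed)
    V = vocab.size
    forbid = np.zeros(V)
    forbid[[vocab.pad_id, vocab.bos_id]] = -np.inf
    E = lambda ids: _nn.embedding_forward(model.params, "embedding", ids)
    out: list[str] = []
    while len(out) < n:
        B = min(4096, 2 * (n - len(out)))
        U = cfg.recurrent_units
        h1 = np.zeros((B, U))
        h2 = np.zeros((B, U))
        token = np.full(B, vocab.bos_id, dtype=np.int64)
        done = np.zeros(B, dtype=bool)
        seqs: list[list[int]] = [[] for _ in range(B)]
        for _ in range(max_len):
            h1 = np.where(done[:, None], h1, _nn.gru_step(model.params, "gru1", E(token), h1))
            h2 = np.where(done[:, None], h2, _nn.gru_step(model.params, "gru2", h1, h2))
            logits = _nn.dense_forward(model.params, "output", h2) + forbid
            if temperature == 0:
                nxt = logits.argmax(axis=1)
            else:
                p = _nn.softmax(logits / temperature)
                # vectorized categorical draw via inverse-CDF
                u = rng.random((B, 1))
                nxt = (p.cumsum(axis=1) < u).sum(axis=1)
                nxt = np.minimum(nxt, V - 1)
            for i in range(B):
                if done[i]:
                    continue
                if nxt[i] == vocab.eos_id:
                    done[i] = True
                else:
                    seqs[i].append(int(nxt[i]))
            token = np.where(done, token, nxt)
            if done.all():
                break
        for s in seqs:
            if s and len(out) < n:
                out.append(detokenize(s, vocab))
    records = [PeptideRecord(sequence=s, source="generated") for s in out]
    return PeptideCorpus(records, name="generated")


# ---------------------------------------------------------------------------
# Persistence: named-tensor archive + plain-text sidecar

def save_model(model: GenModelState, path: str, log: TrainLog | None = None) -> None:
    np.savez(path if path.endswith(".npz") else path + ".npz", **model.params)
    sidecar = {
        "embed_dim": model.config.embed_dim,
        "recurrent_units": model.config.recurrent_units,
        "max_sample_len": model.config.max_sample_len,
        "learning_rate": model.config.learning_rate,
        "batch_size": model.config.batch_size,
        "seed": model.config.seed,
        "trainability": model.trainability,
        "fresh_optimizer_per_phase": True,
        "best_epoch": None if log is None else log.best_epoch,
        "epochs_run": None if log is None else len(log.val_loss),
    }
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(path: str) -> GenModelState:
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        sc = json.load(fh)
    config = GenConfig(
        embed_dim=sc["embed_dim"],
        recurrent_units=sc["recurrent_units"],
        max_sample_len=sc["max_sample_len"],
        learning_rate=sc["learning_rate"],
        batch_size=sc["batch_size"],
        seed=sc["seed"],
    )
    with np.load(base + ".npz") as npz:
        params = {k: npz[k].copy() for k in npz.files}
    return GenModelState(params=params, trainability=sc["trainability"], config=config)
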