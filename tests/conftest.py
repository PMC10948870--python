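"""Shared fixtures: small synthetic corpora and pre-trained models.

Model fixtures are session-scoped because training, although desk-scale,
is the expensive part of the suite; all sizes and seeds are fixed.
"""

from __future__ import annotations

import pytest

import aopgen as ag
from aopgen import synthetic_data as sd

GEN_CONFIG = ag.GenConfig(embed_dim=32, recurrent_units=64, batch_size=64, seed=0)


@pytest.fixture(scope="session")
def pretrain_corpus() -> ag.PeptideCorpus:
    """Broad-composition corpus standing in for the general peptide set."""
    return sd.make_pretrain_corpus(sd.SynthSpec(n=1500, min_len=2, max_len=12, seed=0))


@pytest.fixture(scope="session")
def aop_corpus() -> ag.PeptideCorpus:
    """Y/W/H-enriched labeled corpus standing in for the antioxidant set."""
    return sd.make_aop_corpus(sd.default_aop_spec(n=600, seed=1))


@pytest.fixture(scope="session")
def base_model(pretrain_corpus):
    train_c, val_c = ag.split_train_val(pretrain_corpus, 0.9, seed=0)
    model = ag.build_model(GEN_CONFIG)
    fitted, log = ag.train(model, train_c, val_c, epochs=8)
    return fitted, log


@pytest.fixture(scope="session")
def finetuned_model(base_model, aop_corpus):
    base, _ = base_model
    train_c, val_c = ag.split_train_val(aop_corpus, 0.9, seed=1)
    model = ag.apply_transfer_protocol(base)
    fitted, log = ag.train(model, train_c, val_c, epochs=40)
    return fitted, log


def grammar_strings(n: int, seed: int) -> list[str]:
    """Deterministic toy grammar: concatenations of 'LA' / 'LG' units.

    Every in-grammar string has L at even positions and A/G at odd ones, so a
    sequence model can learn it quickly and its strings are easily told apart
    from uniform random peptides."""
    import numpy as np

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        k = int(rng.integers(2, 6))  # 2-5 units -> lengths 4-10
        out.append("".join(rng.choice(["LA", "LG"], size=k)))
    return out


@pytest.fixture(scope="session")
def grammar_corpus() -> ag.PeptideCorpus:
    return ag.PeptideCorpus.from_sequences(grammar_strings(300, seed=21), name="grammar")


@pytest.fixture(scope="session")
def grammar_model(grammar_corpus):
    train_c, val_c = ag.split_train_val(grammar_corpus, 0.9, seed=2)
    model = ag.build_model(ag.GenConfig(embed_dim=16, recurrent_units=32, seed=2))
    return ag.train(model, train_c, val_c, epochs=30)


@pytest.fixture(scope="session")
def clf_corpus() -> ag.PeptideCorpus:
    """Motif-separable labeled corpus (n=2000) for classifier training."""
    return sd.make_aop_corpus(
        sd.SynthSpec(n=2000, min_len=4, max_len=12,
                     composition=sd.aop_like_composition(),
                     motif="YWH", motif_prob=0.5, seed=11)
    )


@pytest.fixture(scope="session")
def ensemble(clf_corpus):
    cfg = ag.ClfConfig(embed_dim=16, conv_filters=32, epochs=15, seed=0)
    return ag.train_cv(clf_corpus, cfg)
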