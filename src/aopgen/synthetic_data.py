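"""Synthetic corpora with planted, recoverable structure.

The real pipeline was trained on a broad general-peptide corpus and a small
antioxidant corpus; neither ships with accessions, so the test bed emulates
their statistical shape instead: a broad-composition pretraining corpus, a
smaller Tyr/Trp/His-enriched "AOP-like" corpus capped at 15 residues whose
binary activity labels follow a known motif rule, and a reference database
with a controlled overlap fraction for novelty-rate checks.  Everything is a
deterministic function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seqdata import CANONICAL_RESIDUES, PeptideCorpus, PeptideRecord


def uniform_composition() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


def aop_like_composition() -> np.ndarray:
    """Composition up-weighting Y, W, H, P, L — the residues dominating
    experimentally reported short antioxidant peptides."""
    w = {r: 1.0 for r in CANONICAL_RESIDUES}
    w.update({"Y": 6.0, "W": 5.0, "H": 4.0, "P": 3.0, "L": 3.0})
    v = np.array([w[r] for r in CANONICAL_RESIDUES])
    return v / v.sum()


@dataclass
class SynthSpec:
    n: int = 1000
    min_len: int = 2
    max_len: int = 15
    composition: np.ndarray = field(default_factory=uniform_composition)
    motif: str | None = None
    motif_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.composition = np.asarray(self.composition, dtype=float)
        if self.composition.shape != (20,) or not np.isclose(self.composition.sum(), 1.0):
            raise ValueError("composition must be a 20-vector summing to 1")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("need 1 <= min_len <= max_len")
        if not 0.0 <= self.motif_prob <= 1.0:
            raise ValueError("motif_prob must be in [0, 1]")
        if self.motif is not None:
            if any(ch not in CANONICAL_RESIDUES for ch in self.motif):
                raise ValueError("motif must use canonical residues")
            if len(self.motif) > self.min_len:
                raise ValueError("motif longer than min_len cannot always be planted")


def _random_sequences(rng: np.random.Generator, spec: SynthSpec) -> list[str]:
    lengths = rng.integers(spec.min_len, spec.max_len + 1, size=spec.n)
    residues = np.array(list(CANONICAL_RESIDUES))
    return [
        "".join(residues[rng.choice(20, size=L, p=spec.composition)])
        for L in lengths
    ]


def make_pretrain_corpus(spec: SynthSpec) -> PeptideCorpus:
    """Broad corpus: residue-wise draws from the spec composition."""
    rng = np.random.default_rng(spec.seed)
    seqs = _random_sequences(rng, spec)
    return PeptideCorpus(
        [PeptideRecord(sequence=s, source="synthetic-pretrain") for s in seqs],
        name="pretrain",
        notes=f"synthetic; seed={spec.seed}",
    )


def make_aop_corpus(spec: SynthSpec, label_rule=None) -> PeptideCorpus:
    """AOP-like labeled corpus with a planted motif.

    With probability ``motif_prob`` a random window of the sequence is
    overwritten by the motif (keeping length, hence the <= 15 cap).  The
    default label rule is motif presence, so labels are exactly recoverable
    by a string scan.  Raises if the draw yields a single class.
    """
    if spec.motif is None:
        raise ValueError("spec.motif is required for an AOP-like corpus")
    rng = np.random.default_rng(spec.seed)
    seqs = _random_sequences(rng, spec)
    m = spec.motif
    planted = rng.random(spec.n) < spec.motif_prob
    out = []
    for s, plant in zip(seqs, planted):
        if plant:
            start = int(rng.integers(0, len(s) - len(m) + 1))
            s = s[:start] + m + s[start + len(m):]
        out.append(s)
    rule = label_rule or (lambda s: int(m in s))
    records = [
        PeptideRecord(sequence=s, label=rule(s), source="synthetic-aop") for s in out
    ]
    labels = {r.label for r in records}
    if len(labels) < 2:
        raise ValueError(f"label rule produced a single class: {labels}")
    return PeptideCorpus(records, name="aop", notes=f"synthetic; seed={spec.seed}")


def make_reference_db(
    corpus: PeptideCorpus, overlap_fraction: float, extra_n: int, seed: int = 0
) -> set[str]:
    """Reference set containing a known fraction of the corpus plus fresh
    sequences, so the expected novelty rate of the corpus is
    (1 - overlap_fraction) * 100%."""
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    unique = list(dict.fromkeys(corpus.sequences))
    n_overlap = round(overlap_fraction * len(unique))
    picked = set(rng.choice(unique, size=n_overlap, replace=False)) if n_overlap else set()
    corpus_set = set(unique)
    residues = np.array(list(CANONICAL_RESIDUES))
    extras: set[str] = set()
    while len(extras) < extra_n:
        L = int(rng.integers(2, 16))
        s = "".join(residues[rng.integers(0, 20, size=L)])
        if s not in corpus_set:
            extras.add(s)
    return picked | extras


def make_verdict_tables(
    corpus: PeptideCorpus, nontoxic_prob: float = 0.8,
    predictors: tuple[str, ...] = ("toxpredA", "toxpredB"), seed: int = 0,
) -> list:
    """Synthetic stand-ins for external toxicity predictors.

    Each predictor independently marks every corpus sequence nontoxic with
    probability ``nontoxic_prob``; verdicts are deterministic in the seed and
    cover every (deduplicated) corpus sequence, as the cascade requires.
    """
    from .filterchain import ToxicityVerdictTable

    if not 0.0 <= nontoxic_prob <= 1.0:
        raise ValueError("nontoxic_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    unique = list(dict.fromkeys(corpus.sequences))
    tables = []
    for name in predictors:
        draws = rng.random(len(unique)) < nontoxic_prob
        tables.append(ToxicityVerdictTable(
            predictor=name,
            verdicts={s: ("nontoxic" if d else "toxic") for s, d in zip(unique, draws)},
        ))
    return tables


def default_pretrain_spec(n: int = 10_000, seed: int = 0) -> SynthSpec:
    """Conditions emulating the general pretraining corpus (~10k sequences,
    broad composition, lengths 2-15)."""
    return SynthSpec(n=n, min_len=2, max_len=15,
                     composition=uniform_composition(), seed=seed)


def default_aop_spec(n: int = 696, seed: int = 1) -> SynthSpec:
    """Conditions emulating the antioxidant corpus: 696 sequences, <= 15
    residues, Y/W/H-enriched, motif YWH planted in half the sequences."""
    return SynthSpec(n=n, min_len=4, max_len=15,
                     composition=aop_like_composition(),
                     motif="YWH", motif_prob=0.5, seed=seed)
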