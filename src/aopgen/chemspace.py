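"""Chemical-space diagnostics: residue-composition statistics and hydrophobicity.

Used to compare the pretraining corpus, the antioxidant fine-tuning corpus
and the generated set: if transfer learning worked, generated sequences sit
close to the fine-tuning corpus in mean amino-acid fraction and average
hydrophobicity, not the general corpus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqdata import CANONICAL_RESIDUES, PeptideCorpus, PeptideRecord

# Residue -> hydrophobicity, complete over the 20 canonical residues.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
}
HOPP_WOODS = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2, "E": 3.0,
    "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5,
    "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}

SCALES = {
    "kyte-doolittle": KYTE_DOOLITTLE,
    "eisenberg": EISENBERG,
    "hopp-woods": HOPP_WOODS,
}


@dataclass(frozen=True)
class HydrophobicityScale:
    name: str
    values: dict[str, float]

    def __post_init__(self):
        missing = set(CANONICAL_RESIDUES) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")


def get_scale(name: str = "kyte-doolittle") -> HydrophobicityScale:
    return HydrophobicityScale(name=name, values=SCALES[name])


@dataclass
class ChemSpaceSummary:
    name: str
    mean_fraction: np.ndarray  # per residue, order CANONICAL_RESIDUES
    std_fraction: np.ndarray
    avg_hydrophobicity: float
    scale_name: str
    n_sequences: int
    weighting: str = "per-sequence"  # sequences weighted equally, not pooled


def aa_fractions(record: PeptideRecord | str) -> np.ndarray:
    """Residue-fraction vector of one sequence (order: alphabetical code)."""
    seq = record.sequence if isinstance(record, PeptideRecord) else record
    if not seq:
        raise ValueError("empty sequence")
    counts = np.array([seq.count(r) for r in CANONICAL_RESIDUES], dtype=float)
    return counts / len(seq)


def sequence_hydrophobicity(seq: str, scale: HydrophobicityScale) -> float:
    return float(np.mean([scale.values[ch] for ch in seq]))


def corpus_summary(
    corpus: PeptideCorpus,
    scale: HydrophobicityScale | None = None,
    pooled: bool = False,
) -> ChemSpaceSummary:
    """Mean/std of per-sequence residue fractions + average hydrophobicity.

    Default weighting averages per-sequence fraction vectors (every peptide
    counts equally regardless of length); ``pooled=True`` instead pools
    residue counts across the corpus.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    scale = scale or get_scale()
    F = np.stack([aa_fractions(r) for r in corpus])
    if pooled:
        lengths = np.array([len(r) for r in corpus], dtype=float)
        mean = (F * lengths[:, None]).sum(axis=0) / lengths.sum()
    else:
        mean = F.mean(axis=0)
    std = F.std(axis=0)
    hyd = float(np.mean([sequence_hydrophobicity(r.sequence, scale) for r in corpus]))
    return ChemSpaceSummary(
        name=corpus.name, mean_fraction=mean, std_fraction=std,
        avg_hydrophobicity=hyd, scale_name=scale.name, n_sequences=len(corpus),
        weighting="pooled" if pooled else "per-sequence",
    )


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """TV distance between two composition vectors, renormalised to sum 1."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p = p / p.sum()
    q = q / q.sum()
    return float(0.5 * np.abs(p - q).sum())


def compare_corpora(summaries: list[ChemSpaceSummary]) -> dict:
    """Side-by-side fraction table, hydrophobicities and pairwise TV distances."""
    if len(summaries) < 2:
        raise ValueError("need at least two summaries to compare")
    scales = {s.scale_name for s in summaries}
    if len(scales) > 1:
        raise ValueError(f"summaries use different hydrophobicity scales: {scales}")
    import pandas as pd

    table = pd.DataFrame(
        {f"{s.name}_mean": s.mean_fraction for s in summaries}
        | {f"{s.name}_std": s.std_fraction for s in summaries},
        index=list(CANONICAL_RESIDUES),
    )
    tv = {
        (a.name, b.name): total_variation(a.mean_fraction, b.mean_fraction)
        for i, a in enumerate(summaries)
        for b in summaries[i + 1:]
    }
    return {
        "fractions": table,
        "hydrophobicity": {s.name: s.avg_hydrophobicity for s in summaries},
        "tv_distance": tv,
        "scale": summaries[0].scale_name,
    }
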