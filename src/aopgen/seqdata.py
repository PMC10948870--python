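"""Peptide corpora: validation, tokenization, preprocessing, splitting, I/O.

Sequences are uppercase strings over the 20 canonical one-letter amino-acid
codes.  Records optionally carry a binary activity label (1 = active,
0 = inactive) or a free-text label such as ``"chelator"``, plus a source tag.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

PAD_TOKEN = "<pad>"
BOS_TOKEN = "<bos>"
EOS_TOKEN = "<eos>"


class SequenceError(ValueError):
    """A sequence contains a non-canonical character."""

    def __init__(self, sequence: str, position: int, char: str):
        self.sequence = sequence
        self.position = position  # 1-based
        self.char = char
        super().__init__(
            f"invalid character {char!r} at position {position} in sequence {sequence!r}"
        )


@dataclass(frozen=True)
class AminoAcidVocabulary:
    """Token inventory: 20 canonical residues plus pad / begin / end specials.

    Residue ids are contiguous from 0; specials follow.  The begin and end
    markers frame every token sequence fed to the autoregressive model; the
    pad token fills batches to a common length and is excluded from the loss.
    """

    residues: str = CANONICAL_RESIDUES
    specials: tuple[str, ...] = (PAD_TOKEN, BOS_TOKEN, EOS_TOKEN)

    def __post_init__(self):
        if len(self.residues) != 20 or len(set(self.residues)) != 20:
            raise ValueError("vocabulary must contain exactly 20 distinct residues")
        if set(self.specials) & set(self.residues):
            raise ValueError("specials and residues must be disjoint")

    @property
    def size(self) -> int:
        return len(self.residues) + len(self.specials)

    @property
    def pad_id(self) -> int:
        return len(self.residues)

    @property
    def bos_id(self) -> int:
        return len(self.residues) + 1

    @property
    def eos_id(self) -> int:
        return len(self.residues) + 2

    def index_of(self, token: str) -> int:
        if len(token) == 1 and token in self.residues:
            return self.residues.index(token)
        if token in self.specials:
            return len(self.residues) + self.specials.index(token)
        raise KeyError(token)

    def token_of(self, idx: int) -> str:
        if 0 <= idx < len(self.residues):
            return self.residues[idx]
        if idx < self.size:
            return self.specials[idx - len(self.residues)]
        raise KeyError(idx)


DEFAULT_VOCAB = AminoAcidVocabulary()


@dataclass(frozen=True)
class PeptideRecord:
    sequence: str
    label: int | str | None = None
    source: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideCorpus:
    """Ordered collection of peptide records; duplicates allowed until deduped."""

    records: list[PeptideRecord] = field(default_factory=list)
    name: str = ""
    notes: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return PeptideCorpus(self.records[i], name=self.name, notes=self.notes)
        return self.records[i]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> list[int | str | None]:
        return [r.label for r in self.records]

    @classmethod
    def from_sequences(cls, seqs, name: str = "", labels=None) -> "PeptideCorpus":
        if labels is None:
            recs = [validate_sequence(s) for s in seqs]
        else:
            recs = [replace(validate_sequence(s), label=l) for s, l in zip(seqs, labels)]
        return cls(recs, name=name)


def validate_sequence(raw: str, label=None, source=None) -> PeptideRecord:
    """Uppercase and validate a raw sequence against the canonical alphabet.

    Raises :class:`SequenceError` naming the first offending character and its
    1-based position (B, J, O, U, X, Z, digits and whitespace all reject).
    """
    seq = raw.upper()
    if not seq:
        raise SequenceError(seq, 0, "")
    for i, ch in enumerate(seq):
        if ch not in CANONICAL_RESIDUES:
            raise SequenceError(seq, i + 1, ch)
    return PeptideRecord(sequence=seq, label=label, source=source)


def preprocess_corpus(
    corpus: PeptideCorpus,
    max_len: int = 15,
    excluded_labels: set | frozenset = frozenset(),
) -> tuple[PeptideCorpus, dict[str, int]]:
    """Length-cap and label-exclusion filter applied before any training.

    Keeps records with ``len(sequence) <= max_len`` whose label is not in
    ``excluded_labels`` (e.g. ``{"chelator"}``), preserving order.  Returns the
    filtered corpus and a removal count per reason.
    """
    kept = []
    counts = {"too_long": 0, "excluded_label": 0}
    for rec in corpus:
        if len(rec) > max_len:
            counts["too_long"] += 1
        elif rec.label in excluded_labels:
            counts["excluded_label"] += 1
        else:
            kept.append(rec)
    return PeptideCorpus(kept, name=corpus.name, notes=corpus.notes), counts


def tokenize(record: PeptideRecord, vocab: AminoAcidVocabulary = DEFAULT_VOCAB) -> list[int]:
    """Encode a record as [begin, residue ids..., end]."""
    if not record.sequence:
        raise ValueError("cannot tokenize an empty sequence")
    try:
        ids = [vocab.index_of(ch) for ch in record.sequence]
    except KeyError as e:
        raise ValueError(f"unknown residue {e.args[0]!r}") from e
    return [vocab.bos_id, *ids, vocab.eos_id]


def detokenize(ids, vocab: AminoAcidVocabulary = DEFAULT_VOCAB) -> str:
    """Inverse of :func:`tokenize`; ignores begin/end/pad markers."""
    special = {vocab.pad_id, vocab.bos_id, vocab.eos_id}
    return "".join(vocab.token_of(i) for i in ids if i not in special)


def split_train_val(
    corpus: PeptideCorpus, train_fraction: float = 0.9, seed: int = 0
) -> tuple[PeptideCorpus, PeptideCorpus]:
    """Random disjoint, exhaustive train/validation partition.

    Train size is round(train_fraction * n), clamped so both parts are
    non-empty; the same seed always yields the same partition.
    """
    n = len(corpus)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(np.clip(round(train_fraction * n), 1, n - 1))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = PeptideCorpus([corpus[int(i)] for i in perm[:n_train]], name=corpus.name + "/train")
    val = PeptideCorpus([corpus[int(i)] for i in perm[n_train:]], name=corpus.name + "/val")
    return train, val


# ---------------------------------------------------------------------------
# File I/O

def _parse_label(text: str):
    t = text.strip().lower()
    if t in ("1", "active"):
        return 1
    if t in ("0", "inactive"):
        return 0
    return text.strip()


def _format_label(label) -> str:
    return str(label)


def read_corpus(path, fmt: str | None = None, name: str | None = None) -> PeptideCorpus:
    """Read a corpus from FASTA or CSV (columns sequence[,label][,source])."""
    path = str(path)
    if fmt is None:
        fmt = "fasta" if path.endswith((".fa", ".fasta", ".faa")) else "csv"
    records: list[PeptideRecord] = []
    if fmt == "fasta":
        for sr in SeqIO.parse(path, "fasta"):
            label = None
            source = None
            for part in sr.description.split()[1:]:
                if part.startswith("label="):
                    label = _parse_label(part[len("label="):])
                elif part.startswith("source="):
                    source = part[len("source="):]
            records.append(validate_sequence(str(sr.seq), label=label, source=source))
    elif fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "sequence" not in reader.fieldnames:
                raise ValueError(f"{path}: CSV is missing the required 'sequence' column")
            for lineno, row in enumerate(reader, start=2):
                seq = (row.get("sequence") or "").strip()
                if not seq:
                    raise ValueError(f"{path}: line {lineno}: empty sequence field")
                label = row.get("label")
                label = _parse_label(label) if label not in (None, "") else None
                source = row.get("source") or None
                try:
                    records.append(validate_sequence(seq, label=label, source=source))
                except SequenceError as e:
                    raise ValueError(f"{path}: line {lineno}: {e}") from e
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")
    return PeptideCorpus(records, name=name if name is not None else path)


def write_corpus(corpus: PeptideCorpus, path, fmt: str | None = None) -> str:
    """Write a corpus to FASTA (header ``>pep<i> [label=..] [source=..]``) or CSV."""
    path = str(path)
    if fmt is None:
        fmt = "fasta" if path.endswith((".fa", ".fasta", ".faa")) else "csv"
    if fmt == "fasta":
        srs = []
        for i, rec in enumerate(corpus):
            desc = []
            if rec.label is not None:
                desc.append(f"label={_format_label(rec.label)}")
            if rec.source is not None:
                desc.append(f"source={rec.source}")
            srs.append(
                SeqRecord(Seq(rec.sequence), id=f"pep{i + 1}", description=" ".join(desc))
            )
        SeqIO.write(srs, path, "fasta")
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sequence", "label", "source"])
            for rec in corpus:
                writer.writerow(
                    [
                        rec.sequence,
                        "" if rec.label is None else _format_label(rec.label),
                        rec.source or "",
                    ]
                )
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")
    return path
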