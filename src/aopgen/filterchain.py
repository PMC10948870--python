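"""The candidate-selection cascade with per-stage accounting.

Generated peptides pass, in order: deduplication (uniqueness %), novelty
against a reference database (novelty %), unanimous fivefold classifier
consensus at 0.99, intersection of external toxicity verdicts (kept only if
every predictor calls the peptide nontoxic), and finally sphere-exclusion
clustering over Levenshtein distance with centroid selection.  Every stage is
a pure filter and the report chains input/output counts stage to stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from . import classifier as clf
from . import cluster as clu
from .seqdata import PeptideCorpus


@dataclass
class StageEntry:
    name: str
    n_in: int
    n_out: int
    rate: float | None = None  # uniqueness / novelty percentage where defined
    params: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


@dataclass
class FilterReport:
    stages: list[StageEntry] = field(default_factory=list)

    def add(self, entry: StageEntry) -> None:
        if self.stages and entry.n_in != self.stages[-1].n_out:
            raise ValueError(
                f"stage {entry.name!r} input count {entry.n_in} does not chain with "
                f"previous output {self.stages[-1].n_out}"
            )
        if entry.n_out > entry.n_in or entry.n_out < 0:
            raise ValueError(f"stage {entry.name!r} has inconsistent counts")
        self.stages.append(entry)

    def to_rows(self) -> list[dict]:
        return [
            {"stage": s.name, "n_in": s.n_in, "n_out": s.n_out,
             "n_removed": s.n_removed,
             "rate_pct": "" if s.rate is None else f"{s.rate:.4f}",
             "params": ";".join(f"{k}={v}" for k, v in s.params.items())}
            for s in self.stages
        ]

    def to_csv(self, path) -> str:
        rows = self.to_rows()
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
        return str(path)

    def __str__(self) -> str:
        lines = ["filter cascade:"]
        for s in self.stages:
            rate = "" if s.rate is None else f"  ({s.rate:.1f}%)"
            lines.append(f"  {s.name:<12} {s.n_in:>7} -> {s.n_out:>7}{rate}")
        return "\n".join(lines)


@dataclass
class ToxicityVerdictTable:
    """Offline verdict table from one external toxicity predictor."""

    predictor: str
    verdicts: dict[str, str]  # sequence -> "toxic" | "nontoxic"

    def __post_init__(self):
        bad = {v for v in self.verdicts.values()} - {"toxic", "nontoxic"}
        if bad:
            raise ValueError(f"{self.predictor}: non-binary verdicts {sorted(bad)}")

    @classmethod
    def from_csv(cls, path, predictor: str | None = None) -> "ToxicityVerdictTable":
        verdicts = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"sequence", "verdict"} <= set(reader.fieldnames):
                raise ValueError(f"{path}: verdict CSV needs columns sequence,verdict")
            for row in reader:
                verdicts[row["sequence"].strip().upper()] = row["verdict"].strip().lower()
        return cls(predictor=predictor or str(path), verdicts=verdicts)

    def to_csv(self, path) -> str:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sequence", "verdict"])
            for seq, v in self.verdicts.items():
                writer.writerow([seq, v])
        return str(path)


def dedupe(corpus: PeptideCorpus) -> tuple[PeptideCorpus, float]:
    """Keep first occurrences; uniqueness % = unique / input * 100."""
    seen = set()
    kept = []
    for rec in corpus:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            kept.append(rec)
    out = PeptideCorpus(kept, name=corpus.name + "/unique")
    rate = 100.0 * len(out) / len(corpus) if len(corpus) else 100.0
    return out, rate


def novelty_filter(corpus: PeptideCorpus, reference: set[str]) -> tuple[PeptideCorpus, float]:
    """Drop sequences present in the reference database; novelty % kept."""
    reference = {s.upper() for s in reference}
    kept = [r for r in corpus if r.sequence not in reference]
    out = PeptideCorpus(kept, name=corpus.name + "/novel")
    rate = 100.0 * len(out) / len(corpus) if len(corpus) else 100.0
    return out, rate


def toxicity_intersect(
    corpus: PeptideCorpus, verdicts: list[ToxicityVerdictTable]
) -> PeptideCorpus:
    """Keep peptides every predictor calls nontoxic; missing entries error."""
    if not verdicts:
        raise ValueError("at least one toxicity verdict table is required")
    for table in verdicts:
        for rec in corpus:
            if rec.sequence not in table.verdicts:
                raise KeyError(
                    f"sequence {rec.sequence!r} missing from predictor {table.predictor!r}"
                )
    kept = [
        r for r in corpus
        if all(t.verdicts[r.sequence] == "nontoxic" for t in verdicts)
    ]
    return PeptideCorpus(kept, name=corpus.name + "/nontoxic")


def run_cascade(
    generated: PeptideCorpus,
    reference: set[str],
    verdicts: list[ToxicityVerdictTable],
    ensemble: clf.ClassifierEnsemble,
    consensus_threshold: float = 0.99,
    cluster_threshold: float = 2.0,
    predicate: str = "strict",
    recount: str = "dynamic",
) -> tuple[PeptideCorpus, FilterReport]:
    """Full cascade: dedupe -> novelty -> consensus -> toxicity -> centroids."""
    report = FilterReport()

    unique, uniq_rate = dedupe(generated)
    report.add(StageEntry("dedupe", len(generated), len(unique), rate=uniq_rate))

    novel, nov_rate = novelty_filter(unique, reference)
    report.add(StageEntry("novelty", len(unique), len(novel), rate=nov_rate,
                          params={"reference_size": len(reference)}))

    if len(novel):
        preds = clf.predict_ensemble(ensemble, novel)
        passed, _ = clf.consensus_filter(novel, preds, threshold=consensus_threshold)
    else:
        passed = novel
    report.add(StageEntry("consensus", len(novel), len(passed),
                          params={"threshold": consensus_threshold,
                                  "k": ensemble.config.k_folds}))

    nontoxic = toxicity_intersect(passed, verdicts) if len(passed) else passed
    report.add(StageEntry("toxicity", len(passed), len(nontoxic),
                          params={"predictors": ",".join(t.predictor for t in verdicts)}))

    if len(nontoxic):
        dist = clu.pairwise_distances(nontoxic)
        result = clu.butina_cluster(dist, threshold=cluster_threshold,
                                    predicate=predicate, recount=recount)
        final = clu.select_centroids(result, nontoxic)
    else:
        final = nontoxic
    report.add(StageEntry("centroids", len(nontoxic), len(final),
                          params={"threshold": cluster_threshold,
                                  "predicate": predicate, "recount": recount}))
    return final, report
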