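"""Single-pass multi-threshold PRS accumulation.

Each scored SNP contributes ``weight * dosage`` to every p-value threshold
its discovery p-value qualifies for (p <= T, closed).  The engine makes one
pass over the genotype stream: a SNP is added to the bucket of its smallest
qualifying threshold, and buckets are cumulatively summed at the end.  Scores
are divided by each sample's own SNP count (missing genotypes contribute
nothing and are not counted), so the per-sample count can vary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .allele_match import Action, MatchDecision
from .errors import ConfigError, PolyscoreError
from .genotype_io import MISSING_TOL, SnpGenotypes
from .summary_stats import GwasRecord


@dataclass(frozen=True)
class ThresholdSet:
    """Strictly increasing p-value thresholds in (0, 1]."""

    thresholds: tuple[float, ...]

    def __post_init__(self):
        ts = self.thresholds
        if not ts:
            raise ConfigError("at least one p-value threshold is required")
        if any(not (0.0 < t <= 1.0) for t in ts):
            raise ConfigError(f"thresholds must lie in (0, 1]: {ts}")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ConfigError(f"thresholds must be strictly increasing: {ts}")

    def __len__(self) -> int:
        return len(self.thresholds)

    def __iter__(self):
        return iter(self.thresholds)

    def bucket(self, p: float) -> int | None:
        """Index of the smallest threshold with p <= T, or None if p exceeds
        the largest threshold."""
        idx = int(np.searchsorted(self.thresholds, p, side="left"))
        return idx if idx < len(self.thresholds) else None

    @classmethod
    def parse(cls, text: str) -> "ThresholdSet":
        """Parse a comma-separated threshold list, e.g. '0.1,0.2,0.5'."""
        try:
            values = tuple(float(tok) for tok in text.split(",") if tok.strip())
        except ValueError as exc:
            raise ConfigError(f"bad threshold list {text!r}: {exc}")
        return cls(thresholds=values)


DEFAULT_THRESHOLDS = ThresholdSet(thresholds=(0.1, 0.2, 0.3, 0.4, 0.5))


@dataclass
class ScoreTable:
    """Samples x thresholds PRS matrix with per-sample SNP counts.

    ``raw_sums`` and ``snp_counts`` have shape (n_thresholds, n_samples);
    ``avg_scores`` divides by the per-sample count and is NaN where the
    count is zero (no score is not a zero score).
    """

    sample_ids: tuple[str, ...]
    thresholds: ThresholdSet
    raw_sums: np.ndarray
    snp_counts: np.ndarray

    @classmethod
    def empty(cls, sample_ids, thresholds: ThresholdSet) -> "ScoreTable":
        n_t, n_s = len(thresholds), len(sample_ids)
        return cls(
            sample_ids=tuple(sample_ids),
            thresholds=thresholds,
            raw_sums=np.zeros((n_t, n_s)),
            snp_counts=np.zeros((n_t, n_s), dtype=np.int64),
        )

    @property
    def avg_scores(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            avg = self.raw_sums / self.snp_counts
        avg[self.snp_counts == 0] = np.nan
        return avg

    def merge(self, other: "ScoreTable") -> "ScoreTable":
        """Combine partial tables from disjoint chunks of the SNP stream."""
        if other.sample_ids != self.sample_ids or other.thresholds != self.thresholds:
            raise PolyscoreError("cannot merge score tables with different axes")
        return ScoreTable(
            sample_ids=self.sample_ids,
            thresholds=self.thresholds,
            raw_sums=self.raw_sums + other.raw_sums,
            snp_counts=self.snp_counts + other.snp_counts,
        )

    def write(self, path) -> None:
        """Tab-delimited text: sample_id, then PRS_<T> and COUNT_<T> per
        threshold; undefined averages written as NA."""
        avg = self.avg_scores
        with open(path, "w") as fh:
            header = ["sample_id"]
            for t in self.thresholds:
                header += [f"PRS_{t:g}", f"COUNT_{t:g}"]
            fh.write("\t".join(header) + "\n")
            for s, sid in enumerate(self.sample_ids):
                row = [sid]
                for t_idx in range(len(self.thresholds)):
                    a = avg[t_idx, s]
                    row.append("NA" if np.isnan(a) else f"{a:.10g}")
                    row.append(str(int(self.snp_counts[t_idx, s])))
                fh.write("\t".join(row) + "\n")


def effect_dosage(triple, scored: str) -> float:
    """Expected effect-allele count from a probability triple.

    ``2*p_hom_effect + p_het``: allele1 scored uses (p11, p12), allele2
    scored uses (p22, p12).  Missing triples are the caller's business.
    """
    p11, p12, p22 = triple
    if scored == "A1":
        return 2.0 * p11 + p12
    if scored == "A2":
        return 2.0 * p22 + p12
    raise ValueError(f"scored allele must be 'A1' or 'A2', got {scored!r}")


def accumulate(
    stream: Iterable[tuple[GwasRecord, SnpGenotypes, MatchDecision]],
    thresholds: ThresholdSet,
    sample_ids: tuple[str, ...],
) -> ScoreTable:
    """One pass over scored SNPs into a samples x thresholds table.

    Discards must be filtered upstream and each SNP must appear once;
    a duplicate id is fatal (it would double-count the weight).
    Contributions are accumulated in stream order within buckets, so
    results are reproducible run-to-run.
    """
    table = ScoreTable.empty(sample_ids, thresholds)
    seen: set[str] = set()
    for gwas, snp, decision in stream:
        if decision.action is Action.DISCARD:
            raise PolyscoreError(f"discarded SNP {snp.snp_id} reached the scorer")
        if snp.snp_id in seen:
            raise PolyscoreError(f"duplicate SNP {snp.snp_id} in scoring stream")
        seen.add(snp.snp_id)
        bucket = thresholds.bucket(gwas.p_value)
        if bucket is None:
            continue
        probs = snp.probs
        present = probs.sum(axis=1) >= MISSING_TOL
        if decision.action is Action.SCORE_A1:
            dosage = 2.0 * probs[:, 0] + probs[:, 1]
        else:
            dosage = 2.0 * probs[:, 2] + probs[:, 1]
        table.raw_sums[bucket, present] += gwas.weight * dosage[present]
        table.snp_counts[bucket, present] += 1
    # buckets hold "smallest qualifying threshold" totals; cumulate so each
    # threshold includes every SNP with p <= T
    np.cumsum(table.raw_sums, axis=0, out=table.raw_sums)
    np.cumsum(table.snp_counts, axis=0, out=table.snp_counts)
    return table
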