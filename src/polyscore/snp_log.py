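"""Per-threshold SNP log.

Records, for each p-value threshold, which SNPs entered the score and via
which target allele column ("A1"/"A2"), plus a discard list with the reason
each SNP was excluded.  The scored lists are nested across thresholds; the
written layout is columnar with a PRS_<T> / PRS_<T>_flag column pair per
threshold and a Discard (+ reason) column pair, padded to equal length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .allele_match import Action, MatchDecision, Reason
from .scoring import ThresholdSet


@dataclass
class SnpLog:
    thresholds: ThresholdSet
    #: per threshold, list of (snp_id, "A1"/"A2") in stream order
    scored: dict[float, list[tuple[str, str]]] = field(default_factory=dict)
    #: (snp_id, reason string) in stream order
    discards: list[tuple[str, str]] = field(default_factory=list)
    #: scored SNPs whose p-value exceeds every threshold
    above_max_threshold: list[str] = field(default_factory=list)


def build_log(
    decisions: Iterable[tuple[str, float, MatchDecision]],
    thresholds: ThresholdSet,
) -> SnpLog:
    """Assemble the log from (snp_id, p_value, decision) triples, one per SNP.

    A scored SNP is listed under every threshold with p <= T; a discarded SNP
    appears once with its reason; a scored SNP whose p-value exceeds the
    largest threshold is tracked separately (it contributes to no score).
    """
    log = SnpLog(thresholds=thresholds, scored={t: [] for t in thresholds})
    for snp_id, p_value, decision in decisions:
        if decision.action is Action.DISCARD:
            log.discards.append((snp_id, decision.reason.value))
            continue
        label = decision.scored_allele_label
        qualified = False
        for t in thresholds:
            if p_value <= t:
                log.scored[t].append((snp_id, label))
                qualified = True
        if not qualified:
            log.above_max_threshold.append(snp_id)
    return log


def write_log(log: SnpLog, path) -> None:
    """Write the columnar tab-delimited log, columns padded with blanks."""
    columns: list[list[str]] = []
    headers: list[str] = []
    for t in log.thresholds:
        entries = log.scored[t]
        headers += [f"PRS_{t:g}", f"PRS_{t:g}_flag"]
        columns.append([sid for sid, _ in entries])
        columns.append([label for _, label in entries])
    headers += ["Discard", "Discard_reason"]
    columns.append([sid for sid, _ in log.discards])
    columns.append([reason for _, reason in log.discards])

    depth = max((len(c) for c in columns), default=0)
    with open(path, "w") as fh:
        fh.write("\t".join(headers) + "\n")
        for i in range(depth):
            row = [col[i] if i < len(col) else "" for col in columns]
            fh.write("\t".join(row) + "\n")


def read_log(path) -> tuple[dict[float, list[tuple[str, str]]], list[tuple[str, str]]]:
    """Parse a written log back into scored-per-threshold and discard lists."""
    with open(path) as fh:
        headers = fh.readline().rstrip("\n").split("\t")
        rows = [line.rstrip("\n").split("\t") for line in fh]
    scored: dict[float, list[tuple[str, str]]] = {}
    discards: list[tuple[str, str]] = []
    for j in range(0, len(headers), 2):
        name = headers[j]
        cells = [(r[j] if j < len(r) else "", r[j + 1] if j + 1 < len(r) else "")
                 for r in rows]
        cells = [(a, b) for a, b in cells if a]
        if name == "Discard":
            discards = cells
        else:
            scored[float(name.removeprefix("PRS_"))] = cells
    return scored, discards
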