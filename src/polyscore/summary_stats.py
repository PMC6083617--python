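"""Read and normalize discovery GWAS summary statistics.

A summary-statistics table supplies, per SNP, the effect allele, its weight
(a beta coefficient, or the natural log of an odds ratio for binary traits),
the association p-value, and optionally the effect-allele frequency in the
discovery cohort.  GWAS files have no fixed schema, so the column mapping is
explicit user configuration; the defaults match PGC-style headers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError

VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class GwasRecord:
    """One discovery-GWAS SNP: who gets scored and with what weight.

    ``weight`` is on the additive (log-odds or beta) scale.  ``other_allele``
    and ``effect_af`` may be absent; absence of the effect-allele frequency
    makes a strand-ambiguous SNP unrescuable downstream.
    """

    snp_id: str
    effect_allele: str
    weight: float
    p_value: float
    other_allele: str | None = None
    effect_af: float | None = None


@dataclass(frozen=True)
class ColumnMap:
    """Header names for the mapped summary-statistics columns.

    ``a2`` and ``af`` may be None when the file lacks those columns.
    Defaults follow PGC-style headers.
    """

    snp: str = "SNP"
    a1: str = "A1"
    a2: str | None = "A2"
    effect: str = "OR"
    p: str = "P"
    af: str | None = "FRQ_A"


@dataclass
class ParseReport:
    """Per-reason counts of rejected rows, plus duplicate-id removals."""

    n_read: int = 0
    n_kept: int = 0
    rejected: dict[str, int] = field(default_factory=dict)
    duplicate_ids: list[str] = field(default_factory=list)

    def reject(self, reason: str) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + 1

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())


_NA_TOKENS = {"", "NA", "N/A", ".", "-", "NAN"}


def _clean_allele(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    allele = str(value).strip().upper()
    return None if allele in _NA_TOKENS else allele


def read_summary_stats(
    path,
    column_map: ColumnMap | None = None,
    effect_is_or: bool = True,
) -> tuple[list[GwasRecord], ParseReport]:
    """Parse a delimited summary-statistics file into weight records.

    Parameters
    ----------
    path
        Whitespace- or tab-delimited text with a header row; ``.gz`` accepted.
    column_map
        Header-name mapping; defaults to PGC-style names.
    effect_is_or
        When True the effect column holds odds ratios and the stored weight
        is ``ln(OR)``; when False the effect column is used verbatim (beta).

    Returns the records in file order plus a report of dropped rows.  Rows
    with unparseable required fields, non-SNP alleles, out-of-range p-values,
    or non-positive odds ratios are dropped and counted, never fatal.
    """
    cmap = column_map or ColumnMap()
    table = pd.read_csv(path, sep=r"\s+", dtype=str, comment=None)

    required = [cmap.snp, cmap.a1, cmap.effect, cmap.p]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ConfigError(
            f"{path}: mapped column(s) {missing} not found in header "
            f"{list(table.columns)}"
        )
    for optional in (cmap.a2, cmap.af):
        if optional is not None and optional not in table.columns:
            raise ConfigError(f"{path}: mapped column {optional!r} not found in header")
    has_a2 = cmap.a2 is not None
    has_af = cmap.af is not None

    report = ParseReport(n_read=len(table))
    records: list[GwasRecord] = []
    for row in table.itertuples(index=False):
        getter = dict(zip(table.columns, row)).get
        snp_id = getter(cmap.snp)
        if snp_id is None or not str(snp_id).strip():
            report.reject("missing snp id")
            continue
        snp_id = str(snp_id).strip()

        a1 = _clean_allele(getter(cmap.a1))
        if a1 is None or a1 not in VALID_ALLELES:
            report.reject("non-SNP allele")
            continue
        a2 = _clean_allele(getter(cmap.a2)) if has_a2 else None
        if a2 is not None and a2 not in VALID_ALLELES:
            report.reject("non-SNP allele")
            continue
        if a2 is not None and a2 == a1:
            report.reject("identical alleles")
            continue

        try:
            effect = float(getter(cmap.effect))
            p = float(getter(cmap.p))
        except (TypeError, ValueError):
            report.reject("unparseable numeric field")
            continue
        if not math.isfinite(effect) or not math.isfinite(p):
            report.reject("unparseable numeric field")
            continue
        if not (0.0 < p <= 1.0):
            report.reject("p-value out of (0,1]")
            continue
        if effect_is_or:
            if effect <= 0.0:
                report.reject("non-positive odds ratio")
                continue
            weight = math.log(effect)
        else:
            weight = effect

        af = None
        if has_af:
            raw_af = getter(cmap.af)
            try:
                cand = float(raw_af)
            except (TypeError, ValueError):
                cand = math.nan
            # out-of-range AF is dropped, not the row: AF is optional
            if math.isfinite(cand) and 0.0 < cand < 1.0:
                af = cand

        records.append(
            GwasRecord(
                snp_id=snp_id,
                effect_allele=a1,
                other_allele=a2,
                weight=weight,
                p_value=p,
                effect_af=af,
            )
        )

    report.n_kept = len(records)
    return records, report


def deduplicate(records: list[GwasRecord]) -> tuple[list[GwasRecord], list[str]]:
    """Remove every row of any duplicated rsID.

    A duplicated id leaves the weight ambiguous, and a wrong weight is worse
    than a missing SNP, so all copies go.  Returns the surviving records in
    original order and the sorted list of removed ids.
    """
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.snp_id] = counts.get(rec.snp_id, 0) + 1
    dupes = {sid for sid, n in counts.items() if n > 1}
    kept = [rec for rec in records if rec.snp_id not in dupes]
    return kept, sorted(dupes)


def write_summary_stats(records: list[GwasRecord], path, column_map: ColumnMap | None = None) -> None:
    """Write records back out as tab-delimited text (weights as betas).

    The effect column always holds the stored weight (log-odds/beta scale),
    so a round trip uses ``effect_is_or=False``.
    """
    cmap = column_map or ColumnMap()
    cols = [cmap.snp, cmap.a1]
    if cmap.a2 is not None:
        cols.append(cmap.a2)
    cols += [cmap.effect, cmap.p]
    if cmap.af is not None:
        cols.append(cmap.af)
    rows = []
    for rec in records:
        row = {cmap.snp: rec.snp_id, cmap.a1: rec.effect_allele,
               cmap.effect: repr(rec.weight), cmap.p: repr(rec.p_value)}
        if cmap.a2 is not None:
            row[cmap.a2] = rec.other_allele if rec.other_allele is not None else "NA"
        if cmap.af is not None:
            row[cmap.af] = repr(rec.effect_af) if rec.effect_af is not None else "NA"
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
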