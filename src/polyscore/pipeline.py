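"""End-to-end run: summary stats -> allele matching -> scores -> outputs.

The pipeline joins the discovery table to the target genotype stream on
rsID, decides per SNP which target allele carries the weight (or why not),
accumulates scores at every threshold in one pass, and writes the score
table, the optional SNP log, an optional phenotype-fit report, and a
key-value run summary.  All outputs are written atomically (temp file then
rename), so a failed run leaves no partial score file behind.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

from .allele_match import Action, is_strand_ambiguous, match_alleles
from .errors import ConfigError
from .evaluation import best_fit, fit_prs_phenotype, read_phenotype, write_fit_report
from .genotype_io import read_gen, read_vcf, target_allele1_frequency
from .scoring import DEFAULT_THRESHOLDS, ScoreTable, ThresholdSet, accumulate
from .snp_log import build_log, write_log
from .summary_stats import ColumnMap, deduplicate, read_summary_stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sumstats: str
    geno: str
    out_prefix: str
    format: str = "gen"  # "gen" | "vcf"
    sample: str | None = None  # required for GEN
    prob_source: str = "GP"  # VCF only: "GP" | "GT"
    thresholds: ThresholdSet = DEFAULT_THRESHOLDS
    effect_is_or: bool = True
    use_af_matching: bool = True
    write_snp_log: bool = False
    phenotype: str | None = None
    column_map: ColumnMap = field(default_factory=ColumnMap)

    def validate(self) -> None:
        if self.format not in ("gen", "vcf"):
            raise ConfigError(f"format must be 'gen' or 'vcf', got {self.format!r}")
        if self.format == "gen" and self.sample is None:
            raise ConfigError("GEN input requires a SAMPLE file (--sample)")
        for p in filter(None, (self.sumstats, self.geno, self.sample, self.phenotype)):
            if not os.path.exists(p):
                raise ConfigError(f"input file not found: {p}")


@dataclass
class RunSummary:
    n_sumstats_rows: int = 0
    n_sumstats_kept: int = 0
    n_sumstats_rejected: int = 0
    n_duplicate_ids: int = 0
    n_target_snps: int = 0
    n_unmatched_target: int = 0
    n_matched: int = 0
    n_scored: int = 0
    n_above_max_threshold: int = 0
    discards_by_reason: dict[str, int] = field(default_factory=dict)
    snps_per_threshold: dict[float, int] = field(default_factory=dict)
    score_path: str = ""
    snp_log_path: str | None = None
    fit_path: str | None = None
    best_fit_threshold: float | None = None

    @property
    def n_discarded(self) -> int:
        return sum(self.discards_by_reason.values())

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"sumstats_rows\t{self.n_sumstats_rows}\n")
            fh.write(f"sumstats_kept\t{self.n_sumstats_kept}\n")
            fh.write(f"sumstats_rejected\t{self.n_sumstats_rejected}\n")
            fh.write(f"duplicate_ids_removed\t{self.n_duplicate_ids}\n")
            fh.write(f"target_snps\t{self.n_target_snps}\n")
            fh.write(f"target_unmatched\t{self.n_unmatched_target}\n")
            fh.write(f"matched\t{self.n_matched}\n")
            fh.write(f"scored\t{self.n_scored}\n")
            fh.write(f"above_max_threshold\t{self.n_above_max_threshold}\n")
            for reason in sorted(self.discards_by_reason):
                fh.write(f"discarded_{reason}\t{self.discards_by_reason[reason]}\n")
            for t, n in self.snps_per_threshold.items():
                fh.write(f"snps_at_{t:g}\t{n}\n")
            if self.best_fit_threshold is not None:
                fh.write(f"best_fit_threshold\t{self.best_fit_threshold:g}\n")


def _atomic(path: Path, write_fn) -> None:
    tmp = path.with_name(path.name + ".tmp")
    write_fn(tmp)
    os.replace(tmp, path)


def run(config: RunConfig) -> tuple[ScoreTable, RunSummary]:
    """Execute the full scoring pipeline; deterministic, single pass."""
    config.validate()
    summary = RunSummary()

    records, report = read_summary_stats(
        config.sumstats, config.column_map, effect_is_or=config.effect_is_or
    )
    records, dup_ids = deduplicate(records)
    summary.n_sumstats_rows = report.n_read
    summary.n_sumstats_kept = len(records)
    summary.n_sumstats_rejected = report.n_rejected
    summary.n_duplicate_ids = len(dup_ids)
    logger.info("summary stats: %d rows, %d usable (%d rejected, %d duplicate ids)",
                report.n_read, len(records), report.n_rejected, len(dup_ids))
    by_id = {rec.snp_id: rec for rec in records}

    if config.format == "gen":
        cohort, stream = read_gen(config.geno, config.sample)
    else:
        cohort, stream = read_vcf(config.geno, prob_source=config.prob_source)
    logger.info("target cohort: %d samples", len(cohort))

    log_entries: list = []

    def scored_stream():
        for snp in stream:
            summary.n_target_snps += 1
            gwas = by_id.get(snp.snp_id)
            if gwas is None:
                summary.n_unmatched_target += 1
                continue
            summary.n_matched += 1
            af1 = None
            if is_strand_ambiguous(snp.allele1, snp.allele2) and config.use_af_matching:
                af1 = target_allele1_frequency(snp)
            decision = match_alleles(gwas, snp, af1, config.use_af_matching)
            log_entries.append((snp.snp_id, gwas.p_value, decision))
            if decision.action is Action.DISCARD:
                reason = decision.reason.value
                summary.discards_by_reason[reason] = (
                    summary.discards_by_reason.get(reason, 0) + 1
                )
                continue
            summary.n_scored += 1
            yield gwas, snp, decision

    scores = accumulate(scored_stream(), config.thresholds, cohort.sample_ids)

    out = Path(config.out_prefix)
    out.parent.mkdir(parents=True, exist_ok=True)
    score_path = out.with_name(out.name + ".scores.txt")
    _atomic(score_path, scores.write)
    summary.score_path = str(score_path)

    log = build_log(log_entries, config.thresholds)
    summary.n_above_max_threshold = len(log.above_max_threshold)
    summary.snps_per_threshold = {t: len(log.scored[t]) for t in config.thresholds}
    if config.write_snp_log:
        log_path = out.with_name(out.name + ".snplog.txt")
        _atomic(log_path, lambda p: write_log(log, p))
        summary.snp_log_path = str(log_path)

    if config.phenotype is not None:
        phenotype = read_phenotype(config.phenotype)
        fits = [fit_prs_phenotype(scores, phenotype, t) for t in config.thresholds]
        fit_path = out.with_name(out.name + ".fit.txt")
        _atomic(fit_path, lambda p: write_fit_report(fits, p))
        summary.fit_path = str(fit_path)
        summary.best_fit_threshold = best_fit(fits).threshold

    _atomic(out.with_name(out.name + ".summary.txt"), summary.write)
    logger.info("scored %d of %d matched SNPs (%d discarded)",
                summary.n_scored, summary.n_matched, summary.n_discarded)
    return scores, summary
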