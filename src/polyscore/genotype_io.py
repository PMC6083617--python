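"""Stream target genotypes from Oxford GEN/SAMPLE and VCF files.

Both readers normalize to one representation: per SNP, an allele pair and a
per-sample probability triple ``(p11, p12, p22)`` ordered homozygous-allele1,
heterozygous, homozygous-allele2.  Hard calls become degenerate triples
(one component equal to 1); a triple summing to zero marks a missing
genotype.  Triples are never renormalized — residual uncertainty mass is
legitimate in imputation output and the dosage formula consumes raw
probabilities.

Genotypes are consumed as a forward-only stream in bounded memory; every
downstream operation is required to give identical results regardless of
where the stream is chunked.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .errors import FormatError

logger = logging.getLogger(__name__)

#: triples with total probability mass below this are missing genotypes
MISSING_TOL = 1e-9
#: maximum tolerated excess of a triple's sum over 1
SUM_TOL = 1e-6


@dataclass(frozen=True)
class Cohort:
    """Ordered, unique sample identifiers of the target cohort."""

    sample_ids: tuple[str, ...]

    def __post_init__(self):
        if not self.sample_ids:
            raise FormatError("cohort has no samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in cohort")

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class SnpGenotypes:
    """One target SNP: allele pair plus per-sample probability triples.

    ``probs`` has shape (n_samples, 3), columns (p11, p12, p22) relative to
    (allele1, allele2) in file order (VCF: REF, ALT).
    """

    snp_id: str
    allele1: str
    allele2: str
    probs: np.ndarray
    chrom: str | None = None
    pos: int | None = None

    def missing_mask(self) -> np.ndarray:
        """True where a sample's genotype is missing (zero-mass triple)."""
        return self.probs.sum(axis=1) < MISSING_TOL


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sample_file(sample_path) -> Cohort:
    """Read an Oxford SAMPLE file: two header rows, then one row per sample
    with the sample id in the first column."""
    with _open_text(sample_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{sample_path}: needs 2 header rows and >=1 sample row")
    ids = tuple(ln.split()[0] for ln in lines[2:])
    return Cohort(sample_ids=ids)


def _check_triples(probs: np.ndarray, where: str) -> None:
    if np.any(probs < 0) or np.any(probs > 1):
        raise FormatError(f"{where}: genotype probability outside [0,1]")
    sums = probs.sum(axis=1)
    if np.any(sums > 1.0 + SUM_TOL):
        raise FormatError(f"{where}: probability triple sums above 1")


def read_gen(gen_path, sample_path) -> tuple[Cohort, Iterator[SnpGenotypes]]:
    """Stream an Oxford GEN file.

    GEN rows carry 5 leading fields (or 6 with a leading chromosome) followed
    by 3 probabilities per sample in cohort order.  The dialect is detected
    from the first row given the sample count from the SAMPLE file, and every
    row is checked against it.
    """
    cohort = read_sample_file(sample_path)
    n = len(cohort)

    def _stream() -> Iterator[SnpGenotypes]:
        lead: int | None = None
        with _open_text(gen_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                fields = line.split()
                if not fields:
                    continue
                if lead is None:
                    lead = len(fields) - 3 * n
                    if lead not in (5, 6):
                        raise FormatError(
                            f"{gen_path}:{lineno}: {len(fields)} fields do not fit "
                            f"5 or 6 leading columns + 3x{n} probabilities"
                        )
                    logger.info(
                        "GEN dialect: %d leading fields (%s chromosome column)",
                        lead, "with" if lead == 6 else "no",
                    )
                if len(fields) != lead + 3 * n:
                    raise FormatError(
                        f"{gen_path}:{lineno}: expected {lead + 3 * n} fields, "
                        f"got {len(fields)}"
                    )
                if lead == 6:
                    chrom, snp_id, pos_s, a1, a2 = fields[0], fields[1], fields[3], fields[4], fields[5]
                else:
                    chrom, snp_id, pos_s, a1, a2 = None, fields[0], fields[2], fields[3], fields[4]
                try:
                    probs = np.array(fields[lead:], dtype=float).reshape(n, 3)
                except ValueError as exc:
                    raise FormatError(f"{gen_path}:{lineno}: bad probability value ({exc})")
                _check_triples(probs, f"{gen_path}:{lineno}")
                # zero out sub-threshold residual mass so missingness is exact
                probs[probs.sum(axis=1) < MISSING_TOL] = 0.0
                try:
                    pos = int(pos_s)
                except ValueError:
                    pos = None
                yield SnpGenotypes(
                    snp_id=snp_id, chrom=chrom, pos=pos,
                    allele1=a1.upper(), allele2=a2.upper(), probs=probs,
                )

    return cohort, _stream()


def read_vcf(vcf_path, prob_source: str = "GP") -> tuple[Cohort, Iterator[SnpGenotypes]]:
    """Stream biallelic records from a VCF.

    ``prob_source='GP'`` takes the per-sample genotype posterior triple from
    the GP FORMAT field (VCF order REF/REF, REF/ALT, ALT/ALT); ``'GT'`` turns
    diploid hard calls into degenerate triples.  ``./.`` and absent GP become
    missing (zero) triples.  Multi-allelic and non-SNP records are skipped
    with a logged reason.
    """
    from cyvcf2 import VCF

    prob_source = prob_source.upper()
    if prob_source not in ("GP", "GT"):
        raise FormatError(f"unknown probability source {prob_source!r}")

    vcf = VCF(str(vcf_path))
    cohort = Cohort(sample_ids=tuple(vcf.samples))
    n = len(cohort)

    def _stream() -> Iterator[SnpGenotypes]:
        for variant in vcf:
            if len(variant.ALT) != 1:
                logger.info("skipping %s: multi-allelic", variant.ID or variant.POS)
                continue
            ref, alt = variant.REF.upper(), variant.ALT[0].upper()
            if len(ref) != 1 or len(alt) != 1:
                logger.info("skipping %s: not a SNP", variant.ID or variant.POS)
                continue
            snp_id = variant.ID
            if not snp_id:
                logger.info("skipping %s:%s: no rsID", variant.CHROM, variant.POS)
                continue
            if prob_source == "GP":
                gp = variant.format("GP")
                if gp is None:
                    raise FormatError(f"{vcf_path}: FORMAT field GP absent at {snp_id}")
                probs = np.array(gp, dtype=float)
                if probs.shape != (n, 3):
                    raise FormatError(f"{vcf_path}: GP at {snp_id} is not a 3-vector")
                probs[~np.isfinite(probs).all(axis=1)] = 0.0
                _check_triples(probs, f"{vcf_path}:{snp_id}")
                probs[probs.sum(axis=1) < MISSING_TOL] = 0.0
            else:
                gts = variant.genotypes  # [allele_a, allele_b, phased] per sample
                if gts is None:
                    raise FormatError(f"{vcf_path}: FORMAT field GT absent at {snp_id}")
                probs = np.zeros((n, 3), dtype=float)
                for i, gt in enumerate(gts):
                    a, b = gt[0], gt[1]
                    if a < 0 or b < 0:
                        continue  # missing
                    probs[i, a + b] = 1.0
            yield SnpGenotypes(
                snp_id=snp_id, chrom=variant.CHROM, pos=variant.POS,
                allele1=ref, allele2=alt, probs=probs,
            )

    return cohort, _stream()


def target_allele1_frequency(snp: SnpGenotypes) -> float | None:
    """Frequency of allele1 in the target cohort from expected dosages.

    Mean over non-missing samples of ``(2*p11 + p12) / 2``.  Returns None
    when every sample is missing (propagates as a discard reason downstream).
    """
    keep = ~snp.missing_mask()
    if not keep.any():
        return None
    p = snp.probs[keep]
    return float(np.mean((2.0 * p[:, 0] + p[:, 1]) / 2.0))
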