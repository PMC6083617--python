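"""Synthetic discovery + target panels with known ground truth.

The generator emulates the three study inputs — imputed posterior
probabilities, hard calls, and observed (array) genotypes — on a toy scale:
per-SNP genotypes are binomial(2, MAF) with no linkage disequilibrium,
discovery weights are normal(0, 0.1) on the log-odds scale, p-values are
uniform, a configurable fraction of SNPs is strand-ambiguous, and a
configurable fraction of the non-ambiguous SNPs is written to the target
files with both alleles reverse-complemented (opposite-strand reporting).

The discovery effect-allele frequency written to the summary statistics is
the frequency realized in the simulated cohort, so the allele-frequency
rescue of ambiguous SNPs is exactly decidable from the generated data, and
the truth record carries every SNP's correct scored allele plus a naive
reference scorer (`reference_prs`) used as the comparison oracle everywhere.

Imputation noise keeps the probability mode on the true genotype and places
all probabilities on a 1/4096 grid, so triples survive text round-trips and
single-precision VCF parsing bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotype_io import MISSING_TOL, Cohort, SnpGenotypes, target_allele1_frequency
from .scoring import ScoreTable, ThresholdSet
from .summary_stats import GwasRecord

_GRID = 4096  # dyadic grid: exact in float32, float64 and decimal text
_MAX_OFF = int(0.45 * _GRID)  # off-mode mass < mode mass, mode preserved

_AMBIGUOUS_PAIRS = [("A", "T"), ("C", "G")]
_PLAIN_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]
_RC = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic panel.

    Defaults mirror a small imputed cohort: 264 samples (the scale of the
    community cohort the method was demonstrated on), moderate imputation
    uncertainty, a fifth of SNPs strand-ambiguous, and a tenth of the
    non-ambiguous SNPs reported on the opposite strand.
    """

    n_samples: int = 264
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    prop_ambiguous: float = 0.2
    imputation_noise: float = 0.3
    strand_flip_rate: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        assert 0.0 < lo <= hi <= 0.5
        assert 0.0 <= self.prop_ambiguous <= 1.0
        assert 0.0 <= self.strand_flip_rate <= 1.0
        assert 0.0 <= self.missing_rate <= 1.0
        assert self.imputation_noise >= 0.0


@dataclass
class SimSnp:
    """Ground truth for one simulated SNP."""

    snp_id: str
    chrom: str
    pos: int
    # discovery side
    effect_allele: str
    other_allele: str
    weight: float
    p_value: float
    maf: float  # configured (generating) effect-allele frequency
    effect_af: float | None  # realized effect-allele frequency, None if all missing
    # target side (as written to files, i.e. after any strand flip)
    allele1: str
    allele2: str
    pp_probs: np.ndarray  # (n_samples, 3) posterior-probability triples
    hc_probs: np.ndarray  # (n_samples, 3) degenerate hard-call triples
    ambiguous: bool
    flipped: bool
    effect_is_allele1: bool  # positional truth, unaffected by strand flips

    def gwas_record(self) -> GwasRecord:
        return GwasRecord(
            snp_id=self.snp_id,
            effect_allele=self.effect_allele,
            other_allele=self.other_allele,
            weight=self.weight,
            p_value=self.p_value,
            effect_af=self.effect_af,
        )

    def genotypes(self, source: str = "pp") -> SnpGenotypes:
        probs = self.pp_probs if source == "pp" else self.hc_probs
        return SnpGenotypes(
            snp_id=self.snp_id, chrom=self.chrom, pos=self.pos,
            allele1=self.allele1, allele2=self.allele2, probs=probs.copy(),
        )


@dataclass
class SimulatedPanel:
    """A complete synthetic study: cohort, truth per SNP, file writers."""

    config: SimConfig
    cohort: Cohort
    snps: list[SimSnp] = field(default_factory=list)

    # -- file writers ------------------------------------------------------

    def write_sample(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("ID_1 ID_2 missing\n0 0 0\n")
            for sid in self.cohort.sample_ids:
                fh.write(f"{sid} {sid} 0\n")

    def write_gen(self, path, source: str = "pp") -> None:
        """Six-leading-field GEN (chrom, id, rsid, pos, a1, a2, then triples)."""
        with open(path, "w") as fh:
            for snp in self.snps:
                probs = snp.pp_probs if source == "pp" else snp.hc_probs
                lead = [snp.chrom, snp.snp_id, snp.snp_id, str(snp.pos),
                        snp.allele1, snp.allele2]
                body = " ".join(repr(float(v)) for v in probs.ravel())
                fh.write(" ".join(lead) + " " + body + "\n")

    def write_vcf(self, path) -> None:
        """VCF 4.2 with both GT (hard calls) and GP (posterior) per sample."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,Description='
                     '"Genotype posterior probabilities">\n')
            fh.write("##contig=<ID=1>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.cohort.sample_ids) + "\n")
            for snp in self.snps:
                cells = []
                for pp, hc in zip(snp.pp_probs, snp.hc_probs):
                    if hc.sum() < MISSING_TOL:
                        cells.append("./.:.,.,.")
                        continue
                    gt = ("0/0", "0/1", "1/1")[int(np.argmax(hc))]
                    gp = ",".join(repr(float(v)) for v in pp)
                    cells.append(f"{gt}:{gp}")
                fh.write(
                    f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.allele1}\t"
                    f"{snp.allele2}\t.\tPASS\t.\tGT:GP\t" + "\t".join(cells) + "\n"
                )

    def write_sumstats(self, path) -> None:
        """Tab-delimited PGC-style table; the effect column holds the beta."""
        with open(path, "w") as fh:
            fh.write("SNP\tA1\tA2\tBETA\tP\tFRQ_A\n")
            for snp in self.snps:
                af = repr(snp.effect_af) if snp.effect_af is not None else "NA"
                fh.write(
                    f"{snp.snp_id}\t{snp.effect_allele}\t{snp.other_allele}\t"
                    f"{snp.weight!r}\t{snp.p_value!r}\t{af}\n"
                )

    def write_phenotype(self, path, values: np.ndarray) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tphenotype\n")
            for sid, y in zip(self.cohort.sample_ids, values):
                fh.write(f"{sid}\t{float(y)!r}\n")

    def write_all(self, outdir, source: str = "pp") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "sumstats": outdir / "sumstats.txt",
            "gen": outdir / "panel.gen",
            "sample": outdir / "panel.sample",
            "vcf": outdir / "panel.vcf",
        }
        self.write_sumstats(paths["sumstats"])
        self.write_gen(paths["gen"], source=source)
        self.write_sample(paths["sample"])
        self.write_vcf(paths["vcf"])
        return paths


def _hard_calls(pp: np.ndarray) -> np.ndarray:
    """Best-guess triples: per-row argmax, ties broken toward the
    heterozygote; zero rows (missing) stay missing."""
    m = pp.shape[0]
    hc = np.zeros_like(pp)
    present = pp.sum(axis=1) >= MISSING_TOL
    top = pp.max(axis=1)
    idx = np.where(pp[:, 1] == top, 1, pp.argmax(axis=1))
    hc[np.arange(m)[present], idx[present]] = 1.0
    return hc


def simulate_panel(config: SimConfig) -> SimulatedPanel:
    """Generate a panel with full ground truth; byte-reproducible per seed.

    Independent random streams drive each aspect (allele pairs, weights,
    p-values, genotypes, noise, missingness, flips), so e.g. changing
    ``strand_flip_rate`` relabels alleles without touching the genotypes.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(8)
    rng_allele = np.random.default_rng(streams[0])
    rng_weight = np.random.default_rng(streams[1])
    rng_p = np.random.default_rng(streams[2])
    rng_geno = np.random.default_rng(streams[3])
    rng_noise = np.random.default_rng(streams[4])
    rng_miss = np.random.default_rng(streams[5])
    rng_flip = np.random.default_rng(streams[6])
    rng_order = np.random.default_rng(streams[7])

    n, m = config.n_snps, config.n_samples
    lo, hi = config.maf_range

    ambiguous = rng_allele.random(n) < config.prop_ambiguous
    pair_pick = rng_allele.integers(0, 4, size=n)
    mafs = rng_allele.uniform(lo, hi, size=n)
    weights = rng_weight.normal(0.0, 0.1, size=n)
    pvals = rng_p.uniform(0.0, 1.0, size=n)
    counts = rng_geno.binomial(2, mafs[:, None], size=(n, m))  # effect-allele copies
    perturb = rng_noise.random((n, m)) < min(config.imputation_noise, 1.0)
    off_u = rng_noise.random((n, m))
    split_u = rng_noise.random((n, m))
    missing = rng_miss.random((n, m)) < config.missing_rate
    flip = rng_flip.random(n) < config.strand_flip_rate
    effect_first = rng_order.random(n) < 0.5

    cohort = Cohort(sample_ids=tuple(f"S{i:05d}" for i in range(1, m + 1)))
    panel = SimulatedPanel(config=config, cohort=cohort)

    for i in range(n):
        if ambiguous[i]:
            eff, oth = _AMBIGUOUS_PAIRS[pair_pick[i] % 2]
        else:
            eff, oth = _PLAIN_PAIRS[pair_pick[i]]
        # triple index of the true genotype given effect-allele copy count
        if effect_first[i]:
            a1, a2 = eff, oth
            true_idx = 2 - counts[i]  # 2 effect copies = hom allele1 -> p11
        else:
            a1, a2 = oth, eff
            true_idx = counts[i]  # 2 effect copies = hom allele2 -> p22

        pp = np.zeros((m, 3))
        rows = np.arange(m)
        pp[rows, true_idx] = 1.0
        if config.imputation_noise > 0.0:
            off = (off_u[i] * (_MAX_OFF + 1)).astype(int)  # grid units off mode
            part = (split_u[i] * (off + 1)).astype(int)
            for k in range(3):
                sel = perturb[i] & (true_idx == k)
                if not sel.any():
                    continue
                o1, o2 = (j for j in range(3) if j != k)
                pp[sel, k] = (_GRID - off[sel]) / _GRID
                pp[sel, o1] = part[sel] / _GRID
                pp[sel, o2] = (off[sel] - part[sel]) / _GRID
        pp[missing[i]] = 0.0
        hc = _hard_calls(pp)

        flipped = bool(flip[i] and not ambiguous[i])
        w_a1, w_a2 = (_RC[a1], _RC[a2]) if flipped else (a1, a2)

        snp = SimSnp(
            snp_id=f"rs{1000001 + i}",
            chrom="1",
            pos=10_000 + 100 * i,
            effect_allele=eff,
            other_allele=oth,
            weight=float(weights[i]),
            p_value=float(pvals[i]),
            maf=float(mafs[i]),
            effect_af=None,
            allele1=w_a1,
            allele2=w_a2,
            pp_probs=pp,
            hc_probs=hc,
            ambiguous=bool(ambiguous[i]),
            flipped=flipped,
            effect_is_allele1=bool(effect_first[i]),
        )
        # realized frequency; a monomorphic draw (0 or 1) is not a reportable
        # allele frequency and stays absent, like in a real GWAS table
        af1 = target_allele1_frequency(snp.genotypes("pp"))
        if af1 is not None and 0.0 < af1 < 1.0:
            snp.effect_af = af1 if effect_first[i] else 1.0 - af1
        panel.snps.append(snp)

    return panel


def _naive_decision(snp: SimSnp, source: str) -> str | None:
    """Scored-allele label from ground truth, or None for a discard.

    Non-ambiguous SNPs score the allele position the generator placed the
    effect allele at.  Ambiguous SNPs replay the frequency rule naively:
    discovery effect AF and target allele-1 frequency same side of the
    [0.4, 0.6] zone -> A1, opposite sides -> A2, either in zone or
    unavailable -> discard.
    """
    if not snp.ambiguous:
        return "A1" if snp.effect_is_allele1 else "A2"
    d = snp.effect_af
    probs = snp.pp_probs if source == "pp" else snp.hc_probs
    dose_sum = n_obs = 0.0
    for trip in probs:
        if trip.sum() < MISSING_TOL:
            continue
        dose_sum += (2.0 * trip[0] + trip[1]) / 2.0
        n_obs += 1
    if d is None or n_obs == 0:
        return None
    t = dose_sum / n_obs
    if 0.4 <= d <= 0.6 or 0.4 <= t <= 0.6:
        return None
    return "A1" if (d < 0.4) == (t < 0.4) else "A2"


def reference_prs(
    panel: SimulatedPanel,
    thresholds: ThresholdSet,
    source: str = "pp",
    use_af_matching: bool = True,
) -> ScoreTable:
    """Brute-force oracle: per sample, per threshold, re-scan every SNP."""
    m = len(panel.cohort)
    ts = list(thresholds)
    sums = np.zeros((len(ts), m))
    cnts = np.zeros((len(ts), m), dtype=np.int64)
    for snp in panel.snps:
        if snp.ambiguous and not use_af_matching:
            continue
        label = _naive_decision(snp, source)
        if label is None:
            continue
        probs = snp.pp_probs if source == "pp" else snp.hc_probs
        for t_idx, t in enumerate(ts):
            if snp.p_value > t:
                continue
            for s in range(m):
                trip = probs[s]
                if trip.sum() < MISSING_TOL:
                    continue
                if label == "A1":
                    dose = 2.0 * trip[0] + trip[1]
                else:
                    dose = 2.0 * trip[2] + trip[1]
                sums[t_idx, s] += snp.weight * dose
                cnts[t_idx, s] += 1
    return ScoreTable(sample_ids=panel.cohort.sample_ids, thresholds=thresholds,
                      raw_sums=sums, snp_counts=cnts)


def simulate_phenotype(
    prs: np.ndarray,
    target_r2: float,
    seed: int,
    slope: float = 1.0,
) -> np.ndarray:
    """Phenotype = slope*PRS + gaussian noise sized for a target R-squared.

    Noise variance is ``var(slope*prs) * (1 - R2) / R2``; NaN scores yield
    NaN phenotypes.
    """
    assert 0.0 < target_r2 < 1.0
    rng = np.random.default_rng(seed)
    signal = slope * np.asarray(prs, dtype=float)
    sig_var = np.nanvar(signal)
    if sig_var == 0.0:
        raise ValueError("PRS has zero variance; target R-squared unreachable")
    sd = math.sqrt(sig_var * (1.0 - target_r2) / target_r2)
    return signal + rng.normal(0.0, sd, size=signal.shape)
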