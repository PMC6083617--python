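"""Effect-allele reconciliation between discovery and target data.

For a non-ambiguous SNP the discovery effect allele identifies the target
allele directly, or after reverse-complementing the target pair when the two
datasets report opposite strands.  A strand-ambiguous SNP (A/T or C/G) is its
own reverse complement, so alleles alone cannot resolve it; instead the
discovery effect-allele frequency is compared with the target allele-1
frequency.  If both frequencies are below 0.4 or both above 0.6 the effect
allele is target allele 1; if they are on opposite sides it is allele 2; a
frequency inside the closed zone [0.4, 0.6] on either side leaves the match
too uncertain and the SNP is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .genotype_io import SnpGenotypes
from .summary_stats import GwasRecord, VALID_ALLELES

#: inclusive allele-frequency exclusion zone for ambiguous SNPs
AF_ZONE_LOW = 0.4
AF_ZONE_HIGH = 0.6

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class Action(str, Enum):
    SCORE_A1 = "SCORE_A1"
    SCORE_A2 = "SCORE_A2"
    DISCARD = "DISCARD"


class Reason(str, Enum):
    OK = "OK"
    AMBIGUOUS_AF_ZONE = "AMBIGUOUS_AF_ZONE"
    AMBIGUOUS_DISABLED = "AMBIGUOUS_DISABLED"
    ALLELE_MISMATCH = "ALLELE_MISMATCH"
    MISSING_AF = "MISSING_AF"
    AF_CONFLICT = "AF_CONFLICT"
    NON_SNP = "NON_SNP"


@dataclass(frozen=True)
class MatchDecision:
    """Outcome of effect-allele reconciliation for one SNP."""

    snp_id: str
    action: Action
    reason: Reason = Reason.OK

    def __post_init__(self):
        assert (self.action is Action.DISCARD) == (self.reason is not Reason.OK)

    @property
    def scored_allele_label(self) -> str | None:
        if self.action is Action.SCORE_A1:
            return "A1"
        if self.action is Action.SCORE_A2:
            return "A2"
        return None


def reverse_complement(allele: str) -> str:
    """A<->T, C<->G (an involution on single bases)."""
    return _COMPLEMENT[allele]


def is_strand_ambiguous(allele1: str, allele2: str) -> bool:
    """True iff the unordered pair is {A,T} or {C,G} — a pair equal to its
    own reverse complement, from which strand cannot be inferred."""
    return {allele1, allele2} in ({"A", "T"}, {"C", "G"})


def _direct_assign(effect: str, other: str | None, a1: str, a2: str) -> Action | None:
    if effect == a1 and (other is None or other == a2):
        return Action.SCORE_A1
    if effect == a2 and (other is None or other == a1):
        return Action.SCORE_A2
    return None


def _in_zone(f: float) -> bool:
    return AF_ZONE_LOW <= f <= AF_ZONE_HIGH


def match_alleles(
    gwas: GwasRecord,
    snp: SnpGenotypes,
    target_af1: float | None,
    use_af_matching: bool = True,
) -> MatchDecision:
    """Decide which target allele carries the discovery weight, or discard.

    Every input yields a decision; no branch raises.  ``target_af1`` is the
    target cohort's allele-1 frequency (None when uncomputable, e.g. all
    samples missing); it is consulted only for strand-ambiguous pairs.
    """
    a1, a2 = snp.allele1, snp.allele2
    if a1 not in VALID_ALLELES or a2 not in VALID_ALLELES or a1 == a2:
        return MatchDecision(snp.snp_id, Action.DISCARD, Reason.NON_SNP)

    effect, other = gwas.effect_allele, gwas.other_allele

    if not is_strand_ambiguous(a1, a2):
        action = _direct_assign(effect, other, a1, a2)
        if action is None:
            # opposite-strand report: retry against the reverse-complemented
            # target pair (never done for ambiguous pairs — they map to
            # themselves, which is the whole problem)
            action = _direct_assign(
                effect, other, reverse_complement(a1), reverse_complement(a2)
            )
        if action is None:
            return MatchDecision(snp.snp_id, Action.DISCARD, Reason.ALLELE_MISMATCH)
        return MatchDecision(snp.snp_id, action)

    # strand-ambiguous pair
    if not use_af_matching:
        return MatchDecision(snp.snp_id, Action.DISCARD, Reason.AMBIGUOUS_DISABLED)

    # The pair equals its own reverse complement, so the effect allele's
    # letter carries no positional information: it need only belong to the
    # pair, and the assignment rests entirely on the two frequencies.
    if effect not in (a1, a2):
        return MatchDecision(snp.snp_id, Action.DISCARD, Reason.ALLELE_MISMATCH)
    if other is not None and {effect, other} != {a1, a2}:
        return MatchDecision(snp.snp_id, Action.DISCARD, Reason.ALLELE_MISMATCH)

    d, t = gwas.effect_af, target_af1
    if d is None or t is None:
        return MatchDecision(snp.snp_id, Action.DISCARD, Reason.MISSING_AF)
    if _in_zone(d) or _in_zone(t):
        return MatchDecision(snp.snp_id, Action.DISCARD, Reason.AMBIGUOUS_AF_ZONE)

    same_side = (d < AF_ZONE_LOW) == (t < AF_ZONE_LOW)
    action = Action.SCORE_A1 if same_side else Action.SCORE_A2
    return MatchDecision(snp.snp_id, action)
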