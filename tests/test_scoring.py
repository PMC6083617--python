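import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyscore.allele_match import Action, MatchDecision
from polyscore.errors import ConfigError, PolyscoreError
from polyscore.scoring import ScoreTable, ThresholdSet, accumulate, effect_dosage
from polyscore.simulate import SimConfig, reference_prs, simulate_panel
from polyscore.summary_stats import GwasRecord

from conftest import DEFAULT_TS, make_snp


def entry(snp_id, weight, p, probs, action=Action.SCORE_A1, a1="A", a2="G"):
    gwas = GwasRecord(snp_id=snp_id, effect_allele=a1, other_allele=a2,
                      weight=weight, p_value=p)
    snp = make_snp(snp_id=snp_id, a1=a1, a2=a2, probs=probs)
    return gwas, snp, MatchDecision(snp_id, action)


class TestThresholdSet:
    @pytest.mark.parametrize("bad", [(), (0.0, 0.5), (0.5, 0.5), (0.5, 0.2), (0.5, 1.1)])
    def test_invalid(self, bad):
        with pytest.raises(ConfigError):
            ThresholdSet(thresholds=bad)

    def test_parse(self):
        assert ThresholdSet.parse("0.1,0.2,0.5").thresholds == (0.1, 0.2, 0.5)

    def test_bucket_is_closed_at_threshold(self):
        ts = ThresholdSet(thresholds=(0.1, 0.5))
        assert ts.bucket(0.5) == 1
        assert ts.bucket(0.1) == 0
        assert ts.bucket(0.15) == 1
        assert ts.bucket(0.6) is None


@pytest.mark.parametrize("triple,scored,expected", [
    ((1, 0, 0), "A1", 2.0),
    ((0.25, 0.5, 0.25), "A1", 1.0),
    ((0.1, 0.2, 0.7), "A2", 1.6),
    ((0.1, 0.2, 0.7), "A1", 0.4),
])
def test_effect_dosage(triple, scored, expected):
    assert effect_dosage(triple, scored) == pytest.approx(expected, abs=1e-15)


class TestAccumulate:
    def test_single_het_snp(self):
        ts = ThresholdSet(thresholds=(0.5,))
        table = accumulate([entry("rs1", math.log(2), 0.3, [(0, 1, 0)])], ts, ("S1",))
        assert table.raw_sums[0, 0] == pytest.approx(math.log(2))
        assert table.snp_counts[0, 0] == 1
        assert table.avg_scores[0, 0] == pytest.approx(math.log(2))

    def test_snp_enters_smallest_qualifying_threshold_onward(self):
        ts = ThresholdSet(thresholds=(0.1, 0.2))
        table = accumulate([entry("rs1", 0.5, 0.15, [(1, 0, 0)])], ts, ("S1",))
        assert table.snp_counts[:, 0].tolist() == [0, 1]
        assert table.raw_sums[:, 0].tolist() == pytest.approx([0.0, 1.0])

    def test_missing_sample_not_counted(self):
        ts = ThresholdSet(thresholds=(0.5,))
        table = accumulate(
            [entry("rs1", 0.5, 0.3, [(0, 0, 0), (0, 1, 0)])], ts, ("S1", "S2")
        )
        assert table.snp_counts[0].tolist() == [0, 1]
        assert np.isnan(table.avg_scores[0, 0])

    def test_two_snp_average(self):
        ts = ThresholdSet(thresholds=(0.5,))
        stream = [
            entry("rs1", 0.1, 0.2, [(1, 0, 0)]),   # dosage 2 -> +0.2
            entry("rs2", -0.3, 0.2, [(0, 1, 0)]),  # dosage 1 -> -0.3
        ]
        table = accumulate(stream, ts, ("S1",))
        assert table.raw_sums[0, 0] == pytest.approx(-0.1)
        assert table.avg_scores[0, 0] == pytest.approx(-0.05)

    def test_p_above_max_threshold_contributes_nothing(self):
        ts = ThresholdSet(thresholds=(0.1, 0.5))
        table = accumulate([entry("rs1", 0.5, 0.9, [(1, 0, 0)])], ts, ("S1",))
        assert table.snp_counts.sum() == 0

    def test_duplicate_snp_fatal(self):
        ts = ThresholdSet(thresholds=(0.5,))
        stream = [entry("rs1", 0.1, 0.2, [(1, 0, 0)])] * 2
        with pytest.raises(PolyscoreError, match="duplicate"):
            accumulate(stream, ts, ("S1",))

    def test_discard_in_stream_fatal(self):
        ts = ThresholdSet(thresholds=(0.5,))
        gwas, snp, _ = entry("rs1", 0.1, 0.2, [(1, 0, 0)])
        from polyscore.allele_match import Reason

        bad = MatchDecision("rs1", Action.DISCARD, Reason.ALLELE_MISMATCH)
        with pytest.raises(PolyscoreError):
            accumulate([(gwas, snp, bad)], ts, ("S1",))


def panel_stream(panel, source="pp"):
    """Feed a simulated panel's ground truth straight into the scorer."""
    for snp in panel.snps:
        label = "A1" if snp.effect_is_allele1 else "A2"
        action = Action.SCORE_A1 if label == "A1" else Action.SCORE_A2
        yield snp.gwas_record(), snp.genotypes(source), MatchDecision(snp.snp_id, action)


@pytest.fixture(scope="module")
def plain_panel():
    # no ambiguous SNPs: every SNP is scored, truth labels positional
    return simulate_panel(SimConfig(
        n_samples=20, n_snps=50, prop_ambiguous=0.0, imputation_noise=0.4,
        missing_rate=0.1, strand_flip_rate=0.0, seed=23,
    ))


class TestInvariants:
    def test_matches_naive_double_loop(self, plain_panel):
        table = accumulate(panel_stream(plain_panel), DEFAULT_TS,
                           plain_panel.cohort.sample_ids)
        ref = reference_prs(plain_panel, DEFAULT_TS)
        assert np.array_equal(table.snp_counts, ref.snp_counts)
        assert np.allclose(table.raw_sums, ref.raw_sums, rtol=1e-12, atol=1e-12)

    def test_chunk_invariance(self, plain_panel):
        whole = accumulate(panel_stream(plain_panel), DEFAULT_TS,
                           plain_panel.cohort.sample_ids)
        entries = list(panel_stream(plain_panel))
        for size in (1, 7, len(entries)):
            merged = ScoreTable.empty(plain_panel.cohort.sample_ids, DEFAULT_TS)
            for i in range(0, len(entries), size):
                part = accumulate(entries[i:i + size], DEFAULT_TS,
                                  plain_panel.cohort.sample_ids)
                merged = merged.merge(part)
            assert np.array_equal(merged.snp_counts, whole.snp_counts)
            assert np.allclose(merged.raw_sums, whole.raw_sums,
                               rtol=1e-12, atol=1e-12)

    def test_hard_call_equals_allele_count_scoring(self):
        """With degenerate triples, dosage scoring is exact allele counting."""
        panel = simulate_panel(SimConfig(
            n_samples=15, n_snps=30, prop_ambiguous=0.0, imputation_noise=0.0,
            strand_flip_rate=0.0, seed=4,
        ))
        table = accumulate(panel_stream(panel), DEFAULT_TS, panel.cohort.sample_ids)
        # allele-count scoring, accumulated bucket-by-bucket in stream order
        # (the engine's summation order) so equality can be asserted exactly
        ts = list(DEFAULT_TS)
        counts = np.zeros_like(table.raw_sums)
        sums = np.zeros_like(table.raw_sums)
        for snp in panel.snps:
            probs = snp.pp_probs
            assert np.isin(probs, (0.0, 1.0)).all()
            g = probs.argmax(axis=1)  # copies of allele2
            eff = g if not snp.effect_is_allele1 else 2 - g
            bucket = min((i for i, t in enumerate(ts) if snp.p_value <= t),
                         default=None)
            if bucket is not None:
                sums[bucket] += snp.weight * eff
                counts[bucket] += 1
        sums, counts = np.cumsum(sums, axis=0), np.cumsum(counts, axis=0)
        assert np.array_equal(table.raw_sums, sums)
        assert np.array_equal(table.snp_counts, counts)

    def test_counts_monotone_in_threshold(self, plain_panel):
        table = accumulate(panel_stream(plain_panel), DEFAULT_TS,
                           plain_panel.cohort.sample_ids)
        assert (np.diff(table.snp_counts, axis=0) >= 0).all()

    @settings(deadline=None, max_examples=20)
    @given(c=st.floats(-5, 5, allow_nan=False))
    def test_affine_response_to_weights(self, plain_panel, c):
        base = accumulate(panel_stream(plain_panel), DEFAULT_TS,
                          plain_panel.cohort.sample_ids)

        def scaled():
            for gwas, snp, dec in panel_stream(plain_panel):
                yield (GwasRecord(snp_id=gwas.snp_id, effect_allele=gwas.effect_allele,
                                  other_allele=gwas.other_allele,
                                  weight=c * gwas.weight, p_value=gwas.p_value,
                                  effect_af=gwas.effect_af),
                       snp, dec)

        table = accumulate(scaled(), DEFAULT_TS, plain_panel.cohort.sample_ids)
        assert np.allclose(table.raw_sums, c * base.raw_sums, rtol=1e-12, atol=1e-12)
        assert np.allclose(table.avg_scores, c * base.avg_scores,
                           rtol=1e-12, atol=1e-12, equal_nan=True)


def test_score_file_format(tmp_path, plain_panel):
    table = accumulate(panel_stream(plain_panel), DEFAULT_TS,
                       plain_panel.cohort.sample_ids)
    path = tmp_path / "scores.txt"
    table.write(path)
    lines = path.read_text().splitlines()
    header = lines[0].split("\t")
    assert header[0] == "sample_id"
    assert header[1:3] == ["PRS_0.1", "COUNT_0.1"]
    assert len(lines) == 1 + len(plain_panel.cohort)
    # a sample with zero SNPs at a threshold gets NA, not 0
    empty = accumulate([], DEFAULT_TS, ("S1",))
    path2 = tmp_path / "empty.txt"
    empty.write(path2)
    row = path2.read_text().splitlines()[1].split("\t")
    assert row[1] == "NA" and row[2] == "0"
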