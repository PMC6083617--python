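import numpy as np
import pytest

from polyscore import ColumnMap, RunConfig
from polyscore.genotype_io import SnpGenotypes
from polyscore.scoring import ThresholdSet
from polyscore.simulate import SimConfig, simulate_panel

#: column map matching what SimulatedPanel.write_sumstats emits (beta scale)
SIM_CMAP = ColumnMap(effect="BETA")

DEFAULT_TS = ThresholdSet(thresholds=(0.1, 0.2, 0.3, 0.4, 0.5))


def make_snp(snp_id="rs1", a1="A", a2="G", probs=((1.0, 0.0, 0.0),)):
    return SnpGenotypes(
        snp_id=snp_id, allele1=a1, allele2=a2,
        probs=np.array(probs, dtype=float),
    )


@pytest.fixture
def small_panel():
    """A 50-SNP x 20-sample panel exercising every pipeline path."""
    return simulate_panel(SimConfig(
        n_samples=20, n_snps=50, prop_ambiguous=0.3, imputation_noise=0.4,
        strand_flip_rate=0.2, missing_rate=0.05, seed=11,
    ))


@pytest.fixture
def panel_files(small_panel, tmp_path):
    return small_panel.write_all(tmp_path)


def sim_run_config(paths, out_prefix, **kwargs):
    """RunConfig pointed at SimulatedPanel files (beta-scale weights)."""
    defaults = dict(
        sumstats=str(paths["sumstats"]),
        geno=str(paths["gen"]),
        sample=str(paths["sample"]),
        out_prefix=str(out_prefix),
        format="gen",
        effect_is_or=False,
        column_map=SIM_CMAP,
    )
    defaults.update(kwargs)
    return RunConfig(**defaults)
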