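import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import medipchip as mc

settings.register_profile(
    "default", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cfg() -> mc.SimConfig:
    return mc.SimConfig(n_promoters=30, seed=7)


@pytest.fixture(scope="session")
def small_experiment(small_cfg):
    """A 30-promoter, 3v3 experiment with 4 planted DMRs (2 hyper, 2 hypo)."""
    promoters = mc.gen_promoter_set(small_cfg)
    design = mc.gen_array_design(promoters, small_cfg)
    cfg = mc.plant_random_dmrs(small_cfg, 4, 1.5)
    m, truth = mc.gen_medip_experiment(design, cfg, promoters=promoters)
    return promoters, design, m, truth


def toy_design(positions, chrom="chr1", length=50, promoter="gX"):
    """Helper: a single-chromosome design with probes at given starts."""
    rows = [(f"t{i:03d}", chrom, p, p + length, promoter)
            for i, p in enumerate(sorted(positions))]
    return mc.ProbeDesign(pd.DataFrame(
        rows, columns=["probe_id", "chrom", "start", "end", "promoter_id"]))


def toy_intensities(r_values: pd.DataFrame, groups: dict[str, list[str]],
                    input_value: float = 100.0) -> mc.IntensityMatrix:
    """Build an IntensityMatrix whose log2(MeDIP/Input) equals ``r_values``
    exactly (probe x sample log2 units)."""
    input_ = pd.DataFrame(input_value, index=r_values.index, columns=r_values.columns)
    medip = input_ * np.exp2(r_values)
    rows = []
    for g, sample_ids in groups.items():
        for k, sid in enumerate(sample_ids):
            rows.append((sid, g, k + 1))
    samples = pd.DataFrame(rows, columns=["sample_id", "group", "replicate"]
                           ).set_index("sample_id")
    return mc.IntensityMatrix(medip=medip, input_=input_, samples=samples)
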