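import numpy as np
import pandas as pd
import pytest

from dimorph import ExpressionMatrix, SimConfig, simulate_timecourse_study


@pytest.fixture(scope="session")
def small_study():
    """A small two-sex time-course study with known cluster structure."""
    cfg = SimConfig(n_genes=120, K_true=3, sigma2_true=0.05,
                    discordant_fraction=0.25, seed=42)
    matrix, annot, truth = simulate_timecourse_study(cfg)
    return cfg, matrix, annot, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_matrix(rng):
    genes = [f"G{i:03d}" for i in range(50)]
    samples = [f"S{j:02d}" for j in range(20)]
    values = rng.lognormal(4.0, 0.5, size=(50, 20))
    return ExpressionMatrix(genes, samples, values)


def make_annotation(n_per_group: int = 4,
                    ages=(3.0, 6.0, 9.0, 12.0, 18.0)) -> pd.DataFrame:
    rows = []
    for sex in ("M", "F"):
        for age in ages:
            for rep in range(1, n_per_group + 1):
                rows.append({"sample_id": f"{sex}_{age:g}m_r{rep}",
                             "sex": sex, "age_months": age, "replicate": rep})
    return pd.DataFrame(rows)
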