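import numpy as np
import pandas as pd
import pytest

from gutlink.containers import MetaboFeatureMatrix, TaxaTable
from gutlink.simulate import ImplantedEffect, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """Effect-free cohort: taxa and metabolites statistically independent."""
    cfg = SimConfig(n_samples=120, n_taxa=25, n_metabolites=10,
                    locations=("cecum",), seed=11)
    taxa, metab, meta, truth = simulate_cohort(cfg)
    return taxa["cecum"], metab, meta


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with three strong implanted taxon->metabolite effects."""
    effects = [ImplantedEffect(0, 0, binary_effect=1.0, quant_effect=0.6,
                               locations=("cecum",)),
               ImplantedEffect(3, 4, binary_effect=-1.0, quant_effect=-0.6,
                               locations=("cecum",)),
               ImplantedEffect(7, 8, binary_effect=1.2, quant_effect=0.0,
                               locations=("cecum",))]
    cfg = SimConfig(n_samples=300, n_taxa=25, n_metabolites=10,
                    locations=("cecum",), effect_table=effects, seed=29)
    taxa, metab, meta, truth = simulate_cohort(cfg)
    return taxa["cecum"], metab, meta, truth


@pytest.fixture
def count_table():
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 400, size=(12, 8))
    counts[:, -1] = 0  # a never-observed taxon
    return TaxaTable(pd.DataFrame(counts,
                                  index=[f"s{i}" for i in range(12)],
                                  columns=[f"t{j}" for j in range(8)]),
                     location="faeces")


def make_metabo(intensity, orders=None, qc_flags=None, annotation=None):
    data = pd.DataFrame(intensity)
    data.index = [f"s{i}" for i in range(len(data))]
    data.columns = [f"f{j}" for j in range(data.shape[1])]
    n = len(data)
    orders = pd.Series(orders if orders is not None else range(1, n + 1),
                       index=data.index)
    qc = pd.Series(qc_flags if qc_flags is not None else [False] * n,
                   index=data.index)
    return MetaboFeatureMatrix(data=data, injection_order=orders, is_qc=qc,
                               annotation=annotation if annotation is not None
                               else pd.DataFrame())
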