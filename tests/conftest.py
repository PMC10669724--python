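import numpy as np
import pandas as pd
import pytest

import gxecross as g
from gxecross.cohort import zscore

Z_COVS = ["parental_education", "parental_occupation", "monthly_income"]
COVARIATES = ("gender", "age", "parental_education", "parental_occupation",
              "monthly_income")


def standardized_cohort(seed=1, **design_kw):
    """Simulate a cohort and return (raw table, analysis-ready view, truth).

    The view standardizes the ordinal covariates and the environment (the
    outcome stays on its generated scale, matching the truth record) and adds
    the 0/1 risk-group indicator for the focal SNP.
    """
    design = g.SimulationDesign(seed=seed, **design_kw)
    table, truth = g.simulate_cohort(design)
    view = zscore(table, Z_COVS + ["home_supervision"])
    risk = (table.data[design.risk_snp] == design.risk_genotype).astype(float)
    view.data["risk"] = risk.where(table.data[design.risk_snp].notna())
    return table, view, truth


@pytest.fixture(scope="session")
def cohort_d():
    """One default cohort under weak diathesis-stress truth."""
    return standardized_cohort(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231027)


def write_cohort_csv(path, rows):
    """Write a small cohort CSV from a list of dicts."""
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


@pytest.fixture()
def tiny_cohort_csv(tmp_path):
    rows = [
        dict(child_id="c1", gender=1, age=9.5, parental_education=3,
             parental_occupation=4, monthly_income=2, home_supervision=3.2,
             reading=0.1, rs11629841="GT"),
        dict(child_id="c2", gender=2, age=10.1, parental_education=4,
             parental_occupation=5, monthly_income=3, home_supervision=4.0,
             reading=0.7, rs11629841="TT"),
        dict(child_id="c3", gender=1, age=9.9, parental_education=2,
             parental_occupation=6, monthly_income=1, home_supervision=2.8,
             reading=-0.4, rs11629841="TT"),
    ]
    return write_cohort_csv(tmp_path / "tiny.csv", rows)
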