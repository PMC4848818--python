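import numpy as np
import pytest

import hcfc
from hcfc.instrument import FactorSpec, InstrumentSpec, ItemSpec


@pytest.fixture(scope="session")
def hcfc8():
    return hcfc.builtin_hcfc8()


@pytest.fixture(scope="session")
def tiny_spec():
    """One factor, two binary items; item 'a' is the marker."""
    return InstrumentSpec(
        factors=(FactorSpec(name="f", items=(ItemSpec("a"), ItemSpec("b"))),),
        n_categories=2,
    )


@pytest.fixture(scope="session")
def small_table(hcfc8):
    """A 62-respondent simulated survey with covariates and missing cells."""
    cfg = hcfc.default_hcfc_truth(seed=42)
    table, truth = hcfc.generate(cfg, hcfc.default_covariates())
    return table


@pytest.fixture(scope="session")
def recovery_run():
    """The parameter-recovery experiment: truth at n=800, probit fit,
    2 chains x 10,000 iterations.  Shared session-wide (it is the long
    run several posterior checks look at)."""
    cfg = hcfc.default_hcfc_truth(seed=1, n_respondents=800)
    table, truth = hcfc.generate(cfg)
    cc = hcfc.ChainConfig(n_iterations=10_000, burn_in=5_000, n_chains=2,
                          seed=3)
    draws = hcfc.run(table, config=cc)
    return cfg, table, truth, draws
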