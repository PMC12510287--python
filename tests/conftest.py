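import numpy as np
import pytest

from pocenrich.bayes_core import EfficacyCriteria
from pocenrich.cutoff_id import CutoffApproach, CutoffRule
from pocenrich.trial_engine import DesignConfig, DesignKind


@pytest.fixture(scope="session")
def motivating_criteria() -> EfficacyCriteria:
    """TV/LRV = 15%/5% with the conventional confidence levels."""
    return EfficacyCriteria(TV=0.15, LRV=0.05, alpha_TV=0.10, alpha_LRV=0.80)


@pytest.fixture(scope="session")
def motivating_design(motivating_criteria) -> DesignConfig:
    """The motivating trial: interim at 14 of 27 patients, probability-based
    cutoff rule at its chosen operating point."""
    return DesignConfig(
        n_f=14,
        N_f=27,
        criteria=motivating_criteria,
        eta_f=0.10,
        eta_fc=0.90,
        eta_plus=0.75,
        cutoff_rule=CutoffRule(
            approach=CutoffApproach.PROBABILITY_BASED, pp=0.10, diffthr=0.10, pthr=0.80
        ),
        design_kind=DesignKind.BMK_GUIDED,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
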