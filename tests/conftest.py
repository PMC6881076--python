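import numpy as np
import pytest

from regrobust.model import RateParams, TFModel, TFProfileSet
from regrobust.synthdata import gen_enhancer, gen_pwm


@pytest.fixture(scope="session")
def stripe():
    """The frozen eight-factor stripe configuration."""
    from regrobust.synthdata import stripe_fixture

    return stripe_fixture(seed=0)


@pytest.fixture(scope="session")
def stripe_evaluator(stripe):
    from regrobust.perturb import ModelEvaluator

    return ModelEvaluator(*stripe)


@pytest.fixture()
def tiny_model():
    """One activator with a single planted site on a short position grid."""
    pwm = gen_pwm("act", 4, 1.8, seed=2)
    enh = gen_enhancer("tiny", 30, [(pwm, 10, "+")], seed=3)
    tfs = {"act": TFModel(pwm, role="activator", alpha=4.0, Keq_scale=5.0)}
    positions = np.array([38.0, 40.0, 42.0, 44.0, 46.0])
    conc = np.array([[0.2], [1.0], [2.0], [1.0], [0.2]])
    profiles = TFProfileSet(positions, conc, ["act"])
    rate_params = RateParams(R_max=1.0, N0=1.5, beta=3.0)
    return enh, tfs, profiles, rate_params
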