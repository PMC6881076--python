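"""The default synthetic stripe configuration.

An eight-factor setup patterned on the gap-gene system that regulates the
second even-skipped stripe: an anterior activator gradient (bcd-like), a
coactivated anterior factor (hb-like), weak broad activators (cad-like,
dst-like), and four repressors whose domains flank the stripe (gt-like
anterior, kr-like central, kni-like and tll-like posterior). Run through the
thermodynamic model, the planted enhancer drives a single interior stripe
with its anterior border set by the gt-like repressor and its posterior
border by the kr-like repressor.

All numbers here are frozen fixture constants; they define the synthetic
study conditions and are not fitted to any data.
"""

from __future__ import annotations

from .model import RateParams, TFModel, default_position_grid

STRIPE_GRID_STEP = 0.5


def stripe_fixture(seed: int = 0, length: int = 240, grid_step: float = STRIPE_GRID_STEP):
    """Build (enhancer, tfs, profiles, rate_params) for the stripe configuration.

    Deterministic given the seed (which sets the PWM consensus draws and the
    enhancer background sequence). Positions of interest: stripe peak near
    40.5% embryo length, anterior border near 39%, anterior interstripe near
    36.5%.
    """
    from .synthdata import Bump, Front, gen_enhancer, gen_pwm, gen_tf_gradients

    grid = default_position_grid(step=grid_step)
    specs = {
        "bcd": [Front(center=46.0, width=2.5, amplitude=2.0, sign=-1.0)],
        "cad": [Front(center=60.0, width=5.0, amplitude=0.8, sign=1.0)],
        "dst": [Bump(center=64.0, width=1000.0, amplitude=0.5)],
        "hb": [Front(center=45.0, width=2.0, amplitude=1.5, sign=-1.0),
               Bump(center=85.0, width=4.0, amplitude=1.2)],
        "kr": [Bump(center=47.0, width=2.5, amplitude=2.0)],
        "kni": [Bump(center=58.0, width=4.0, amplitude=2.0)],
        "gt": [Bump(center=35.0, width=2.0, amplitude=2.0),
               Bump(center=75.0, width=5.0, amplitude=2.0)],
        "tll": [Front(center=82.0, width=2.5, amplitude=2.0, sign=1.0)],
    }
    profiles = gen_tf_gradients(specs, grid, seed=seed)

    pwm_spec = {  # (width, mean information in bits)
        "bcd": (8, 1.6), "cad": (6, 1.6), "dst": (6, 1.6), "hb": (8, 1.6),
        "kr": (8, 1.6), "kni": (7, 1.6), "gt": (8, 1.6), "tll": (7, 1.6),
    }
    pwms = {name: gen_pwm(name, w, bits, seed=seed * 101 + k)
            for k, (name, (w, bits)) in enumerate(pwm_spec.items())}

    tfs = {
        "bcd": TFModel(pwms["bcd"], role="activator", alpha=3.0, Keq_scale=5.0),
        "cad": TFModel(pwms["cad"], role="activator", alpha=1.0, Keq_scale=5.0),
        "dst": TFModel(pwms["dst"], role="activator", alpha=1.0, Keq_scale=5.0),
        "hb": TFModel(pwms["hb"], role="repressor", alpha=0.5, Keq_scale=5.0,
                      coactivated_by=("bcd", 150.0)),
        "kr": TFModel(pwms["kr"], role="repressor", Keq_scale=5.0,
                      quench_eff=0.9, quench_range=240.0),
        "kni": TFModel(pwms["kni"], role="repressor", Keq_scale=5.0,
                       quench_eff=0.9, quench_range=240.0),
        "gt": TFModel(pwms["gt"], role="repressor", Keq_scale=5.0,
                      quench_eff=0.9, quench_range=240.0),
        "tll": TFModel(pwms["tll"], role="repressor", Keq_scale=5.0,
                       quench_eff=0.9, quench_range=240.0),
    }

    planted = [
        (pwms["bcd"], 10, "+"),
        (pwms["bcd"], 30, "+"),
        (pwms["bcd"], 50, "-"),
        (pwms["hb"], 70, "+"),
        (pwms["hb"], 90, "+"),
        (pwms["cad"], 110, "+"),
        (pwms["dst"], 125, "+"),
        (pwms["gt"], 140, "+"),
        (pwms["gt"], 158, "-"),
        (pwms["kr"], 176, "+"),
        (pwms["kr"], 194, "+"),
        (pwms["kni"], 212, "+"),
        (pwms["tll"], 226, "+"),
    ]
    enh = gen_enhancer("stripe2_like", length, planted, seed=seed + 7)
    rate_params = RateParams(R_max=1.0, N0=4.0, beta=4.0)
    return enh, tfs, profiles, rate_params


#: embryo positions of interest in the stripe fixture (% embryo length)
STRIPE_PEAK = 40.5
STRIPE_ANTERIOR_BORDER = 39.0
STRIPE_INTERSTRIPE = 36.5
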