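"""Tabular and YAML interchange: TF profiles, robustness curves, model config."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import RateParams, TFModel, TFProfileSet
from .pwm import PWM
from .robustats import RobustnessCurve


def read_profiles_tsv(path: str | Path) -> TFProfileSet:
    """TSV with a 'position' column followed by one column per TF."""
    df = pd.read_csv(path, sep="\t")
    if "position" not in df.columns:
        raise ValueError(f"{path}: missing 'position' column")
    tf_names = [c for c in df.columns if c != "position"]
    return TFProfileSet(df["position"].to_numpy(float),
                        df[tf_names].to_numpy(float), tf_names)


def write_profiles_tsv(profiles: TFProfileSet, path: str | Path) -> None:
    df = pd.DataFrame(profiles.conc, columns=profiles.tf_names)
    df.insert(0, "position", profiles.positions)
    df.to_csv(path, sep="\t", index=False)


def read_curve_tsv(path: str | Path, n: int) -> RobustnessCurve:
    """TSV with columns r, var_log_m and optional n_reps."""
    df = pd.read_csv(path, sep="\t")
    n_reps = df["n_reps"].to_numpy() if "n_reps" in df.columns else 0
    return RobustnessCurve(df["r"].to_numpy(float), df["var_log_m"].to_numpy(float),
                           n=n, n_reps=n_reps)


def write_curve_tsv(curve: RobustnessCurve, path: str | Path) -> None:
    df = pd.DataFrame({"r": curve.r.astype(int), "var_log_m": curve.var_log_m})
    df["n_reps"] = curve.n_reps
    df.to_csv(path, sep="\t", index=False)


def write_track_tsv(positions, values, path: str | Path, **extra) -> None:
    df = pd.DataFrame({"position": positions, "value": values, **extra})
    df.to_csv(path, sep="\t", index=False)


def load_model_config(path: str | Path, pwms: dict[str, PWM]) -> tuple[dict[str, TFModel], RateParams]:
    """YAML model configuration.

    Layout::

        rate_params: {R_max: 1.0, N0: 3.0, beta: 1.5}
        tfs:
          bcd:
            role: activator
            alpha: 2.0
            Keq_scale: 5.0
          gt:
            role: repressor
            quench_eff: 0.9
            quench_range: 150
            coop_partners: [[gt, 2.0, 60]]
          hb:
            role: repressor
            alpha: 1.5
            coactivated_by: [bcd, 150]
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    rp = RateParams(**cfg.get("rate_params", {}))
    tfs = {}
    for name, spec in cfg["tfs"].items():
        if name not in pwms:
            raise ValueError(f"config names TF {name!r} with no PWM provided")
        spec = dict(spec)
        coop = [tuple(x) for x in spec.pop("coop_partners", [])]
        coact = spec.pop("coactivated_by", None)
        tfs[name] = TFModel(pwms[name], coop_partners=coop,
                            coactivated_by=tuple(coact) if coact else None, **spec)
    return tfs, rp
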