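"""Saturation-mutagenesis reporter (MPRA) variance analysis.

From barcode-level DNA/RNA UMI counts to Var(log expression) as a function
of the number of introduced mutations r, and the error-adjusted saturation
fit Var(r) = V0 * (1 - (1 - n0/n)^r) + c0 + c1*r. Expression per barcode and
replicate is the RNA/DNA UMI ratio; barcodes unseen in the DNA pool are
excluded, and an r stratum enters the curve only when it holds at least
min_barcodes barcodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .robustats import RobustnessCurve, SaturationFit, fit_saturation

#: continuity correction added to both UMI counts before the ratio
COUNT_OFFSET = 0.5


@dataclass
class MPRABarcodeTable:
    """Barcode rows with mutation counts and per-replicate UMI counts."""

    df: pd.DataFrame
    element: str = ""
    n: int | None = None  # element length in bp (total mutable positions)

    def __post_init__(self) -> None:
        required = {"barcode", "n_mut"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if not self.replicates:
            raise ValueError("no dna_umi_rep*/rna_umi_rep* column pairs found")
        count_cols = ["n_mut"] + [c for c in self.df.columns if "_umi_" in c]
        for col in count_cols:
            bad = self.df.index[self.df[col] < 0]
            if len(bad):
                raise ValueError(f"negative counts in {col} at rows {list(bad[:5])}")

    @property
    def replicates(self) -> list[str]:
        reps = sorted(c.removeprefix("dna_umi_") for c in self.df.columns
                      if c.startswith("dna_umi_"))
        return [r for r in reps if f"rna_umi_{r}" in self.df.columns]


@dataclass
class MPRAVarianceCurve:
    """Var(log expression) per retained mutation count r, per replicate."""

    r: np.ndarray
    var_log_expr: pd.DataFrame  # index r, one column per replicate
    barcode_counts: np.ndarray
    n: int | None = None

    @property
    def replicates(self) -> list[str]:
        return list(self.var_log_expr.columns)


def read_barcode_table(path: str | Path, element: str = "",
                       n: int | None = None) -> MPRABarcodeTable:
    """Read a TSV of (barcode, n_mut, dna_umi_rep*, rna_umi_rep*) rows.

    Malformed rows are rejected with their line numbers.
    """
    df = pd.read_csv(path, sep="\t")
    numeric = [c for c in df.columns if c != "barcode"]
    coerced = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad][:10]]  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    neg = (coerced < 0).any(axis=1)
    if neg.any():
        lines = [int(i) + 2 for i in df.index[neg][:10]]
        raise ValueError(f"{path}: negative counts at lines {lines}")
    df[numeric] = coerced.astype(int)
    return MPRABarcodeTable(df, element=element or Path(path).stem, n=n)


def write_barcode_table(table: MPRABarcodeTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def filter_barcodes(table: MPRABarcodeTable, min_dna: int = 1,
                    mode: str = "all") -> MPRABarcodeTable:
    """Keep barcodes observed in the DNA pool.

    mode="all" (default) requires dna_umi >= min_dna in every replicate;
    mode="any" in at least one.
    """
    dna = table.df[[f"dna_umi_{r}" for r in table.replicates]]
    ok = (dna >= min_dna).all(axis=1) if mode == "all" else (dna >= min_dna).any(axis=1)
    out = MPRABarcodeTable(table.df[ok].reset_index(drop=True),
                           element=table.element, n=table.n)
    if len(out.df) == 0:
        raise ValueError("no barcodes survive the DNA-presence filter")
    return out


def expression_and_variance(table: MPRABarcodeTable,
                            min_barcodes: int = 100,
                            offset: float = COUNT_OFFSET) -> MPRAVarianceCurve:
    """Var of log((rna + offset) / (dna + offset)) over barcodes, per r.

    Only mutation counts represented by at least min_barcodes barcodes are
    retained; r = 0 rows (unmutated references) are excluded from the curve.
    """
    df = table.df
    counts = df.groupby("n_mut").size()
    keep_r = sorted(int(r) for r, c in counts.items()
                    if c >= min_barcodes and r >= 1)
    if not keep_r:
        raise ValueError("no mutation count reaches the barcode minimum")
    data = {}
    for rep in table.replicates:
        expr = (df[f"rna_umi_{rep}"] + offset) / (df[f"dna_umi_{rep}"] + offset)
        log_e = np.log(expr)
        data[rep] = df.assign(_log=log_e).groupby("n_mut")["_log"].var(ddof=1)
    var = pd.DataFrame(data).loc[keep_r]
    return MPRAVarianceCurve(
        r=np.array(keep_r, dtype=int),
        var_log_expr=var,
        barcode_counts=counts.loc[keep_r].to_numpy(),
        n=table.n,
    )


def fit_mpra(curve: MPRAVarianceCurve, n: int | None = None, seed: int = 0,
             weighting: str = "inverse_variance") -> dict[str, SaturationFit]:
    """Error-adjusted saturation fit per replicate.

    Fits Var(r) = V0 * (1 - (1 - n0/n)^r) + c0 + c1*r with c0, c1 >= 0; n is
    the element's mutable length, supplied here or on the curve. The default
    weighting is inverse-variance (the sampling error of a sample variance is
    proportional to its value, so squared residuals are weighted by 1/y^2);
    weighting="none" gives ordinary least squares.
    """
    n = n if n is not None else curve.n
    if n is None:
        raise ValueError("element length n must be supplied")
    if len(curve.r) < 5:
        raise ValueError("need at least 5 retained r values")
    if weighting not in ("inverse_variance", "none"):
        raise ValueError("weighting must be 'inverse_variance' or 'none'")
    fits = {}
    for rep in curve.replicates:
        y = curve.var_log_expr[rep].to_numpy()
        rc = RobustnessCurve(r=curve.r, var_log_m=y,
                             n=n, n_reps=curve.barcode_counts)
        w = 1.0 / np.maximum(y, 1e-6) ** 2 if weighting == "inverse_variance" else None
        fits[rep] = fit_saturation(rc, with_error_terms=True, seed=seed, weights=w)
    return fits
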