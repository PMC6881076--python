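"""Per-nucleotide conservation from a multiple alignment, and its
association with mutational sensitivity.

Conservation at a reference base is the percent of non-reference species
carrying the same nucleotide in that alignment column; gaps count as
non-matching. Alignment columns where the reference has a gap carry no
reference coordinate and are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO
from scipy import stats

GAP = "-"


@dataclass
class AlignedSet:
    """Aligned sequences over {A,C,G,T,-} keyed by species, with a reference."""

    seqs: dict[str, str]
    ref_name: str
    columns: np.ndarray = field(init=False)  # alignment column per ref base

    def __post_init__(self) -> None:
        if self.ref_name not in self.seqs:
            raise ValueError(f"reference {self.ref_name!r} absent from alignment")
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        ref = self.seqs[self.ref_name]
        self.columns = np.array([i for i, b in enumerate(ref) if b != GAP], dtype=int)

    @property
    def ref_length(self) -> int:
        return len(self.columns)

    @property
    def ref_ungapped(self) -> str:
        ref = self.seqs[self.ref_name]
        return "".join(ref[i] for i in self.columns)


def read_alignment(path: str | Path, ref_name: str) -> AlignedSet:
    aln = AlignIO.read(str(path), "fasta")
    return AlignedSet({rec.id: str(rec.seq).upper() for rec in aln}, ref_name)


def write_alignment(aln: AlignedSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in aln.seqs.items():
            fh.write(f">{name}\n{seq}\n")


def column_conservation(aln: AlignedSet) -> np.ndarray:
    """Percent of non-reference species matching the reference, per ref base."""
    ref = aln.seqs[aln.ref_name]
    others = [s for name, s in aln.seqs.items() if name != aln.ref_name]
    if not others:
        raise ValueError("alignment has no non-reference species")
    out = np.empty(aln.ref_length)
    for k, col in enumerate(aln.columns):
        matches = sum(1 for s in others if s[col] == ref[col])
        out[k] = 100.0 * matches / len(others)
    return out


def sensitivity_conservation(track_values: np.ndarray, cons: np.ndarray,
                             n0: int) -> dict:
    """Compare conservation of the n0 most-sensitive bases against the rest.

    track_values is per-base sensitivity (NaN at masked bases) on the same
    reference coordinates as cons. Returns group means and the Spearman rank
    correlation (mid-ranks for ties, asymptotic two-sided p). A constant
    input makes the correlation undefined; it is returned as NaN with a flag.
    """
    track_values = np.asarray(track_values, dtype=float)
    cons = np.asarray(cons, dtype=float)
    if track_values.shape != cons.shape:
        raise ValueError("sensitivity track and conservation must align")
    valid = ~np.isnan(track_values)
    if n0 >= valid.sum():
        raise ValueError("n0 must be smaller than the number of scored bases")
    vals = np.where(valid, track_values, -np.inf)
    top = np.argsort(vals)[::-1][:n0]
    flag = np.zeros(len(track_values), dtype=bool)
    flag[top] = True
    background = valid & ~flag
    t, c = track_values[valid], cons[valid]
    undefined = np.ptp(t) == 0 or np.ptp(c) == 0
    if undefined:
        rho_s, p = float("nan"), float("nan")
    else:
        res = stats.spearmanr(t, c)
        rho_s, p = float(res.statistic), float(res.pvalue)
    return {
        "mean_cons_sensitive": float(cons[flag].mean()),
        "mean_cons_background": float(cons[background].mean()),
        "spearman_rho": rho_s,
        "p": p,
        "undefined": bool(undefined),
        "sensitive_flag": flag,
    }
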