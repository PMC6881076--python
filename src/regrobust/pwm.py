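"""Position weight matrices in bits, with count-matrix conversion and TSV IO."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: default gap below the best possible score that still counts as a site
DEFAULT_THRESHOLD_GAP_BITS = 6.0


@dataclass
class PWM:
    """Log-odds scoring matrix for one transcription factor.

    ``logodds`` is width x 4 (columns A, C, G, T) in bits. ``max_score`` is
    the score of the consensus (sum of per-position maxima); a window is a
    modeled site when its score is at least ``threshold``.
    """

    tf_name: str
    logodds: np.ndarray
    threshold: float | None = None
    max_score: float = field(init=False)

    def __post_init__(self) -> None:
        self.logodds = np.asarray(self.logodds, dtype=float)
        if self.logodds.ndim != 2 or self.logodds.shape[1] != 4:
            raise ValueError(f"{self.tf_name}: logodds must be width x 4")
        self.max_score = float(self.logodds.max(axis=1).sum())
        if self.threshold is None:
            self.threshold = self.max_score - DEFAULT_THRESHOLD_GAP_BITS
        if self.threshold > self.max_score:
            raise ValueError(f"{self.tf_name}: threshold exceeds max score")

    @property
    def width(self) -> int:
        return self.logodds.shape[0]

    @property
    def consensus_codes(self) -> np.ndarray:
        return self.logodds.argmax(axis=1)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[c] for c in self.consensus_codes)

    @property
    def rc_logodds(self) -> np.ndarray:
        """Matrix scoring the reverse strand: reversed positions, complemented bases."""
        return self.logodds[::-1, ::-1]

    def score(self, codes: np.ndarray) -> float:
        """Score one window of integer codes on the forward strand."""
        codes = np.asarray(codes)
        if len(codes) != self.width:
            raise ValueError("window length != PWM width")
        return float(self.logodds[np.arange(self.width), codes].sum())


def pwm_from_counts(tf_name: str, counts: np.ndarray, pseudocount: float = 0.5,
                    threshold: float | None = None) -> PWM:
    """Convert a count matrix to bits against a uniform background."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    return PWM(tf_name, np.log2(probs / 0.25), threshold=threshold)


def information_content(pwm: PWM) -> float:
    """Mean per-column information in bits, from the implied probabilities."""
    probs = 0.25 * 2.0 ** pwm.logodds
    probs = probs / probs.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log2(probs / 0.25), 0.0)
    return float(terms.sum(axis=1).mean())


def read_pwm_tsv(path: str | Path, tf_name: str | None = None,
                 threshold: float | None = None) -> PWM:
    """Read a PWM from TSV with columns A, C, G, T.

    Values that are all non-negative are treated as counts (converted with
    pseudocount 0.5 and uniform background); otherwise as log-odds in bits.
    """
    path = Path(path)
    rows = []
    header = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None and any(f.upper() in "ACGT" and len(f) == 1 for f in fields):
                header = [f.upper() for f in fields]
                continue
            rows.append([float(x) for x in fields])
    mat = np.array(rows, dtype=float)
    if mat.shape[1] != 4:
        raise ValueError(f"{path}: expected 4 columns, got {mat.shape[1]}")
    if header is not None:
        order = [header.index(b) for b in "ACGT"]
        mat = mat[:, order]
    name = tf_name or path.stem
    if (mat >= 0).all() and mat.max() > 2.0:
        return pwm_from_counts(name, mat, threshold=threshold)
    return PWM(name, mat, threshold=threshold)


def write_pwm_tsv(pwm: PWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("A\tC\tG\tT\n")
        for row in pwm.logodds:
            fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")
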