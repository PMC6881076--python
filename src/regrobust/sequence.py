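"""Enhancer sequences with chromatin-accessibility masks.

The substrate of every sequence perturbation in the pipeline: a DNA string,
a per-base boolean mask marking open chromatin (TF binding inside closed
chromatin is excluded from the model), and a signed offset of the element's
first base relative to the transcription start site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(ALPHABET)}
COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class EnhancerSequence:
    """A DNA element plus its open-chromatin mask.

    Parameters
    ----------
    name : str
        Element identifier.
    seq : str
        Sequence over {A, C, G, T}. Ambiguity codes are rejected.
    accessible : np.ndarray of bool
        Per-base open-chromatin flag, same length as ``seq``.
    offset_bp : int
        Signed offset of base 0 relative to the TSS.
    """

    name: str
    seq: str
    accessible: np.ndarray = field(default=None)  # type: ignore[assignment]
    offset_bp: int = 0

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"{self.name}: sequence contains non-ACGT characters {sorted(bad)}"
            )
        if self.accessible is None:
            self.accessible = np.ones(len(self.seq), dtype=bool)
        self.accessible = np.asarray(self.accessible, dtype=bool)
        if len(self.accessible) != len(self.seq):
            raise ValueError(
                f"{self.name}: mask length {len(self.accessible)} != "
                f"sequence length {len(self.seq)}"
            )
        if len(self.seq) and not self.accessible.any():
            raise ValueError(f"{self.name}: no accessible bases")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def codes(self) -> np.ndarray:
        """Sequence as integer codes A=0, C=1, G=2, T=3."""
        return np.fromiter((_CODE[b] for b in self.seq), dtype=np.int8, count=len(self.seq))

    @property
    def n_accessible(self) -> int:
        return int(self.accessible.sum())

    @property
    def accessible_indices(self) -> np.ndarray:
        return np.flatnonzero(self.accessible)

    def with_mutations(self, positions, new_bases) -> "EnhancerSequence":
        """Return a copy with the given substitutions applied."""
        s = list(self.seq)
        for p, b in zip(positions, new_bases):
            s[p] = b
        return EnhancerSequence(self.name, "".join(s), self.accessible.copy(), self.offset_bp)


def read_fasta(path: str | Path) -> list[EnhancerSequence]:
    """Load enhancers from FASTA; every base starts accessible."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(EnhancerSequence(rec.id, str(rec.seq)))
    if not out:
        raise ValueError(f"no sequences in {path}")
    return out


def write_fasta(enhancers, path: str | Path) -> None:
    recs = [SeqRecord(Seq(e.seq), id=e.name, description="") for e in enhancers]
    SeqIO.write(recs, str(path), "fasta")


def apply_bed_mask(enh: EnhancerSequence, path: str | Path) -> EnhancerSequence:
    """Restrict accessibility to the union of BED intervals (0-based, half-open).

    Intervals are interpreted in element coordinates when the BED name column
    matches the element, using columns chromStart/chromEnd.
    """
    mask = np.zeros(len(enh), dtype=bool)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if chrom != enh.name:
                continue
            start = max(start, 0)
            end = min(end, len(enh))
            if end > start:
                mask[start:end] = True
    if not mask.any():
        raise ValueError(f"BED mask leaves no accessible base on {enh.name}")
    return EnhancerSequence(enh.name, enh.seq, mask, enh.offset_bp)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]
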