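"""Seeded generators for every input the pipeline consumes.

Emulates: smooth gap-gene-like TF gradients on the 35.5-92.5% embryo-length
grid, PWMs of requested information content, enhancers with planted
consensus binding sites, toy systems with known robustness structure
(r-robust and geometric-mean), MPRA barcode tables with a planted
saturation-variance law, and multiple alignments with a planted
per-base conservation profile. Every generator is a pure function of its
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import hypergeom

from .conservation import AlignedSet
from .model import (
    EnhancerSequence,
    RateParams,
    TFModel,
    TFProfileSet,
    default_position_grid,
)
from .mpra import MPRABarcodeTable
from .pwm import PWM
from .sequence import ALPHABET, revcomp

# ---------------------------------------------------------------------------
# TF gradients


@dataclass
class Bump:
    """Gaussian bump component of a gradient: amp * exp(-(x-center)^2/2w^2)."""

    center: float
    width: float
    amplitude: float


@dataclass
class Front:
    """Logistic front: amp / (1 + exp(-sign*(x-center)/width))."""

    center: float
    width: float
    amplitude: float
    sign: float = 1.0  # +1 rises toward the posterior, -1 toward the anterior


def gen_tf_gradients(tf_specs: dict[str, list], grid=None,
                     seed: int = 0) -> TFProfileSet:
    """Smooth non-negative concentration profiles from bump/front components.

    tf_specs maps TF name to a list of Bump/Front components; an empty list
    gives an all-zero profile. Deterministic given (specs, seed); the seed is
    reserved for optional noise extensions and does not currently perturb the
    smooth profiles.
    """
    if grid is None:
        grid = default_position_grid()
    grid = np.asarray(grid, dtype=float)
    names = list(tf_specs)
    conc = np.zeros((len(grid), len(names)))
    for j, name in enumerate(names):
        for comp in tf_specs[name]:
            if comp.amplitude < 0:
                raise ValueError(f"{name}: negative amplitude")
            if isinstance(comp, Bump):
                conc[:, j] += comp.amplitude * np.exp(
                    -0.5 * ((grid - comp.center) / comp.width) ** 2)
            elif isinstance(comp, Front):
                conc[:, j] += comp.amplitude * expit(
                    comp.sign * (grid - comp.center) / comp.width)
            else:
                raise TypeError(f"unknown gradient component {comp!r}")
    return TFProfileSet(grid, conc, names)


# ---------------------------------------------------------------------------
# PWMs and enhancers


def _column_info(p: np.ndarray) -> float:
    q = np.maximum(p, 1e-12)
    return float((q * np.log2(q / 0.25)).sum())


def gen_pwm(tf_name: str, width: int, info_bits: float, seed: int = 0,
            threshold: float | None = None) -> PWM:
    """A PWM whose mean per-column information content hits info_bits.

    Each column interpolates between a random Dirichlet draw and a point mass
    on a random consensus base, with the mixing weight solved per column so
    the information content equals info_bits exactly (within bisection
    tolerance; info_bits = 2 gives consensus-only columns up to a numerical
    probability floor). The Dirichlet component makes the non-consensus
    probabilities heterogeneous, so the three alternates of a base score
    differently, as in measured motifs.
    """
    if not 0 < info_bits <= 2:
        raise ValueError("info_bits must lie in (0, 2]")
    rng = np.random.default_rng(seed)
    probs = np.empty((width, 4))
    for k in range(width):
        base = rng.dirichlet(np.ones(4))
        c = int(rng.integers(0, 4))
        point = np.zeros(4)
        point[c] = 1.0

        def info_at(lam):
            return _column_info((1 - lam) * base + lam * point)

        if info_at(0.0) >= info_bits:
            # overly informative draw: shrink toward uniform instead
            uniform = np.full(4, 0.25)

            def info_shrunk(mu):
                return _column_info((1 - mu) * uniform + mu * base)

            lo, hi = 0.0, 1.0
            for _ in range(100):
                mid = 0.5 * (lo + hi)
                if info_shrunk(mid) < info_bits:
                    lo = mid
                else:
                    hi = mid
            mu = 0.5 * (lo + hi)
            probs[k] = (1 - mu) * uniform + mu * base
        else:
            lo, hi = 0.0, 1.0
            for _ in range(100):
                mid = 0.5 * (lo + hi)
                if info_at(mid) < info_bits:
                    lo = mid
                else:
                    hi = mid
            lam = 0.5 * (lo + hi)
            probs[k] = (1 - lam) * base + lam * point
    probs = np.maximum(probs, 1e-9)
    return PWM(tf_name, np.log2(probs / 0.25), threshold=threshold)


def gen_enhancer(name: str, length: int, planted_sites=None, seed: int = 0,
                 closed_intervals=None) -> EnhancerSequence:
    """Random background sequence with consensus sites planted at fixed spots.

    planted_sites: list of (pwm, start, strand); sites must fit and must not
    overlap one another. closed_intervals: list of (start, end) half-open
    intervals masked as closed chromatin.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(ALPHABET), size=length))
    occupied = np.zeros(length, dtype=bool)
    for pwm, start, strand in planted_sites or []:
        end = start + pwm.width
        if start < 0 or end > length:
            raise ValueError(f"planted site {pwm.tf_name}@{start} exceeds length")
        if occupied[start:end].any():
            raise ValueError(f"planted site {pwm.tf_name}@{start} overlaps another")
        occupied[start:end] = True
        motif = pwm.consensus if strand == "+" else revcomp(pwm.consensus)
        seq[start:end] = list(motif)
    mask = np.ones(length, dtype=bool)
    for s, e in closed_intervals or []:
        mask[s:e] = False
    return EnhancerSequence(name, "".join(seq), mask)


# ---------------------------------------------------------------------------
# toy systems with known robustness structure


@dataclass
class ToyRRobustSystem:
    """n parameters of which the first n0 are sensitive, non-cumulatively.

    Output rule: log M = w * log s_i* where i* is the lowest-index perturbed
    sensitive parameter, else log M = 0. Because the log-scales are symmetric
    about zero, Var(log M) over random r-subsets equals the probability of
    hitting at least one sensitive parameter times V0 = w^2 * A^2 / 3.
    """

    n: int
    n0: int
    w: float = 1.0
    sensitive: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.n0 <= self.n:
            raise ValueError("n0 must lie in [0, n]")
        self.sensitive = np.arange(self.n0)

    def V0(self, A: float) -> float:
        return self.w**2 * A**2 / 3.0


def hit_probability_without_replacement(n: int, n0: int, r: int) -> float:
    """P(>= 1 sensitive parameter in an r-subset drawn without replacement)."""
    return float(1.0 - hypergeom.pmf(0, n, n0, r))


def expected_toy_variance(n: int, n0: int, r: int, V0: float) -> float:
    """Exact Var(log M) of the toy system under without-replacement draws."""
    return hit_probability_without_replacement(n, n0, r) * V0


def sample_toy_system(sys: ToyRRobustSystem, r: int, A: float, n_reps: int,
                      seed: int = 0) -> float:
    """Empirical Var(log M) at one r; scales s_i = exp(A X_i), X ~ U(-1, 1).

    Each replicate perturbs a uniform r-subset drawn without replacement.
    Because log M depends only on whether a sensitive parameter was hit (and
    then equals the i.i.d. log-scale of one hit), the replicate is sampled
    from the exact output law: a hypergeometric hit count and one uniform
    log-scale. sample_toy_system_explicit keeps the literal subset draw for
    cross-checking.
    """
    if r > sys.n:
        raise ValueError("r exceeds n")
    if r == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    hits = rng.hypergeometric(sys.n0, sys.n - sys.n0, r, size=n_reps)
    x = rng.uniform(-1.0, 1.0, size=n_reps)
    log_m = np.where(hits > 0, sys.w * A * x, 0.0)
    return float(np.var(log_m, ddof=1))


def sample_toy_system_explicit(sys: ToyRRobustSystem, r: int, A: float,
                               n_reps: int, seed: int = 0) -> float:
    """Literal implementation of the toy output rule, replicate by replicate.

    Draws the r-subset and all r scales explicitly and reads off the scale of
    the lowest-index perturbed sensitive parameter; the independent route
    used to validate sample_toy_system's distributional shortcut.
    """
    if r > sys.n:
        raise ValueError("r exceeds n")
    if r == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    log_m = np.zeros(n_reps)
    for i in range(n_reps):
        chosen = np.sort(rng.choice(sys.n, size=r, replace=False))
        x = rng.uniform(-1.0, 1.0, size=r)
        hit = np.flatnonzero(chosen < sys.n0)
        if len(hit):
            log_m[i] = sys.w * A * x[hit[0]]
    return float(np.var(log_m, ddof=1))


def toy_curve(sys: ToyRRobustSystem, r_grid, A: float, n_reps: int, seed: int = 0):
    """RobustnessCurve of the toy system over an r grid (fresh draws per r)."""
    from .robustats import RobustnessCurve

    r_grid = np.asarray(r_grid, dtype=int)
    var = np.array([
        sample_toy_system(sys, int(r), A, n_reps,
                          seed=int(np.random.SeedSequence([seed, k]).generate_state(1)[0]) % (2**31))
        for k, r in enumerate(r_grid)
    ])
    return RobustnessCurve(r=r_grid, var_log_m=var, n=sys.n, n_reps=n_reps)


@dataclass
class GeometricMeanSystem:
    """M = (K1 K2 ... Kn)^(1/n): the canonical distributed-robust function."""

    n: int


def sample_geometric_system(sys: GeometricMeanSystem, r: int, V_K: float,
                            n_reps: int, seed: int = 0) -> float:
    """Empirical Var(log M) with r parameters perturbed at log-variance V_K.

    log M = (1/n) * sum of the r perturbed log-scales; the expectation is
    V_K * r / n^2 (V_K / n at full perturbation).
    """
    if r > sys.n:
        raise ValueError("r exceeds n")
    if r == 0:
        return 0.0
    A = float(np.sqrt(3.0 * V_K))
    rng = np.random.default_rng(seed)
    x = rng.uniform(-1.0, 1.0, size=(n_reps, r))
    log_m = A * x.sum(axis=1) / sys.n
    return float(np.var(log_m, ddof=1))


# ---------------------------------------------------------------------------
# MPRA barcode tables


def gen_mpra_table(n: int, n0: float, V0: float, c0: float, c1: float,
                   n_barcodes: int, r_range=(1, 20), seed: int = 0,
                   depth_dna: float = 50.0, depth_rna: float = 50.0,
                   n_replicates: int = 3, element: str = "synthetic") -> MPRABarcodeTable:
    """Barcode table with a planted saturation-variance structure.

    Each barcode carries r mutations (uniform over r_range inclusive) and a
    latent log-expression drawn with variance
    V0 * (1 - (1 - n0/n)^r) + c0 + c1*r, shared across replicates; UMI counts
    are Poisson at the stated depths, RNA depth modulated by expression.
    """
    import pandas as pd

    if min(n0, V0, c0, c1) < 0 or n <= 0:
        raise ValueError("parameters must be non-negative, n positive")
    rng = np.random.default_rng(seed)
    r = rng.integers(r_range[0], r_range[1] + 1, size=n_barcodes)
    var = V0 * (1.0 - (1.0 - n0 / n) ** r) + c0 + c1 * r
    log_e = rng.normal(0.0, np.sqrt(var))
    rows = {"barcode": [f"BC{i:07d}" for i in range(n_barcodes)], "n_mut": r}
    for rep in range(1, n_replicates + 1):
        rows[f"dna_umi_rep{rep}"] = rng.poisson(depth_dna, size=n_barcodes)
        rows[f"rna_umi_rep{rep}"] = rng.poisson(depth_rna * np.exp(log_e))
    return MPRABarcodeTable(pd.DataFrame(rows), element=element, n=n)


# ---------------------------------------------------------------------------
# alignments


def gen_alignment(ref: str, n_species: int, cons_profile, seed: int = 0,
                  ref_name: str = "melanogaster") -> AlignedSet:
    """Alignment whose columns match the reference with planted probability.

    cons_profile gives, per reference base, the probability that each
    non-reference species carries the same nucleotide; mismatches are uniform
    over the three alternates.
    """
    cons = np.broadcast_to(np.asarray(cons_profile, dtype=float), (len(ref),))
    if (cons < 0).any() or (cons > 1).any():
        raise ValueError("cons_profile must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    seqs = {ref_name: ref}
    alt = {b: [c for c in ALPHABET if c != b] for b in ALPHABET}
    for k in range(n_species):
        match = rng.random(len(ref)) < cons
        bases = [ref[i] if match[i] else alt[ref[i]][rng.integers(3)]
                 for i in range(len(ref))]
        seqs[f"sp{k + 1}"] = "".join(bases)
    return AlignedSet(seqs, ref_name)


# ---------------------------------------------------------------------------
# the default stripe configuration

from ._stripe import stripe_fixture  # noqa: E402,F401  (re-export)
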