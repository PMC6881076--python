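"""Monte-Carlo perturbation of TF levels and enhancer sequence.

Two perturbation channels: (i) multiplying one TF's concentration everywhere
by a random fold ratio s_T = exp(A X), X ~ Uniform(-1, 1), so that
Var(log s_T) = A^2/3; and (ii) substituting r nucleotides drawn uniformly
without replacement from open chromatin, each replaced by one of the three
alternate bases with equal probability. Deterministic single-base and
pairwise sensitivity scans complement the Monte-Carlo routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np

from .model import (
    BindingSite,
    EnhancerSequence,
    RateParams,
    TFModel,
    TFProfileSet,
    apply_coactivation,
    apply_quenching,
    occupancy,
    raw_rate_profile,
    scan_sites,
    transcription_rate,
)
from .robustats import RobustnessCurve

#: floor applied to model output before taking logs, as a fraction of the
#: wild-type profile maximum
FLOOR_FRACTION = 1e-6

_ALT = {0: (1, 2, 3), 1: (0, 2, 3), 2: (0, 1, 3), 3: (0, 1, 2)}
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# TF concentration perturbation


@dataclass
class TFPerturbationSpec:
    """One TF, a magnitude A, and a replicate count with its seed."""

    tf_name: str
    A: float
    n_reps: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("A must be >= 0")


@dataclass
class TFPerturbationDraws:
    """Lazy bundle of perturbed profile sets sharing one latent draw each."""

    profiles: TFProfileSet
    spec: TFPerturbationSpec
    s_T: np.ndarray
    log_s: np.ndarray

    def profile(self, i: int) -> TFProfileSet:
        return self.profiles.scaled(self.spec.tf_name, float(self.s_T[i]))


def draw_scales(A: float, n_reps: int, rng: np.random.Generator) -> np.ndarray:
    """Fold ratios s = exp(A X) with X ~ Uniform(-1, 1)."""
    return np.exp(A * rng.uniform(-1.0, 1.0, size=n_reps))


def perturb_tf(profiles: TFProfileSet, spec: TFPerturbationSpec) -> TFPerturbationDraws:
    """Draw n_reps fold ratios for one TF; the same factor at every position."""
    profiles.index_of(spec.tf_name)  # raises on unknown TF
    rng = np.random.default_rng(spec.seed)
    if spec.A == 0.0:
        s = np.ones(spec.n_reps)
    else:
        s = draw_scales(spec.A, spec.n_reps, rng)
    return TFPerturbationDraws(profiles, spec, s, np.log(s))


# ---------------------------------------------------------------------------
# sequence mutation


@dataclass
class MutationSet:
    """r distinct accessible positions and their substituted bases."""

    positions: np.ndarray
    new_bases: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)

    @property
    def r(self) -> int:
        return len(self.positions)

    @property
    def new_codes(self) -> np.ndarray:
        return np.fromiter((_BASES.index(b) for b in self.new_bases), dtype=np.int8,
                           count=len(self.new_bases))


def draw_mutations(enh: EnhancerSequence, r: int, rng: np.random.Generator) -> MutationSet:
    """Sample r accessible positions without replacement; uniform alternate base."""
    acc = enh.accessible_indices
    if not 1 <= r <= len(acc):
        raise ValueError(f"r = {r} outside [1, {len(acc)}] accessible bases")
    positions = rng.choice(acc, size=r, replace=False)
    codes = enh.codes
    picks = rng.integers(0, 3, size=r)
    new = [_BASES[_ALT[int(codes[p])][k]] for p, k in zip(positions, picks)]
    return MutationSet(positions, new)


# ---------------------------------------------------------------------------
# fast mutant evaluation: incremental PWM rescoring


class ModelEvaluator:
    """Evaluates the model at fixed embryo positions for many sequence mutants.

    Wild-type window scores are computed once per TF and strand; a mutant
    only rescoring the windows that overlap its substituted bases. Assumes
    no cooperativity rules (the perturbation fixtures are cooperativity-free;
    occupancy falls back transparently if rules are present).
    """

    def __init__(self, enh: EnhancerSequence, tfs: dict[str, TFModel],
                 profiles: TFProfileSet, rate_params: RateParams):
        self.enh = enh
        self.tfs = tfs
        self.profiles = profiles
        self.rate_params = rate_params
        self.codes = enh.codes
        n = len(enh)
        acc = np.concatenate([[0], np.cumsum(enh.accessible)])
        self._tf_names = list(tfs)
        self._mats = {}
        self._wt_scores = {}
        self._open = {}
        for name, tf in tfs.items():
            w = tf.pwm.width
            if w > n:
                continue
            self._open[name] = (acc[w:] - acc[:-w]) == w
            for strand, mat in (("+", tf.pwm.logodds), ("-", tf.pwm.rc_logodds)):
                self._mats[(name, strand)] = mat
                self._wt_scores[(name, strand)] = self._score_all(self.codes, mat)
        self._conc_cache: dict[float, dict[str, float]] = {}
        wt = raw_rate_profile(enh, tfs, profiles, rate_params)
        self.wt_raw = wt
        self.floor = FLOOR_FRACTION * float(wt.max())

    @staticmethod
    def _score_all(codes: np.ndarray, mat: np.ndarray) -> np.ndarray:
        w = mat.shape[0]
        n = len(codes) - w + 1
        if n <= 0:
            return np.empty(0)
        out = np.zeros(n)
        for k in range(w):
            out += mat[k, codes[k:k + n]]
        return out

    def conc_at(self, position: float) -> dict[str, float]:
        if position not in self._conc_cache:
            self._conc_cache[position] = self.profiles.at(position)
        return self._conc_cache[position]

    def _mutant_scores(self, mut: MutationSet | None):
        if mut is None or mut.r == 0:
            return self.codes, self._wt_scores
        codes = self.codes.copy()
        codes[mut.positions] = mut.new_codes
        scores = {}
        for name, tf in self.tfs.items():
            w = tf.pwm.width
            nwin = len(codes) - w + 1
            if nwin <= 0:
                continue
            idx = set()
            for p in mut.positions:
                lo = max(int(p) - w + 1, 0)
                hi = min(int(p), nwin - 1)
                idx.update(range(lo, hi + 1))
            idx = np.fromiter(idx, dtype=int) if idx else np.empty(0, dtype=int)
            for strand in "+-":
                mat = self._mats[(name, strand)]
                sc = self._wt_scores[(name, strand)].copy()
                if len(idx):
                    win = codes[idx[None, :] + np.arange(w)[:, None]]
                    sc[idx] = (mat[np.arange(w)[:, None], win]).sum(axis=0)
                scores[(name, strand)] = sc
        return codes, scores

    def sites_for(self, mut: MutationSet | None = None) -> list[BindingSite]:
        _, scores = self._mutant_scores(mut)
        sites: list[BindingSite] = []
        for name, tf in self.tfs.items():
            if (name, "+") not in scores:
                continue
            w = tf.pwm.width
            open_win = self._open[name]
            thr = tf.pwm.threshold
            for strand in "+-":
                sc = scores[(name, strand)]
                for s in np.flatnonzero((sc >= thr) & open_win):
                    sites.append(BindingSite(name, int(s), int(s) + w, strand,
                                             float(sc[s])))
        sites.sort(key=lambda s: (s.start, s.strand, s.tf_name))
        return sites

    def rate(self, position: float, mut: MutationSet | None = None,
             conc: dict[str, float] | None = None,
             sites: list[BindingSite] | None = None) -> float:
        """Raw synthesis rate at one embryo position for a mutant sequence."""
        if sites is None:
            sites = self.sites_for(mut)
        if conc is None:
            conc = self.conc_at(position)
        if not sites:
            return transcription_rate(0.0, self.rate_params)
        st = occupancy(sites, self.tfs, conc)
        st = apply_coactivation(apply_quenching(st, self.tfs), self.tfs)
        return transcription_rate(float(st.contributions.sum()), self.rate_params)

    def log_rate(self, position: float, mut: MutationSet | None = None,
                 sites: list[BindingSite] | None = None) -> float:
        return float(np.log(max(self.rate(position, mut, sites=sites), self.floor)))


# ---------------------------------------------------------------------------
# Monte-Carlo variance versus number of mutated nucleotides


def default_r_grid(n_accessible: int, n_points: int = 30,
                   max_frac: float = 0.10) -> np.ndarray:
    """Approximately geometric grid of integers from 1 to 10% of n, deduplicated."""
    rmax = max(int(np.floor(max_frac * n_accessible)), 1)
    grid = np.unique(np.round(np.geomspace(1, rmax, n_points)).astype(int))
    return grid


def variance_vs_r(enh: EnhancerSequence, tfs: dict[str, TFModel],
                  profiles: TFProfileSet, rate_params: RateParams,
                  r_grid, n_reps: int, position: float, seed: int = 0,
                  evaluator: ModelEvaluator | None = None) -> RobustnessCurve:
    """Var over replicates of log output at one position, per mutation count r.

    Fresh mutant sequences each replicate; n is the accessible-base count.
    """
    ev = evaluator or ModelEvaluator(enh, tfs, profiles, rate_params)
    r_grid = np.asarray(r_grid, dtype=int)
    n_acc = enh.n_accessible
    if (r_grid < 1).any() or (r_grid > n_acc).any():
        raise ValueError("r_grid must lie within [1, accessible count]")
    rng = np.random.default_rng(seed)
    variances = np.empty(len(r_grid))
    for k, r in enumerate(r_grid):
        logs = np.empty(n_reps)
        for i in range(n_reps):
            logs[i] = ev.log_rate(position, draw_mutations(enh, int(r), rng))
        variances[k] = float(np.var(logs, ddof=1))
    return RobustnessCurve(r=r_grid, var_log_m=variances, n=n_acc, n_reps=n_reps)


# ---------------------------------------------------------------------------
# robustness ratio to TF fluctuations


def tf_rho_scan(enh: EnhancerSequence, tfs: dict[str, TFModel],
                profiles: TFProfileSet, rate_params: RateParams,
                A: float, n_reps: int, seed: int = 0,
                tf_names: list[str] | None = None,
                positions=None):
    """rho = Var(log fold-change output) / Var(log fold-change TF), per TF and position.

    The fold-change reference is the unperturbed output at the same position;
    logs are floored. Returns a dict mapping TF name to (positions, rho,
    at_floor flag) arrays.
    """
    if A <= 0:
        raise ValueError("A must be > 0")
    ev = ModelEvaluator(enh, tfs, profiles, rate_params)
    sites = ev.sites_for(None)
    if positions is None:
        positions = profiles.positions
    positions = np.asarray(positions, dtype=float)
    pos_idx = [int(np.argmin(np.abs(profiles.positions - p))) for p in positions]
    tf_names = tf_names or list(tfs)
    out = {}
    for t, name in enumerate(tf_names):
        j = profiles.index_of(name)
        rng = np.random.default_rng(np.random.SeedSequence([seed, t]))
        s = draw_scales(A, n_reps, rng)
        var_log_s = float(np.var(np.log(s), ddof=1))
        log_m = np.empty((n_reps, len(positions)))
        for i in range(n_reps):
            for k, pi in enumerate(pos_idx):
                conc = dict(zip(profiles.tf_names, profiles.conc[pi]))
                conc[name] = conc[name] * s[i]
                log_m[i, k] = np.log(max(ev.rate(positions[k], conc=conc,
                                                 sites=sites), ev.floor))
        wt = np.array([np.log(max(ev.wt_raw[pi], ev.floor)) for pi in pos_idx])
        var_log_m = np.var(log_m - wt, axis=0, ddof=1)
        rho = var_log_m / var_log_s
        at_floor = np.array([ev.wt_raw[pi] <= ev.floor for pi in pos_idx])
        out[name] = {"positions": positions, "rho": rho, "var_log_m": var_log_m,
                     "var_log_s": var_log_s, "at_floor": at_floor}
    return out


def rho_of_map(map_fn, A: float, n_reps: int, seed: int = 0,
               reference: float = 1.0) -> float:
    """rho for a scalar input-output map under multiplicative perturbation.

    Perturbs the input K by s = exp(A X) and returns
    Var(log(f(K s)/f(K))) / Var(log s); 1 for the identity map, 4 for a
    quadratic, 0 for a constant. The calibration route for the robustness
    ratio.
    """
    if A <= 0:
        raise ValueError("A must be > 0")
    rng = np.random.default_rng(seed)
    s = draw_scales(A, n_reps, rng)
    ref = map_fn(reference)
    out = np.array([map_fn(reference * si) for si in s], dtype=float)
    log_fold = np.log(out / ref)
    return float(np.var(log_fold, ddof=1) / np.var(np.log(s), ddof=1))


# ---------------------------------------------------------------------------
# deterministic sensitivity scans


@dataclass
class SensitivityTrack:
    """Per-base log-variance of output under single-base substitution."""

    values: np.ndarray  # NaN at masked bases
    position: float
    sensitive_flag: np.ndarray | None = None

    def top_n(self, n0: int) -> np.ndarray:
        """Boolean flag over bases marking the n0 most sensitive."""
        vals = np.where(np.isnan(self.values), -np.inf, self.values)
        order = np.argsort(vals)[::-1][:n0]
        flag = np.zeros(len(self.values), dtype=bool)
        flag[order] = True
        return flag


def sensitive_count(track: "SensitivityTrack") -> int:
    """Number of sensitive nucleotides implied by a single-base scan.

    Separates sensitive from insensitive bases at the largest gap in the
    sorted distribution of per-base log-variances, the conventional choice
    when sensitivities are strongly heterogeneous. Returns 0 for an all-zero
    track.
    """
    v = track.values[np.isfinite(track.values)]
    v = np.sort(v[v > 0])[::-1]
    if len(v) == 0:
        return 0
    if len(v) == 1:
        return 1
    gaps = v[:-1] - v[1:]
    return int(np.argmax(gaps)) + 1


def snp_scan(enh: EnhancerSequence, tfs: dict[str, TFModel],
             profiles: TFProfileSet, rate_params: RateParams,
             position: float,
             evaluator: ModelEvaluator | None = None) -> SensitivityTrack:
    """Exhaustive single-nucleotide scan: per accessible base, the population
    variance over the three substitution outcomes of log output."""
    ev = evaluator or ModelEvaluator(enh, tfs, profiles, rate_params)
    codes = enh.codes
    values = np.full(len(enh), np.nan)
    for p in enh.accessible_indices:
        logs = [ev.log_rate(position, MutationSet([p], [_BASES[a]]))
                for a in _ALT[int(codes[p])]]
        values[p] = float(np.var(logs))
    return SensitivityTrack(values, position)


def pairwise_scan(enh: EnhancerSequence, tfs: dict[str, TFModel],
                  profiles: TFProfileSet, rate_params: RateParams,
                  position: float, max_pairs: int | None = None,
                  seed: int = 0,
                  evaluator: ModelEvaluator | None = None) -> SensitivityTrack:
    """Per-base log-variance when bases are perturbed two at a time.

    Every pair contributes all nine substitution combinations; a base's value
    is the variance over every mutant that touches it. When the pair count
    exceeds max_pairs, pairs are sampled uniformly without replacement.
    """
    ev = evaluator or ModelEvaluator(enh, tfs, profiles, rate_params)
    acc = enh.accessible_indices
    pairs = list(combinations(acc.tolist(), 2))
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(keep)]
    codes = enh.codes
    logs_by_base: dict[int, list[float]] = {int(p): [] for p in acc}
    for p, q in pairs:
        for a, b in product(_ALT[int(codes[p])], _ALT[int(codes[q])]):
            lm = ev.log_rate(position, MutationSet([p, q], [_BASES[a], _BASES[b]]))
            logs_by_base[p].append(lm)
            logs_by_base[q].append(lm)
    values = np.full(len(enh), np.nan)
    for p, logs in logs_by_base.items():
        values[p] = float(np.var(logs)) if logs else 0.0
    return SensitivityTrack(values, position)


def pwm_delta_scan(enh: EnhancerSequence, pwms) -> dict[str, np.ndarray]:
    """Mean change in PWM score per base and TF under single-base substitution.

    For each base and TF: the mean over the three substitutions of the summed
    score change across that TF's modeled sites overlapping the base, scored
    in place (no re-thresholding).
    """
    pwms = list(pwms)
    sites = scan_sites(enh, pwms)
    by_tf = {p.tf_name: p for p in pwms}
    codes = enh.codes
    out = {p.tf_name: np.zeros(len(enh)) for p in pwms}
    for s in sites:
        pwm = by_tf[s.tf_name]
        mat = pwm.logodds if s.strand == "+" else pwm.rc_logodds
        for i in range(s.start, s.end):
            k = i - s.start
            old = int(codes[i])
            delta = np.mean([mat[k, a] - mat[k, old] for a in _ALT[old]])
            out[s.tf_name][i] += delta
    return out


# ---------------------------------------------------------------------------
# printed protocol bookkeeping


def tf_perturbation_protocol_size(a_start: float = 0.0, a_stop: float = 3.0,
                                  a_step: float = 0.1, n_reps: int = 10_000) -> int:
    """Total simulations in the TF-perturbation protocol: one batch of n_reps
    per magnitude A on the grid (0 to 3 in steps of 0.1 -> 310,000)."""
    n_a = int(round((a_stop - a_start) / a_step)) + 1
    return n_a * n_reps
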