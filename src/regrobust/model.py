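"""Thermodynamic sequence-level model of enhancer-driven transcription.

The model maps an enhancer sequence plus transcription-factor concentrations
to a relative mRNA synthesis rate at each position along the embryo's
anterior-posterior axis. Binding of TFs to open chromatin is treated by
equilibrium thermodynamics over all configurations of mutually
non-overlapping bound sites, with optional pairwise cooperativity. Bound
repressors attenuate nearby bound activators (short-range quenching), or —
for factors carrying a coactivation rule — contribute activation when a
partner activator is bound within range. The resulting net activation N
drives a saturating transcription rate law.

Coordinates are 0-based, half-open; both strands are scanned; a site must
lie fully within accessible chromatin to be modeled.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .pwm import PWM
from .sequence import EnhancerSequence

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# domain types


@dataclass
class TFModel:
    """A transcription factor's binding and regulatory parameters.

    alpha is the activation strength per fully occupied site (0 for plain
    repressors); Keq_scale the association constant at consensus score;
    quench_eff/quench_range parametrize short-range repression (repressors
    only); coop_partners lists (tf_name, omega, range_bp) cooperativity
    rules applied once per co-bound non-overlapping pair within range;
    coactivated_by = (tf_name, range_bp) converts this repressor's bound
    sites into activation gated by partner occupancy.
    """

    pwm: PWM
    role: str = "activator"
    alpha: float = 1.0
    Keq_scale: float = 1.0
    quench_eff: float = 0.0
    quench_range: float = 100.0
    coop_partners: list[tuple[str, float, float]] = field(default_factory=list)
    coactivated_by: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if self.role not in ("activator", "repressor"):
            raise ValueError(f"{self.name}: role must be activator or repressor")
        if not 0.0 <= self.quench_eff <= 1.0:
            raise ValueError(f"{self.name}: quench_eff must lie in [0, 1]")
        if self.alpha < 0:
            raise ValueError(f"{self.name}: alpha must be >= 0")
        for _, omega, _ in self.coop_partners:
            if omega < 0:
                raise ValueError(f"{self.name}: cooperativity omega must be >= 0")

    @property
    def name(self) -> str:
        return self.pwm.tf_name


@dataclass
class RateParams:
    """Saturating rate law: rate = R_max * sigmoid(beta * (N - N0))."""

    R_max: float = 1.0
    N0: float = 1.0
    beta: float = 1.0


@dataclass
class TFProfileSet:
    """TF concentrations on a grid of embryo positions (% embryo length)."""

    positions: np.ndarray
    conc: np.ndarray  # positions x TFs
    tf_names: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if (np.diff(self.positions) <= 0).any():
            raise ValueError("positions must be strictly increasing")
        if self.conc.shape != (len(self.positions), len(self.tf_names)):
            raise ValueError("conc must be positions x TFs")
        if (self.conc < 0).any():
            raise ValueError("concentrations must be non-negative")

    def index_of(self, tf_name: str) -> int:
        try:
            return self.tf_names.index(tf_name)
        except ValueError:
            raise KeyError(f"unknown TF {tf_name!r}") from None

    def at(self, position: float) -> dict[str, float]:
        i = int(np.argmin(np.abs(self.positions - position)))
        if abs(self.positions[i] - position) > 1e-9:
            raise ValueError(f"position {position} not on the grid")
        return dict(zip(self.tf_names, self.conc[i]))

    def scaled(self, tf_name: str, factor: float) -> "TFProfileSet":
        j = self.index_of(tf_name)
        conc = self.conc.copy()
        conc[:, j] *= factor
        return TFProfileSet(self.positions, conc, list(self.tf_names))


def default_position_grid(start: float = 35.5, stop: float = 92.5,
                          step: float = 0.5) -> np.ndarray:
    """The modeled anterior-posterior region, in % embryo length."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass
class BindingSite:
    """One modeled binding site; weight_w is filled in per embryo position."""

    tf_name: str
    start: int
    end: int
    strand: str
    score: float
    weight_w: float = 0.0

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "BindingSite") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class OccupancyState:
    """Fractional occupancies and the derived activation bookkeeping."""

    sites: list[BindingSite]
    f: np.ndarray
    f_effective: np.ndarray | None = None
    contributions: np.ndarray | None = None  # activation per site
    N: float | None = None


@dataclass
class ExpressionProfile:
    """Relative mRNA synthesis rate per position, scaled to max 1."""

    positions: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.rate.shape != self.positions.shape:
            raise ValueError("rate and positions must align")
        if not np.isfinite(self.rate).all() or (self.rate < 0).any():
            raise ValueError("rates must be finite and non-negative")


# ---------------------------------------------------------------------------
# site scanning


def _window_scores(codes: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Scores of every window of len(logodds) against the matrix."""
    w = logodds.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    out = np.zeros(n)
    for k in range(w):
        out += logodds[k, codes[k:k + n]]
    return out


def scan_sites(enh: EnhancerSequence, pwms: list[PWM]) -> list[BindingSite]:
    """All windows on either strand scoring >= threshold, fully in open chromatin.

    Sites are sorted by start, then strand (+ before -), then TF name.
    The reverse-strand score is the forward score of the window's reverse
    complement.
    """
    codes = enh.codes
    # window fully accessible <=> cumulative accessible count covers the window
    acc = np.concatenate([[0], np.cumsum(enh.accessible)])
    sites: list[BindingSite] = []
    for pwm in pwms:
        w = pwm.width
        if w > len(enh):
            continue
        open_win = (acc[w:] - acc[:-w]) == w
        for strand, mat in (("+", pwm.logodds), ("-", pwm.rc_logodds)):
            scores = _window_scores(codes, mat)
            hits = np.flatnonzero((scores >= pwm.threshold) & open_win)
            for s in hits:
                sites.append(BindingSite(pwm.tf_name, int(s), int(s) + w,
                                         strand, float(scores[s])))
    sites.sort(key=lambda s: (s.start, s.strand, s.tf_name))
    return sites


def site_weights(sites: list[BindingSite], tfs: dict[str, TFModel],
                 conc: dict[str, float]) -> np.ndarray:
    """Statistical weights w = Keq_scale * 2^(score - max_score) * [TF]."""
    w = np.empty(len(sites))
    for i, s in enumerate(sites):
        tf = tfs[s.tf_name]
        w[i] = tf.Keq_scale * 2.0 ** (s.score - tf.pwm.max_score) * conc.get(s.tf_name, 0.0)
    return w


# ---------------------------------------------------------------------------
# occupancy: partition function over non-overlapping configurations


def _coop_lookup(sites, tfs):
    """Symmetric omega(i, j) for co-bound pairs within range; None if no rule."""
    pairs = {}
    by_name = {}
    for i, s in enumerate(sites):
        by_name.setdefault(s.tf_name, []).append(i)
    for tf in tfs.values():
        for partner, omega, rng in tf.coop_partners:
            for i in by_name.get(tf.name, []):
                for j in by_name.get(partner, []):
                    if i == j:
                        continue
                    a, b = min(i, j), max(i, j)
                    if abs(sites[a].center - sites[b].center) <= rng \
                            and not sites[a].overlaps(sites[b]):
                        # one omega factor per pair; a duplicate rule on the
                        # partner side must not double-count
                        pairs[(a, b)] = omega
    return pairs


def occupancy_enumerate(sites: list[BindingSite], tfs: dict[str, TFModel],
                        weights: np.ndarray) -> OccupancyState:
    """Brute-force reference: enumerate every non-overlapping configuration.

    Exponential in the number of sites; the independent check for the
    dynamic-programming route on small instances.
    """
    m = len(sites)
    if m > 20:
        raise ValueError("enumeration reference limited to 20 sites")
    coop = _coop_lookup(sites, tfs)
    Z = 0.0
    zi = np.zeros(m)
    for mask in range(1 << m):
        members = [i for i in range(m) if mask >> i & 1]
        if any(sites[a].overlaps(sites[b]) for a, b in combinations(members, 2)):
            continue
        wt = 1.0
        for i in members:
            wt *= weights[i]
        for a, b in combinations(members, 2):
            wt *= coop.get((a, b), 1.0)
        Z += wt
        for i in members:
            zi[i] += wt
    return OccupancyState(sites, zi / Z)


def _occupancy_dp_plain(sites, weights):
    """Forward/backward DP without cooperativity; exact marginals.

    Configs split independently around a bound site into sites entirely to
    its left (end <= start) and entirely to its right, so
    f_j = w_j * Z_left(j) * Z_right(j) / Z.
    """
    m = len(sites)
    by_end = sorted(range(m), key=lambda i: (sites[i].end, sites[i].start))
    ends = [sites[i].end for i in by_end]
    zpref = [1.0]
    for k, i in enumerate(by_end):
        p = bisect_right(ends, sites[i].start, 0, k)
        zpref.append(zpref[k] + weights[i] * zpref[p])

    by_start = sorted(range(m), key=lambda i: (sites[i].start, sites[i].end))
    starts = [sites[i].start for i in by_start]
    zsuf = [1.0] * (m + 1)
    for k in range(m - 1, -1, -1):
        i = by_start[k]
        q = bisect_left(starts, sites[i].end, k + 1, m)
        zsuf[k] = zsuf[k + 1] + weights[i] * zsuf[q]

    Z = zpref[m]
    f = np.empty(m)
    for i in range(m):
        zl = zpref[bisect_right(ends, sites[i].start)]
        zr = zsuf[bisect_left(starts, sites[i].end)]
        f[i] = weights[i] * zl * zr / Z
    return f, Z


def _dp_coop_partition(order, sites, weights, coop, horizon, forced=None):
    """Set-state forward DP over sites sorted by start.

    State = frozenset of bound sites still able to overlap or cooperate with
    upcoming sites; sites are retired from the state once every later site
    lies beyond both their extent and the cooperativity horizon.
    """
    states = {frozenset(): 1.0}
    for idx, i in enumerate(order):
        si = sites[i]
        nxt = {}
        for state, z in states.items():
            live = frozenset(
                j for j in state
                if sites[j].end > si.start or sites[j].center + horizon >= si.start
            )
            if forced is None or i != forced:
                nxt[live] = nxt.get(live, 0.0) + z
            if all(not sites[j].overlaps(si) for j in live):
                w = weights[i]
                for j in live:
                    a, b = min(i, j), max(i, j)
                    w *= coop.get((a, b), 1.0)
                key = live | {i}
                nxt[key] = nxt.get(key, 0.0) + z * w
        states = nxt
    return sum(states.values())


def occupancy(sites: list[BindingSite], tfs: dict[str, TFModel],
              conc: dict[str, float] | None = None,
              weights: np.ndarray | None = None) -> OccupancyState:
    """Exact fractional occupancies under the configuration partition function.

    Z sums over all sets of mutually non-overlapping bound sites, each
    configuration weighted by the product of site weights times one omega
    factor per co-bound cooperating pair within range; f_i is the total
    weight of configurations containing site i, divided by Z. Without
    cooperativity a forward/backward interval DP is used; with cooperativity
    an exact sliding-window DP with forced-inclusion reruns per site.
    """
    if weights is None:
        if conc is None:
            raise ValueError("provide conc or precomputed weights")
        weights = site_weights(sites, tfs, conc)
    weights = np.asarray(weights, dtype=float)
    m = len(sites)
    if m == 0:
        return OccupancyState([], np.empty(0))
    coop = _coop_lookup(sites, tfs)
    if not coop:
        f, _ = _occupancy_dp_plain(sites, weights)
        return OccupancyState(sites, f)
    horizon = max((rng for tf in tfs.values() for _, _, rng in tf.coop_partners),
                  default=0.0)
    order = sorted(range(m), key=lambda i: (sites[i].start, sites[i].end))
    Z = _dp_coop_partition(order, sites, weights, coop, horizon)
    f = np.empty(m)
    for i in range(m):
        f[i] = _dp_coop_partition(order, sites, weights, coop, horizon, forced=i) / Z
    return OccupancyState(sites, f)


# ---------------------------------------------------------------------------
# quenching, coactivation, net activation, rate law


def _is_quencher(tf: TFModel) -> bool:
    return tf.role == "repressor" and tf.coactivated_by is None


def apply_quenching(state: OccupancyState, tfs: dict[str, TFModel]) -> OccupancyState:
    """Attenuate activator occupancy by nearby bound repressors.

    f_effective(a) = f(a) * prod over repressor sites q within quench_range
    of (1 - quench_eff(q) * f(q)); distances are center-to-center in bp.
    Coactivated factors do not quench (their repressive mode is converted).
    """
    sites, f = state.sites, state.f
    f_eff = f.copy()
    quenchers = [(i, tfs[s.tf_name]) for i, s in enumerate(sites)
                 if _is_quencher(tfs[s.tf_name])]
    for a, sa in enumerate(sites):
        if tfs[sa.tf_name].role != "activator":
            continue
        factor = 1.0
        for q, tfq in quenchers:
            if abs(sites[q].center - sa.center) <= tfq.quench_range:
                factor *= 1.0 - tfq.quench_eff * f[q]
        f_eff[a] = f[a] * factor
    return OccupancyState(sites, f, f_effective=f_eff)


def apply_coactivation(state: OccupancyState, tfs: dict[str, TFModel]) -> OccupancyState:
    """Assign per-site activation contributions, converting coactivated repressors.

    An activator site contributes alpha * f_effective. A site of a TF with
    coactivated_by = (partner, range) contributes alpha * f * g where
    g = 1 - prod over partner sites within range of (1 - f(partner site)):
    the probability at least one partner is bound nearby.
    """
    sites, f = state.sites, state.f
    f_eff = state.f_effective if state.f_effective is not None else f
    contrib = np.zeros(len(sites))
    for i, s in enumerate(sites):
        tf = tfs[s.tf_name]
        if tf.role == "activator":
            contrib[i] = tf.alpha * f_eff[i]
        elif tf.coactivated_by is not None:
            partner, rng = tf.coactivated_by
            miss = 1.0
            for j, sp in enumerate(sites):
                if sp.tf_name == partner and abs(sp.center - s.center) <= rng:
                    miss *= 1.0 - f[j]
            contrib[i] = tf.alpha * f[i] * (1.0 - miss)
    return OccupancyState(sites, f, f_effective=f_eff, contributions=contrib)


def net_activation(state: OccupancyState, tfs: dict[str, TFModel]) -> float:
    """Net activation N: the sum of per-site activation contributions."""
    if state.contributions is None:
        state = apply_coactivation(apply_quenching(state, tfs), tfs)
    return float(state.contributions.sum())


def transcription_rate(N, params: RateParams):
    """Saturating rate law, monotone in N and bounded by R_max.

    A logistic saturation with midpoint N0 and steepness beta; large
    arguments return the limiting values without overflow.
    """
    x = np.clip(params.beta * (np.asarray(N, dtype=float) - params.N0), -700, 700)
    out = params.R_max / (1.0 + np.exp(-x))
    return float(out) if np.isscalar(N) else out


# ---------------------------------------------------------------------------
# the full pipeline


def _state_at(sites, tfs, conc):
    st = occupancy(sites, tfs, conc)
    st = apply_quenching(st, tfs)
    return apply_coactivation(st, tfs)


def raw_rate_profile(enh: EnhancerSequence, tfs: dict[str, TFModel],
                     profiles: TFProfileSet, rate_params: RateParams,
                     sites: list[BindingSite] | None = None) -> np.ndarray:
    """Unscaled synthesis rate at every grid position."""
    if sites is None:
        sites = scan_sites(enh, [tf.pwm for tf in tfs.values()])
    rates = np.empty(len(profiles.positions))
    for i in range(len(profiles.positions)):
        conc = dict(zip(profiles.tf_names, profiles.conc[i]))
        if not sites or all(v == 0.0 for v in conc.values()):
            rates[i] = transcription_rate(0.0, rate_params)
            continue
        st = _state_at(sites, tfs, conc)
        rates[i] = transcription_rate(st.contributions.sum(), rate_params)
    return rates


def predict_expression(enh: EnhancerSequence, tfs: dict[str, TFModel],
                       profiles: TFProfileSet, rate_params: RateParams) -> ExpressionProfile:
    """Predicted relative expression, rescaled so the profile maximum is 1.

    With zero activation everywhere the baseline rate is uniform; such a
    flat-baseline profile is reported as all zeros.
    """
    rates = raw_rate_profile(enh, tfs, profiles, rate_params)
    baseline = transcription_rate(0.0, rate_params)
    rel = np.maximum(rates - baseline, 0.0)
    top = rel.max()
    if top <= 0.0:
        return ExpressionProfile(profiles.positions, np.zeros_like(rates))
    return ExpressionProfile(profiles.positions, rel / top)


def activation_share(enh: EnhancerSequence, tfs: dict[str, TFModel],
                     profiles: TFProfileSet, position: float) -> np.ndarray:
    """Per-base fraction of net activation N at one embryo position.

    Each contributing site spreads its contribution uniformly over its bases;
    shares sum to 1 over covered bases.
    """
    sites = scan_sites(enh, [tf.pwm for tf in tfs.values()])
    conc = profiles.at(position)
    st = _state_at(sites, tfs, conc)
    N = st.contributions.sum()
    if N <= 0.0:
        raise ValueError("no activation to apportion (N = 0)")
    share = np.zeros(len(enh))
    for s, c in zip(sites, st.contributions):
        if c > 0.0:
            share[s.start:s.end] += c / (s.end - s.start)
    return share / N
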