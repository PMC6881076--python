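"""The thermodynamic model: scanning, occupancy, quenching, rate law."""

import numpy as np
import pytest

from regrobust.model import (
    BindingSite,
    EnhancerSequence,
    OccupancyState,
    RateParams,
    TFModel,
    TFProfileSet,
    activation_share,
    apply_coactivation,
    apply_quenching,
    net_activation,
    occupancy,
    occupancy_enumerate,
    predict_expression,
    raw_rate_profile,
    scan_sites,
    transcription_rate,
)
from regrobust.pwm import PWM
from regrobust.sequence import revcomp
from regrobust.synthdata import gen_enhancer, gen_pwm


def _brute_force_scan(enh, pwm):
    """Independent rescoring of every window on both strands."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for start in range(len(enh.seq) - pwm.width + 1):
        if not enh.accessible[start:start + pwm.width].all():
            continue
        window = enh.seq[start:start + pwm.width]
        for strand, w in (("+", window), ("-", revcomp(window))):
            score = sum(pwm.logodds[k, code[b]] for k, b in enumerate(w))
            if score >= pwm.threshold:
                hits.append((start, strand, score))
    return hits


class TestScanSites:
    def test_planted_consensus_single_hit(self):
        pwm = gen_pwm("tf", 4, 1.9, seed=1, threshold=None)
        pwm.threshold = pwm.max_score - 0.5  # only the consensus passes
        enh = gen_enhancer("e", 10, [(pwm, 3, "+")], seed=5)
        sites = [s for s in scan_sites(enh, [pwm]) if s.strand == "+"]
        assert len(sites) == 1
        assert (sites[0].start, sites[0].end) == (3, 7)
        assert sites[0].score == pytest.approx(pwm.max_score)

    def test_mask_closes_site(self):
        pwm = gen_pwm("tf", 4, 1.9, seed=1)
        pwm.threshold = pwm.max_score - 0.5
        enh = gen_enhancer("e", 10, [(pwm, 3, "+")], seed=5,
                           closed_intervals=[(4, 6)])
        assert scan_sites(enh, [pwm]) == []

    def test_planted_sites_recovered_vs_bruteforce(self):
        pwm = gen_pwm("tf", 6, 1.7, seed=4)
        planted_at = [20, 60, 120, 180, 250]
        enh = gen_enhancer("e", 300, [(pwm, p, "+") for p in planted_at], seed=9)
        sites = scan_sites(enh, [pwm])
        assert len(sites) >= 5
        found = {(s.start, s.strand) for s in sites}
        for p in planted_at:
            assert (p, "+") in found
        # every site agrees with an independent rescoring routine
        oracle = set()
        for start, strand, score in _brute_force_scan(enh, pwm):
            oracle.add((start, strand, round(score, 9)))
        assert {(s.start, s.strand, round(s.score, 9)) for s in sites} == oracle

    def test_sites_sorted_and_fully_accessible(self, stripe):
        enh, tfs, _, _ = stripe
        sites = scan_sites(enh, [tf.pwm for tf in tfs.values()])
        keys = [(s.start, s.strand, s.tf_name) for s in sites]
        assert keys == sorted(keys)
        for s in sites:
            assert enh.accessible[s.start:s.end].all()


def _plain_tf(pwm, **kw):
    return TFModel(pwm, role=kw.pop("role", "activator"), **kw)


@pytest.fixture()
def pwm4():
    return gen_pwm("a", 4, 1.5, seed=1)


class TestOccupancy:
    def test_single_site_half_occupied(self, pwm4):
        tfs = {"a": _plain_tf(pwm4)}
        sites = [BindingSite("a", 0, 4, "+", pwm4.max_score)]
        st = occupancy(sites, tfs, weights=np.array([1.0]))
        assert st.f[0] == pytest.approx(0.5)

    def test_overlapping_pair_thirds(self, pwm4):
        tfs = {"a": _plain_tf(pwm4)}
        sites = [BindingSite("a", 0, 4, "+", pwm4.max_score),
                 BindingSite("a", 2, 6, "+", pwm4.max_score)]
        st = occupancy(sites, tfs, weights=np.ones(2))
        assert st.f == pytest.approx([1 / 3, 1 / 3])

    def test_cooperative_pair(self, pwm4):
        tfs = {"a": _plain_tf(pwm4, coop_partners=[("a", 2.0, 50.0)])}
        sites = [BindingSite("a", 0, 4, "+", pwm4.max_score),
                 BindingSite("a", 10, 14, "+", pwm4.max_score)]
        st = occupancy(sites, tfs, weights=np.ones(2))
        # Z = 1 + 1 + 1 + 2 = 5; configs with site 1: alone (1) + pair (2)
        assert st.f == pytest.approx([0.6, 0.6])

    def test_zero_concentration_zero_occupancy(self, pwm4):
        tfs = {"a": _plain_tf(pwm4)}
        sites = [BindingSite("a", 0, 4, "+", pwm4.max_score)]
        st = occupancy(sites, tfs, conc={"a": 0.0})
        assert st.f == pytest.approx([0.0])

    @pytest.mark.parametrize("with_coop", [False, True])
    def test_dp_matches_enumeration_random_instances(self, pwm4, with_coop):
        rng = np.random.default_rng(42 + with_coop)
        tf = _plain_tf(pwm4, coop_partners=[("a", 1.7, 25.0)] if with_coop else [])
        tfs = {"a": tf}
        for _ in range(40):
            m = int(rng.integers(1, 13))
            starts = rng.integers(0, 80, size=m)
            widths = rng.integers(3, 10, size=m)
            sites = sorted(
                (BindingSite("a", int(s), int(s + w), "+", pwm4.max_score)
                 for s, w in zip(starts, widths)),
                key=lambda x: x.start)
            w = rng.uniform(0.05, 4.0, size=m)
            np.testing.assert_allclose(
                occupancy(sites, tfs, weights=w).f,
                occupancy_enumerate(sites, tfs, w).f, atol=1e-9)

    def test_occupancy_monotone_in_concentration(self, pwm4):
        tfs = {"a": _plain_tf(pwm4, Keq_scale=2.0)}
        sites = [BindingSite("a", 0, 4, "+", pwm4.max_score),
                 BindingSite("a", 6, 10, "+", pwm4.max_score - 1.0)]
        last = -1.0
        for conc in [0.0, 0.1, 0.5, 1.0, 5.0, 50.0]:
            f = occupancy(sites, tfs, conc={"a": conc}).f
            assert (f >= 0).all() and (f <= 1).all()
            assert f[0] >= last
            last = f[0]


class TestQuenchingAndCoactivation:
    def _two_site_state(self, pwm4, f_act, f_rep, rep_start):
        sites = [BindingSite("act", 0, 4, "+", pwm4.max_score),
                 BindingSite("rep", rep_start, rep_start + 4, "+", pwm4.max_score)]
        return OccupancyState(sites, np.array([f_act, f_rep]))

    def _tfs(self, pwm4, quench_eff=0.5, quench_range=20.0):
        return {
            "act": TFModel(PWM("act", pwm4.logodds), role="activator", alpha=1.0),
            "rep": TFModel(PWM("rep", pwm4.logodds), role="repressor",
                           quench_eff=quench_eff, quench_range=quench_range),
        }

    def test_unbound_repressor_leaves_activators(self, pwm4):
        st = self._two_site_state(pwm4, 0.8, 0.0, rep_start=6)
        out = apply_quenching(st, self._tfs(pwm4))
        assert out.f_effective[0] == pytest.approx(0.8)

    def test_quenching_within_range(self, pwm4):
        st = self._two_site_state(pwm4, 0.8, 1.0, rep_start=6)
        out = apply_quenching(st, self._tfs(pwm4, quench_eff=0.5, quench_range=20))
        assert out.f_effective[0] == pytest.approx(0.4)

    def test_quenching_out_of_range(self, pwm4):
        st = self._two_site_state(pwm4, 0.8, 1.0, rep_start=60)
        out = apply_quenching(st, self._tfs(pwm4, quench_eff=0.5, quench_range=20))
        assert out.f_effective[0] == pytest.approx(0.8)

    def _coact_tfs(self, pwm4, alpha=2.0, rng=30.0):
        return {
            "part": TFModel(PWM("part", pwm4.logodds), role="activator", alpha=1.0),
            "co": TFModel(PWM("co", pwm4.logodds), role="repressor", alpha=alpha,
                          coactivated_by=("part", rng)),
        }

    def test_coactivation_no_partner_in_range(self, pwm4):
        sites = [BindingSite("co", 0, 4, "+", pwm4.max_score),
                 BindingSite("part", 100, 104, "+", pwm4.max_score)]
        st = OccupancyState(sites, np.array([1.0, 1.0]))
        out = apply_coactivation(apply_quenching(st, self._coact_tfs(pwm4)),
                                 self._coact_tfs(pwm4))
        assert out.contributions[0] == pytest.approx(0.0)

    def test_coactivation_full_partner(self, pwm4):
        sites = [BindingSite("co", 0, 4, "+", pwm4.max_score),
                 BindingSite("part", 10, 14, "+", pwm4.max_score)]
        tfs = self._coact_tfs(pwm4, alpha=2.0)
        st = OccupancyState(sites, np.array([1.0, 1.0]))
        out = apply_coactivation(apply_quenching(st, tfs), tfs)
        assert out.contributions[0] == pytest.approx(2.0)

    def test_coactivation_partial_partner_matches_product(self, pwm4):
        # g = 1 - (1 - f_partner); contribution alpha * f * f_partner
        tfs = self._coact_tfs(pwm4, alpha=2.0)
        sites = [BindingSite("co", 0, 4, "+", pwm4.max_score),
                 BindingSite("part", 10, 14, "+", pwm4.max_score)]
        st = OccupancyState(sites, np.array([0.7, 0.5]))
        out = apply_coactivation(apply_quenching(st, tfs), tfs)
        assert out.contributions[0] == pytest.approx(2.0 * 0.7 * 0.5)
        # two partner sites: g = 1 - (1-f1)(1-f2), enumerated over bound subsets
        sites3 = sites + [BindingSite("part", 20, 24, "+", pwm4.max_score)]
        st3 = OccupancyState(sites3, np.array([0.7, 0.5, 0.3]))
        out3 = apply_coactivation(apply_quenching(st3, tfs), tfs)
        # oracle: enumerate partner-bound configurations for P(>=1 bound)
        g = sum(
            (0.5 if b1 else 0.5) * (0.3 if b2 else 0.7)
            for b1 in (True, False) for b2 in (True, False) if b1 or b2)
        assert g == pytest.approx(1 - (1 - 0.5) * (1 - 0.3))
        assert out3.contributions[0] == pytest.approx(2.0 * 0.7 * g)


class TestNetActivationAndRate:
    def test_no_sites_zero(self, pwm4):
        st = OccupancyState([], np.empty(0))
        st.contributions = np.empty(0)
        assert net_activation(st, {}) == 0.0

    def test_two_half_occupied_activators(self, pwm4):
        tfs = {"a": _plain_tf(pwm4, alpha=1.0)}
        sites = [BindingSite("a", 0, 4, "+", pwm4.max_score),
                 BindingSite("a", 10, 14, "+", pwm4.max_score)]
        st = OccupancyState(sites, np.array([0.5, 0.5]))
        assert net_activation(st, tfs) == pytest.approx(1.0)

    def test_mixed_case_matches_manual_sum(self, pwm4):
        tfs = {
            "a": TFModel(PWM("a", pwm4.logodds), role="activator", alpha=2.0),
            "q": TFModel(PWM("q", pwm4.logodds), role="repressor",
                         quench_eff=0.5, quench_range=50.0),
        }
        sites = [BindingSite("a", 0, 4, "+", pwm4.max_score),
                 BindingSite("q", 10, 14, "+", pwm4.max_score),
                 BindingSite("a", 30, 34, "+", pwm4.max_score)]
        st = OccupancyState(sites, np.array([0.8, 0.6, 0.4]))
        N = net_activation(st, tfs)
        manual = 2.0 * 0.8 * (1 - 0.5 * 0.6) + 2.0 * 0.4 * (1 - 0.5 * 0.6)
        assert N == pytest.approx(manual)

    def test_rate_midpoint_and_saturation(self):
        rp = RateParams(R_max=2.0, N0=3.0, beta=1.0)
        assert transcription_rate(3.0, rp) == pytest.approx(1.0)
        assert transcription_rate(1e9, rp) == pytest.approx(2.0)
        assert transcription_rate(np.log(3.0) + 1.0, RateParams(1.0, 1.0, 1.0)) \
            == pytest.approx(0.75)

    def test_rate_monotone_bounded_no_overflow(self):
        rp = RateParams(R_max=1.5, N0=0.0, beta=2.0)
        ns = np.array([-1e6, -10, 0, 10, 1e6])
        rates = transcription_rate(ns, rp)
        assert (np.diff(rates) >= 0).all()
        assert (rates >= 0).all() and (rates <= 1.5).all()
        assert np.isfinite(rates).all()


class TestPredictExpression:
    def test_zero_concentrations_zero_profile(self, tiny_model):
        enh, tfs, profiles, rp = tiny_model
        prof0 = TFProfileSet(profiles.positions,
                             np.zeros_like(profiles.conc), profiles.tf_names)
        pred = predict_expression(enh, tfs, prof0, rp)
        assert (pred.rate == 0).all()

    def test_activator_bump_peaks_at_bump(self, tiny_model):
        enh, tfs, profiles, rp = tiny_model
        pred = predict_expression(enh, tfs, profiles, rp)
        assert pred.positions[np.argmax(pred.rate)] == 42.0
        assert pred.rate.max() == pytest.approx(1.0)

    def test_stripe_fixture_single_interior_stripe(self, stripe):
        enh, tfs, profiles, rp = stripe
        pred = predict_expression(enh, tfs, profiles, rp)
        peak_pos = pred.positions[np.argmax(pred.rate)]
        assert 39.0 <= peak_pos <= 42.0
        # both flanks below 10% of the peak
        assert pred.rate[pred.positions <= 37.0].max() < 0.10
        assert pred.rate[pred.positions >= 45.0].max() < 0.10
        # the above-10% region is one contiguous interior block
        above = np.flatnonzero(pred.rate > 0.10)
        assert (np.diff(above) == 1).all()
        assert 0 < above[0] and above[-1] < len(pred.rate) - 1

    def test_deterministic(self, stripe):
        enh, tfs, profiles, rp = stripe
        a = predict_expression(enh, tfs, profiles, rp)
        b = predict_expression(enh, tfs, profiles, rp)
        assert (a.rate == b.rate).all()

    def test_closing_chromatin_removes_exactly_that_site(self, stripe):
        enh, tfs, profiles, rp = stripe
        pwms = [tf.pwm for tf in tfs.values()]
        sites = scan_sites(enh, pwms)
        target = sites[0]
        masked = EnhancerSequence(
            enh.name, enh.seq, enh.accessible.copy(), enh.offset_bp)
        masked.accessible[target.start:target.end] = False
        remaining = scan_sites(masked, pwms)
        removed = [s for s in sites if s not in remaining]
        for s in removed:  # only sites overlapping the closed window vanish
            assert s.start < target.end and target.start < s.end


class TestActivationShare:
    def test_single_site_uniform_share(self):
        pwm = gen_pwm("act", 8, 2.0, seed=4)
        pwm.threshold = pwm.max_score - 0.5  # the planted site only
        enh = gen_enhancer("e", 40, [(pwm, 12, "+")], seed=6)
        tfs = {"act": TFModel(pwm, role="activator", alpha=1.0)}
        profiles = TFProfileSet(np.array([40.0]), np.array([[1.0]]), ["act"])
        share = activation_share(enh, tfs, profiles, 40.0)
        covered = share[share > 0]
        assert len(covered) == 8
        assert covered == pytest.approx(np.full(8, 1.0 / 8))
        assert share.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_equal_sites_split_half(self):
        pwm = gen_pwm("act", 4, 2.0, seed=2)
        enh = gen_enhancer("e", 30, [(pwm, 5, "+"), (pwm, 20, "+")], seed=3)
        tfs = {"act": TFModel(pwm, role="activator", alpha=1.0)}
        profiles = TFProfileSet(np.array([40.0]), np.array([[1.0]]), ["act"])
        share = activation_share(enh, tfs, profiles, 40.0)
        assert share[5:9].sum() == pytest.approx(0.5)
        assert share[20:24].sum() == pytest.approx(0.5)

    def test_shares_sum_to_one_general(self, stripe):
        enh, tfs, profiles, _ = stripe
        share = activation_share(enh, tfs, profiles, 40.5)
        assert share.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_activation_errors(self, tiny_model):
        enh, tfs, profiles, rp = tiny_model
        prof0 = TFProfileSet(profiles.positions,
                             np.zeros_like(profiles.conc), profiles.tf_names)
        with pytest.raises(ValueError, match="no activation"):
            activation_share(enh, tfs, prof0, 42.0)


def test_raw_profile_matches_incremental_evaluator(stripe):
    """The batch profile and the mutant-rescoring evaluator agree at wild type."""
    from regrobust.perturb import ModelEvaluator

    enh, tfs, profiles, rp = stripe
    ev = ModelEvaluator(enh, tfs, profiles, rp)
    direct = raw_rate_profile(enh, tfs, profiles, rp)
    for i in range(0, len(profiles.positions), 10):
        pos = float(profiles.positions[i])
        assert ev.rate(pos) == pytest.approx(direct[i], rel=1e-12)
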