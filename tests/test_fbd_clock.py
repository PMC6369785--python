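"""FBD density, HKY likelihood, clock sampler contracts, HPD summaries."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cyclophylo.clock import (
    ClockPriors,
    ClockSettings,
    hpd_interval,
    run_clock_mcmc,
    summarize_ages,
)
from cyclophylo.fbd import FBDParams, TimeTree, fbd_log_density
from cyclophylo.hky import HkyEngine, HkyParams, hky_rate_matrix
from cyclophylo.nexus_io import CalibrationTable
from cyclophylo.simulate import (
    SimulationConfig,
    simulate_alignment,
    simulate_fbd_tree,
)
from cyclophylo.tree import Cladogram, Node


def bd_closed_form(tt, lam, mu):
    """Independent constant-rate birth-death density (rho=1, psi=0),
    conditioned on the root age, via the textbook p1 expression."""

    def p1(t):
        r = lam - mu
        return r**2 * math.exp(-r * t) / (lam - mu * math.exp(-r * t)) ** 2

    n = len(tt.tree.leaves())
    logf = (n - 2) * math.log(lam) + math.log(p1(tt.root_age))
    for node in tt.tree.postorder():
        if not node.is_leaf:
            logf += math.log(p1(node.age))
    return logf


def two_tip_timetree(age=10.0):
    root = Node()
    root.age = age
    for label in ("A", "B"):
        leaf = Node(label)
        leaf.age = 0.0
        root.add_child(leaf)
    return TimeTree(Cladogram(root, rooted=True))


class TestFbdDensity:
    def test_reduces_to_birth_death_closed_form(self):
        rng = random.Random(3)
        cfg = SimulationConfig(
            seed=3, n_extant=5, n_fossil=0, lam=0.05, mu=0.02, psi=0.0,
            rho=1.0, origin_time=60.0,
        )
        for _ in range(10):
            tt = simulate_fbd_tree(cfg, rng)
            got = fbd_log_density(tt, FBDParams(0.05, 0.02, 0.0, 1.0))
            want = bd_closed_form(tt, 0.05, 0.02)
            assert got == pytest.approx(want, abs=1e-8)

    def test_child_older_than_parent_gives_minus_inf(self):
        tt = two_tip_timetree()
        tt.tree.leaves()[0].age = 99.0
        tt.tree.leaves()[0].is_fossil = True  # dodge the extant-age check
        assert fbd_log_density(tt, FBDParams(0.1, 0.05, 0.01, 1.0)) == -math.inf

    def test_generating_parameters_beat_perturbed_on_average(self):
        rng = random.Random(11)
        cfg = SimulationConfig(
            seed=9, n_extant=5, n_fossil=2, lam=0.05, mu=0.02, psi=0.01,
            rho=0.8, origin_time=80.0,
        )
        gen = FBDParams(0.05, 0.02, 0.01, 0.8)
        pert = FBDParams(0.10, 0.02, 0.01, 0.8)
        dg = dp = 0.0
        for _ in range(25):
            tt = simulate_fbd_tree(cfg, rng)
            dg += fbd_log_density(tt, gen)
            dp += fbd_log_density(tt, pert)
        assert dg > dp

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            FBDParams(lam=-1.0, mu=0.1, psi=0.0, rho=1.0)
        with pytest.raises(ValueError):
            FBDParams(lam=1.0, mu=0.1, psi=0.0, rho=0.0)


class TestHky:
    def test_zero_branch_identical_sequences_closed_form(self):
        tt = two_tip_timetree(age=0.0)
        par = HkyParams(kappa=3.0, pi=(0.4, 0.2, 0.1, 0.3))
        eng = HkyEngine({"A": "ACGT", "B": "ACGT"})
        ll = eng.loglik(tt, 1.0, par)
        assert ll == pytest.approx(sum(math.log(p) for p in par.pi))

    def test_jc_reduction_matches_independent_jc_pruning(self):
        # kappa=1, uniform pi: HKY collapses to JC69, for which p_ii and
        # p_ij have the familiar closed form
        def jc_p(t):
            e = math.exp(-4.0 * t / 3.0)
            return 0.25 + 0.75 * e, 0.25 - 0.25 * e

        seqs = {"A": "ACGTAC", "B": "ACGTTT", "C": "AGGTAC"}
        root = Node()
        root.age = 2.0
        inner = Node()
        inner.age = 1.0
        for lbl in ("A", "B"):
            leaf = Node(lbl)
            leaf.age = 0.0
            inner.add_child(leaf)
        c = Node("C")
        c.age = 0.0
        root.add_child(inner)
        root.add_child(c)
        tt = TimeTree(Cladogram(root, rooted=True))
        rate = 0.07

        def jc_loglik():
            total = 0.0
            for site in range(6):
                lik = 0.0
                for x in range(4):  # root state
                    for y in range(4):  # inner state
                        p = 0.25
                        same, diff = jc_p(1.0 * rate)
                        p *= same if x == y else diff
                        for leaf, node_age in (("A", 1.0), ("B", 1.0)):
                            s = "ACGT".index(seqs[leaf][site])
                            p2 = jc_p(1.0 * rate)
                            p *= p2[0] if s == y else p2[1]
                        s = "ACGT".index(seqs["C"][site])
                        p3 = jc_p(2.0 * rate)
                        p *= p3[0] if s == x else p3[1]
                        lik += p
                total += math.log(lik)
            return total

        eng = HkyEngine(seqs)
        got = eng.loglik(tt, rate, HkyParams(kappa=1.0))
        assert got == pytest.approx(jc_loglik(), rel=1e-9)

    def test_invariant_to_site_order(self):
        tt = two_tip_timetree(age=4.0)
        par = HkyParams(kappa=2.5, pi=(0.3, 0.2, 0.2, 0.3))
        a = HkyEngine({"A": "AACGTT", "B": "AACGTA"}).loglik(tt, 0.05, par)
        b = HkyEngine({"A": "TAACGT", "B": "AAACGT"}).loglik(tt, 0.05, par)
        assert a == pytest.approx(b)

    def test_fossil_tip_without_sequence_marginalised(self):
        root = Node()
        root.age = 10.0
        f = Node("fossilX")
        f.age = 4.0
        f.is_fossil = True
        inner = Node()
        inner.age = 5.0
        for lbl in ("A", "B"):
            leaf = Node(lbl)
            leaf.age = 0.0
            inner.add_child(leaf)
        root.add_child(f)
        root.add_child(inner)
        tt = TimeTree(Cladogram(root, rooted=True))
        par = HkyParams()
        with_fossil = HkyEngine({"A": "ACGT", "B": "ACCT"}).loglik(tt, 0.02, par)
        # pruning the fossil by hand gives the same value: its subtree
        # contributes a factor of exactly 1
        pruned_root = Node()
        pruned_root.age = 5.0
        for lbl in ("A", "B"):
            leaf = Node(lbl)
            leaf.age = 0.0
            pruned_root.add_child(leaf)
        tt2 = TimeTree(Cladogram(pruned_root, rooted=True))
        without = HkyEngine({"A": "ACGT", "B": "ACCT"}).loglik(tt2, 0.02, par)
        assert with_fossil == pytest.approx(without)

    def test_rate_matrix_rows_sum_to_zero_and_unit_scale(self):
        par = HkyParams(kappa=5.0, pi=(0.1, 0.2, 0.3, 0.4))
        Q = hky_rate_matrix(par)
        assert np.allclose(Q.sum(axis=1), 0.0)
        assert -(np.asarray(par.pi) * np.diag(Q)).sum() == pytest.approx(1.0)


class TestClockSampler:
    def _setup(self, seed=4):
        rng = random.Random(seed)
        cfg = SimulationConfig(
            seed=seed, n_extant=5, n_fossil=2, lam=0.08, mu=0.04, psi=0.02,
            rho=1.0, origin_time=40.0, exact_taxon_counts=True,
            partition_lengths=(120, 100), clock_rate=0.01,
        )
        tt = simulate_fbd_tree(cfg, rng)
        alns = simulate_alignment(tt, cfg, rng)
        # hagfish-fossil-style window: (93.9, 100.5)-like bounds scaled here
        cal = CalibrationTable(
            {t.label: (max(t.age - 3, 0.0), t.age + 3) for t in tt.fossil_tips()}
        )
        topo = tt.tree.copy()
        for n in topo.postorder():
            n.age = None
        return Cladogram(topo.root, rooted=True), alns, cal, tt

    def test_zero_iteration_trace_contains_only_initial_state(self):
        topo, alns, cal, _ = self._setup()
        trace, _ = run_clock_mcmc(
            topo, alns, cal, FBDParams(0.08, 0.04, 0.02, 1.0),
            ClockPriors(root_age_range=(1.0, 60.0)),
            ClockSettings(iterations=0, seed=1),
        )
        assert trace.n_samples() == 1

    def test_sampled_fossil_ages_always_inside_calibration(self):
        topo, alns, cal, _ = self._setup()
        trace, _ = run_clock_mcmc(
            topo, alns, cal, FBDParams(0.08, 0.04, 0.02, 1.0),
            ClockPriors(root_age_range=(1.0, 60.0)),
            ClockSettings(iterations=150, seed=2),
        )
        for label, samples in trace.tip_ages.items():
            lo, hi = cal[label]
            assert all(lo <= a <= hi for a in samples)

    def test_node_age_samples_never_violate_parent_child_order(self):
        topo, alns, cal, _ = self._setup()
        trace, final = run_clock_mcmc(
            topo, alns, cal, FBDParams(0.08, 0.04, 0.02, 1.0),
            ClockPriors(root_age_range=(1.0, 60.0)),
            ClockSettings(iterations=100, seed=3),
        )
        final.validate()
        keys = {k: v for k, v in trace.node_ages.items()}
        # every sampled state keeps nested clades older outward
        n = trace.n_samples()
        for i in range(n):
            for a, sa in keys.items():
                for b, sb in keys.items():
                    if a < b:
                        assert sa[i] <= sb[i] + 1e-9

    def test_deterministic_given_seed(self):
        topo, alns, cal, _ = self._setup()
        args = (
            topo, alns, cal, FBDParams(0.08, 0.04, 0.02, 1.0),
            ClockPriors(root_age_range=(1.0, 60.0)),
        )
        t1, _ = run_clock_mcmc(*args, ClockSettings(iterations=80, seed=5))
        t2, _ = run_clock_mcmc(*args, ClockSettings(iterations=80, seed=5))
        assert t1.log_posterior == t2.log_posterior
        assert t1.rate == t2.rate

    def test_calibration_topology_mismatch_rejected(self):
        topo, alns, cal, _ = self._setup()
        bad = CalibrationTable({"nosuchtip": (1.0, 2.0)})
        from cyclophylo.tree import TreeError

        with pytest.raises(TreeError):
            run_clock_mcmc(
                topo, alns, bad, FBDParams(0.08, 0.04, 0.02, 1.0),
                ClockPriors(root_age_range=(1.0, 60.0)),
                ClockSettings(iterations=1, seed=1),
            )


class TestHpd:
    def test_degenerate_samples(self):
        assert hpd_interval([5.0] * 10, 0.95) == (5.0, 5.0)

    def test_matches_all_windows_oracle(self, rng):
        for _ in range(20):
            xs = [rng.gauss(0, 1) for _ in range(rng.randrange(5, 60))]
            level = rng.choice([0.5, 0.8, 0.95])
            lo, hi = hpd_interval(xs, level)
            # oracle: brute force over every contiguous window of sorted xs
            ss = sorted(xs)
            w = max(1, math.ceil(level * len(ss)))
            widths = [
                (ss[i + w - 1] - ss[i], ss[i], ss[i + w - 1])
                for i in range(len(ss) - w + 1)
            ]
            best = min(widths)
            assert (lo, hi) == (best[1], best[2])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50))
    @settings(max_examples=40, deadline=None)
    def test_narrower_level_gives_narrower_overlapping_interval(self, xs):
        # strict set-nesting of shortest intervals can fail for multimodal
        # samples (a dense extreme cluster anchors the 50% window outside a
        # 95% window that trimmed that extreme), but the 50% interval is
        # never wider and always overlaps the 95% interval
        lo50, hi50 = hpd_interval(xs, 0.5)
        lo95, hi95 = hpd_interval(xs, 0.95)
        assert hi50 - lo50 <= hi95 - lo95
        assert lo50 <= hi95 and lo95 <= hi50

    def test_nesting_holds_for_unimodal_samples(self, rng):
        xs = sorted(rng.gauss(0, 1) for _ in range(200))
        lo50, hi50 = hpd_interval(xs, 0.5)
        lo95, hi95 = hpd_interval(xs, 0.95)
        assert lo95 <= lo50 and hi50 <= hi95

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval([], 0.95)
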