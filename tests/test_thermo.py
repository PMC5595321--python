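"""Configuration-ensemble partition sums and the SNP perturbation algebra."""

import math

import numpy as np
import pytest

from gapvar.annotate import PWM, RegulatoryRegion, scan_sites
from gapvar.thermo import (RegulationParams, TFParams, ThermoParams,
                           activation_sensitivity, brute_force_partition,
                           classify_local_context, partition_functions,
                           perturbed_activation, site_delta, site_weight)

from .conftest import make_site, simple_params


def random_instance(rng, max_sites=12):
    """A random mixed-role site set with random overlaps/omega/beta/ranges."""
    tfs = ["A", "B", "C"]
    params = ThermoParams(
        tf={t: TFParams(K=1.0, omega=float(rng.uniform(1, 3)),
                        coop_range=int(rng.integers(0, 12)))
            for t in tfs},
        regulation={
            (t, "g"): (
                RegulationParams("activator",
                                 alpha=float(rng.uniform(1.5, 5)))
                if rng.random() < 0.5
                else RegulationParams("repressor",
                                      beta=float(rng.uniform(0.2, 2)),
                                      rep_range=int(rng.integers(0, 12)))
            )
            for t in tfs
        },
    )
    n = int(rng.integers(1, max_sites + 1))
    sites = []
    for _ in range(n):
        start = int(rng.integers(0, 40))
        length = int(rng.integers(4, 9))
        sites.append(make_site(tfs[int(rng.integers(3))], start,
                               start + length))
    weights = rng.uniform(0, 2, size=n)
    return sites, weights, params


class TestSiteWeight:
    def setup_method(self):
        self.pwm = PWM("A", np.array([[1.0, 0, 0, 0]] * 3))
        self.params = simple_params({"A": "activator"}, K=2.0)
        self.site = make_site("A", 0, 3, score=self.pwm.max_score)

    def test_zero_concentration(self):
        assert site_weight(self.site, 0.0, self.params, self.pwm) == 0.0

    def test_strongest_site_weight_is_k_times_v(self):
        assert site_weight(self.site, 1.5, self.params, self.pwm) \
            == pytest.approx(3.0)

    def test_weaker_site_scales_by_exp_score_gap(self):
        site = make_site("A", 0, 3, score=self.pwm.max_score + math.log(0.5))
        assert site_weight(site, 1.5, self.params, self.pwm) \
            == pytest.approx(1.5)

    def test_negative_concentration_raises(self):
        with pytest.raises(ValueError):
            site_weight(self.site, -1.0, self.params, self.pwm)

    def test_unnormalized_flag(self):
        params = simple_params({"A": "activator"}, K=2.0)
        params.normalize_by_max = False
        site = make_site("A", 0, 3, score=0.0)
        assert site_weight(site, 1.0, params, self.pwm) == pytest.approx(2.0)


class TestPartitionFunctions:
    def test_no_sites_gives_half(self):
        params = simple_params({"A": "activator"})
        res = brute_force_partition([], np.zeros(0), params, "g")
        assert (res.z_off, res.z_on, res.e) == (1.0, 1.0, 0.5)

    def test_single_activator(self):
        params = simple_params({"A": "activator"}, alpha=3.0)
        res = brute_force_partition([make_site("A", 0, 5)], np.array([1.0]),
                                    params, "g")
        assert res.z_off == pytest.approx(2.0)
        assert res.z_on == pytest.approx(4.0)
        assert res.e == pytest.approx(2 / 3)

    def test_activator_with_in_range_repressor(self):
        params = simple_params({"A": "activator", "R": "repressor"},
                               alpha=3.0, beta=1.0, rep_range=5)
        sites = [make_site("A", 0, 5), make_site("R", 7, 12)]
        res = brute_force_partition(sites, np.ones(2), params, "g")
        assert res.z_off == pytest.approx(5.0)
        assert res.z_on == pytest.approx(9.0)
        assert res.e == pytest.approx(9 / 14)

    def test_overlap_exclusion(self):
        params = simple_params({"A": "activator"}, alpha=2.0)
        sites = [make_site("A", 0, 5), make_site("A", 3, 8)]
        res = brute_force_partition(sites, np.ones(2), params, "g")
        assert res.e == pytest.approx(5 / 8)

    def test_cooperative_pair_carries_omega_squared(self):
        params = simple_params({"A": "activator"}, alpha=2.0, omega=2.0,
                               coop_range=10)
        sites = [make_site("A", 0, 5), make_site("A", 7, 12)]
        res = partition_functions(sites, np.ones(2), params, "g")
        assert res.z_off == pytest.approx(7.0)
        assert res.z_on == pytest.approx(21.0)
        assert res.e == pytest.approx(0.75)

    def test_omega_per_pair_convention(self):
        params = simple_params({"A": "activator"}, alpha=2.0, omega=2.0,
                               coop_range=10)
        params.omega_per_pair = True
        sites = [make_site("A", 0, 5), make_site("A", 7, 12)]
        res = partition_functions(sites, np.ones(2), params, "g")
        assert res.z_off == pytest.approx(1 + 1 + 1 + 2.0)

    def test_all_zero_weights(self):
        params = simple_params({"A": "activator"})
        sites = [make_site("A", 0, 5), make_site("A", 10, 15)]
        res = partition_functions(sites, np.zeros(2), params, "g")
        assert res.e == 0.5

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            sites, weights, params = random_instance(rng)
            bf = brute_force_partition(sites, weights, params, "g")
            dp = partition_functions(sites, weights, params, "g")
            assert dp.z_on == pytest.approx(bf.z_on, rel=1e-10)
            assert dp.z_off == pytest.approx(bf.z_off, rel=1e-10)

    def test_vectorized_weights_match_scalar_calls(self):
        rng = np.random.default_rng(7)
        sites, _, params = random_instance(rng, max_sites=6)
        w = rng.uniform(0, 2, size=(len(sites), 5))
        res = partition_functions(sites, w, params, "g")
        for m in range(5):
            single = partition_functions(sites, w[:, m], params, "g")
            assert res.e[m] == pytest.approx(float(single.e), rel=1e-12)

    def test_e_always_in_unit_interval(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            sites, weights, params = random_instance(rng)
            e = float(partition_functions(sites, weights, params, "g").e)
            assert 0.0 < e < 1.0


class TestSiteDelta:
    def _setup(self):
        pwm = PWM("A", np.array([[1.0, 0.0, -1.0, 0.0],
                                 [0.5, 0.5, 0.0, -0.5]]))
        params = simple_params({"A": "activator"}, K=2.0)
        region = RegulatoryRegion("g", "AAAA")
        sites = scan_sites(region, {"A": pwm}, {"A": 1.4})
        return pwm, params, region, sites[0]

    def test_symmetric_column_gives_zero_delta(self):
        pwm, params, region, site = self._setup()
        d = site_delta(site, 1, "C", pwm, 1.0, params, region.sequence)
        assert d.delta == pytest.approx(0.0)  # col2 A and C entries equal
        assert d.q_mut == pytest.approx(d.q_ref)

    def test_example_mutation(self):
        pwm, params, region, site = self._setup()
        d = site_delta(site, 1, "T", pwm, 1.0, params, region.sequence)
        assert d.delta == pytest.approx(math.exp(-0.5) - math.exp(0.5))
        # identity against direct recomputation of the mutated window
        from gapvar.annotate import pwm_score
        q_direct = (2.0 * math.exp(pwm_score("AT", pwm) - pwm.max_score))
        assert d.q_mut == pytest.approx(q_direct, rel=1e-12)

    def test_identity_on_random_triples(self):
        """q(S~) = q(S) + q(Sbar)*delta to machine precision, 500 triples."""
        from gapvar.annotate import pwm_score

        rng = np.random.default_rng(11)
        for _ in range(500):
            k = int(rng.integers(2, 9))
            pwm = PWM("A", rng.normal(size=(k, 4)))
            params = simple_params({"A": "activator"},
                                   K=float(rng.uniform(0.5, 5)))
            seq = "".join(rng.choice(list("ACGT"), size=k))
            strand = "+" if rng.random() < 0.5 else "-"
            site = make_site("A", 0, k, strand=strand,
                             score=pwm_score(seq, pwm, strand))
            j = int(rng.integers(k))
            new = rng.choice([c for c in "ACGT" if c != seq[j]])
            conc = float(rng.uniform(0.1, 3))
            d = site_delta(site, j, new, pwm, conc, params, seq)
            mut_seq = seq[:j] + new + seq[j + 1:]
            q_direct = (params.tf_params("A").K * conc
                        * math.exp(pwm_score(mut_seq, pwm, strand)
                                   - pwm.max_score))
            assert d.q_mut == pytest.approx(q_direct, rel=1e-12)

    def test_out_of_range_position_raises(self):
        pwm, params, region, site = self._setup()
        with pytest.raises(ValueError):
            site_delta(site, 5, "C", pwm, 1.0, params, region.sequence)

    def test_same_nucleotide_raises(self):
        pwm, params, region, site = self._setup()
        with pytest.raises(ValueError):
            site_delta(site, 0, "A", pwm, 1.0, params, region.sequence)


class TestPerturbedActivation:
    def _instance(self, rng):
        from gapvar.annotate import pwm_score

        k = 5
        pwm = PWM("A", rng.normal(size=(k, 4)))
        roles = {"A": "activator", "R": "repressor"}
        params = simple_params(roles, rep_range=6)
        seq = "".join(rng.choice(list("ACGT"), size=40))
        sites = []
        for start in (0, 8, 20, 30):
            tf = "A" if start % 16 == 0 else "R"
            window = seq[start:start + k]
            sites.append(make_site(tf, start, start + k,
                                   score=pwm_score(window, pwm)))
        weights = rng.uniform(0.2, 2, size=len(sites))
        return pwm, params, seq, sites, weights

    def test_zero_deltas_reproduce_reference(self):
        rng = np.random.default_rng(3)
        pwm, params, seq, sites, weights = self._instance(rng)
        res = perturbed_activation(sites, [], weights, params, "g")
        ref = partition_functions(sites, weights, params, "g")
        assert float(res.e) == pytest.approx(float(ref.e))

    def test_equals_full_recomputation(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            pwm, params, seq, sites, weights = self._instance(rng)
            idx = int(rng.integers(len(sites)))
            site = sites[idx]
            j = int(rng.integers(site.length))
            old = seq[site.start + j]
            new = rng.choice([c for c in "ACGT" if c != old])
            conc = weights[idx] / (params.tf_params(site.tf_name).K
                                   * math.exp(site.score - pwm.max_score))
            d = site_delta(site, j, new, pwm, conc, params, seq)
            res = perturbed_activation(sites, [d], weights, params, "g")
            w2 = weights.copy()
            w2[idx] = d.q_mut
            direct = partition_functions(sites, w2, params, "g")
            assert float(res.e) == pytest.approx(float(direct.e), rel=1e-10)

    def test_two_deltas_on_one_site_rejected(self):
        rng = np.random.default_rng(5)
        pwm, params, seq, sites, weights = self._instance(rng)
        site = sites[0]
        conc = 1.0
        d1 = site_delta(site, 0, "A" if seq[site.start] != "A" else "C",
                        pwm, conc, params, seq)
        with pytest.raises(ValueError, match="one delta per site"):
            perturbed_activation(sites, [d1, d1], weights, params, "g")

    def test_partition_sums_affine_in_each_delta(self):
        """Second finite difference of Z_ON and Z_OFF in a single weight
        perturbation vanishes (multilinear response structure)."""
        rng = np.random.default_rng(6)
        for _ in range(50):
            sites, weights, params = random_instance(rng, max_sites=8)
            idx = int(rng.integers(len(sites)))
            vals = []
            for eps in (0.0, 0.5, 1.0):
                w = weights.copy()
                w[idx] = weights[idx] + eps
                res = partition_functions(sites, w, params, "g")
                vals.append((float(res.z_on), float(res.z_off)))
            for comp in range(2):
                a, b, c = (v[comp] for v in vals)
                second = a - 2 * b + c
                scale = max(abs(a), abs(c), 1e-300)
                assert abs(second) / scale < 1e-9


class TestActivationSensitivity:
    def test_neutral_tf_zero_derivative(self):
        params = ThermoParams(
            tf={"A": TFParams(K=1.0)},
            regulation={("A", "g"): RegulationParams("activator",
                                                     alpha=1.0 + 1e-12)},
        )
        s = activation_sensitivity([make_site("A", 0, 5)], np.array([1.0]),
                                   params, 0, "g")
        assert s == pytest.approx(0.0, abs=1e-9)

    def test_single_activator_closed_form(self):
        params = simple_params({"A": "activator"}, alpha=3.0)
        s = activation_sensitivity([make_site("A", 0, 5)], np.array([1.0]),
                                   params, 0, "g")
        assert s == pytest.approx(1 / 18, rel=1e-6)

    def test_signs_for_isolated_roles(self):
        params = simple_params({"A": "activator", "R": "repressor"},
                               alpha=3.0, beta=1.5, rep_range=6)
        sites = [make_site("A", 0, 5), make_site("R", 8, 13)]
        w = np.array([1.0, 0.8])
        assert activation_sensitivity(sites, w, params, 0, "g") > 0
        assert activation_sensitivity(sites, w, params, 1, "g") < 0

    def test_agrees_with_central_differences(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            sites, weights, params = random_instance(rng, max_sites=6)
            idx = int(rng.integers(len(sites)))
            s = activation_sensitivity(sites, weights, params, idx, "g")

            def e_at(q):
                w = weights.copy()
                w[idx] = q
                return float(partition_functions(sites, w, params, "g").e)

            h = max(1e-6 * weights[idx], 1e-7)
            fd = (e_at(weights[idx] + h) - e_at(weights[idx] - h)) / (2 * h)
            assert s == pytest.approx(fd, rel=1e-5, abs=1e-10)


class TestLocalContext:
    def _params(self):
        return simple_params(
            {"A1": "activator", "A2": "activator",
             "R1": "repressor", "R2": "repressor"},
            rep_range=8,
        )

    def test_lone_site_is_independent(self):
        params = self._params()
        site = make_site("A1", 10, 15)
        assert classify_local_context(site, [site], params, 12) \
            == {"independent"}

    def test_overlap_same_type(self):
        params = self._params()
        s1 = make_site("A1", 10, 15)
        s2 = make_site("A2", 13, 18)
        labels = classify_local_context(s1, [s1, s2], params, 11)
        assert labels == {"overlap_same_type"}

    def test_snp_in_overlap(self):
        params = self._params()
        s1 = make_site("A1", 10, 15)
        s2 = make_site("R1", 13, 18)
        labels = classify_local_context(s1, [s1, s2], params, 14)
        assert "snp_in_overlap" in labels

    def test_shared_repression_direct(self):
        params = self._params()
        r1 = make_site("R1", 0, 5)
        act = make_site("A1", 8, 13)
        r2 = make_site("R2", 16, 21)
        labels = classify_local_context(r1, [r1, act, r2], params, 2)
        assert "shared_repression_direct" in labels

    def test_shared_repression_mediated(self):
        params = self._params()
        # R1 -- within range of R2 -- R2 within range of A; A out of R1 range
        r1 = make_site("R1", 0, 5)
        r2 = make_site("R2", 10, 15)
        act = make_site("A1", 20, 25)
        labels = classify_local_context(r1, [r1, r2, act], params, 2)
        assert "shared_repression_mediated" in labels

    def test_snp_outside_site_raises(self):
        params = self._params()
        site = make_site("A1", 10, 15)
        with pytest.raises(ValueError):
            classify_local_context(site, [site], params, 20)
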