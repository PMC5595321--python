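"""SNP tables, genotype application, SNV enumeration, SFS, families."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gapvar.annotate import RegulatoryRegion
from gapvar.population import (SFS, SNP, Genotype, SNPTable, apply_genotype,
                               enumerate_snvs, estimate_sfs,
                               filter_snp_table, model_site_union,
                               simulate_family)

from .conftest import make_site


def raw_table(cells, gene="g", pos=None, ref=None, alt=None):
    """Raw nucleotide-call table: cells is {row_index: [calls per genotype]}."""
    n_gen = len(next(iter(cells.values())))
    gens = [f"g{j}" for j in range(n_gen)]
    rows = []
    for i, calls in cells.items():
        rows.append(
            dict(gene=gene, pos=(pos or {}).get(i, i),
                 ref=(ref or {}).get(i, "A"), alt=(alt or {}).get(i, ""),
                 **dict(zip(gens, calls)))
        )
    return pd.DataFrame(rows)


class TestFilterSnpTable:
    def test_triallelic_row_dropped(self):
        raw = raw_table({0: ["A", "C", "G", "A"]})
        t = filter_snp_table(raw, min_coverage=2)
        assert t.n_rows == 0

    def test_heterozygous_call_becomes_missing(self):
        raw = raw_table({0: ["A/C", "C", "A", "A"]})
        t = filter_snp_table(raw, min_coverage=3, downsample=False)
        assert t.n_rows == 1
        assert t.calls[0, 0] == -1
        assert t.coverage()[0] == 3

    def test_low_coverage_row_excluded_from_density_set(self):
        raw = raw_table({0: ["A", "C", ".", "."]})  # coverage 2 < 4
        t = filter_snp_table(raw, min_coverage=4, downsample=True)
        assert t.n_rows == 0

    def test_effect_scoring_mode_keeps_all_polymorphic_rows(self):
        raw = raw_table({0: ["A", "C", ".", "."]})
        t = filter_snp_table(raw, min_coverage=4, downsample=False)
        assert t.n_rows == 1 and t.rows["polymorphic"].iat[0]

    def test_downsampling_to_exact_depth(self):
        raw = raw_table({0: ["A", "C", "C", "A", "A", "C"]})
        t = filter_snp_table(raw, min_coverage=4, downsample=True, seed=0)
        assert t.coverage()[0] == 4

    def test_monomorphic_after_downsampling_flagged(self):
        rng_hits = 0
        for seed in range(30):
            raw = raw_table({0: ["C", "A", "A", "A", "A"]})
            t = filter_snp_table(raw, min_coverage=3, downsample=True,
                                 seed=seed)
            if not t.rows["polymorphic"].iat[0]:
                rng_hits += 1
                assert t.alt_counts()[0] == 0
        assert rng_hits > 0  # the single alt call is sometimes dropped

    def test_bad_genotypes_dropped(self):
        raw = raw_table({0: ["A", "C", "C"]})
        t = filter_snp_table(raw, min_coverage=2, downsample=False,
                             drop_genotypes=["g0"])
        assert t.genotypes == ["g1", "g2"]

    def test_ref_mismatch_raises(self):
        raw = raw_table({0: ["A", "C"]})
        with pytest.raises(ValueError, match="mismatch"):
            filter_snp_table(raw, reference={"g": "CCCC"},
                             min_coverage=2, downsample=False)


class TestApplyGenotype:
    def _region(self):
        return RegulatoryRegion("g", "ACGTACGTAC", accessible=[(0, 10)])

    def test_empty_genotype_is_identity(self):
        region = self._region()
        mut, _ = apply_genotype(region, Genotype("x"))
        assert mut.sequence == region.sequence

    def test_substitution_and_roundtrip(self):
        region = self._region()
        snp = SNP("g", 3, "T", "G")
        mut, _ = apply_genotype(region, Genotype("x", (snp,)))
        assert mut.sequence[3] == "G"
        back, _ = apply_genotype(mut, Genotype("y", (SNP("g", 3, "G", "T"),)))
        assert back.sequence == region.sequence

    def test_only_overlapping_sites_rescored(self):
        from gapvar.annotate import PWM
        region = self._region()
        pwm = PWM("t", np.ones((2, 4)))
        sites = [make_site("t", 0, 2, score=2.0),
                 make_site("t", 4, 6, score=2.0)]
        snp = SNP("g", 0, "A", "C")
        _, new_sites = apply_genotype(region, Genotype("x", (snp,)),
                                      sites, {"t": pwm})
        assert new_sites[0].score == pytest.approx(2.0)  # rescored, same pwm
        assert new_sites[1] is sites[1]  # untouched object

    def test_overlapping_sites_both_rescored(self):
        from gapvar.annotate import PWM
        region = self._region()
        pwm = PWM("t", np.zeros((4, 4)))
        sites = [make_site("t", 0, 4, score=1.0),
                 make_site("t", 2, 6, score=1.0)]
        snp = SNP("g", 3, "T", "G")
        _, new_sites = apply_genotype(region, Genotype("x", (snp,)),
                                      sites, {"t": pwm})
        assert new_sites[0] is not sites[0]
        assert new_sites[1] is not sites[1]

    def test_ref_mismatch_raises(self):
        region = self._region()
        with pytest.raises(ValueError, match="mismatch"):
            apply_genotype(region, Genotype("x", (SNP("g", 3, "A", "G"),)))


class TestEnumerateSnvs:
    def test_single_position(self):
        snvs = enumerate_snvs([make_site("t", 0, 1)], {"g": "A"})
        assert len(snvs) == 3
        assert {s.alt for s in snvs} == {"C", "G", "T"}

    def test_overlapping_sites_counted_once(self):
        ref = {"g": "A" * 30}
        sites = [make_site("t", 10, 20), make_site("t", 15, 25)]
        snvs = enumerate_snvs(sites, ref)
        assert len(snvs) == 3 * 15

    def test_union_size_scaling(self):
        # three disjoint sites totalling 20 bp -> 60 SNVs
        ref = {"g": "ACGT" * 10}
        sites = [make_site("t", 0, 5), make_site("t", 10, 20),
                 make_site("t", 25, 30)]
        assert len(enumerate_snvs(sites, ref)) == 60

    def test_nonmodel_sites_excluded(self):
        ref = {"g": "A" * 10}
        sites = [make_site("t", 0, 5, is_model=False)]
        assert enumerate_snvs(sites, ref) == []


class TestSfs:
    def _table(self, alt_counts, n_gen=6):
        rows = pd.DataFrame(
            [dict(gene="g", pos=i, ref="A", alt="C", polymorphic=True)
             for i in range(len(alt_counts))]
        )
        calls = np.zeros((len(alt_counts), n_gen), dtype=int)
        for i, c in enumerate(alt_counts):
            calls[i, :c] = 1
        return SNPTable(rows=rows, calls=calls,
                        genotypes=[f"g{j}" for j in range(n_gen)])

    def test_histogram_example(self):
        sfs = estimate_sfs(self._table([1, 1, 2]))
        assert sfs.probs[1] == pytest.approx(2 / 3)
        assert sfs.probs[2] == pytest.approx(1 / 3)

    def test_single_row_point_mass(self):
        sfs = estimate_sfs(self._table([3]))
        assert sfs.probs == {3: 1.0}

    def test_normalization(self):
        sfs = estimate_sfs(self._table([1, 2, 3, 2, 1]))
        assert sum(sfs.probs.values()) == pytest.approx(1.0)

    def test_no_polymorphic_rows_raises(self):
        t = self._table([1])
        t.rows["polymorphic"] = False
        with pytest.raises(ValueError):
            estimate_sfs(t)

    def test_rescaled_count_stays_polymorphic(self):
        sfs = SFS({1: 0.5, 9: 0.5}, sample_size=10)
        rng = np.random.default_rng(0)
        counts = [sfs.sample_count(rng, 5) for _ in range(200)]
        assert all(1 <= c <= 4 for c in counts)


class TestSimulateFamily:
    def _setup(self):
        ref = {"g": "ACGT" * 50}
        sites = [make_site("t", 0, 60), make_site("t", 80, 140)]
        return ref, sites

    def test_total_snp_constraint_exact(self):
        ref, sites = self._setup()
        fam = simulate_family(sites, ref, sfs=SFS.watterson(20),
                              mode="neutral", n_genotypes=20, total_snps=40,
                              seed=1)
        positions = {(s.gene, s.pos) for s in fam.snps}
        assert len(positions) == 40
        union = set(model_site_union(sites)["g"])
        assert all(p in union for _, p in positions)

    def test_population_mode_preserves_count_multiset(self):
        ref, sites = self._setup()
        template = [0, 1, 1, 3, 5]
        fam = simulate_family(sites, ref, template_counts=template,
                              mode="population", n_genotypes=5, total_snps=0,
                              seed=2)
        counts = sorted(len(g.snps) for g in fam.genotypes)
        assert counts == sorted(template)

    def test_same_seed_reproduces_family(self):
        ref, sites = self._setup()
        kw = dict(sfs=SFS.watterson(10), mode="neutral", n_genotypes=10,
                  total_snps=15, seed=7)
        f1 = simulate_family(sites, ref, **kw)
        f2 = simulate_family(sites, ref, **kw)
        assert f1.snps == f2.snps
        assert [g.snps for g in f1.genotypes] == [g.snps for g in f2.genotypes]

    def test_infeasible_constraint_raises(self):
        ref = {"g": "A" * 20}
        sites = [make_site("t", 0, 5)]
        with pytest.raises(ValueError):
            simulate_family(sites, ref, sfs=SFS.watterson(5), mode="neutral",
                            n_genotypes=5, total_snps=10, seed=0)

    def test_neutral_allele_counts_follow_sfs(self):
        """Aggregated carrier counts converge to the input spectrum."""
        ref = {"g": "ACGT" * 200}
        sites = [make_site("t", 0, 800)]
        sfs = SFS({1: 0.5, 2: 0.3, 5: 0.2}, sample_size=20)
        observed = {}
        for seed in range(40):
            fam = simulate_family(sites, ref, sfs=sfs, mode="neutral",
                                  n_genotypes=20, total_snps=100, seed=seed)
            tab = fam.snp_table()
            for c in tab.alt_counts():
                observed[int(c)] = observed.get(int(c), 0) + 1
        total = sum(observed.values())
        support = sorted(sfs.probs)
        obs = np.array([observed.get(c, 0) for c in support], dtype=float)
        exp = np.array([sfs.probs[c] * total for c in support])
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = 1 - stats.chi2.cdf(chi2, df=len(support) - 1)
        assert p > 0.01
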