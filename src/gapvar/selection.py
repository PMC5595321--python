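"""Resampling statistics for detecting purifying selection.

All resampling p-values follow the (1 + k) / (1 + n) convention (k null
draws as or more extreme than the observation among n), which never
returns zero with finite resamples.  The SNP-density comparison between
model binding sites and other sequence classes uses a major-allele-matched
bootstrap to control for GC-content and length confounds.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .population import ALT, MISSING

__all__ = [
    "DensityEstimate",
    "AdditivityResult",
    "matched_bootstrap_density",
    "density_difference_pvalue",
    "resample_counts_test",
    "additivity_analysis",
    "family_pvalue",
    "permutation_corr_test",
    "bootstrap_dist_test",
]


@dataclass
class DensityEstimate:
    """Bootstrap SNP-density replicates (polymorphic fraction per bp).

    ``paired_poly`` (on the focal member of a pair of estimates) holds one
    canonical matched-pair outcome sample per outer fold: an array of
    (focal polymorphic, partner polymorphic) 0/1 pairs used by the exact
    sign-flip test.
    """

    densities: np.ndarray  # shape (n_resample, n_boot)
    n_unmatched: int = 0
    paired_poly: np.ndarray | None = None  # (n_resample, n_pairs, 2)

    @property
    def flat(self):
        return self.densities.ravel()

    @property
    def median(self):
        return float(np.median(self.flat))


def _row_state(calls, rows, depth, rng):
    """Down-sample each row to ``depth`` non-missing genotypes; return
    (major allele, polymorphic flag) per row.  Rows below depth -> None."""
    majors = np.empty(calls.shape[0], dtype=object)
    poly = np.zeros(calls.shape[0], dtype=bool)
    usable = np.zeros(calls.shape[0], dtype=bool)
    for i in range(calls.shape[0]):
        present = np.flatnonzero(calls[i] != MISSING)
        if present.size < depth:
            continue
        take = (present if present.size == depth
                else rng.choice(present, size=depth, replace=False))
        sub = calls[i, take]
        n_alt = int((sub == ALT).sum())
        n_ref = depth - n_alt
        majors[i] = rows["alt"].iat[i] if n_alt > n_ref else rows["ref"].iat[i]
        poly[i] = 0 < n_alt < depth
        usable[i] = True
    return majors, poly, usable


def matched_bootstrap_density(focal_idx, other_idx, table, n_boot=500,
                              n_resample=20, depth=170, seed=None):
    """Major-allele-matched bootstrap SNP densities for two region classes.

    ``focal_idx`` and ``other_idx`` index rows of ``table`` (every position
    of each class must have a row; monomorphic positions carry
    ``polymorphic=False``).  Outer loop: down-sample genotypes to
    ``depth``.  Each focal position is paired with the other-class
    positions sharing its major allele; the inner bootstrap samples pairs
    with replacement until the pair count equals the focal length and
    reports the polymorphic fraction of each member.  Focal positions with
    no partner are skipped and counted.

    Returns (focal DensityEstimate, other DensityEstimate).
    """
    rng = np.random.default_rng(seed)
    focal_idx = np.asarray(focal_idx, dtype=int)
    other_idx = np.asarray(other_idx, dtype=int)
    out_f = np.empty((n_resample, n_boot))
    out_o = np.empty((n_resample, n_boot))
    n_unmatched = 0
    paired = []
    for r in range(n_resample):
        majors, poly, usable = _row_state(table.calls, table.rows, depth, rng)
        foc = focal_idx[usable[focal_idx]]
        oth = other_idx[usable[other_idx]]
        partners = []
        matched_focal = []
        for i in foc:
            mates = oth[majors[oth] == majors[i]]
            if mates.size == 0:
                n_unmatched += 1
                continue
            partners.append(mates)
            matched_focal.append(i)
        if not matched_focal:
            raise ValueError("no focal position has a matchable partner")
        matched_focal = np.array(matched_focal)
        lengths = np.array([p.size for p in partners])
        pad = np.zeros((len(partners), lengths.max()), dtype=int)
        for j, p in enumerate(partners):
            pad[j, : p.size] = p
        n_pairs = foc.size  # sample until pair count = focal length
        pick = rng.integers(matched_focal.size, size=(n_boot, n_pairs))
        mate_col = (rng.random((n_boot, n_pairs)) * lengths[pick]).astype(int)
        mates = pad[pick, mate_col]
        out_f[r] = poly[matched_focal[pick]].mean(axis=1)
        out_o[r] = poly[mates].mean(axis=1)
        # one canonical matched-pair outcome sample for the sign-flip test;
        # mates are assigned distinct where the pool allows so the pair
        # differences stay (near-)independent
        canon_mate = np.empty(len(partners), dtype=int)
        taken = set()
        order = rng.permutation(len(partners))
        for j in order:
            pool = partners[j]
            free = pool[~np.isin(pool, list(taken))] if taken else pool
            choice_pool = free if free.size else pool
            m = int(choice_pool[rng.integers(choice_pool.size)])
            canon_mate[j] = m
            taken.add(m)
        paired.append(np.stack([poly[matched_focal],
                                poly[canon_mate]], axis=1).astype(int))
    paired = np.array(paired)
    return (DensityEstimate(out_f, n_unmatched, paired_poly=paired),
            DensityEstimate(out_o, n_unmatched))


def density_difference_pvalue(focal: DensityEstimate,
                              other: DensityEstimate,
                              n_null: int = 999, seed: int | None = None) -> float:
    """Two-sided p for the focal vs other SNP-density difference.

    Exact under the null: within a matched pair the two polymorphism
    outcomes are exchangeable, so the observed summed pair difference is
    compared against its sign-flip permutation distribution (pairs pooled
    over the outer genotype-resampling folds).
    """
    if focal.paired_poly is None:
        raise ValueError("focal estimate carries no matched-pair sample")
    rng = np.random.default_rng(seed)
    d = (focal.paired_poly[..., 0] - focal.paired_poly[..., 1]).ravel()
    active = d[d != 0]
    if active.size == 0:
        return 1.0
    obs = active.sum()
    signs = rng.choice([-1, 1], size=(n_null, active.size))
    nulls = (signs * np.abs(active)).sum(axis=1)
    hi = (1 + int((nulls >= obs).sum())) / (1 + n_null)
    lo = (1 + int((nulls <= obs).sum())) / (1 + n_null)
    return min(1.0, 2.0 * min(hi, lo))


def _resample_p(k, n):
    return (1 + k) / (1 + n)


def resample_counts_test(observed_stat, null_sampler, n=1000, tail="upper",
                         seed=None) -> float:
    """Monte-Carlo p-value of an observed statistic against a null sampler.

    ``null_sampler(rng)`` draws one null statistic per call.
    """
    if n < 1:
        raise ValueError("need at least one resample")
    rng = np.random.default_rng(seed)
    nulls = np.array([null_sampler(rng) for _ in range(n)], dtype=float)
    upper = _resample_p(int((nulls >= observed_stat).sum()), n)
    lower = _resample_p(int((nulls <= observed_stat).sum()), n)
    if tail == "upper":
        return upper
    if tail == "lower":
        return lower
    if tail == "two-sided":
        return min(1.0, 2.0 * min(upper, lower))
    raise ValueError(f"unknown tail {tail!r}")


@dataclass
class AdditivityResult:
    """Genotype score vs. summed single-SNP scores, against y = x."""

    x: np.ndarray  # sum of per-SNP Delta-v components
    y: np.ndarray  # genotype Delta-v components
    labels: np.ndarray  # 'single_dominant' or 'competing'
    deviation: float  # mean perpendicular distance |y - x| / sqrt(2)


def additivity_analysis(genotype_dv, snp_dv_sets, prevalence_threshold=0.7,
                        tol=0.0):
    """Collect (sum of SNP scores, genotype score) pairs per grid component.

    ``genotype_dv`` maps genotype id -> Delta-v vector; ``snp_dv_sets``
    maps genotype id -> list of per-SNP Delta-v vectors (the SNPs carried
    by that genotype, each simulated alone).  A component k enters when at
    least two SNPs of the genotype have non-vanishing (|dv| > tol)
    influence there; components belong to a single gene's pattern and a
    SNP only perturbs its own gene's region, so such SNPs necessarily
    share the gene.

    A point is 'competing' iff (largest - sum of rest) < threshold *
    largest for the absolute per-SNP scores at that component, else
    'single_dominant'.  The deviation is the mean perpendicular distance
    |y - x| / sqrt(2) to the additivity line y = x.
    """
    xs, ys, labels = [], [], []
    for gid, dv_gen in genotype_dv.items():
        dv_snps = snp_dv_sets.get(gid, [])
        if not dv_snps:
            continue
        dv_snps = np.asarray(dv_snps, dtype=float)
        dv_gen = np.asarray(dv_gen, dtype=float)
        active = np.abs(dv_snps) > tol
        multi = active.sum(axis=0) >= 2
        for k in np.flatnonzero(multi):
            col = dv_snps[:, k]
            xs.append(col.sum())
            ys.append(dv_gen[k])
            mags = np.sort(np.abs(col[active[:, k]]))[::-1]
            largest, rest = mags[0], mags[1:].sum()
            labels.append(
                "competing"
                if (largest - rest) < prevalence_threshold * largest
                else "single_dominant"
            )
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    dev = float(np.mean(np.abs(y - x)) / math.sqrt(2)) if x.size else 0.0
    return AdditivityResult(x=x, y=y, labels=np.asarray(labels), deviation=dev)


def family_pvalue(population_stat, family_stats, tail="lower") -> float:
    """p = (1 + #{families as or more extreme}) / (1 + n_families)."""
    fam = np.asarray(family_stats, dtype=float)
    if fam.size == 0:
        raise ValueError("empty family list")
    if tail == "lower":
        k = int((fam <= population_stat).sum())
    elif tail == "upper":
        k = int((fam >= population_stat).sum())
    elif tail == "two-sided":
        return min(
            1.0,
            2.0 * min(
                family_pvalue(population_stat, fam, "lower"),
                family_pvalue(population_stat, fam, "upper"),
            ),
        )
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return _resample_p(k, fam.size)


def permutation_corr_test(x, y, n_perm=1000, method="rank", tail="two-sided",
                          seed=None):
    """Correlation coefficient with a permutation p-value.

    Spearman ('rank') or Pearson ('linear'); y is permuted ``n_perm``
    times, or all permutations are enumerated when n! <= n_perm.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")

    if method == "rank":
        corr = lambda a, b: stats.spearmanr(a, b).statistic
    elif method == "linear":
        corr = lambda a, b: stats.pearsonr(a, b).statistic
    else:
        raise ValueError(f"unknown method {method!r}")

    obs = float(corr(x, y))
    n = x.size
    exhaustive = math.factorial(n) <= n_perm
    if exhaustive:
        nulls = np.array(
            [corr(x, np.array(p)) for p in itertools.permutations(y)]
        )
    else:
        rng = np.random.default_rng(seed)
        nulls = np.array(
            [corr(x, rng.permutation(y)) for _ in range(n_perm)]
        )
    m = nulls.size
    if exhaustive:
        # exact test: the observed permutation is one of the enumerated ones
        upper = (nulls >= obs - 1e-12).sum() / m
        lower = (nulls <= obs + 1e-12).sum() / m
    else:
        upper = _resample_p(int((nulls >= obs - 1e-12).sum()), m)
        lower = _resample_p(int((nulls <= obs + 1e-12).sum()), m)
    if tail == "upper":
        p = upper
    elif tail == "lower":
        p = lower
    elif tail == "two-sided":
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return obs, float(p)


def _ks_statistic(a, b):
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def _chisq_statistic(a, b, edges):
    ca, _ = np.histogram(a, bins=edges)
    cb, _ = np.histogram(b, bins=edges)
    tot = ca + cb
    mask = tot > 0
    ea = tot * a.size / (a.size + b.size)
    eb = tot * b.size / (a.size + b.size)
    return float(
        (((ca - ea) ** 2 / np.where(ea > 0, ea, 1))[mask]).sum()
        + (((cb - eb) ** 2 / np.where(eb > 0, eb, 1))[mask]).sum()
    )


def _pooled_decile_edges(pooled, n1, n2, min_expected=5):
    """Decile bins of the pooled sample, merged until expected counts >= 5."""
    qs = np.quantile(pooled, np.linspace(0, 1, 11))
    edges = np.unique(qs)
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    frac1 = n1 / (n1 + n2)
    while edges.size > 2:
        counts, _ = np.histogram(pooled, bins=edges)
        expected = counts * min(frac1, 1 - frac1)
        if np.all(expected >= min_expected):
            break
        j = int(np.argmin(expected))
        drop = j + 1 if j + 1 < edges.size - 1 else j
        edges = np.delete(edges, drop)
    return edges


def bootstrap_dist_test(sample1, sample2, statistic="ks", n_boot=999,
                        seed=None) -> float:
    """Two-sample bootstrap test: observed KS or chi-square statistic
    against its null from resampling both samples from the pooled data."""
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    if statistic == "ks":
        stat = lambda x, y: _ks_statistic(x, y)
    elif statistic == "chisq":
        edges = _pooled_decile_edges(pooled, a.size, b.size)
        stat = lambda x, y: _chisq_statistic(x, y, edges)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    obs = stat(a, b)
    k = 0
    for _ in range(n_boot):
        ra = rng.choice(pooled, size=a.size, replace=True)
        rb = rng.choice(pooled, size=b.size, replace=True)
        if stat(ra, rb) >= obs - 1e-12:
            k += 1
    return _resample_p(k, n_boot)
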