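"""Population polymorphism data: SNP tables, genotypes, SFS, families.

A SNP table holds biallelic polymorphic positions (rows) against haploid
genotypes (columns) with calls in {ref, alt, missing}.  Raw tables carry
nucleotide calls ('A', 'C/G' for heterozygous, '.' for missing) and are
filtered into the biallelic 0/1/-1 form; heterozygous diploid calls are
relabeled missing because the expression model is haploid.  Families of
randomly mutated genotypes are simulated inside the model-TFBS position
union, either under a neutral site frequency spectrum or mirroring the
per-genotype SNP counts of the study population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import rescore_sites

__all__ = [
    "SNP",
    "SNPTable",
    "Genotype",
    "SFS",
    "Family",
    "filter_snp_table",
    "apply_genotype",
    "enumerate_snvs",
    "estimate_sfs",
    "simulate_family",
    "model_site_union",
]

MISSING = -1
REF = 0
ALT = 1


@dataclass(frozen=True)
class SNP:
    gene: str
    pos: int
    ref: str
    alt: str


@dataclass
class SNPTable:
    """Biallelic SNP calls: ``calls`` is (n_rows, n_genotypes) of 0/1/-1.

    ``rows`` is a DataFrame with columns gene, pos, ref, alt and a boolean
    ``polymorphic`` flag; ``genotypes`` names the columns of ``calls``.
    """

    rows: pd.DataFrame
    calls: np.ndarray
    genotypes: list

    def __post_init__(self):
        if self.calls.shape != (len(self.rows), len(self.genotypes)):
            raise ValueError("calls shape mismatch")

    @property
    def n_rows(self):
        return len(self.rows)

    def coverage(self) -> np.ndarray:
        return (self.calls != MISSING).sum(axis=1)

    def alt_counts(self) -> np.ndarray:
        return (self.calls == ALT).sum(axis=1)

    def major_alleles(self) -> np.ndarray:
        """Most frequent nucleotide among non-missing calls per row; ties
        broken toward the reference allele."""
        alt = self.alt_counts()
        cov = self.coverage()
        ref_n = cov - alt
        out = np.where(alt > ref_n, self.rows["alt"], self.rows["ref"])
        return np.asarray(out)

    def polymorphic_mask(self) -> np.ndarray:
        return self.rows["polymorphic"].to_numpy()

    def row_snp(self, i) -> SNP:
        r = self.rows.iloc[i]
        return SNP(r["gene"], int(r["pos"]), r["ref"], r["alt"])

    def to_frame(self) -> pd.DataFrame:
        df = self.rows.copy()
        sym = np.array([".", "0", "1"])
        for j, g in enumerate(self.genotypes):
            df[g] = sym[self.calls[:, j] + 1]
        return df

    @classmethod
    def from_frame(cls, df) -> "SNPTable":
        meta_cols = ["gene", "pos", "ref", "alt"]
        extra = ["polymorphic"] if "polymorphic" in df.columns else []
        gens = [c for c in df.columns if c not in meta_cols + extra]
        calls = np.empty((len(df), len(gens)), dtype=int)
        code = {".": MISSING, "0": REF, "1": ALT, 0: REF, 1: ALT}
        for j, g in enumerate(gens):
            calls[:, j] = [code[str(x)] for x in df[g]]
        rows = df[meta_cols].reset_index(drop=True).copy()
        if extra:
            rows["polymorphic"] = df["polymorphic"].to_numpy()
        else:
            alt = (calls == ALT).sum(axis=1)
            cov = (calls != MISSING).sum(axis=1)
            rows["polymorphic"] = (alt > 0) & (alt < cov)
        return cls(rows=rows, calls=calls, genotypes=gens)


@dataclass(frozen=True)
class Genotype:
    """A haploid genotype: the SNPs it carries relative to the reference."""

    id: str
    snps: tuple = ()

    def __post_init__(self):
        keys = [(s.gene, s.pos) for s in self.snps]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate SNP positions in genotype")


def filter_snp_table(raw: pd.DataFrame, reference=None, min_coverage=170,
                     downsample=True, drop_genotypes=(), seed=None):
    """Filter a raw nucleotide-call table into a biallelic SNPTable.

    Rows with more than two alleles are removed; configured bad genotypes
    dropped; heterozygous calls ('X/Y') relabeled missing.  With
    ``downsample`` (the density-analysis mode), rows with coverage below
    ``min_coverage`` are dropped and all others down-sampled to exactly
    ``min_coverage`` genotypes; rows monomorphic after down-sampling are
    flagged non-polymorphic.  Without it (effect-scoring mode) all rows
    are kept at full coverage.

    ``reference`` optionally maps gene -> sequence for ref-allele checks.
    """
    rng = np.random.default_rng(seed)
    raw = raw.drop(columns=list(drop_genotypes), errors="ignore")
    meta_cols = ["gene", "pos", "ref", "alt"]
    gens = [c for c in raw.columns if c not in meta_cols]

    kept_rows = []
    kept_calls = []
    for _, r in raw.iterrows():
        ref = str(r["ref"]).upper()
        if reference is not None:
            seq = reference[r["gene"]]
            if seq[int(r["pos"])].upper() != ref:
                raise ValueError(
                    f"ref allele mismatch at {r['gene']}:{r['pos']}"
                )
        cells = []
        for g in gens:
            c = str(r[g]).upper()
            cells.append("." if ("/" in c or c == ".") else c)
        alleles = sorted({c for c in cells if c != "."})
        if len(alleles) > 2:
            continue
        alt = str(r.get("alt", "")).upper()
        non_ref = [a for a in alleles if a != ref]
        if non_ref:
            alt = non_ref[0]
        elif not alt or alt == "NAN":
            continue  # monomorphic reference row with no declared alt
        calls = np.array(
            [MISSING if c == "." else (ALT if c == alt else REF)
             for c in cells],
            dtype=int,
        )
        cov = int((calls != MISSING).sum())
        if downsample:
            if cov < min_coverage:
                continue
            if cov > min_coverage:
                present = np.flatnonzero(calls != MISSING)
                keep = rng.choice(present, size=min_coverage, replace=False)
                new = np.full(calls.size, MISSING, dtype=int)
                new[keep] = calls[keep]
                calls = new
        n_alt = int((calls == ALT).sum())
        n_ref = int((calls == REF).sum())
        kept_rows.append(
            dict(gene=r["gene"], pos=int(r["pos"]), ref=ref, alt=alt,
                 polymorphic=(n_alt > 0 and n_ref > 0))
        )
        kept_calls.append(calls)
    rows = pd.DataFrame(kept_rows,
                        columns=meta_cols + ["polymorphic"])
    calls = (np.vstack(kept_calls) if kept_calls
             else np.empty((0, len(gens)), dtype=int))
    return SNPTable(rows=rows, calls=calls, genotypes=list(gens))


def apply_genotype(region, genotype: Genotype, sites=None, pwms=None):
    """Superimpose a genotype's SNPs onto the reference sequence.

    Returns (mutated_region, rescored_sites).  P_s is recomputed for every
    site whose window overlaps a SNP (site inventory fixed: no new sites).
    """
    seq = list(region.sequence)
    touched = set()
    for s in genotype.snps:
        if s.gene != region.gene:
            continue
        if not 0 <= s.pos < len(seq):
            raise ValueError(f"SNP position {s.pos} outside region")
        if seq[s.pos].upper() != s.ref.upper():
            raise ValueError(
                f"ref allele mismatch at {region.gene}:{s.pos} "
                f"(expected {s.ref}, found {seq[s.pos]})"
            )
        seq[s.pos] = s.alt.upper()
        touched.add(s.pos)
    mutated = region.with_sequence("".join(seq))
    new_sites = None
    if sites is not None:
        if pwms is None:
            raise ValueError("pwms required to re-score sites")
        hit = [s for s in sites
               if any(s.start <= p < s.end for p in touched)]
        rescored = {id(s): ns for s, ns in
                    zip(hit, rescore_sites(hit, mutated, pwms))}
        new_sites = [rescored.get(id(s), s) for s in sites]
    return mutated, new_sites


def model_site_union(sites):
    """Sorted position union of model-site intervals, per gene."""
    union = {}
    for s in sites:
        if s.is_model:
            union.setdefault(s.gene, set()).update(range(s.start, s.end))
    return {g: sorted(p) for g, p in union.items()}


def enumerate_snvs(model_sites, reference):
    """All single-nucleotide variants in the model-site position union.

    ``reference`` maps gene -> sequence.  Returns a list of SNPs: three
    alternative nucleotides per union position.
    """
    union = model_site_union(model_sites)
    out = []
    for gene in sorted(union):
        seq = reference[gene]
        for pos in union[gene]:
            ref = seq[pos].upper()
            for alt in "ACGT":
                if alt != ref:
                    out.append(SNP(gene, pos, ref, alt))
    return out


@dataclass(frozen=True)
class SFS:
    """Site frequency spectrum: distribution of alt-allele counts.

    ``probs`` maps derived-allele count -> probability; counts lie in
    [1, sample_size - 1].
    """

    probs: dict
    sample_size: int

    def __post_init__(self):
        p = dict(self.probs)
        total = sum(p.values())
        if total <= 0:
            raise ValueError("empty spectrum")
        if abs(total - 1.0) > 1e-9:
            p = {k: v / total for k, v in p.items()}
        for k in p:
            if not 1 <= k <= self.sample_size - 1:
                raise ValueError("spectrum support outside [1, n-1]")
        object.__setattr__(self, "probs", p)

    def sample_count(self, rng, n_genotypes):
        """Draw a derived-allele count rescaled to ``n_genotypes``.

        A drawn frequency f maps to max(1, round(f * n_genotypes)), capped
        at n_genotypes - 1 to preserve polymorphism.
        """
        counts = np.array(sorted(self.probs))
        p = np.array([self.probs[c] for c in counts])
        c = rng.choice(counts, p=p)
        f = c / self.sample_size
        return int(min(max(1, round(f * n_genotypes)), n_genotypes - 1))

    @classmethod
    def watterson(cls, sample_size):
        """Neutral expectation: P(count = i) proportional to 1/i."""
        probs = {i: 1.0 / i for i in range(1, sample_size)}
        return cls(probs=probs, sample_size=sample_size)


def estimate_sfs(table: SNPTable) -> SFS:
    """Normalized histogram of alt-allele counts over polymorphic rows."""
    mask = table.polymorphic_mask()
    if not mask.any():
        raise ValueError("no polymorphic rows")
    counts = table.alt_counts()[mask]
    n = int(table.coverage()[mask].max())
    probs = {}
    for c in counts:
        probs[int(c)] = probs.get(int(c), 0) + 1
    return SFS(probs=probs, sample_size=n)


@dataclass
class Family:
    """A simulated cohort of randomly mutated genotypes."""

    genotypes: list
    snps: list
    sfs_mode: str
    seed: int | None

    def snp_table(self) -> SNPTable:
        rows = pd.DataFrame(
            [dict(gene=s.gene, pos=s.pos, ref=s.ref, alt=s.alt,
                  polymorphic=True) for s in self.snps]
        )
        ids = [g.id for g in self.genotypes]
        calls = np.zeros((len(self.snps), len(ids)), dtype=int)
        index = {(s.gene, s.pos): i for i, s in enumerate(self.snps)}
        for j, g in enumerate(self.genotypes):
            for s in g.snps:
                calls[index[(s.gene, s.pos)], j] = ALT
        return SNPTable(rows=rows, calls=calls, genotypes=ids)


def simulate_family(model_sites, reference, sfs=None, template_counts=None,
                    mode="neutral", n_genotypes=213, total_snps=90,
                    seed=None) -> Family:
    """Simulate one family of randomly mutated genotypes.

    Neutral mode: ``total_snps`` SNPs at distinct uniformly drawn positions
    of the model-site union, alt allele uniform among the three
    non-reference nucleotides, carrier count drawn from ``sfs`` rescaled to
    ``n_genotypes`` and assigned to that many uniformly chosen genotypes.

    Population mode: each simulated genotype carries exactly as many SNPs
    as the corresponding entry of ``template_counts`` (the study
    population's per-genotype SNP counts); positions uniform in the union.
    """
    rng = np.random.default_rng(seed)
    union = model_site_union(model_sites)
    positions = [(g, p) for g in sorted(union) for p in union[g]]
    if mode == "neutral":
        if sfs is None:
            raise ValueError("neutral mode requires an SFS")
        if total_snps > len(positions):
            raise ValueError("more SNPs requested than union positions")
        idx = rng.choice(len(positions), size=total_snps, replace=False)
        snps = []
        carriers = {}
        for i in sorted(idx):
            gene, pos = positions[i]
            ref = reference[gene][pos].upper()
            alt = rng.choice([c for c in "ACGT" if c != ref])
            snp = SNP(gene, pos, ref, str(alt))
            snps.append(snp)
            count = sfs.sample_count(rng, n_genotypes)
            carriers[snp] = rng.choice(n_genotypes, size=count, replace=False)
        per_genotype = [[] for _ in range(n_genotypes)]
        for snp, idxs in carriers.items():
            for j in idxs:
                per_genotype[j].append(snp)
    elif mode == "population":
        if template_counts is None:
            raise ValueError("population mode requires template counts")
        if len(template_counts) != n_genotypes:
            raise ValueError("one template count per genotype required")
        per_genotype = []
        snp_index = {}
        snps = []
        for count in template_counts:
            if count > len(positions):
                raise ValueError("genotype SNP count exceeds union size")
            idx = rng.choice(len(positions), size=int(count), replace=False)
            mine = []
            for i in sorted(idx):
                gene, pos = positions[i]
                key = (gene, pos)
                if key not in snp_index:
                    ref = reference[gene][pos].upper()
                    alt = rng.choice([c for c in "ACGT" if c != ref])
                    snp_index[key] = SNP(gene, pos, ref, str(alt))
                    snps.append(snp_index[key])
                mine.append(snp_index[key])
            per_genotype.append(mine)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    genotypes = [
        Genotype(id=f"sim_{j:03d}", snps=tuple(g))
        for j, g in enumerate(per_genotype)
    ]
    return Family(genotypes=genotypes, snps=snps, sfs_mode=mode, seed=seed)
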