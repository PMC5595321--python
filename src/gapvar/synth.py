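"""Synthetic datasets with known ground truth.

Generates the full input bundle the pipeline consumes: PWMs for a panel of
activator and repressor TFs, regulatory regions with planted binding sites
of graded affinity inside accessible chromatin, smooth spatial TF
gradients over the nucleus grid and the two cleavage cycles, thermodynamic
and kinetic parameters, a wild-type reference solution, and haploid
populations whose SNP allele counts follow a configurable site frequency
spectrum.  Every planted site is recorded in a ground-truth ledger so
tests never re-infer what the generator knows.

The default scale mirrors the study conditions: 4 genes, 8 TFs, 50 -> 100
nuclei, 9 output times, 213 genotypes, 90 SNPs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import PWM, revcomp, scan_sites
from .dynamics import (DynParams, GeneDynParams, GridSpec, TFProfiles,
                       compute_activation_field, integrate_dynamics)
from .population import ALT, REF, SFS, SNP, Genotype, SNPTable, model_site_union
from .thermo import RegulationParams, TFParams, ThermoParams

__all__ = [
    "SynthConfig",
    "SynthBundle",
    "generate_reference_dataset",
    "generate_tf_profiles",
    "generate_population",
]

DEFAULT_GENES = ("hb", "Kr", "gt", "kni")
DEFAULT_TFS = ("Bcd", "Cad", "Hb", "Kr", "Gt", "Kni", "Tll", "Hkb")
DEFAULT_ROLES = {
    "Bcd": "activator", "Cad": "activator", "Hb": "activator",
    "Kr": "repressor", "Gt": "repressor", "Kni": "repressor",
    "Tll": "repressor", "Hkb": "repressor",
}


@dataclass
class SynthConfig:
    """Knobs of the synthetic generator (defaults = study-scale run)."""

    genes: tuple = DEFAULT_GENES
    tfs: tuple = DEFAULT_TFS
    roles: dict = field(default_factory=lambda: dict(DEFAULT_ROLES))
    region_length: int = 800
    background_gc: float = 0.45
    motif_length: int = 7
    consensus_count: float = 85.0  # of 100; sets motif information content
    sites_per_gene: int = 12
    overlap_pairs_per_gene: int = 1
    weak_fraction: float = 0.4  # fraction of planted sites one step below consensus
    # thermodynamics
    k_range: tuple = (2.0, 8.0)
    alpha_range: tuple = (2.0, 5.0)
    beta_range: tuple = (0.5, 2.0)
    rep_range: int = 10
    coop_tfs: tuple = ("Hb",)
    omega: float = 2.0
    coop_range: int = 10
    # gradients
    amplitude_range: tuple = (0.5, 2.0)
    profile_noise: float = 0.0
    # dynamics
    grid: GridSpec = field(default_factory=GridSpec)
    solver_step: float = 0.01
    field_resolution: float = 2.0
    # population
    n_genotypes: int = 213
    n_snps: int = 90

    @classmethod
    def small(cls, **overrides):
        """A desk/test scale: 2 genes, 4 TFs, 16 -> 32 nuclei."""
        base = dict(
            genes=("hb", "Kr"),
            tfs=("Bcd", "Cad", "Kr", "Kni"),
            roles={"Bcd": "activator", "Cad": "activator",
                   "Kr": "repressor", "Kni": "repressor"},
            region_length=320,
            sites_per_gene=8,
            overlap_pairs_per_gene=1,
            grid=GridSpec(nuclei_c13=16),
            solver_step=0.05,
            field_resolution=4.0,
            n_genotypes=50,
            n_snps=30,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def tiny(cls, **overrides):
        """Minimal scale for calibration studies needing many pipeline runs:
        1 gene, 2 TFs, 8 -> 16 nuclei, coarse solver step."""
        base = dict(
            genes=("hb",),
            tfs=("Bcd", "Kr"),
            roles={"Bcd": "activator", "Kr": "repressor"},
            region_length=200,
            sites_per_gene=6,
            overlap_pairs_per_gene=0,
            grid=GridSpec(nuclei_c13=8),
            solver_step=0.2,
            field_resolution=8.0,
            n_genotypes=50,
            n_snps=12,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SynthBundle:
    """Everything a pipeline run needs, plus the ground-truth ledger."""

    config: SynthConfig
    seed: int | None
    regions: dict
    pwms: dict
    counts: dict
    thresholds: dict
    sites_by_gene: dict
    profiles: TFProfiles
    thermo_params: ThermoParams
    dyn_params: DynParams
    grid: GridSpec
    field: object
    wildtype: object
    ledger: pd.DataFrame

    @property
    def reference_sequences(self):
        return {g: r.sequence for g, r in self.regions.items()}

    def model_sites(self, gene=None):
        if gene is not None:
            return [s for s in self.sites_by_gene[gene] if s.is_model]
        return [s for sites in self.sites_by_gene.values()
                for s in sites if s.is_model]

    def write(self, outdir):
        from . import io as _io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _io.write_regions(outdir, self.regions)
        _io.write_pwms(outdir / "pwms.txt", self.pwms, dialect="counts",
                       counts=self.counts)
        _io.write_sites_bed(
            outdir / "sites.bed",
            [s for sites in self.sites_by_gene.values() for s in sites],
        )
        _io.write_profiles(outdir / "profiles.tsv", self.profiles)
        _io.write_params(outdir / "params.yaml", self.thermo_params,
                         self.dyn_params, self.grid)
        self.ledger.to_csv(outdir / "planted_sites.tsv", sep="\t", index=False)
        wt = []
        for j, t in enumerate(self.wildtype.times):
            for gi, g in enumerate(self.wildtype.genes):
                for i in range(self.wildtype.v[j].shape[0]):
                    wt.append((g, i, t, self.wildtype.u[j][i, gi],
                               self.wildtype.v[j][i, gi]))
        pd.DataFrame(
            wt, columns=["gene", "nucleus", "time", "mrna", "protein"]
        ).to_csv(outdir / "wildtype.tsv", sep="\t", index=False)
        manifest = {
            "seed": self.seed,
            "genes": list(self.config.genes),
            "tfs": list(self.config.tfs),
            "n_model_sites": int(self.ledger["recovered"].sum()),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _make_pwm(rng, tf, k, consensus_count):
    consensus = "".join(rng.choice(list("ACGT"), size=k))
    counts = np.full((k, 4), (100.0 - consensus_count) / 3.0)
    for j, c in enumerate(consensus):
        counts[j, "ACGT".index(c)] = consensus_count
    pwm = PWM.from_counts(tf, counts)
    return pwm, counts, consensus


def _weaken(consensus, pwm, threshold, rng):
    """One suboptimal substitution, kept above the scan threshold."""
    order = rng.permutation(len(consensus))
    for j in order:
        for alt in "ACGT":
            if alt == consensus[j]:
                continue
            cand = consensus[:j] + alt + consensus[j + 1:]
            if pwm.score(cand) >= threshold:
                return cand
    return consensus


def _random_sequence(rng, length, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _place_sites(rng, config, accessible, pwm_lengths, tf_cycle):
    """Choose (tf, start, overlap_partner) slots inside the accessible
    interval: mostly disjoint sites, plus configured overlapping pairs."""
    lo, hi = accessible
    placed = []  # (tf, start, end, tier)
    occupied = []

    def fits(start, end, allow=None):
        for (s, e) in occupied:
            if (s, e) == allow:
                continue
            if start < e and s < end:
                return False
        return True

    n_weak = int(round(config.sites_per_gene * config.weak_fraction))
    tiers = (["weak"] * n_weak
             + ["strong"] * (config.sites_per_gene - n_weak))
    rng.shuffle(tiers)
    for i in range(config.sites_per_gene):
        tf = tf_cycle[i % len(tf_cycle)]
        k = pwm_lengths[tf]
        for _ in range(400):
            start = int(rng.integers(lo, hi - k))
            if fits(start, start + k):
                placed.append([tf, start, start + k, tiers[i], None])
                occupied.append((start, start + k))
                break
        else:
            raise RuntimeError("cannot place planted sites; region too small")
    # overlapping pairs: shift a copy of another TF's motif onto an
    # existing site so the SNP-in-overlap mechanism exists by construction
    for i in range(config.overlap_pairs_per_gene):
        host = placed[int(rng.integers(len(placed)))]
        tf = tf_cycle[(i + 1) % len(tf_cycle)]
        if tf == host[0]:
            tf = tf_cycle[(i + 2) % len(tf_cycle)]
        k = pwm_lengths[tf]
        start = host[1] + int(rng.integers(1, max(2, host[2] - host[1] - 1)))
        if start + k <= hi:
            placed.append([tf, start, start + k, "strong", host[0]])
            occupied.append((start, start + k))
    return placed


def generate_tf_profiles(config: SynthConfig, grid: GridSpec, seed=None,
                         shapes=None) -> TFProfiles:
    """Smooth nonnegative TF gradients over nuclei x time, both cycles.

    Shapes rotate through gaussian / exponential / logistic along the A-P
    axis; amplitude rises linearly by 30% over the 71 minutes (a mild,
    monotone temporal modulation).  Optional multiplicative log-normal
    noise with s.d. ``config.profile_noise``.
    """
    rng = np.random.default_rng(seed)
    kinds = shapes or ("gaussian", "exponential", "logistic")
    times13 = np.array([0.0, grid.duration_c13 / 2, grid.duration_c13])
    times14 = np.array([grid.duration_c13,
                        grid.duration_c13 + grid.duration_c14a / 2,
                        grid.total_duration])
    data = {}
    for it, tf in enumerate(config.tfs):
        kind = kinds[it % len(kinds)]
        amp = rng.uniform(*config.amplitude_range)
        center = rng.uniform(0.2, 0.8)
        width = rng.uniform(0.12, 0.3)

        def shape(x):
            if kind == "gaussian":
                return amp * np.exp(-((x - center) ** 2) / (2 * width**2))
            if kind == "exponential":
                return amp * np.exp(-x / max(width, 0.05))
            return amp / (1.0 + np.exp(-(x - center) / (width / 4)))

        for cyc, times, n in ((13, times13, grid.nuclei_c13),
                              (14, times14, grid.nuclei_c14a)):
            x = (np.arange(n) + 0.5) / n
            base = shape(x)[:, None]
            tmod = (1.0 + 0.3 * times / grid.total_duration)[None, :]
            vals = base * tmod
            if config.profile_noise > 0:
                vals = vals * rng.lognormal(
                    0.0, config.profile_noise, size=vals.shape
                )
            data[(tf, cyc)] = (times, vals)
    return TFProfiles(data)


def _thermo_params(rng, config: SynthConfig) -> ThermoParams:
    tf_params = {}
    for tf in config.tfs:
        coop = tf in config.coop_tfs
        tf_params[tf] = TFParams(
            K=float(rng.uniform(*config.k_range)),
            omega=config.omega if coop else 1.0,
            coop_range=config.coop_range if coop else 0,
        )
    regulation = {}
    for tf in config.tfs:
        role = config.roles[tf]
        for gene in config.genes:
            if role == "activator":
                regulation[(tf, gene)] = RegulationParams(
                    role="activator",
                    alpha=float(rng.uniform(*config.alpha_range)),
                )
            else:
                regulation[(tf, gene)] = RegulationParams(
                    role="repressor",
                    beta=float(rng.uniform(*config.beta_range)),
                    rep_range=config.rep_range,
                )
    return ThermoParams(tf=tf_params, regulation=regulation)


def _dyn_params(rng, config: SynthConfig) -> DynParams:
    genes = {}
    for gene in config.genes:
        d_u13 = float(rng.uniform(0.1, 0.3))
        d_v13 = float(rng.uniform(0.05, 0.15))
        genes[gene] = GeneDynParams(
            r_u=float(rng.uniform(1.5, 3.0)),
            r_v=float(rng.uniform(1.0, 2.0)),
            lambda_u=float(rng.uniform(0.15, 0.25)),
            lambda_v=float(rng.uniform(0.1, 0.2)),
            d_u={13: d_u13, 14: d_u13 / 2},  # diffusion halves at division
            d_v={13: d_v13, 14: d_v13 / 2},
            tau=6.0,
        )
    return DynParams(genes=genes)


def generate_reference_dataset(config: SynthConfig = None,
                               seed=None) -> SynthBundle:
    """Generate the full reference bundle for one seed.

    Planted sites are guaranteed to be re-discovered by scanning at the
    mean + 3 s.d. thresholds because their windows score above threshold
    by construction; the surrounding random background may contribute
    additional (genuine) sites.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(seed)

    pwms, counts, consensi = {}, {}, {}
    for tf in config.tfs:
        pwm, cnt, cons = _make_pwm(rng, tf, config.motif_length,
                                   config.consensus_count)
        pwms[tf], counts[tf], consensi[tf] = pwm, cnt, cons
    thresholds = {tf: pwms[tf].threshold() for tf in config.tfs}
    pwm_lengths = {tf: pwms[tf].k for tf in config.tfs}

    thermo_params = _thermo_params(rng, config)
    dyn_params = _dyn_params(rng, config)
    grid = config.grid

    regions = {}
    ledger_rows = []
    from .annotate import RegulatoryRegion

    for gene in config.genes:
        L = config.region_length
        acc = (int(0.05 * L), int(0.85 * L))
        cds = (int(0.9 * L), L)
        tf_cycle = list(config.tfs)
        rng.shuffle(tf_cycle)
        placed = _place_sites(rng, config, acc, pwm_lengths, tf_cycle)
        seq = list(_random_sequence(rng, L, config.background_gc))
        for tf, start, end, tier, partner in placed:
            motif = consensi[tf]
            if tier == "weak":
                motif = _weaken(consensi[tf], pwms[tf], thresholds[tf], rng)
            if rng.random() < 0.5:
                motif = revcomp(motif)
            seq[start:end] = list(motif)
        region = RegulatoryRegion(
            gene=gene, sequence="".join(seq),
            accessible=[acc], cds=[cds],
        )
        regions[gene] = region
        sites = scan_sites(region, pwms, thresholds)
        found = {(s.tf_name, s.start, s.end) for s in sites if s.is_model}
        for tf, start, end, tier, partner in placed:
            window = region.sequence[start:end]
            realized = max(pwms[tf].score(window, "+"),
                           pwms[tf].score(window, "-"))
            ledger_rows.append(
                dict(gene=gene, tf=tf, start=start, end=end, tier=tier,
                     role=config.roles[tf],
                     overlaps=partner if partner else "",
                     realized_score=realized,
                     above_threshold=realized >= thresholds[tf],
                     recovered=(tf, start, end) in found)
            )

    sites_by_gene = {
        gene: scan_sites(regions[gene], pwms, thresholds)
        for gene in config.genes
    }
    profiles = generate_tf_profiles(
        config, grid, seed=rng.integers(2**31 - 1)
    )
    fld = compute_activation_field(
        sites_by_gene, pwms, profiles, thermo_params, grid,
        resolution=config.field_resolution,
    )
    wildtype = integrate_dynamics(fld, dyn_params, grid,
                                  step=config.solver_step)
    return SynthBundle(
        config=config, seed=seed, regions=regions, pwms=pwms, counts=counts,
        thresholds=thresholds, sites_by_gene=sites_by_gene,
        profiles=profiles, thermo_params=thermo_params,
        dyn_params=dyn_params, grid=grid, field=fld, wildtype=wildtype,
        ledger=pd.DataFrame(ledger_rows),
    )


def generate_population(config: SynthConfig, model_sites, reference,
                        seed=None, sfs: SFS = None, n_snps=None,
                        missing_rate=0.0, reject_score=None,
                        score_cutoff=None):
    """Simulate a haploid study population as a SNPTable + genotypes.

    SNPs are placed at distinct uniform positions of the model-site union
    with carrier counts drawn from ``sfs`` (neutral 1/i spectrum by
    default).  ``reject_score`` (a mapping SNP -> phenotypic score) with
    ``score_cutoff`` rejects candidate SNPs scoring above the cutoff,
    creating a positive control for purifying-selection tests.
    """
    rng = np.random.default_rng(seed)
    n_gen = config.n_genotypes
    n_snps = config.n_snps if n_snps is None else n_snps
    sfs = sfs or SFS.watterson(n_gen)
    union = model_site_union(model_sites)
    positions = [(g, p) for g in sorted(union) for p in union[g]]
    if n_snps > len(positions):
        raise ValueError("more SNPs requested than model-site positions")

    chosen = []
    used = set()
    attempts = 0
    while len(chosen) < n_snps:
        attempts += 1
        if attempts > 200 * n_snps:
            raise RuntimeError("selection filter rejects too many candidates")
        i = int(rng.integers(len(positions)))
        if i in used:
            continue
        gene, pos = positions[i]
        ref = reference[gene][pos].upper()
        alt = str(rng.choice([c for c in "ACGT" if c != ref]))
        snp = SNP(gene, pos, ref, alt)
        if reject_score is not None and score_cutoff is not None:
            if reject_score.get(snp, 0.0) > score_cutoff:
                continue
        used.add(i)
        chosen.append(snp)
    chosen.sort(key=lambda s: (s.gene, s.pos))

    calls = np.zeros((n_snps, n_gen), dtype=int)
    for r, snp in enumerate(chosen):
        count = sfs.sample_count(rng, n_gen)
        carriers = rng.choice(n_gen, size=count, replace=False)
        calls[r, carriers] = ALT
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = -1
    ids = [f"geno_{j:03d}" for j in range(n_gen)]
    rows = pd.DataFrame(
        [dict(gene=s.gene, pos=s.pos, ref=s.ref, alt=s.alt, polymorphic=True)
         for s in chosen]
    )
    table = SNPTable(rows=rows, calls=calls, genotypes=ids)
    genotypes = []
    for j, gid in enumerate(ids):
        mine = tuple(chosen[r] for r in range(n_snps)
                     if calls[r, j] == ALT)
        genotypes.append(Genotype(id=gid, snps=mine))
    return table, genotypes
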