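"""Shared fixtures: synthetic bundles and hand-built mini regulatory systems."""

import numpy as np
import pytest

from gapvar.annotate import PWM, BindingSite, RegulatoryRegion, scan_sites
from gapvar.dynamics import (DynParams, GeneDynParams, GridSpec, TFProfiles,
                             compute_activation_field, integrate_dynamics)
from gapvar.synth import SynthConfig, generate_reference_dataset
from gapvar.thermo import RegulationParams, TFParams, ThermoParams


@pytest.fixture(scope="session")
def small_bundle():
    """Two-gene, four-TF bundle at reduced grid scale (fixed seed)."""
    return generate_reference_dataset(SynthConfig.small(), seed=42)


@pytest.fixture(scope="session")
def tiny_bundle():
    """One-gene, two-TF bundle for pipeline-heavy statistics (fixed seed)."""
    return generate_reference_dataset(SynthConfig.tiny(n_snps=30), seed=9)


@pytest.fixture(scope="session")
def tiny_snv_scores(tiny_bundle):
    """Per-SNV score table over the tiny bundle's model-site union."""
    from gapvar.pipeline import snv_score_table
    from gapvar.population import enumerate_snvs

    snvs = enumerate_snvs(tiny_bundle.model_sites(),
                          tiny_bundle.reference_sequences)
    table = snv_score_table(tiny_bundle, snvs)
    return snvs, table


def make_site(tf, start, end, gene="g", score=0.0, strand="+", is_model=True):
    return BindingSite(tf_name=tf, gene=gene, start=start, end=end,
                       strand=strand, score=score, is_model=is_model)


def consensus_pwm(tf, consensus, consensus_count=85.0):
    counts = np.full((len(consensus), 4), (100.0 - consensus_count) / 3.0)
    for j, c in enumerate(consensus):
        counts[j, "ACGT".index(c)] = consensus_count
    return PWM.from_counts(tf, counts)


class MiniSystem:
    """A hand-built one-gene regulatory system for targeted constructs.

    Wraps region, sites, PWMs, parameters, profiles and the grid with a
    ``solve`` method so a test can plant exactly the site configuration it
    needs and push mutations through the full field + dynamics pipeline.
    """

    def __init__(self, sequence, pwms, params, profiles, gene="g",
                 grid=None, dyn=None, accessible=None):
        self.gene = gene
        self.pwms = pwms
        self.params = params
        self.profiles = profiles
        self.grid = grid or GridSpec(nuclei_c13=8)
        self.region = RegulatoryRegion(
            gene, sequence,
            accessible=accessible or [(0, len(sequence))],
        )
        self.thresholds = {tf: p.threshold() for tf, p in pwms.items()}
        self.sites = scan_sites(self.region, pwms, self.thresholds)
        self.dyn = dyn or DynParams(genes={gene: GeneDynParams(
            r_u=2.0, r_v=1.5, lambda_u=0.2, lambda_v=0.15,
            d_u={13: 0.2, 14: 0.1}, d_v={13: 0.1, 14: 0.05}, tau=3.0,
        )})

    def solve(self, sites=None, step=0.2, resolution=8.0):
        fld = compute_activation_field(
            {self.gene: sites if sites is not None else self.sites},
            self.pwms, self.profiles, self.params, self.grid,
            resolution=resolution,
        )
        return integrate_dynamics(fld, self.dyn, self.grid, step=step)


def gradient_profiles(tfs_shapes, grid, amplitude=3.0):
    """Exponential A-P gradients: shape 'anterior' decays from the front,
    'posterior' from the rear, 'flat' is constant."""
    t13 = np.array([0.0, grid.duration_c13])
    t14 = np.array([grid.duration_c13, grid.total_duration])
    data = {}
    for tf, shape in tfs_shapes.items():
        for cyc, times, n in ((13, t13, grid.nuclei_c13),
                              (14, t14, grid.nuclei_c14a)):
            x = (np.arange(n) + 0.5) / n
            if shape == "anterior":
                prof = amplitude * np.exp(-x / 0.2)
            elif shape == "posterior":
                prof = amplitude * np.exp(-(1 - x) / 0.2)
            else:
                prof = np.full(n, amplitude)
            data[(tf, cyc)] = (times, np.tile(prof[:, None], (1, times.size)))
    return TFProfiles(data)


def simple_params(roles, alpha=4.0, beta=1.0, rep_range=10, K=5.0,
                  gene="g", omega=1.0, coop_range=0):
    """ThermoParams from a {tf: 'activator'|'repressor'} map."""
    return ThermoParams(
        tf={tf: TFParams(K=K, omega=omega, coop_range=coop_range)
            for tf in roles},
        regulation={
            (tf, gene): (
                RegulationParams("activator", alpha=alpha)
                if role == "activator"
                else RegulationParams("repressor", beta=beta,
                                      rep_range=rep_range)
            )
            for tf, role in roles.items()
        },
    )
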