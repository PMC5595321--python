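"""End-to-end scoring: genotype -> mutated solution -> regulatory scores.

A SNP (or set of SNPs) is superimposed on the reference sequence, the
affected model sites are re-scored (no sites are created or removed), the
activation field and the reaction-diffusion solution are recomputed for
the affected genes, and the perturbation is summarized by the regulatory
scores.  Unaffected genes keep the wild-type solution, which is exact
because genes are coupled only through the shared TF profiles, not through
each other's products.
"""

from __future__ import annotations

import numpy as np

from .dynamics import ExpressionState, compute_activation_field, integrate_dynamics
from .population import Genotype, SNP, apply_genotype
from .scores import DeltaScores, delta_scores

__all__ = [
    "field_at_outputs",
    "mutated_state",
    "score_genotype",
    "score_snp",
    "snv_score_table",
]


def field_at_outputs(field, grid, genes=None) -> np.ndarray:
    """Activation probabilities flattened over the output grid, in the
    same (time, gene, nucleus) order as ExpressionState.flat_v()."""
    genes = genes if genes is not None else field.genes
    chunks = []
    for t in grid.output_times:
        cols = [field.at(g, t) for g in genes]
        chunks.append(np.stack(cols, axis=1).ravel())
    return np.concatenate(chunks)


def _merge_states(reference: ExpressionState, partial: ExpressionState):
    """Overlay the recomputed columns of ``partial`` onto the reference."""
    genes = reference.genes
    u, v = [], []
    idx = {g: partial.genes.index(g) for g in partial.genes}
    for j in range(len(reference.times)):
        uj = reference.u[j].copy()
        vj = reference.v[j].copy()
        for g in partial.genes:
            gi = genes.index(g)
            uj[:, gi] = partial.u[j][:, idx[g]]
            vj[:, gi] = partial.v[j][:, idx[g]]
        u.append(uj)
        v.append(vj)
    return ExpressionState(genes=genes, times=reference.times, u=u, v=v)


def mutated_state(bundle, genotype: Genotype, step=None):
    """Model solution and activation field for one genotype.

    Returns (state, field_flat) where ``field_flat`` is the mutated
    activation field sampled on the output grid (reference values for
    unaffected genes).
    """
    step = step if step is not None else bundle.config.solver_step
    affected = sorted({s.gene for s in genotype.snps})
    ref_flat_e = field_at_outputs(bundle.field, bundle.grid,
                                  bundle.wildtype.genes)
    if not affected:
        return bundle.wildtype, ref_flat_e
    sites_by_gene = {}
    for gene in affected:
        _, new_sites = apply_genotype(
            bundle.regions[gene], genotype,
            bundle.sites_by_gene[gene], bundle.pwms,
        )
        sites_by_gene[gene] = new_sites
    fld = compute_activation_field(
        sites_by_gene, bundle.pwms, bundle.profiles, bundle.thermo_params,
        bundle.grid, resolution=bundle.config.field_resolution,
    )
    partial = integrate_dynamics(fld, bundle.dyn_params, bundle.grid,
                                 step=step)
    state = _merge_states(bundle.wildtype, partial)

    # overlay mutated activation values onto the reference field vector
    genes = bundle.wildtype.genes
    e_flat = ref_flat_e.copy()
    offset = 0
    for t in bundle.grid.output_times:
        n = bundle.grid.nuclei_at(t)
        for gi, g in enumerate(genes):
            if g in sites_by_gene:
                e_flat[offset + np.arange(n) * len(genes) + gi] = fld.at(g, t)
        offset += n * len(genes)
    return state, e_flat


def score_genotype(bundle, genotype: Genotype, step=None,
                   tol=None) -> DeltaScores:
    """All regulatory scores of one genotype against the wild type."""
    state, e_mut = mutated_state(bundle, genotype, step=step)
    e_ref = field_at_outputs(bundle.field, bundle.grid,
                             bundle.wildtype.genes)
    return delta_scores(state, bundle.wildtype, e_mut=e_mut, e_ref=e_ref,
                        tol=tol)


def score_snp(bundle, snp: SNP, step=None, tol=None) -> DeltaScores:
    """Regulatory scores of a single SNP superimposed on the reference."""
    geno = Genotype(id=f"snv_{snp.gene}_{snp.pos}_{snp.alt}", snps=(snp,))
    return score_genotype(bundle, geno, step=step, tol=tol)


def snv_score_table(bundle, snvs, step=None, progress=False):
    """wPGP, RMS and mean Delta-v for a list of single-nucleotide variants.

    Returns a pandas DataFrame with one row per SNV.
    """
    import pandas as pd

    rows = []
    for i, snp in enumerate(snvs):
        sc = score_snp(bundle, snp, step=step)
        rows.append(
            dict(gene=snp.gene, pos=snp.pos, ref=snp.ref, alt=snp.alt,
                 wpgp=sc.wpgp, rms=sc.rms, mean_dv=sc.mean_dv, sign=sc.sign)
        )
        if progress and (i + 1) % 50 == 0:
            print(f"scored {i + 1}/{len(snvs)} SNVs")
    return pd.DataFrame(rows)
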