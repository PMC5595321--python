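"""Regulatory scores quantifying a mutation's perturbation of expression.

Two scalar scores compare a mutated solution v with the reference (wild
type) solution V over the full nucleus x time x gene grid: the root mean
square distance and the weighted pattern generating potential (wPGP), a
reward/penalty measure sensitive to changes in expression-domain shape.
Signed per-grid-point differences Delta-v (protein) and Delta-E
(activation probability) give direction: a variant is classified as
activating, repressing, alternating, or of zero influence from the signs
of the Delta-v components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import PWM, pwm_score

__all__ = [
    "DeltaScores",
    "BindingScore",
    "rms_score",
    "wpgp_score",
    "wpgp_components",
    "delta_scores",
    "classify_sign",
    "binding_score",
    "cv_percentile",
    "default_sign_tolerance",
]


class DegeneratePatternError(ValueError):
    """Reference pattern flat at its maximum: the wPGP penalty is undefined."""


def _check_states(v, V):
    if v.genes != V.genes or len(v.v) != len(V.v):
        raise ValueError("expression states are on different grids")
    for a, b in zip(v.v, V.v):
        if a.shape != b.shape:
            raise ValueError("expression states are on different grids")


def rms_score(v, V) -> float:
    """Root mean square distance between two solutions over all N points."""
    _check_states(v, V)
    diff = v.flat_v() - V.flat_v()
    return float(np.sqrt(np.mean(diff**2)))


def wpgp_components(v, V, subset=None):
    """Per-(gene, time) wPGP components f = 0.5 - 0.5*(reward - penalty).

    reward  = sum_i V * min(V, v) / sum_i V^2
    penalty = sum_i min(max(0, v - V), Vmax - V) * (Vmax - V)
              / sum_i (Vmax - V)^2

    The overexpression excess is saturated at Vmax - V, which keeps both
    reward and penalty in [0, 1] and hence every component in [0, 1] for
    arbitrary nonnegative patterns.

    ``subset`` optionally restricts to an iterable of (gene, time_index)
    pairs (the restricted-score option).  Returns a dict keyed by
    (gene, time_index).
    """
    _check_states(v, V)
    keys = (
        set(subset) if subset is not None
        else {(g, j) for g in V.genes for j in range(len(V.times))}
    )
    out = {}
    for g in V.genes:
        gi = V.genes.index(g)
        for j in range(len(V.times)):
            if (g, j) not in keys:
                continue
            ref = V.v[j][:, gi]
            mut = v.v[j][:, gi]
            ref_sq = float(np.sum(ref**2))
            if ref_sq == 0.0:
                raise ValueError(
                    f"reference pattern identically zero for {(g, j)}"
                )
            reward = float(np.sum(ref * np.minimum(ref, mut)) / ref_sq)
            vmax = float(ref.max())
            pen_den = float(np.sum((vmax - ref) ** 2))
            over = np.minimum(np.maximum(0.0, mut - ref), vmax - ref)
            if pen_den == 0.0:
                if np.any(mut > ref):
                    raise DegeneratePatternError(
                        f"flat-at-max reference pattern for {(g, j)}"
                    )
                penalty = 0.0
            else:
                penalty = float(np.sum(over * (vmax - ref)) / pen_den)
            out[(g, j)] = 0.5 - 0.5 * (reward - penalty)
    return out


def wpgp_score(v, V, subset=None):
    """Total wPGP regulatory score: sum of the f components."""
    return float(sum(wpgp_components(v, V, subset=subset).values()))


def default_sign_tolerance(V) -> float:
    """Float-noise guard for sign classification: 1e-9 x max |V|."""
    m = float(np.max(np.abs(V.flat_v()))) if V.n_points else 0.0
    return 1e-9 * m if m > 0 else 1e-12


def classify_sign(dv, tol) -> str:
    """Sign of influence from the Delta-v components.

    'positive' if all components >= -tol and some > tol; 'negative'
    symmetric; 'zero' if all |components| <= tol; 'alternating' otherwise.
    """
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    dv = np.asarray(dv, dtype=float)
    if np.all(np.abs(dv) <= tol):
        return "zero"
    has_pos = bool(np.any(dv > tol))
    has_neg = bool(np.any(dv < -tol))
    if has_pos and not has_neg:
        return "positive"
    if has_neg and not has_pos:
        return "negative"
    return "alternating"


@dataclass
class DeltaScores:
    """Signed and scalar perturbation summaries for one SNP or genotype."""

    dv: np.ndarray
    de: np.ndarray | None
    mean_dv: float
    rms: float
    wpgp: float
    sign: str


def delta_scores(v, V, e_mut=None, e_ref=None, tol=None) -> DeltaScores:
    """All perturbation scores of a mutated solution against the reference.

    Delta-v and Delta-E are componentwise mutated-minus-reference vectors;
    <Delta-v> is the mean over all N components.
    """
    _check_states(v, V)
    dv = v.flat_v() - V.flat_v()
    de = None
    if e_mut is not None and e_ref is not None:
        e_mut = np.asarray(e_mut, float).ravel()
        e_ref = np.asarray(e_ref, float).ravel()
        if e_mut.shape != e_ref.shape:
            raise ValueError("activation fields are on different grids")
        de = e_mut - e_ref
    if tol is None:
        tol = default_sign_tolerance(V)
    return DeltaScores(
        dv=dv,
        de=de,
        mean_dv=float(dv.mean()),
        rms=rms_score(v, V),
        wpgp=wpgp_score(v, V),
        sign=classify_sign(dv, tol),
    )


@dataclass(frozen=True)
class BindingScore:
    """Binding-energy change of a site: Delta-P signed, w_b = |Delta-P|."""

    delta_p: float

    @property
    def w_b(self) -> float:
        return abs(self.delta_p)


def binding_score(site_ref: str, site_mut: str, pwm: PWM,
                  strand: str = "+") -> BindingScore:
    """w_b = |P(S_mut) - P(S_ref)| from the PWM scores of the two windows.

    Under the weight model Delta-P = log(q_mut / q_ref).
    """
    if len(site_ref) != len(site_mut):
        raise ValueError("reference and mutated windows differ in length")
    p_ref = pwm_score(site_ref, pwm, strand)
    p_mut = pwm_score(site_mut, pwm, strand)
    return BindingScore(delta_p=p_mut - p_ref)


def cv_percentile(values, percentile: float) -> float:
    """Coefficient of variation (population sd / mean) over the values
    strictly above the given percentile of the full set."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value set")
    if percentile <= 0:
        sel = values  # percentile 0 = no filtering
    else:
        cut = np.percentile(values, percentile)
        sel = values[values > cut]
    if sel.size == 0:
        raise ValueError("no values above the percentile cutoff")
    mean = sel.mean()
    if mean == 0:
        raise ValueError("zero mean after filtering")
    return float(sel.std() / mean)
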