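"""Thermodynamic model of transcriptional activation.

The probability E that the basal transcriptional machinery (BTM) occupies
the promoter is computed from the statistical weights of all molecular
configurations of a regulatory region.  A configuration assigns each TFBS a
state: free, bound, or (for repressor sites) bound-effective, which forbids
binding of any other site within the repression range d and carries an
extra factor beta.  Bound same-TF sites within the cooperativity range each
gain a factor omega per cooperating bound neighbour (a bound pair carries
omega^2 under the default convention).  With Z_OFF the total configuration
weight and Z_ON the weight with each bound activator contributing its
activation efficiency alpha,

    E = Z_ON / (Z_ON + Z_OFF),

so E = 1/2 with nothing bound (basal promoter weight 1 by default).

Weights can be scalars or aligned vectors (one entry per nucleus/time
point); the enumeration and the dynamic program both broadcast over the
trailing axis, which is what makes whole activation fields cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .annotate import PWM, BindingSite, pwm_score, revcomp, _INDEX

__all__ = [
    "TFParams",
    "RegulationParams",
    "ThermoParams",
    "PartitionResult",
    "SiteDelta",
    "site_weight",
    "brute_force_partition",
    "partition_functions",
    "site_delta",
    "perturbed_activation",
    "activation_sensitivity",
    "classify_local_context",
]

FREE, BOUND, EFFECTIVE = 0, 1, 2


@dataclass(frozen=True)
class TFParams:
    """Per-TF constants: association constant K, cooperativity omega and
    its range in bp (omega = 1 disables cooperative binding)."""

    K: float
    omega: float = 1.0
    coop_range: int = 0

    def __post_init__(self):
        if self.K <= 0:
            raise ValueError("association constant K must be > 0")
        if self.omega < 1:
            raise ValueError("cooperativity omega must be >= 1")
        if self.coop_range < 0:
            raise ValueError("cooperativity range must be >= 0")


@dataclass(frozen=True)
class RegulationParams:
    """Per TF x target-gene role and efficiency.

    Activators carry alpha > 1 (promoter activation per bound site);
    repressors carry beta > 0 (weight of the effective, quenching state)
    and a repression range d in bp.
    """

    role: str
    alpha: float | None = None
    beta: float | None = None
    rep_range: int = 0

    def __post_init__(self):
        if self.role not in ("activator", "repressor"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "activator":
            if self.alpha is None or self.alpha <= 1:
                raise ValueError("activators require alpha > 1")
        else:
            if self.beta is None or self.beta <= 0:
                raise ValueError("repressors require beta > 0")
            if self.rep_range < 0:
                raise ValueError("repression range must be >= 0")


@dataclass
class ThermoParams:
    """All thermodynamic constants, keyed by TF and by (TF, gene).

    ``normalize_by_max`` makes q_s = K * v * exp(P_s - P_max) so that K is
    the association constant of the strongest possible site of the TF; the
    unnormalized exp(P_s) form is available by switching it off.
    ``omega_per_pair`` switches the cooperativity convention from one
    omega per bound cooperating site (pair factor omega^2, the default) to
    one omega per pair.
    """

    tf: dict = field(default_factory=dict)
    regulation: dict = field(default_factory=dict)
    btm_basal_weight: float = 1.0
    normalize_by_max: bool = True
    omega_per_pair: bool = False

    def tf_params(self, tf_name) -> TFParams:
        return self.tf[tf_name]

    def regulation_params(self, tf_name, gene) -> RegulationParams:
        return self.regulation[(tf_name, gene)]

    def role(self, tf_name, gene) -> str:
        return self.regulation[(tf_name, gene)].role


@dataclass
class PartitionResult:
    """Z_ON, Z_OFF and the activation probability E = Z_ON/(Z_ON+Z_OFF)."""

    z_on: np.ndarray
    z_off: np.ndarray

    @property
    def e(self):
        return self.z_on / (self.z_on + self.z_off)


def site_weight(site: BindingSite, tf_concentration, params: ThermoParams,
                pwm: PWM):
    """Statistical weight q_s = K * v * exp(P_s - P_max) of an occupied site.

    ``tf_concentration`` may be a scalar or an array (e.g. one value per
    nucleus/time point).
    """
    v = np.asarray(tf_concentration, dtype=float)
    if np.any(v < 0):
        raise ValueError("TF concentration must be >= 0")
    K = params.tf_params(site.tf_name).K
    ref = pwm.max_score if params.normalize_by_max else 0.0
    return K * v * math.exp(site.score - ref)


def _site_info(sites, params, gene):
    """Precompute per-site role/alpha/beta/ranges for the ensemble sums."""
    info = []
    for s in sites:
        tfp = params.tf_params(s.tf_name)
        reg = params.regulation_params(s.tf_name, gene)
        info.append(
            dict(
                tf=s.tf_name, start=s.start, end=s.end,
                is_repressor=reg.role == "repressor",
                alpha=reg.alpha if reg.role == "activator" else 1.0,
                beta=reg.beta if reg.role == "repressor" else 1.0,
                d=reg.rep_range if reg.role == "repressor" else 0,
                omega=tfp.omega, coop_range=tfp.coop_range,
            )
        )
    return info


def _gap(a, b):
    """Gap in bp between two (start, end) intervals; 0 when overlapping."""
    return max(0, max(a["start"], b["start"]) - min(a["end"], b["end"]))


def _overlap(a, b):
    return a["start"] < b["end"] and b["start"] < a["end"]


def _coop_factor(a, b, per_pair):
    if a["tf"] != b["tf"] or a["omega"] == 1.0:
        return 1.0
    if _gap(a, b) > a["coop_range"]:
        return 1.0
    return a["omega"] if per_pair else a["omega"] ** 2


def _check_weights(sites, weights):
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != len(sites):
        raise ValueError("one weight (row) required per site")
    if np.any(w < 0):
        raise ValueError("site weights must be >= 0")
    return w


def brute_force_partition(sites, weights, params: ThermoParams, gene=None):
    """Enumerate every legal configuration explicitly (oracle, <= 16 sites).

    Weights may be shape (n_sites,) of scalars or (n_sites, M) vectors.
    """
    if len(sites) > 16:
        raise ValueError("brute-force enumeration limited to 16 sites")
    gene = gene if gene is not None else (sites[0].gene if sites else None)
    weights = _check_weights(sites, weights)
    order = sorted(range(len(sites)), key=lambda i: (sites[i].start, sites[i].end))
    info = [_site_info([sites[i]], params, gene)[0] for i in order]
    q = [weights[i] for i in order]
    tail_shape = weights.shape[1:]
    per_pair = params.omega_per_pair

    z_off = np.zeros(tail_shape)
    z_on = np.zeros(tail_shape)

    def recurse(idx, chosen, w_acc, alpha_acc):
        nonlocal z_off, z_on
        if idx == len(info):
            z_off = z_off + w_acc
            z_on = z_on + w_acc * alpha_acc
            return
        a = info[idx]
        # free
        recurse(idx + 1, chosen, w_acc, alpha_acc)
        states = (BOUND, EFFECTIVE) if a["is_repressor"] else (BOUND,)
        for state in states:
            mult = q[idx] * (a["beta"] if state == EFFECTIVE else 1.0)
            legal = True
            coop = 1.0
            for jdx, jstate in chosen:
                b = info[jdx]
                if _overlap(a, b):
                    legal = False
                    break
                if jstate == EFFECTIVE and _gap(a, b) <= b["d"]:
                    legal = False
                    break
                if state == EFFECTIVE and _gap(a, b) <= a["d"]:
                    legal = False
                    break
                coop *= _coop_factor(a, b, per_pair)
            if not legal:
                continue
            recurse(
                idx + 1, chosen + [(idx, state)],
                w_acc * mult * coop,
                alpha_acc * a["alpha"],
            )

    recurse(0, [], np.ones(tail_shape), 1.0)
    return PartitionResult(z_on=params.btm_basal_weight * z_on, z_off=z_off)


def partition_functions(sites, weights, params: ThermoParams, gene=None):
    """Partition sums by dynamic programming over position-sorted sites.

    Exactly equal to :func:`brute_force_partition` but scalable: the
    recursion memoizes on the 'frontier' of already-bound sites that can
    still interact (overlap, cooperate, or repress) with sites not yet
    decided.  Interaction reach is bounded, so the frontier stays small.
    """
    gene = gene if gene is not None else (sites[0].gene if sites else None)
    weights = _check_weights(sites, weights)
    order = sorted(range(len(sites)), key=lambda i: (sites[i].start, sites[i].end))
    info = [_site_info([sites[i]], params, gene)[0] for i in order]
    q = [weights[i] for i in order]
    tail_shape = weights.shape[1:]
    per_pair = params.omega_per_pair
    n = len(info)

    reach = 0
    for a in info:
        reach = max(reach, a["coop_range"] if a["omega"] > 1 else 0, a["d"])

    @lru_cache(maxsize=None)
    def rec(idx, frontier):
        # frontier: tuple of (site index, state) for bound sites with
        # end + reach > start of every undecided site
        if idx == n:
            one = np.ones(tail_shape)
            return one, one
        a = info[idx]
        kept = tuple(
            (j, st) for j, st in frontier
            if info[j]["end"] + reach >= a["start"]
        )
        # free
        w_off, w_on = rec(idx + 1, kept)
        z_off = np.array(w_off, copy=True)
        z_on = np.array(w_on, copy=True)
        states = (BOUND, EFFECTIVE) if a["is_repressor"] else (BOUND,)
        for state in states:
            legal = True
            coop = 1.0
            for j, jstate in kept:
                b = info[j]
                if _overlap(a, b):
                    legal = False
                    break
                if jstate == EFFECTIVE and _gap(a, b) <= b["d"]:
                    legal = False
                    break
                if state == EFFECTIVE and _gap(a, b) <= a["d"]:
                    legal = False
                    break
                coop *= _coop_factor(a, b, per_pair)
            if not legal:
                continue
            sub_off, sub_on = rec(idx + 1, kept + ((idx, state),))
            mult = q[idx] * (a["beta"] if state == EFFECTIVE else 1.0) * coop
            z_off = z_off + mult * sub_off
            z_on = z_on + mult * a["alpha"] * sub_on
        return z_off, z_on

    z_off, z_on = rec(0, ())
    rec.cache_clear()
    return PartitionResult(z_on=params.btm_basal_weight * z_on, z_off=z_off)


@dataclass(frozen=True)
class SiteDelta:
    """Linear perturbation of one site's weight by one point mutation.

    The mutated weight satisfies q(S~) = q(S) + q(Sbar) * delta exactly,
    where Sbar is the site with the mutated PWM column removed and
    delta = exp(L_new) - exp(L_old) for that column's log-odds L.
    """

    site: BindingSite
    j: int
    old: str
    new: str
    delta: float
    reduced_weight: float
    q_ref: float

    @property
    def q_mut(self):
        return self.q_ref + self.reduced_weight * self.delta


def site_delta(site: BindingSite, j: int, new_nucleotide: str, pwm: PWM,
               tf_concentration, params: ThermoParams,
               region_sequence: str) -> SiteDelta:
    """Decompose a point mutation at genomic offset ``j`` within a site.

    ``j`` is relative to the site start in genomic coordinates; for minus
    strand sites the PWM column and nucleotides are strand-flipped
    internally.
    """
    if not 0 <= j < site.length:
        raise ValueError(f"position {j} outside site of length {site.length}")
    old = region_sequence[site.start + j].upper()
    new = new_nucleotide.upper()
    if new == old:
        raise ValueError("new nucleotide equals the reference nucleotide")
    if new not in "ACGT" or old not in "ACGT":
        raise ValueError("nucleotides must be A/C/G/T")
    if site.strand == "+":
        col, old_m, new_m = j, old, new
    else:
        col = site.length - 1 - j
        old_m, new_m = revcomp(old), revcomp(new)
    L = pwm.logodds[col]
    l_old = L[_INDEX[old_m]]
    l_new = L[_INDEX[new_m]]
    delta = float(math.exp(l_new) - math.exp(l_old))
    q_ref = float(site_weight(site, tf_concentration, params, pwm))
    # reduced site: the j-th column's contribution removed from P_s
    ref = pwm.max_score if params.normalize_by_max else 0.0
    K = params.tf_params(site.tf_name).K
    reduced = K * float(tf_concentration) * math.exp(site.score - l_old - ref)
    return SiteDelta(site=site, j=j, old=old, new=new, delta=delta,
                     reduced_weight=float(reduced), q_ref=q_ref)


def perturbed_activation(sites, deltas, weights, params: ThermoParams,
                         gene=None) -> PartitionResult:
    """Activation of a mutated genotype via the linear weight perturbations.

    Applies q -> q + q(Sbar) * delta for each perturbed site and re-runs
    the partition sums; Z_ON and Z_OFF are affine in each delta at fixed
    others (the multilinear response structure).
    """
    weights = _check_weights(sites, weights)
    seen = set()
    w = np.array(weights, dtype=float, copy=True)
    index = {id(s): i for i, s in enumerate(sites)}
    for d in deltas:
        i = index.get(id(d.site))
        if i is None:
            matches = [k for k, s in enumerate(sites) if s == d.site]
            if not matches:
                raise ValueError("delta refers to a site not in the ensemble")
            i = matches[0]
        if i in seen:
            raise ValueError("at most one delta per site")
        seen.add(i)
        w[i] = w[i] + d.reduced_weight * d.delta
    if np.any(w < 0):
        w = np.clip(w, 0.0, None)
    return partition_functions(sites, w, params, gene)


def activation_sensitivity(sites, weights, params: ThermoParams, s: int,
                           gene=None) -> float:
    """dE/dq_s by central finite differences with Richardson extrapolation."""
    weights = _check_weights(sites, weights)

    def e_at(qs):
        w = np.array(weights, dtype=float, copy=True)
        w[s] = qs
        return float(partition_functions(sites, w, params, gene).e)

    q0 = float(weights[s])
    h = max(1e-6 * abs(q0), 1e-8)
    d1 = (e_at(q0 + h) - e_at(q0 - h)) / (2 * h)
    d2 = (e_at(q0 + h / 2) - e_at(q0 - h / 2)) / h
    return (4 * d2 - d1) / 3


def classify_local_context(site, all_sites, params: ThermoParams,
                           snp_position: int, gene=None):
    """Classify the local interaction context of a polymorphic site.

    Returns a label set describing which sign-alternation mechanisms the
    site can participate in: overlap with a same-type site, a SNP inside a
    site intersection, an activator under shared repression (directly by
    this repressor and another, or mediated through a repressor-repressor
    range chain), or 'independent' when the site overlaps nothing,
    cooperates with nothing and shares no repression target.
    """
    if not site.contains(snp_position):
        raise ValueError("SNP position outside the site")
    gene = gene if gene is not None else site.gene
    others = [s for s in all_sites if s is not site]
    labels = set()

    my_reg = params.regulation_params(site.tf_name, gene)
    my_tf = params.tf_params(site.tf_name)

    overlapping = [s for s in others if site.overlaps(s)]
    for s in overlapping:
        if params.role(s.tf_name, gene) == my_reg.role:
            labels.add("overlap_same_type")
        if s.contains(snp_position):
            labels.add("snp_in_overlap")

    cooperating = [
        s for s in others
        if s.tf_name == site.tf_name and my_tf.omega > 1
        and site.gap_to(s) <= my_tf.coop_range and not site.overlaps(s)
    ]

    shares_repression = False
    if my_reg.role == "repressor":
        d1 = my_reg.rep_range
        repressors = [
            (s, params.regulation_params(s.tf_name, gene))
            for s in others
            if params.role(s.tf_name, gene) == "repressor"
        ]
        activators = [
            s for s in others if params.role(s.tf_name, gene) == "activator"
        ]
        for a in activators:
            if site.gap_to(a) <= d1:
                for r2, reg2 in repressors:
                    if r2 is not a and r2.gap_to(a) <= reg2.rep_range:
                        labels.add("shared_repression_direct")
                        shares_repression = True
        for r2, reg2 in repressors:
            if site.gap_to(r2) <= reg2.rep_range or site.gap_to(r2) <= d1:
                for a in activators:
                    if r2.gap_to(a) <= reg2.rep_range and site.gap_to(a) > d1:
                        labels.add("shared_repression_mediated")
                        shares_repression = True

    if not overlapping and not cooperating and not shares_repression:
        labels.add("independent")
    return labels
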