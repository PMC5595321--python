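"""Reaction-diffusion-delay dynamics of gap-gene expression.

mRNA u and protein v of each gene evolve on a row of nuclei over cleavage
cycles 13 and 14A:

    du_i/dt = R_u E_i(t) - lambda_u u_i + D_u(n) [(u_{i-1}-u_i) + (u_{i+1}-u_i)]
    dv_i/dt = R_v u_i(t - tau) - lambda_v v_i + D_v(n) [...]

driven by a precomputed activation field E (no feedback: the regulatory
inputs are data-driven TF profiles).  Boundary nuclei use only their
existing neighbour (zero flux).  At the C13 -> C14A transition each nucleus
divides, mother i mapping to daughters 2i, 2i+1 with copied concentrations.
Integration is a fixed-step explicit 4th-order Runge-Kutta scheme with a
stored history for the transcription-to-protein delay tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "GeneDynParams",
    "DynParams",
    "TFProfiles",
    "ActivationField",
    "ExpressionState",
    "compute_activation_field",
    "integrate_dynamics",
]


def _default_output_times():
    # mid-C13, then the midpoints of the eight C14A time classes T1-T8
    return [10.5] + [21.0 + 50.0 / 8.0 * (k - 0.5) for k in range(1, 9)]


@dataclass(frozen=True)
class GridSpec:
    """Nucleus/time grid: 50 nuclei in C13, doubling to 100 in C14A,
    21 + 50 minutes, sampled at 9 output times (mid-C13 and time classes
    T1-T8)."""

    nuclei_c13: int = 50
    duration_c13: float = 21.0
    duration_c14a: float = 50.0
    output_times: tuple = field(default_factory=lambda: tuple(_default_output_times()))

    def __post_init__(self):
        t = np.asarray(self.output_times, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("output times must be strictly increasing")
        if t[0] < 0 or t[-1] > self.total_duration:
            raise ValueError("output times must lie within the two cycles")

    @property
    def nuclei_c14a(self) -> int:
        return 2 * self.nuclei_c13

    @property
    def total_duration(self) -> float:
        return self.duration_c13 + self.duration_c14a

    def cycle_at(self, t: float) -> int:
        return 13 if t < self.duration_c13 else 14

    def nuclei_at(self, t: float) -> int:
        return self.nuclei_c13 if t < self.duration_c13 else self.nuclei_c14a

    def n_points(self, n_genes: int = 4) -> int:
        """Total grid size N over genes, nuclei and output times."""
        return n_genes * sum(self.nuclei_at(t) for t in self.output_times)

    def positions(self, t: float) -> np.ndarray:
        """Nucleus centres on the A-P axis as fractions of its length."""
        n = self.nuclei_at(t)
        return (np.arange(n) + 0.5) / n


@dataclass(frozen=True)
class GeneDynParams:
    """Kinetic constants of one gene: synthesis R (a.u./min), decay lambda
    (1/min), diffusion D (1/min, per cleavage cycle), protein delay tau
    (min)."""

    r_u: float
    r_v: float
    lambda_u: float
    lambda_v: float
    d_u: dict
    d_v: dict
    tau: float = 0.0

    def __post_init__(self):
        for name in ("r_u", "r_v", "lambda_u", "lambda_v", "tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for d in (self.d_u, self.d_v):
            if any(v < 0 for v in d.values()):
                raise ValueError("diffusion coefficients must be >= 0")


@dataclass
class DynParams:
    genes: dict  # gene name -> GeneDynParams

    def __getitem__(self, gene):
        return self.genes[gene]


class TFProfiles:
    """Spatio-temporal TF concentration profiles.

    ``data[(tf, cycle)] = (times, values)`` with values of shape
    (n_nuclei, n_times); evaluation interpolates linearly in time and
    clamps outside the supplied range.
    """

    def __init__(self, data):
        self.data = dict(data)
        for (tf, cyc), (times, values) in self.data.items():
            times = np.asarray(times, float)
            values = np.asarray(values, float)
            if values.ndim != 2 or values.shape[1] != times.size:
                raise ValueError(f"profile shape mismatch for {(tf, cyc)}")
            if np.any(values < 0):
                raise ValueError("TF concentrations must be >= 0")
            self.data[(tf, cyc)] = (times, values)

    @property
    def tfs(self):
        return sorted({tf for tf, _ in self.data})

    def at(self, tf, cycle, t):
        """Concentration vector over nuclei at time t (linear in time)."""
        times, values = self.data[(tf, cycle)]
        t = np.clip(t, times[0], times[-1])
        j = np.searchsorted(times, t, side="right") - 1
        j = min(max(j, 0), times.size - 2) if times.size > 1 else 0
        if times.size == 1:
            return values[:, 0]
        frac = (t - times[j]) / (times[j + 1] - times[j])
        return (1 - frac) * values[:, j] + frac * values[:, j + 1]

    def to_frame(self):
        import pandas as pd

        rows = []
        for (tf, cyc), (times, values) in sorted(self.data.items()):
            for jt, t in enumerate(times):
                for i in range(values.shape[0]):
                    rows.append((tf, cyc, i, t, values[i, jt]))
        return pd.DataFrame(
            rows, columns=["tf", "cycle", "nucleus", "time", "concentration"]
        )

    @classmethod
    def from_frame(cls, frame):
        data = {}
        for (tf, cyc), sub in frame.groupby(["tf", "cycle"]):
            piv = sub.pivot(index="nucleus", columns="time",
                            values="concentration").sort_index()
            data[(tf, int(cyc))] = (piv.columns.to_numpy(float),
                                    piv.to_numpy(float))
        return cls(data)


@dataclass
class ActivationField:
    """Activation probabilities E per gene on dense per-cycle time grids.

    ``values[gene][cycle]`` is an array of shape (n_nuclei(cycle),
    n_times(cycle)) aligned with ``times[cycle]``.
    """

    times: dict  # cycle -> 1d array
    values: dict  # gene -> {cycle: 2d array}
    grid: GridSpec

    @property
    def genes(self):
        return sorted(self.values)

    def at(self, gene, t, cycle=None):
        cyc = cycle if cycle is not None else self.grid.cycle_at(t)
        times = self.times[cyc]
        vals = self.values[gene][cyc]
        t = np.clip(t, times[0], times[-1])
        if times.size == 1:
            return vals[:, 0]
        j = int(np.searchsorted(times, t, side="right")) - 1
        j = min(max(j, 0), times.size - 2)
        frac = (t - times[j]) / (times[j + 1] - times[j])
        return (1 - frac) * vals[:, j] + frac * vals[:, j + 1]


def compute_activation_field(sites_by_gene, pwms, profiles: TFProfiles,
                             thermo_params, grid: GridSpec,
                             times_per_cycle=None, resolution=1.0):
    """Evaluate E for every gene, nucleus and field time point.

    Only model sites enter the ensemble.  For each gene and cycle the site
    weights are assembled from the (time-interpolated) TF concentration of
    each site's TF at every (nucleus, time) pair and a single vectorized
    partition-function pass produces the whole field.
    """
    from . import thermo as _thermo

    if times_per_cycle is None:
        t13 = np.union1d(
            np.arange(0.0, grid.duration_c13 + 1e-9, resolution),
            [grid.duration_c13],
        )
        t14 = np.union1d(
            np.arange(grid.duration_c13, grid.total_duration + 1e-9,
                      resolution),
            [grid.total_duration],
        )
        times_per_cycle = {13: t13, 14: t14}
    times_per_cycle = {c: np.asarray(t, float) for c, t in times_per_cycle.items()}

    values = {}
    for gene, sites in sites_by_gene.items():
        model_sites = [s for s in sites if s.is_model]
        values[gene] = {}
        for cyc, times in times_per_cycle.items():
            n_nuc = grid.nuclei_c13 if cyc == 13 else grid.nuclei_c14a
            m = n_nuc * times.size
            if not model_sites:
                values[gene][cyc] = np.full((n_nuc, times.size), 0.5)
                continue
            conc = {}
            for tf in {s.tf_name for s in model_sites}:
                if (tf, cyc) not in profiles.data:
                    raise ValueError(
                        f"no profile for TF {tf} in cycle {cyc}"
                    )
                cols = [profiles.at(tf, cyc, t) for t in times]
                mat = np.stack(cols, axis=1)
                if mat.shape[0] != n_nuc:
                    raise ValueError(
                        f"profile for {tf} cycle {cyc} has {mat.shape[0]} "
                        f"nuclei, grid expects {n_nuc}"
                    )
                conc[tf] = mat.reshape(m)
            weights = np.stack(
                [
                    _thermo.site_weight(s, conc[s.tf_name], thermo_params,
                                        pwms[s.tf_name])
                    for s in model_sites
                ]
            )
            res = _thermo.partition_functions(model_sites, weights,
                                              thermo_params, gene)
            values[gene][cyc] = np.asarray(res.e).reshape(n_nuc, times.size)
    return ActivationField(times=times_per_cycle, values=values, grid=grid)


@dataclass
class ExpressionState:
    """mRNA and protein concentrations at the output times.

    ``u[j]`` and ``v[j]`` are arrays of shape (n_nuclei(t_j), n_genes) for
    output time ``times[j]``; 50 nuclei at the C13 time, 100 at T1-T8.
    """

    genes: list
    times: np.ndarray
    u: list
    v: list

    def flat_v(self) -> np.ndarray:
        """Protein concentrations flattened over the full N-point grid."""
        return np.concatenate([arr.ravel() for arr in self.v])

    def flat_u(self) -> np.ndarray:
        return np.concatenate([arr.ravel() for arr in self.u])

    @property
    def n_points(self) -> int:
        return sum(arr.size for arr in self.v)

    def gene_time_v(self, gene, j):
        """Spatial protein pattern of one gene at output time index j."""
        g = self.genes.index(gene)
        return self.v[j][:, g]


def _laplacian(x):
    """Nearest-neighbour coupling with zero-flux boundaries, per column."""
    out = np.zeros_like(x)
    out[1:] += x[:-1] - x[1:]
    out[:-1] += x[1:] - x[:-1]
    return out


def integrate_dynamics(field: ActivationField, params: DynParams,
                       grid: GridSpec, init=None, step: float = 0.01,
                       check_nonnegative: bool = True) -> ExpressionState:
    """Integrate the delay reaction-diffusion equations over C13 + C14A.

    ``init`` is an optional pair (u0, v0) of shape (nuclei_c13, n_genes)
    arrays; the mRNA history for t < 0 equals u0 (zero by default).  The
    delay tau must be 0 or at least one solver step.
    """
    genes = field.genes
    n_genes = len(genes)
    gp = [params[g] for g in genes]
    for p in gp:
        if 0 < p.tau < step:
            raise ValueError("tau must be 0 or >= the solver step")

    r_u = np.array([p.r_u for p in gp])
    r_v = np.array([p.r_v for p in gp])
    lam_u = np.array([p.lambda_u for p in gp])
    lam_v = np.array([p.lambda_v for p in gp])
    tau = np.array([p.tau for p in gp])

    if init is None:
        u = np.zeros((grid.nuclei_c13, n_genes))
        v = np.zeros((grid.nuclei_c13, n_genes))
    else:
        u, v = (np.array(a, dtype=float, copy=True) for a in init)
        if u.shape != (grid.nuclei_c13, n_genes) or v.shape != u.shape:
            raise ValueError("init arrays must be (nuclei_c13, n_genes)")
        if np.any(u < 0) or np.any(v < 0):
            raise ValueError("initial concentrations must be >= 0")

    u_init = u.copy()
    # mRNA history on the step grid: hist_u[k] = u(k * step), post-division
    hist_u = [u.copy()]

    def u_delayed(t_query):
        """u(t - tau) per gene from the stored history (linear in time).

        Before t = 0 the history equals the initial condition.  The step
        grid is uniform, so the bracketing history index is arithmetic.
        """
        cols = []
        n_now = hist_u[-1].shape[0]
        for g in range(n_genes):
            tq = t_query - tau[g]
            if tq <= 0:
                base = u_init[:, g]
                cols.append(np.repeat(base, 2) if n_now > base.size else base)
                continue
            x = tq / step
            j = min(int(x), len(hist_u) - 2)
            frac = x - j
            a, b = hist_u[j][:, g], hist_u[j + 1][:, g]
            if a.size != b.size:  # bracketing the division instant
                a = np.repeat(a, 2)
            ug = (1 - frac) * a + frac * b
            if ug.size < n_now:
                ug = np.repeat(ug, 2)
            cols.append(ug)
        return np.stack(cols, axis=1)

    out_times = np.asarray(grid.output_times, float)
    out_u, out_v = [None] * out_times.size, [None] * out_times.size

    t_end = grid.total_duration
    t_div = grid.duration_c13
    next_out = 0
    n_steps = int(round(t_end / step))

    # activation field precomputed on the half-step stage grid, per cycle
    def _interp_cycle(gene, cyc, ts):
        times = field.times[cyc]
        vals = field.values[gene][cyc]
        tc = np.clip(ts, times[0], times[-1])
        if times.size == 1:
            return np.repeat(vals, ts.size, axis=1)
        j = np.clip(np.searchsorted(times, tc, side="right") - 1,
                    0, times.size - 2)
        frac = (tc - times[j]) / (times[j + 1] - times[j])
        return vals[:, j] * (1 - frac) + vals[:, j + 1] * frac

    stage_t = np.minimum(np.arange(2 * n_steps + 1) * (step / 2.0), t_end)
    k_c13 = sum(1 for k in range(n_steps) if k * step < t_div - 1e-12)
    ts13 = stage_t[: 2 * k_c13 + 1]
    ts14 = stage_t[2 * k_c13:]
    e_cache = {}
    if ts13.size:
        e_cache[13] = np.stack(
            [_interp_cycle(g, 13, ts13) for g in genes], axis=2
        ).transpose(1, 0, 2)  # (n_stages, nuclei, genes)
    if ts14.size:
        e_cache[14] = np.stack(
            [_interp_cycle(g, 14, ts14) for g in genes], axis=2
        ).transpose(1, 0, 2)
    d_cache = {
        cyc: (np.array([p.d_u[cyc] for p in gp]),
              np.array([p.d_v[cyc] for p in gp]))
        for cyc in (13, 14)
    }

    def rhs(stage_idx, u_arr, v_arr, cycle, u_del_now):
        d_u, d_v = d_cache[cycle]
        off = 0 if cycle == 13 else 2 * k_c13
        e = e_cache[cycle][stage_idx - off]
        du = r_u * e - lam_u * u_arr + d_u * _laplacian(u_arr)
        dv = r_v * u_del_now - lam_v * v_arr + d_v * _laplacian(v_arr)
        return du, dv

    def record_outputs(t0, t1, u0, v0, u1, v1):
        """Emit output times falling in (t0, t1] by linear interpolation."""
        nonlocal next_out
        while next_out < out_times.size and out_times[next_out] <= t1 + 1e-9:
            to = out_times[next_out]
            if t1 == t0:
                frac = 1.0
            else:
                frac = (to - t0) / (t1 - t0)
            frac = min(max(frac, 0.0), 1.0)
            if u0.shape != u1.shape:  # interval brackets the division
                u0 = np.repeat(u0, 2, axis=0)
                v0 = np.repeat(v0, 2, axis=0)
            out_u[next_out] = (1 - frac) * u0 + frac * u1
            out_v[next_out] = (1 - frac) * v0 + frac * v1
            next_out += 1

    for k in range(n_steps):
        t0 = k * step
        t1 = min((k + 1) * step, t_end)
        h = t1 - t0
        cycle = 13 if t0 < t_div - 1e-12 else 14
        u_prev, v_prev = u.copy(), v.copy()

        def stage_udel(ts, u_stage):
            # tau = 0 uses the stage value itself; otherwise the history
            if not np.any(tau > 0):
                return u_stage
            ud = u_delayed(ts)
            cols = [
                u_stage[:, g] if tau[g] == 0 else ud[:, g]
                for g in range(n_genes)
            ]
            return np.stack(cols, axis=1)

        s0, s1, s2 = 2 * k, 2 * k + 1, 2 * k + 2
        du1, dv1 = rhs(s0, u, v, cycle, stage_udel(t0, u))
        u2, v2 = u + 0.5 * h * du1, v + 0.5 * h * dv1
        du2, dv2 = rhs(s1, u2, v2, cycle, stage_udel(t0 + 0.5 * h, u2))
        u3, v3 = u + 0.5 * h * du2, v + 0.5 * h * dv2
        du3, dv3 = rhs(s1, u3, v3, cycle, stage_udel(t0 + 0.5 * h, u3))
        u4, v4 = u + h * du3, v + h * dv3
        du4, dv4 = rhs(s2, u4, v4, cycle, stage_udel(t1, u4))
        u = u + h / 6.0 * (du1 + 2 * du2 + 2 * du3 + du4)
        v = v + h / 6.0 * (dv1 + 2 * dv2 + 2 * dv3 + dv4)

        if check_nonnegative and (np.any(u < -1e-9) or np.any(v < -1e-9)):
            raise RuntimeError(
                "negative concentrations produced; reduce the solver step"
            )
        u = np.clip(u, 0.0, None)
        v = np.clip(v, 0.0, None)

        record_outputs(t0, t1, u_prev, v_prev, u, v)

        # nuclear division at the C13 -> C14A boundary
        if t1 >= t_div - 1e-9 and u.shape[0] == grid.nuclei_c13:
            u = np.repeat(u, 2, axis=0)
            v = np.repeat(v, 2, axis=0)

        hist_u.append(u.copy())

    record_outputs(t_end, t_end, u, v, u, v)
    return ExpressionState(genes=list(genes), times=out_times,
                           u=out_u, v=out_v)
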