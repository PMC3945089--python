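"""Statistical-thermodynamics core: ensemble occupancy of the BTM.

The model follows the Shea-Ackers picture. An enhancer's annotated binding
sites define an ensemble of configurations sigma, each a non-overlapping
subset of bound sites. Every configuration has a Boltzmann weight

    W(sigma) = prod_{bound site s} q_s  *  prod_{adjacent same-TF pairs
               within coop_dist} omega_tf,
    q_s = K_tf * [TF] * rel_affinity_s,

and a transcriptional effect Q(sigma) coupling it to the promoter-bound
basal transcriptional machinery (BTM). In DIRECT mode every bound molecule
contributes its alpha_tf (activators alpha >= 1, repressors alpha <= 1). In
SRR (short-range repression) mode repressors have no direct BTM coupling;
instead a bound repressor quenches an adjacently bound activator within
srr_range, scaling the activator's contribution from alpha to
1 + (alpha - 1) * (1 - beta) (full quench beta = 1 neutralises it).
"Adjacent" always means consecutive bound sites of the configuration.

Expression at one axis position is the fractional BTM occupancy

    E = Z_on / (Z_off + Z_on),
    Z_off = sum_sigma W(sigma),   Z_on = q_btm * sum_sigma W(sigma) Q(sigma),

with the empty configuration contributing W = Q = 1. Both sums are computed
by a dynamic program over sites in left-to-right order, linear in the site
count up to the short-range neighbour corrections, and checked in the test
suite against explicit enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import AxisProfile, PWM, Sequence, TFContext
from .scoring import mean_wpgp
from .sites import SiteAnnotation, Site, scan_sites

DIRECT = "direct"
SRR = "srr"

# a-priori "reasonable range" used whenever fitting is unconstrained
WIDE_BOUNDS = {
    "K": (1e-2, 1e2),
    "alpha_act": (1.0, 1e2),
    "alpha_rep": (1e-3, 1.0),
    "omega": (1.0, 20.0),
    "beta": (0.0, 1.0),
    "q_btm": (1e-4, 10.0),
}

_RESCALE_LIMIT = 1e250
_RESCALE_FACTOR = 2.0 ** -512


@dataclass
class TFParams:
    """Per-TF thermodynamic parameters.

    K: binding scale multiplying concentration x relative affinity.
    alpha: BTM interaction (activator >= 1, repressor <= 1 in DIRECT mode).
    omega: homotypic cooperativity for adjacent bound site pairs (>= 1).
    srr_beta: quenching efficiency in [0, 1] (repressors, SRR mode only).
    """

    K: float
    alpha: float
    omega: float = 1.0
    srr_beta: float = 0.0
    role: str = "activator"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.K) and self.K > 0):
            raise ValueError("K must be positive and finite")
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError("alpha must be positive and finite")
        if self.omega < 1:
            raise ValueError("omega must be >= 1")
        if not 0 <= self.srr_beta <= 1:
            raise ValueError("srr_beta must lie in [0, 1]")
        if self.role not in ("activator", "repressor"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "activator" and self.alpha < 1:
            raise ValueError("activator alpha must be >= 1")
        if self.role == "repressor" and self.alpha > 1:
            raise ValueError("repressor alpha must be <= 1")


@dataclass
class ThermoParams:
    """Full parameter set theta: one TFParams per TF plus the global BTM weight."""

    per_tf: list[TFParams]
    q_btm: float
    mode: str = DIRECT
    coop_dist: int = 50
    srr_range: int = 150

    def __post_init__(self) -> None:
        if not self.per_tf:
            raise ValueError("need at least one TF")
        if self.q_btm <= 0 or not np.isfinite(self.q_btm):
            raise ValueError("q_btm must be positive and finite")
        if self.mode not in (DIRECT, SRR):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_tfs(self) -> int:
        return len(self.per_tf)

    def copy(self) -> "ThermoParams":
        return ThermoParams(
            [replace(p) for p in self.per_tf],
            self.q_btm,
            self.mode,
            self.coop_dist,
            self.srr_range,
        )

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "q_btm": self.q_btm,
            "coop_dist": self.coop_dist,
            "srr_range": self.srr_range,
            "per_tf": [
                {
                    "K": p.K,
                    "alpha": p.alpha,
                    "omega": p.omega,
                    "srr_beta": p.srr_beta,
                    "role": p.role,
                }
                for p in self.per_tf
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThermoParams":
        return cls(
            [TFParams(**p) for p in d["per_tf"]],
            d["q_btm"],
            d.get("mode", DIRECT),
            d.get("coop_dist", 50),
            d.get("srr_range", 150),
        )


def count_free_parameters(theta: ThermoParams, n_tfs: int | None = None) -> int:
    """Number of free parameters: 3 per TF (K, alpha, omega) plus one global.

    In SRR mode the per-repressor quenching efficiencies are additional free
    parameters, reported separately by :func:`free_parameter_breakdown`; this
    function returns the grand total.
    """
    if n_tfs is None:
        n_tfs = theta.n_tfs
    if n_tfs < 1:
        raise ValueError("need at least one TF")
    return sum(free_parameter_breakdown(theta, n_tfs).values())


def free_parameter_breakdown(theta: ThermoParams, n_tfs: int | None = None) -> dict:
    if n_tfs is None:
        n_tfs = theta.n_tfs
    if n_tfs < 1:
        raise ValueError("need at least one TF")
    out = {"per_tf": 3 * n_tfs, "global": 1}
    if theta.mode == SRR:
        out["srr"] = sum(1 for p in theta.per_tf[:n_tfs] if p.role == "repressor")
    return out


def site_statweight(site: Site, params: TFParams, concentration: float) -> float:
    """Statistical weight of one bound site: q = K * [TF] * rel_affinity."""
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    return params.K * concentration * site.rel_affinity


def _pair_factors(theta: ThermoParams, tf_j: int, tf_i: int, gap: int):
    """(W pair factor, Q pair factor) between adjacently bound sites j < i."""
    pj, pi = theta.per_tf[tf_j], theta.per_tf[tf_i]
    w = 1.0
    if tf_j == tf_i and gap <= theta.coop_dist:
        w = pj.omega
    qf = 1.0
    if theta.mode == SRR and gap <= theta.srr_range:
        roles = (pj.role, pi.role)
        if roles == ("activator", "repressor"):
            act, rep = pj, pi
        elif roles == ("repressor", "activator"):
            act, rep = pi, pj
        else:
            act = None
        if act is not None and act.alpha > 0:
            qf = (1.0 + (act.alpha - 1.0) * (1.0 - rep.srr_beta)) / act.alpha
    return w, qf


def _base_on_factor(theta: ThermoParams, tf: int) -> float:
    p = theta.per_tf[tf]
    if theta.mode == SRR and p.role == "repressor":
        return 1.0
    return p.alpha


def _dp_partition(starts, ends, tf, aff, theta: ThermoParams, conc):
    """Vectorised partition sums over one or many concentration columns.

    conc has shape (n_tfs,) or (n_tfs, n_bins). Returns (Z_off, Z_on,
    log2_scale) with shapes matching the bin dimension; the true sums are
    Z * 2**log2_scale (joint rescaling keeps the occupancy ratio exact when
    the raw sums would overflow).
    """
    conc = np.asarray(conc, dtype=float)
    scalar = conc.ndim == 1
    if scalar:
        conc = conc[:, None]
    if np.any(conc < 0):
        raise ValueError("concentrations must be nonnegative")
    n = len(starts)
    n_bins = conc.shape[1]
    if n and np.any(np.diff(starts) < 0):
        raise ValueError("sites must be sorted by start")

    K = np.array([p.K for p in theta.per_tf])
    a_on = np.array([_base_on_factor(theta, t) for t in range(theta.n_tfs)])
    q = K[tf][:, None] * conc[tf, :] * aff[:, None] if n else np.zeros((0, n_bins))

    maxdist = max(theta.coop_dist, theta.srr_range if theta.mode == SRR else 0)
    end_order = np.argsort(ends, kind="stable") if n else np.array([], int)
    sorted_ends = ends[end_order] if n else np.array([], int)

    A_off = np.zeros((n, n_bins))
    A_on = np.zeros((n, n_bins))
    S_off = np.ones(n_bins)  # 1 (empty config) + folded A_off terms
    S_on = np.ones(n_bins)
    log2_scale = 0.0
    ptr = 0
    for i in range(n):
        while ptr < n and sorted_ends[ptr] <= starts[i]:
            j = end_order[ptr]
            S_off += A_off[j]
            S_on += A_on[j]
            ptr += 1
        corr_off = np.zeros(n_bins)
        corr_on = np.zeros(n_bins)
        if maxdist >= 0 and ptr:
            lo = np.searchsorted(sorted_ends[:ptr], starts[i] - maxdist, side="left")
            for p_ in range(lo, ptr):
                j = end_order[p_]
                gap = int(starts[i] - ends[j])
                wf, qf = _pair_factors(theta, int(tf[j]), int(tf[i]), gap)
                if wf != 1.0:
                    corr_off += A_off[j] * (wf - 1.0)
                if wf * qf != 1.0:
                    corr_on += A_on[j] * (wf * qf - 1.0)
        A_off[i] = q[i] * (S_off + corr_off)
        A_on[i] = q[i] * a_on[tf[i]] * (S_on + corr_on)
        peak = max(A_off[i].max(initial=0.0), A_on[i].max(initial=0.0),
                   S_off.max(), S_on.max())
        if peak > _RESCALE_LIMIT:
            A_off *= _RESCALE_FACTOR
            A_on *= _RESCALE_FACTOR
            S_off *= _RESCALE_FACTOR
            S_on *= _RESCALE_FACTOR
            log2_scale += 512.0
    while ptr < n:
        j = end_order[ptr]
        S_off += A_off[j]
        S_on += A_on[j]
        ptr += 1
    z_off, z_on = S_off, theta.q_btm * S_on
    if scalar:
        return float(z_off[0]), float(z_on[0]), log2_scale
    return z_off, z_on, log2_scale


def partition_sums(
    annotation: SiteAnnotation, theta: ThermoParams, concentrations
) -> tuple[float, float]:
    """(Z_off, Z_on) summed over all non-overlapping binding configurations."""
    if theta.n_tfs != len(annotation.tf_names):
        raise ValueError("theta must provide one TFParams per annotated TF")
    starts, ends, tf, aff = annotation.arrays()
    z_off, z_on, s = _dp_partition(starts, ends, tf, aff, theta,
                                   np.asarray(concentrations, float))
    return z_off * 2.0 ** s, z_on * 2.0 ** s


def brute_force_partition(
    annotation: SiteAnnotation, theta: ThermoParams, concentrations
) -> tuple[float, float]:
    """Explicit enumeration of every configuration (oracle for the DP)."""
    sites = annotation.sites
    if len(sites) > 20:
        raise ValueError("brute force capped at 20 sites")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be nonnegative")

    z_off, z_on = 0.0, 0.0
    n = len(sites)

    def weight_of(config: list[Site]) -> tuple[float, float]:
        w, qv = 1.0, 1.0
        for k, s in enumerate(config):
            p = theta.per_tf[s.tf_index]
            w *= p.K * conc[s.tf_index] * s.rel_affinity
            qv *= _base_on_factor(theta, s.tf_index)
            if k:
                prev = config[k - 1]
                gap = s.start - prev.end
                wf, qf = _pair_factors(theta, prev.tf_index, s.tf_index, gap)
                w *= wf
                qv *= qf
        return w, qv

    def rec(idx: int, config: list[Site]) -> None:
        nonlocal z_off, z_on
        if idx == n:
            w, qv = weight_of(config)
            z_off += w
            z_on += w * qv
            return
        rec(idx + 1, config)  # idx unbound
        s = sites[idx]
        if not config or s.start >= config[-1].end:
            config.append(s)
            rec(idx + 1, config)
            config.pop()

    rec(0, [])
    return z_off, theta.q_btm * z_on


def occupancy_profile(
    annotation: SiteAnnotation, theta: ThermoParams, conc_matrix: np.ndarray
) -> np.ndarray:
    """E(x) = Z_on / (Z_off + Z_on) per axis bin; conc_matrix is (n_tfs, n_bins)."""
    starts, ends, tf, aff = annotation.arrays()
    z_off, z_on, _ = _dp_partition(starts, ends, tf, aff, theta, conc_matrix)
    return z_on / (z_off + z_on)


def _context_concentrations(
    annotation: SiteAnnotation, ctx: TFContext
) -> np.ndarray:
    """Concentration matrix reordered to the annotation's TF indexing."""
    rows = []
    for name in annotation.tf_names:
        if name not in ctx.tf_names:
            raise KeyError(f"TF {name!r} annotated but absent from the context")
        rows.append(ctx.profiles[ctx.index_of(name)].values)
    return np.stack(rows)


def predict_expression(
    seq_or_sites,
    theta: ThermoParams,
    ctx: TFContext,
    pwms: list[PWM] | None = None,
    rel_affinity_threshold: float = 0.01,
) -> AxisProfile:
    """Predicted expression readout of one sequence along the axis.

    Accepts either a pre-computed :class:`SiteAnnotation` or a
    :class:`Sequence` (then ``pwms`` is required and sites are scanned
    first). Output is the BTM occupancy per bin, in (0, 1).
    """
    if isinstance(seq_or_sites, Sequence):
        if pwms is None:
            raise ValueError("pwms required when predicting from a raw sequence")
        annotation = scan_sites(seq_or_sites, pwms, rel_affinity_threshold)
    else:
        annotation = seq_or_sites
    if theta.n_tfs != len(annotation.tf_names):
        raise ValueError("theta must provide one TFParams per annotated TF")
    conc = _context_concentrations(annotation, ctx)
    return AxisProfile(occupancy_profile(annotation, theta, conc), ctx.axis)


# ---------------------------------------------------------------------------
# theta <-> optimisation vector


def theta_to_vector(theta: ThermoParams) -> np.ndarray:
    """Flatten theta into log-space (betas linear), for numerical optimisers."""
    v = []
    for p in theta.per_tf:
        v += [np.log(p.K), np.log(p.alpha), np.log(p.omega)]
        if theta.mode == SRR and p.role == "repressor":
            v.append(p.srr_beta)
    v.append(np.log(theta.q_btm))
    return np.array(v)


def theta_from_vector(v: np.ndarray, template: ThermoParams) -> ThermoParams:
    out = template.copy()
    k = 0
    for p in out.per_tf:
        p.K = float(np.exp(v[k]))
        p.alpha = float(np.exp(v[k + 1]))
        p.omega = float(np.exp(v[k + 2]))
        k += 3
        if out.mode == SRR and p.role == "repressor":
            p.srr_beta = float(np.clip(v[k], 0.0, 1.0))
            k += 1
    out.q_btm = float(np.exp(v[k]))
    return out


def theta_bounds(init: ThermoParams, constrained: bool) -> list[tuple[float, float]]:
    """Optimiser box per vector entry.

    Constrained mode restricts every parameter to [init/2, 2*init] (the
    constrained estimation strategy); unconstrained mode uses the package's
    wide a-priori ranges. Role/validity constraints (activator alpha >= 1,
    repressor alpha <= 1, omega >= 1, beta in [0, 1]) always apply.
    """
    ln2 = np.log(2.0)
    bounds: list[tuple[float, float]] = []

    def box(value, lo, hi, log=True):
        if log:
            lo, hi = np.log(lo), np.log(hi)
            value = np.log(value)
        if constrained:
            lo, hi = max(lo, value - ln2), min(hi, value + ln2)
        if lo > hi:  # init sits at the edge of the a-priori range
            lo = hi = np.clip(value, lo, hi)
        return (float(lo), float(hi))

    for p in init.per_tf:
        bounds.append(box(p.K, *WIDE_BOUNDS["K"]))
        a_lo, a_hi = (
            WIDE_BOUNDS["alpha_act"] if p.role == "activator"
            else WIDE_BOUNDS["alpha_rep"]
        )
        bounds.append(box(p.alpha, a_lo, a_hi))
        bounds.append(box(p.omega, *WIDE_BOUNDS["omega"]))
        if init.mode == SRR and p.role == "repressor":
            lo, hi = WIDE_BOUNDS["beta"]
            if constrained:
                lo, hi = max(lo, p.srr_beta / 2), min(hi, 2 * p.srr_beta)
                if lo > hi:
                    lo = hi = p.srr_beta
            bounds.append((lo, hi))
    bounds.append(box(init.q_btm, *WIDE_BOUNDS["q_btm"]))
    return bounds


def fit_enhancer_set(
    enhancers,
    ctx: TFContext,
    init: ThermoParams,
    bounds_mode: str = "constrained",
    pwms: list[PWM] | None = None,
    rel_affinity_threshold: float = 0.01,
    seed: int = 0,
    n_restarts: int = 5,
) -> ThermoParams:
    """Fit theta to a panel of enhancers by maximising the mean w-PGP.

    ``enhancers`` is a list of (Sequence | SiteAnnotation, AxisProfile)
    pairs on the context's grid. ``bounds_mode`` is 'constrained' (two-fold
    box around ``init``) or 'unconstrained' (wide a-priori ranges). The
    optimiser alternates Nelder-Mead simplex and bounded quasi-Newton
    rounds with seeded random restarts inside the box.
    """
    from .optimize import alternating_maximize  # local import: avoid cycle

    if bounds_mode not in ("constrained", "unconstrained"):
        raise ValueError(f"unknown bounds_mode {bounds_mode!r}")
    if not enhancers:
        raise ValueError("need at least one enhancer")
    pairs = []
    for seq_or_sites, profile in enhancers:
        if isinstance(seq_or_sites, Sequence):
            if pwms is None:
                raise ValueError("pwms required for raw sequences")
            ann = scan_sites(seq_or_sites, pwms, rel_affinity_threshold)
        else:
            ann = seq_or_sites
        if np.all(profile.values == 0):
            raise ValueError(
                f"enhancer {ann.sequence_id!r}: all-zero target profile"
            )
        pairs.append((ann, _context_concentrations(ann, ctx), profile.values))

    template = init.copy()

    def objective(v: np.ndarray) -> float:
        theta = theta_from_vector(v, template)
        preds = []
        for ann, conc, target in pairs:
            starts, ends, tf, aff = ann.arrays()
            z_off, z_on, _ = _dp_partition(starts, ends, tf, aff, theta, conc)
            preds.append((z_on / (z_off + z_on), target))
        return mean_wpgp(preds)

    x0 = theta_to_vector(init)
    bounds = theta_bounds(init, constrained=(bounds_mode == "constrained"))
    best = alternating_maximize(
        objective, x0, bounds, seed=seed, n_restarts=n_restarts
    )
    return theta_from_vector(best, template)
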