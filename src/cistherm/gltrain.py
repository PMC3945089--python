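"""Two-tiered locus-level training.

Tier one is the thermodynamic readout of candidate sequence windows; tier
two aggregates selected windows into the gene's prediction as a nonnegative
weighted sum, clipped to [0, 1]. Training alternates:

Phase 1   enumerate every window on a (start_step, length grid) over the
          locus and keep, for each expression stripe, the n_candidates
          windows whose readout best fits that stripe (w-PGP).
Phase 2   greedy inclusion: stripes are processed anterior to posterior;
          for stripe i every remaining candidate is evaluated by
          re-optimising the window weights against the gene profile
          restricted to stripes 1..i, and the best candidate is accepted
          only if it strictly improves the running best score.
Outer     the thermodynamic parameters are then re-fitted (constrained to a
          two-fold box around their initial values) with windows and
          weights fixed, and the loop returns to Phase 1, stopping after
          outer_iters iterations or when the score improves by < delta.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import AxisProfile, PWM, Sequence, TFContext
from .optimize import alternating_maximize, maximize_nonnegative
from .scoring import wpgp_arrays
from .sites import SiteAnnotation, scan_sites
from .thermo import (
    ThermoParams,
    _context_concentrations,
    _dp_partition,
    theta_bounds,
    theta_from_vector,
    theta_to_vector,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Window:
    """A candidate sequence window, 0-based half-open in locus coordinates."""

    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class StripeProfile:
    """One expression stripe: the gene profile inside its extent, 0 elsewhere."""

    index: int
    profile: AxisProfile
    extent: tuple[int, int]  # bin indices, half-open

    @property
    def axis_extent(self) -> tuple[float, float]:
        lo, hi = self.extent
        return float(self.profile.axis[lo]), float(self.profile.axis[hi - 1])


@dataclass
class TrainConfig:
    """Training settings; the defaults are the published operating point."""

    n_candidates: int = 5
    start_step: int = 100
    min_len: int = 500
    max_len: int = 2500
    len_step: int = 50
    outer_iters: int = 100  # N_I
    delta: float = 1e-4
    on_threshold: float = 0.5
    rel_affinity_threshold: float = 0.01
    accessibility_mask: list[tuple[int, int]] | None = None
    mask_min_coverage: float = 0.5
    theta_refit_restarts: int = 0
    seed: int = 0


@dataclass
class GLModel:
    """A trained two-tiered model: windows, their weights, and theta."""

    windows: list[Window]
    weights: np.ndarray
    theta: ThermoParams
    score: float
    annotation: SiteAnnotation
    axis: np.ndarray
    gene_profile: AxisProfile | None = None
    history: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "windows": [{"start": w.start, "length": w.length} for w in self.windows],
            "weights": [float(w) for w in self.weights],
            "theta": self.theta.to_dict(),
            "score": self.score,
            "axis": [float(x) for x in self.axis],
        }


def decompose_stripes(
    gene_profile: AxisProfile, on_threshold: float = 0.5
) -> list[StripeProfile]:
    """Split a profile into its contiguous ON domains (anterior to posterior).

    A bin is ON iff its value >= on_threshold (the OFF convention is
    value < threshold). Each stripe's profile equals the gene profile
    inside the run and is zero elsewhere.
    """
    if not 0 < on_threshold < 1:
        raise ValueError("on_threshold must lie in (0, 1)")
    v = gene_profile.values
    if v.max() > 1 + 1e-9:
        raise ValueError("gene profile must be scaled to [0, 1]")
    on = v >= on_threshold
    if not on.any():
        raise ValueError("no expression domains: no bin reaches the ON threshold")
    stripes: list[StripeProfile] = []
    i = 0
    n = len(v)
    while i < n:
        if on[i]:
            j = i
            while j < n and on[j]:
                j += 1
            masked = np.zeros_like(v)
            masked[i:j] = v[i:j]
            stripes.append(
                StripeProfile(len(stripes), AxisProfile(masked, gene_profile.axis), (i, j))
            )
            i = j
        else:
            i += 1
    return stripes


def enumerate_windows(locus_length: int, cfg: TrainConfig) -> list[Window]:
    """All windows on the (start_step, length) grid that fit inside the locus."""
    if locus_length < cfg.min_len:
        raise ValueError(
            f"locus ({locus_length} bp) shorter than the minimum window "
            f"({cfg.min_len} bp)"
        )
    out = []
    for start in range(0, locus_length - cfg.min_len + 1, cfg.start_step):
        for length in range(cfg.min_len, cfg.max_len + 1, cfg.len_step):
            if start + length <= locus_length:
                out.append(Window(start, length))
    return out


def _mask_coverage(window: Window, mask: list[tuple[int, int]]) -> float:
    covered = 0
    for lo, hi in mask:
        covered += max(0, min(hi, window.end) - max(lo, window.start))
    return covered / window.length


def window_passes_mask(window: Window, cfg: TrainConfig) -> bool:
    if cfg.accessibility_mask is None:
        return True
    return _mask_coverage(window, cfg.accessibility_mask) >= cfg.mask_min_coverage


class ReadoutCache:
    """Thermodynamic readouts of windows over one locus annotation.

    Windows whose site subsets coincide share one dynamic-programming run;
    the cache is valid for one (theta, concentration) pair.
    """

    def __init__(self, annotation: SiteAnnotation, theta: ThermoParams,
                 conc: np.ndarray):
        self.annotation = annotation
        self.theta = theta
        self.conc = conc
        self._starts, self._ends, self._tf, self._aff = annotation.arrays()
        self._by_subset: dict[tuple, np.ndarray] = {}
        self._by_window: dict[Window, np.ndarray] = {}
        self._basal = None

    def _site_indices(self, window: Window) -> np.ndarray:
        lo = np.searchsorted(self._starts, window.start, side="left")
        hi = np.searchsorted(self._starts, window.end, side="left")
        idx = np.arange(lo, hi)
        return idx[self._ends[idx] <= window.end]

    @property
    def basal(self) -> np.ndarray:
        if self._basal is None:
            q = self.theta.q_btm
            self._basal = np.full(self.conc.shape[1], q / (1.0 + q))
        return self._basal

    def readout(self, window: Window) -> np.ndarray:
        cached = self._by_window.get(window)
        if cached is not None:
            return cached
        idx = self._site_indices(window)
        key = tuple(idx)
        sub = self._by_subset.get(key)
        if sub is None:
            if len(idx) == 0:
                sub = self.basal
            else:
                z_off, z_on, _ = _dp_partition(
                    self._starts[idx], self._ends[idx], self._tf[idx],
                    self._aff[idx], self.theta, self.conc,
                )
                sub = z_on / (z_off + z_on)
            self._by_subset[key] = sub
        self._by_window[window] = sub
        return sub


def phase1_scan(
    locus,
    stripes: list[StripeProfile],
    theta: ThermoParams,
    ctx: TFContext,
    cfg: TrainConfig,
    pwms: list[PWM] | None = None,
    annotation: SiteAnnotation | None = None,
):
    """Find the n_candidates best windows for every stripe.

    Returns (candidates, cache): ``candidates[i]`` is the list of top
    windows for stripe i (best first, ties broken towards leftmost start
    then shortest length), ``cache`` the shared readout cache.
    """
    if annotation is None:
        if isinstance(locus, SiteAnnotation):
            annotation = locus
        else:
            if pwms is None:
                raise ValueError("pwms required when scanning a raw sequence")
            annotation = scan_sites(locus, pwms, cfg.rel_affinity_threshold)
    conc = _context_concentrations(annotation, ctx)
    cache = ReadoutCache(annotation, theta, conc)
    windows = [
        w for w in enumerate_windows(annotation.seq_length, cfg)
        if window_passes_mask(w, cfg)
    ]
    # windows with identical site content have identical readouts and are the
    # same candidate; keep only the shortest (then leftmost) representative so
    # site-free flanks neither pad winners nor flood the candidate pools
    by_sites: dict[tuple, Window] = {}
    for w in windows:
        key = tuple(cache._site_indices(w))
        best = by_sites.get(key)
        if best is None or (w.length, w.start) < (best.length, best.start):
            by_sites[key] = w
    windows = sorted(by_sites.values(), key=lambda w: (w.start, w.length))
    scored: dict[int, list] = {s.index: [] for s in stripes}
    for w in windows:
        pred = cache.readout(w)
        for s in stripes:
            score = wpgp_arrays(pred, s.profile.values).score
            scored[s.index].append((-score, w.length, w.start, w))
    candidates: dict[int, list[Window]] = {}
    for s in stripes:
        ranked = sorted(scored[s.index])
        candidates[s.index] = [item[3] for item in ranked[: cfg.n_candidates]]
    return candidates, cache


def aggregate(readouts: list[np.ndarray], weights: np.ndarray) -> np.ndarray:
    """Weighted sum of window readouts, clipped to [0, 1] before scoring."""
    if len(readouts) == 0:
        raise ValueError("no readouts")
    stack = np.stack(readouts)
    return np.clip(weights @ stack, 0.0, 1.0)


def optimize_weights(
    windows: list[Window],
    readouts: list[np.ndarray],
    target: np.ndarray,
    init_weights: np.ndarray | None = None,
):
    """Nonnegative window weights maximising the w-PGP of the aggregate.

    Seeded by nonnegative least squares against the target, then refined by
    alternating simplex / bounded quasi-Newton. Returns (weights, score).
    """
    from scipy.optimize import nnls

    if not windows:
        raise ValueError("need at least one window")
    stack = np.stack(readouts)
    if np.all(stack == 0):
        warnings.warn("all window readouts are zero; weights set to 0")
        return np.zeros(len(windows)), 0.0

    def objective(w):
        return wpgp_arrays(np.clip(w @ stack, 0.0, 1.0), target).score

    starts = []
    w_nnls, _ = nnls(stack.T, target)
    starts.append(w_nnls)
    if init_weights is not None:
        starts.append(np.maximum(np.asarray(init_weights, float), 0.0))
    best_w, best_s = None, -1.0
    for w0 in starts:
        w = maximize_nonnegative(objective, w0)
        s = objective(w)
        if s > best_s:
            best_w, best_s = w, s
    return best_w, best_s


def _cumulative_target(stripes: list[StripeProfile], upto: int,
                       gene_profile: AxisProfile) -> np.ndarray:
    """The gene profile limited to the first upto+1 stripes.

    Later stripes are erased (set to 0) while valleys keep their real
    sub-threshold values; zeroing the valleys instead would reward
    suppressing expression below the real basal level and systematically
    favour windows padded with repressive flanking sequence.
    """
    v = gene_profile.values.copy()
    for s in stripes[upto + 1 :]:
        lo, hi = s.extent
        v[lo:hi] = 0.0
    return v


def phase2_greedy(
    candidates: dict[int, list[Window]],
    theta: ThermoParams,
    ctx: TFContext,
    gene_profile: AxisProfile,
    cfg: TrainConfig,
    cache: ReadoutCache,
    stripes: list[StripeProfile],
) -> GLModel:
    """Greedy window inclusion, stripes processed anterior to posterior."""
    pools = {i: list(ws) for i, ws in candidates.items()}
    selected: list[Window] = []
    weights = np.zeros(0)
    best_score = 0.0
    for s in stripes:
        target = _cumulative_target(stripes, s.index, gene_profile)
        # Re-baseline the running best against the extended target: the score
        # of the carried-over model drops when a new stripe enters the target,
        # and acceptance must compare like with like.
        if selected:
            weights, best_score = optimize_weights(
                selected, [cache.readout(w) for w in selected], target, weights
            )
        else:
            best_score = 0.0
        pool = pools.get(s.index, [])
        while pool:
            evals = []
            for w in pool:
                trial = selected + [w]
                init = np.concatenate([weights, [1.0]]) if len(weights) else None
                w_opt, score = optimize_weights(
                    trial, [cache.readout(t) for t in trial], target, init
                )
                evals.append((w, score, w_opt))
            top = max(e[1] for e in evals)
            # candidates within delta of the top are tied (improvements below
            # delta are immaterial throughout); parsimony breaks the tie
            w_star, score_star, w_opt = min(
                (e for e in evals if e[1] >= top - cfg.delta),
                key=lambda e: (e[0].length, e[0].start),
            )
            # improvement must exceed the small constant delta: bare float
            # gains from an extra degree of freedom would otherwise admit
            # near-duplicate windows
            if score_star > best_score + cfg.delta:
                selected.append(w_star)
                weights = w_opt
                best_score = score_star
                pool.remove(w_star)
            else:
                break

    if selected:
        # final weight fit against the full gene profile (incl. sub-threshold bins)
        weights, final_score = optimize_weights(
            selected, [cache.readout(w) for w in selected],
            gene_profile.values, weights,
        )
    else:
        weights, final_score = np.zeros(0), 0.0
    return GLModel(
        selected, weights, theta.copy(), final_score,
        cache.annotation, gene_profile.axis, gene_profile,
    )


def predict_gene_expression(model: GLModel, ctx: TFContext) -> AxisProfile:
    """Weighted sum of the model windows' readouts, clipped to [0, 1]."""
    if not model.windows:
        return AxisProfile(np.zeros(ctx.n_bins), ctx.axis)
    conc = _context_concentrations(model.annotation, ctx)
    cache = ReadoutCache(model.annotation, model.theta, conc)
    pred = aggregate([cache.readout(w) for w in model.windows], model.weights)
    return AxisProfile(pred, ctx.axis)


def refit_theta(
    model: GLModel,
    ctx: TFContext,
    init_theta: ThermoParams,
    target: np.ndarray,
    constrained: bool = True,
    seed: int = 0,
    n_restarts: int = 0,
) -> tuple[ThermoParams, float]:
    """Re-fit theta with windows and weights held fixed.

    The box is [init/2, 2*init] per parameter in constrained mode (around
    the pre-training values, not the current iterate), else the wide
    a-priori ranges. Returns (theta, aggregate score under it).
    """
    conc = _context_concentrations(model.annotation, ctx)
    starts_l, ends_l, tf_l, aff_l = model.annotation.arrays()
    subsets = []
    helper = ReadoutCache(model.annotation, init_theta, conc)
    for w in model.windows:
        subsets.append(helper._site_indices(w))
    template = init_theta.copy()

    def objective(v):
        theta = theta_from_vector(v, template)
        readouts = []
        for idx in subsets:
            if len(idx) == 0:
                readouts.append(np.full(conc.shape[1], theta.q_btm / (1 + theta.q_btm)))
                continue
            z_off, z_on, _ = _dp_partition(
                starts_l[idx], ends_l[idx], tf_l[idx], aff_l[idx], theta, conc
            )
            readouts.append(z_on / (z_off + z_on))
        return wpgp_arrays(aggregate(readouts, model.weights), target).score

    if not model.windows:
        return model.theta.copy(), 0.0
    x0 = theta_to_vector(model.theta)
    bounds = theta_bounds(init_theta, constrained=constrained)
    best = alternating_maximize(objective, x0, bounds, seed=seed,
                                n_restarts=n_restarts)
    return theta_from_vector(best, template), objective(best)


def fit_locus(
    locus,
    gene_profile: AxisProfile,
    ctx: TFContext,
    init_theta: ThermoParams,
    cfg: TrainConfig | None = None,
    pwms: list[PWM] | None = None,
    annotation: SiteAnnotation | None = None,
    constrained: bool = True,
) -> GLModel:
    """Train the two-tiered model on one locus.

    ``locus`` may be a Sequence (``pwms`` required) or a pre-computed
    SiteAnnotation (also accepted via ``annotation=``, e.g. for
    site-relocation controls). ``init_theta`` should come from a panel
    pre-fit on external enhancers (or its synthetic equivalent);
    ``constrained=False`` lifts the two-fold box (control experiments).
    Returns the best model seen across outer iterations, with the score
    trajectory in ``model.history``.
    """
    cfg = cfg or TrainConfig()
    if annotation is None:
        if isinstance(locus, SiteAnnotation):
            annotation = locus
        else:
            if pwms is None:
                raise ValueError("pwms required when fitting from a raw sequence")
            annotation = scan_sites(locus, pwms, cfg.rel_affinity_threshold)
    stripes = decompose_stripes(gene_profile, cfg.on_threshold)
    theta = init_theta.copy()
    best: GLModel | None = None
    history: list[dict] = []
    for it in range(cfg.outer_iters):
        candidates, cache = phase1_scan(
            annotation, stripes, theta, ctx, cfg, annotation=annotation
        )
        model_it = phase2_greedy(
            candidates, theta, ctx, gene_profile, cfg, cache, stripes
        )
        new_theta, refit_score = refit_theta(
            model_it, ctx, init_theta, gene_profile.values,
            constrained=constrained, seed=cfg.seed,
            n_restarts=cfg.theta_refit_restarts,
        )
        prev_best = best.score if best is not None else 0.0
        if best is None or model_it.score > best.score:
            best = model_it
        if refit_score > best.score:
            best = GLModel(
                model_it.windows, model_it.weights, new_theta, refit_score,
                annotation, gene_profile.axis, gene_profile,
            )
        history.append(
            {"iteration": it, "phase2_score": model_it.score,
             "refit_score": refit_score, "best_score": best.score}
        )
        logger.info(
            "outer iteration %d: phase2 %.4f, theta refit %.4f, best %.4f",
            it, model_it.score, refit_score, best.score,
        )
        improvement = best.score - prev_best
        theta = new_theta
        if it > 0 and improvement < cfg.delta:
            break
    best.history = history
    return best
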