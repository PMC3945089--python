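"""Post-fit analyses of a trained locus model.

* Metropolis-Hastings sampling of regulatory architectures (which windows
  carry weight, and how much) in proportion to their fit score.
* In-silico TF knockdowns and the TF-to-stripe interaction network they
  imply.
* The enhancer cross-talk hypergraph: does interpreting sites of one
  selected enhancer together with sites of another improve or worsen the
  locus model?
* The two-enhancer promoter-competition closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gltrain import (
    GLModel,
    ReadoutCache,
    TrainConfig,
    Window,
    StripeProfile,
    aggregate,
    enumerate_windows,
    optimize_weights,
    predict_gene_expression,
)
from .io import AxisProfile, TFContext
from .scoring import wpgp_arrays
from .sites import SiteAnnotation, scan_sites
from .thermo import ThermoParams, _context_concentrations

EMPTY_ARCHITECTURE_SCORE = 1e-6  # score floor for the all-zero bit vector


@dataclass
class ArchitectureSample:
    """One MCMC sample: a sparse extended weight vector over the window grid."""

    active_indices: np.ndarray
    active_weights: np.ndarray
    score: float
    n_windows: int

    def ext_weights(self) -> np.ndarray:
        v = np.zeros(self.n_windows)
        v[self.active_indices] = self.active_weights
        return v

    def bits(self) -> np.ndarray:
        b = np.zeros(self.n_windows, dtype=bool)
        b[self.active_indices] = True
        return b


@dataclass(frozen=True)
class NetworkEdge:
    tf: str
    stripe_index: int
    sign: str  # 'activation' | 'repression'
    evidence: dict


@dataclass(frozen=True)
class Hyperedge:
    """Donor sites interpreted together with an acceptor enhancer's sites."""

    donor_enhancer: int
    donor_sites: tuple[int, ...]  # global site indices, contiguous in donor order
    acceptor_enhancer: int
    weight: float  # delta w-PGP; negative = avoided interaction


def propose_bits(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One proposal move: pick two distinct bits, toggle each with prob 1/2.

    Leaves the vector unchanged with probability 1/4, flips one bit with
    probability 1/2 and two bits with probability 1/4; all vectors at a
    given Hamming distance are equally likely.
    """
    n = len(bits)
    if n < 2:
        raise ValueError("need at least two grid windows")
    new = bits.copy()
    i, j = rng.choice(n, size=2, replace=False)
    for k in (i, j):
        if rng.random() < 0.5:
            new[k] = ~new[k]
    return new


def mcmc_sample(
    locus,
    gene_profile: AxisProfile,
    theta: ThermoParams,
    ctx: TFContext,
    cfg: TrainConfig | None = None,
    n_samples: int = 10000,
    rng_seed: int = 0,
    windows: list[Window] | None = None,
    pwms=None,
    readouts: list[np.ndarray] | None = None,
):
    """Sample architectures with probability proportional to their score.

    The state is an extended weight vector over the full window grid
    (starts at multiples of start_step, lengths min_len..max_len in
    len_step increments). A move toggles at most two grid bits; weights
    over the proposed active set are drawn from a flat Dirichlet, and the
    proposal is accepted with probability min(1, score_new / score_old).
    The score of the empty architecture is floored at a small epsilon.

    Returns (samples, mean_weights, windows): every post-move state, the
    per-grid-window average weight over the chain, and the grid.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cfg = cfg or TrainConfig()
    if readouts is not None:
        if windows is None:
            raise ValueError("explicit readouts require explicit windows")
        stack = np.stack(readouts)
    else:
        if isinstance(locus, SiteAnnotation):
            annotation = locus
        else:
            if pwms is None:
                raise ValueError("pwms required when sampling from a raw sequence")
            annotation = scan_sites(locus, pwms, cfg.rel_affinity_threshold)
        if windows is None:
            windows = enumerate_windows(annotation.seq_length, cfg)
        conc = _context_concentrations(annotation, ctx)
        cache = ReadoutCache(annotation, theta, conc)
        stack = np.stack([cache.readout(w) for w in windows])
    target = gene_profile.values
    n = len(windows)
    rng = np.random.default_rng(rng_seed)

    def draw_weights(bits: np.ndarray) -> np.ndarray:
        active = np.nonzero(bits)[0]
        if len(active) == 0:
            return np.empty(0)
        return rng.dirichlet(np.ones(len(active)))

    def score_of(bits: np.ndarray, w_active: np.ndarray) -> float:
        active = np.nonzero(bits)[0]
        if len(active) == 0:
            return EMPTY_ARCHITECTURE_SCORE
        pred = np.clip(w_active @ stack[active], 0.0, 1.0)
        s = wpgp_arrays(pred, target).score
        return max(s, EMPTY_ARCHITECTURE_SCORE)

    bits = np.zeros(n, dtype=bool)
    w_active = draw_weights(bits)
    score = score_of(bits, w_active)

    samples: list[ArchitectureSample] = []
    weight_sum = np.zeros(n)
    for _ in range(n_samples):
        new_bits = propose_bits(bits, rng)
        new_w = draw_weights(new_bits)
        new_score = score_of(new_bits, new_w)
        if rng.random() < min(1.0, new_score / score):
            bits, w_active, score = new_bits, new_w, new_score
        active = np.nonzero(bits)[0]
        samples.append(ArchitectureSample(active, w_active.copy(), score, n))
        weight_sum[active] += w_active
    return samples, weight_sum / n_samples, windows


def knockdown_tf(model: GLModel, ctx: TFContext, tf: str) -> AxisProfile:
    """Re-run (not re-fit) the trained model with one TF's concentration zeroed."""
    return predict_gene_expression(model, ctx.with_knockdown(tf))


def _half_max_crossings(values: np.ndarray, axis: np.ndarray,
                        peak_bin: int) -> tuple[float, float]:
    """Axis positions where the profile crosses half its peak, on each flank."""
    level = values[peak_bin] / 2.0
    left = axis[0]
    for i in range(peak_bin, 0, -1):
        if values[i - 1] < level <= values[i]:
            f = (level - values[i - 1]) / (values[i] - values[i - 1])
            left = axis[i - 1] + f * (axis[i] - axis[i - 1])
            break
    right = axis[-1]
    for i in range(peak_bin, len(values) - 1):
        if values[i + 1] < level <= values[i]:
            f = (values[i] - level) / (values[i] - values[i + 1])
            right = axis[i] + f * (axis[i + 1] - axis[i])
            break
    return float(left), float(right)


def classify_knockdown_effect(
    baseline: AxisProfile,
    knocked: AxisProfile,
    stripe: StripeProfile,
    level_threshold_pct: float = 2.0,
    boundary_threshold_pct: float = 1.0,
) -> tuple[str, dict] | None:
    """Edge call for one (TF knockdown, stripe) pair.

    Weakening the stripe's peak by >= level_threshold_pct implies an
    activation edge; strengthening it by the same margin and/or shifting a
    half-maximum boundary by >= boundary_threshold_pct of the axis implies
    a repression edge. Level changes are relative to the baseline peak;
    boundaries are measured at half of each profile's own stripe peak.
    """
    lo, hi = stripe.extent
    base = baseline.values
    peak_bin = lo + int(np.argmax(base[lo:hi]))
    base_peak = base[peak_bin]
    if base_peak <= 0:
        warnings.warn(f"stripe {stripe.index}: zero predicted peak; skipped")
        return None
    kd = knocked.values
    kd_peak_bin = lo + int(np.argmax(kd[lo:hi]))
    level_change_pct = 100.0 * (kd[peak_bin] - base_peak) / base_peak

    bl, br = _half_max_crossings(base, baseline.axis, peak_bin)
    if kd[kd_peak_bin] > 0:
        kl, kr = _half_max_crossings(kd, knocked.axis, kd_peak_bin)
        boundary_shift_pct = 100.0 * max(abs(kl - bl), abs(kr - br))
    else:
        boundary_shift_pct = 0.0

    evidence = {
        "level_change_pct": float(level_change_pct),
        "boundary_shift_pct": float(boundary_shift_pct),
    }
    if level_change_pct <= -level_threshold_pct:
        return "activation", evidence
    if (level_change_pct >= level_threshold_pct
            or boundary_shift_pct >= boundary_threshold_pct):
        return "repression", evidence
    return None


def infer_network(
    model: GLModel, ctx: TFContext, stripes: list[StripeProfile]
) -> list[NetworkEdge]:
    """TF-to-stripe edges from in-silico knockdown of every TF in turn."""
    baseline = predict_gene_expression(model, ctx)
    edges: list[NetworkEdge] = []
    for tf in ctx.tf_names:
        knocked = knockdown_tf(model, ctx, tf)
        for stripe in stripes:
            call = classify_knockdown_effect(baseline, knocked, stripe)
            if call is not None:
                sign, evidence = call
                edges.append(NetworkEdge(tf, stripe.index, sign, evidence))
    return edges


def _enhancer_site_indices(model: GLModel) -> list[np.ndarray]:
    starts, ends, _, _ = model.annotation.arrays()
    out = []
    for w in sorted(model.windows, key=lambda w: (w.start, w.length)):
        lo = np.searchsorted(starts, w.start, side="left")
        hi = np.searchsorted(starts, w.end, side="left")
        idx = np.arange(lo, hi)
        out.append(idx[ends[idx] <= w.end])
    return out


def crosstalk_hypergraph(
    model: GLModel,
    ctx: TFContext,
    gene_profile: AxisProfile,
    max_block: int = 5,
    refit_theta_box: bool = True,
) -> list[Hyperedge]:
    """Probe cross-enhancer site interactions.

    For every ordered pair of selected enhancers and every block of 1 to
    max_block contiguous donor sites, a new model is optimised in which the
    acceptor enhancer's site set is augmented by the donor block (window
    weights re-fitted, and theta re-fitted within its two-fold box when
    ``refit_theta_box``); the hyperedge weight is the new score minus the
    original score. Within-enhancer hyperedges carry weight zero by
    definition and are not enumerated explicitly (:func:`hypergraph_to_graph`
    accounts for them).
    """
    if len(model.windows) < 2:
        warnings.warn("cross-talk needs >= 2 selected windows; empty result")
        return []
    order = sorted(range(len(model.windows)),
                   key=lambda k: (model.windows[k].start, model.windows[k].length))
    windows = [model.windows[k] for k in order]
    weights = np.asarray(model.weights, float)[order]
    enh_sites = _enhancer_site_indices(model)

    starts, ends, tf, aff = model.annotation.arrays()
    conc = _context_concentrations(model.annotation, ctx)

    def readout_for(idx: np.ndarray) -> np.ndarray:
        from .thermo import _dp_partition

        if len(idx) == 0:
            q = model.theta.q_btm
            return np.full(conc.shape[1], q / (1.0 + q))
        idx = np.unique(idx)
        z_off, z_on, _ = _dp_partition(
            starts[idx], ends[idx], tf[idx], aff[idx], model.theta, conc
        )
        return z_on / (z_off + z_on)

    base_readouts = [readout_for(idx) for idx in enh_sites]
    base_pred = aggregate(base_readouts, weights)
    base_score = wpgp_arrays(base_pred, gene_profile.values).score

    hyperedges: list[Hyperedge] = []
    for d, donor_idx in enumerate(enh_sites):
        for a in range(len(enh_sites)):
            if a == d:
                continue
            for blk_len in range(1, min(max_block, len(donor_idx)) + 1):
                for s0 in range(len(donor_idx) - blk_len + 1):
                    block = donor_idx[s0 : s0 + blk_len]
                    new_sites = list(enh_sites)
                    new_sites[a] = np.union1d(enh_sites[a], block)
                    readouts = [
                        base_readouts[k] if k != a else readout_for(new_sites[k])
                        for k in range(len(enh_sites))
                    ]
                    new_w, new_score = optimize_weights(
                        windows, readouts, gene_profile.values, weights
                    )
                    if refit_theta_box:
                        # windows no longer delimit the augmented site sets, so
                        # refit theta on the explicit per-enhancer subsets
                        _, refit_score = _refit_theta_on_subsets(
                            new_sites, weights_init=new_w, model=model, ctx=ctx,
                            gene_profile=gene_profile,
                        )
                        new_score = max(new_score, refit_score)
                    hyperedges.append(
                        Hyperedge(d, tuple(int(i) for i in block), a,
                                  float(new_score - base_score))
                    )
    return hyperedges


def _refit_theta_on_subsets(site_subsets, weights_init, model: GLModel,
                            ctx: TFContext, gene_profile: AxisProfile):
    """Constrained theta re-fit where enhancers are explicit site subsets."""
    from .optimize import alternating_maximize
    from .thermo import (_dp_partition, theta_bounds, theta_from_vector,
                         theta_to_vector)

    starts, ends, tf, aff = model.annotation.arrays()
    conc = _context_concentrations(model.annotation, ctx)
    template = model.theta.copy()
    subsets = [np.unique(idx) for idx in site_subsets]

    def objective(v):
        theta = theta_from_vector(v, template)
        readouts = []
        for idx in subsets:
            if len(idx) == 0:
                readouts.append(
                    np.full(conc.shape[1], theta.q_btm / (1 + theta.q_btm))
                )
                continue
            z_off, z_on, _ = _dp_partition(
                starts[idx], ends[idx], tf[idx], aff[idx], theta, conc
            )
            readouts.append(z_on / (z_off + z_on))
        pred = aggregate(readouts, weights_init)
        return wpgp_arrays(pred, gene_profile.values).score

    x0 = theta_to_vector(model.theta)
    bounds = theta_bounds(model.theta, constrained=True)
    best = alternating_maximize(objective, x0, bounds, rounds=1,
                                nm_maxiter=60, lbfgs_maxiter=25)
    return theta_from_vector(best, template), objective(best)


def hypergraph_to_graph(hyperedges: list[Hyperedge]) -> pd.DataFrame:
    """Average the hypergraph into a site x enhancer weight matrix.

    Rows are donor sites (locus order), columns are enhancers (locus
    order); entry (i, j) is the mean weight of every hyperedge in which
    site i appears in the donor block and enhancer j is the acceptor. A
    site's column against its own enhancer is zero (within-enhancer
    hyperedges all carry weight zero), so all sites of one enhancer share
    one weight against any fixed acceptor drawn from the same block pool.
    """
    if not hyperedges:
        raise ValueError("empty hyperedge list")
    site_ids = sorted({i for h in hyperedges for i in h.donor_sites})
    enh_ids = sorted({h.acceptor_enhancer for h in hyperedges}
                     | {h.donor_enhancer for h in hyperedges})
    mat = np.zeros((len(site_ids), len(enh_ids)))
    counts = np.zeros_like(mat)
    row = {s: k for k, s in enumerate(site_ids)}
    col = {e: k for k, e in enumerate(enh_ids)}
    for h in hyperedges:
        for s in h.donor_sites:
            mat[row[s], col[h.acceptor_enhancer]] += h.weight
            counts[row[s], col[h.acceptor_enhancer]] += 1
    with np.errstate(invalid="ignore"):
        mat = np.where(counts > 0, mat / np.maximum(counts, 1), 0.0)
    return pd.DataFrame(
        mat,
        index=[f"site_{s}" for s in site_ids],
        columns=[f"enhancer_{e}" for e in enh_ids],
    )


def two_enhancer_combined_readout(p):
    """Combined readout of two identical enhancers competing for one promoter.

    If each enhancer alone drives expression probability p and the two
    interact with the promoter independently and exclusively (at most one
    is promoter-bound at a time), the combined readout is 2p/(1+p): close
    to the additive 2p for small p and approaching 1 - (1-p)^2 for large p.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p must lie in [0, 1]")
    out = 2 * arr / (1 + arr)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out
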