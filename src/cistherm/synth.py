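"""Synthetic data: forward-simulated loci with known regulatory architecture.

The generator emulates the inputs of a blastoderm-style patterning study:
TF concentration profiles along a single anterior-posterior axis, sharp
motifs, a multi-kilobase locus with planted enhancers, and a striped target
expression profile produced by the package's own forward model (so that
recovery can be scored against known truth).

The default trans environment is one broadly distributed activator (a
Gaussian dome over the axis) plus one repressor per stripe whose profile is
high everywhere except a cleared band around that stripe (the clearing is
the composition of a falling and a rising logistic edge). Each planted
enhancer carries consensus activator sites plus consensus sites of its
stripe's repressor, so its thermodynamic readout is ON only inside the
cleared band - stripes arise from activator input gated by repressive
borders, and a stripe cannot be produced by activator sites alone.

Also here: the negative-control generators (random sequence, random
expression pattern, site relocation, locus swap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gltrain import GLModel, TrainConfig, decompose_stripes, fit_locus
from .io import ALPHABET, AxisProfile, PWM, Sequence, TFContext
from .sites import revcomp, scan_sites, shuffle_site_positions
from .thermo import DIRECT, TFParams, ThermoParams, predict_expression


def logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def gradient_profile(axis, center=0.5, scale=0.08, rising=True, peak=1.0):
    """Monotone logistic gradient along the axis."""
    s = scale if rising else -scale
    return peak * logistic((axis - center) / s)


def bump_profile(axis, center=0.5, sigma=0.1, peak=1.0):
    """Unimodal Gaussian domain."""
    return peak * np.exp(-((axis - center) ** 2) / (2 * sigma**2))


def clearing_profile(axis, center, halfwidth=0.07, scale=0.02, peak=1.0):
    """High everywhere except a cleared band: 1 - (rising x falling logistic)."""
    plateau = logistic((axis - (center - halfwidth)) / scale) * logistic(
        ((center + halfwidth) - axis) / scale
    )
    return peak * (1.0 - plateau)


def _default_enhancers() -> list[tuple[int, int, int]]:
    return [(1000, 1000, 0), (3500, 1000, 1), (6000, 1000, 2)]


@dataclass
class SynthSpec:
    """Conditions of one synthetic study; the defaults are the standard bed.

    planted_enhancers: (start bp, length bp, stripe index) triples.
    The trans environment provides 1 activator + one repressor per stripe,
    so n_tfs must be >= 1 + number of stripes.
    """

    seed: int
    n_tfs: int = 4
    motif_length: int = 8
    locus_length: int = 8000
    axis_bins: int = 100
    planted_enhancers: list[tuple[int, int, int]] = field(
        default_factory=_default_enhancers
    )
    true_theta: ThermoParams | None = None
    true_weights: list[float] | None = None
    base_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    act_sites_per_enhancer: int = 5
    rep_sites_per_enhancer: int = 6
    consensus_prob: float = 0.85
    act_sigma: float = 0.35
    clear_halfwidth: float = 0.07
    clear_scale: float = 0.02
    tf_kinds: list[str] | None = None  # override: 'bump'|'gradient'|'clearing'
    rel_affinity_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        n_stripes = self.n_stripes
        if self.n_tfs < 1 + n_stripes:
            raise ValueError(
                f"{self.n_tfs} TFs cannot host 1 activator + {n_stripes} repressors"
            )
        ends = sorted((s, s + ln) for s, ln, _ in self.planted_enhancers)
        for (s1, e1), (s2, e2) in zip(ends, ends[1:]):
            if s2 < e1:
                raise ValueError("planted enhancers overlap")
        for s, ln, _ in self.planted_enhancers:
            if s < 0 or s + ln > self.locus_length:
                raise ValueError("planted enhancer outside locus")
        if self.true_theta is None:
            self.true_theta = default_true_theta(self.n_tfs)
        if self.true_weights is None:
            self.true_weights = [1.0] * len(self.planted_enhancers)

    @property
    def n_stripes(self) -> int:
        if not self.planted_enhancers:
            return 0
        return max(s for _, _, s in self.planted_enhancers) + 1

    @property
    def stripe_centers(self) -> np.ndarray:
        n = max(self.n_stripes, self.n_tfs - 1)
        return (np.arange(n) + 1) / (n + 1)

    @property
    def tf_names(self) -> list[str]:
        return ["ACT"] + [f"R{k + 1}" for k in range(self.n_tfs - 1)]


def default_true_theta(n_tfs: int) -> ThermoParams:
    """The generator's ground-truth thermodynamic parameters (DIRECT mode)."""
    per_tf = [TFParams(K=2.0, alpha=5.0, omega=1.0, role="activator")]
    per_tf += [
        TFParams(K=3.0, alpha=0.01, omega=1.0, role="repressor")
        for _ in range(n_tfs - 1)
    ]
    return ThermoParams(per_tf, q_btm=0.02, mode=DIRECT)


def gen_tf_context(spec: SynthSpec) -> TFContext:
    """Concentration profiles and roles of the synthetic trans environment."""
    axis = np.linspace(0.0, 1.0, spec.axis_bins)
    centers = spec.stripe_centers
    profiles, roles = [], []
    kinds = spec.tf_kinds
    for t in range(spec.n_tfs):
        kind = kinds[t] if kinds is not None else (
            "bump" if t == 0 else "clearing"
        )
        if t == 0:
            center = 0.5
        else:
            center = float(centers[(t - 1) % len(centers)])
        if kind == "bump":
            v = bump_profile(axis, center, spec.act_sigma if t == 0 else 0.1)
        elif kind == "gradient":
            v = gradient_profile(axis, center, rising=(t % 2 == 0))
        elif kind == "clearing":
            v = clearing_profile(axis, center, spec.clear_halfwidth,
                                 spec.clear_scale)
        else:
            raise ValueError(f"unknown profile kind {kind!r}")
        profiles.append(AxisProfile(v, axis))
        roles.append("activator" if t == 0 else "repressor")
    return TFContext(spec.tf_names, profiles, roles)


def gen_motifs(spec: SynthSpec) -> list[PWM]:
    """Sharp random motifs: consensus_prob on a random consensus word.

    Consensus words are rejection-sampled to pairwise Hamming distance >= 3
    (including reverse complements), so one factor's planted word is never
    a near-consensus match for another factor.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    words: list[np.ndarray] = []
    while len(words) < spec.n_tfs:
        cand = rng.integers(0, 4, size=spec.motif_length)
        rc = (3 - cand)[::-1]
        ok = all(
            min(int(np.sum(cand != w)), int(np.sum(rc != w))) >= 3 for w in words
        )
        if ok:
            words.append(cand)
    pwms = []
    off = (1.0 - spec.consensus_prob) / 3.0
    for name, consensus in zip(spec.tf_names, words):
        probs = np.full((spec.motif_length, 4), off)
        probs[np.arange(spec.motif_length), consensus] = spec.consensus_prob
        pwms.append(PWM(name, probs))
    return pwms


def gen_random_sequence(length: int, base_freqs, seed: int,
                        seq_id: str = "random") -> Sequence:
    """I.i.d. random DNA with the given base composition."""
    if length < 1:
        raise ValueError("length must be >= 1")
    freqs = np.asarray(base_freqs, dtype=float)
    if len(freqs) != 4 or np.any(freqs < 0) or not np.isclose(freqs.sum(), 1.0):
        raise ValueError("base_freqs must be 4 nonnegative values summing to 1")
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=length, p=freqs)
    return Sequence(seq_id, "".join(ALPHABET[c] for c in codes))


def base_composition(seq: Sequence) -> np.ndarray:
    counts = np.array([seq.residues.count(c) for c in ALPHABET], dtype=float)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


def _neutralize_confounders(
    residues: list[str],
    start: int,
    length: int,
    own_rep_tf: int,
    planted_sites: list[dict],
    pwms: list[PWM],
    rng: np.random.Generator,
    min_affinity: float = 0.2,
    max_rounds: int = 20,
) -> None:
    """Scrub chance strong off-target repressor sites inside a planted enhancer.

    The generator's contract is that each planted enhancer drives its
    intended stripe; a chance near-consensus site of a *different* stripe's
    repressor inside the enhancer would silence it in its own cleared band.
    Any such site (relative affinity >= min_affinity) gets one background
    base outside the planted words redrawn, until the region is clean.
    """
    planted_spans = [
        (p["start"], p["start"] + p["length"])
        for p in planted_sites
        if start <= p["start"] and p["start"] + p["length"] <= start + length
    ]

    def protected(pos: int) -> bool:
        return any(lo <= pos < hi for lo, hi in planted_spans)

    for _ in range(max_rounds):
        sub = Sequence("sub", "".join(residues[start : start + length]))
        ann = scan_sites(sub, pwms, min_affinity)
        offenders = [
            s for s in ann.sites
            if s.tf_index not in (0, own_rep_tf)
            and not all(protected(start + p) for p in range(s.start, s.end))
        ]
        if not offenders:
            return
        for s in offenders:
            free = [start + p for p in range(s.start, s.end)
                    if not protected(start + p)]
            pos = free[rng.integers(0, len(free))]
            current = residues[pos]
            residues[pos] = ALPHABET[
                (ALPHABET.index(current) + 1 + rng.integers(0, 3)) % 4
            ]


def gen_synthetic_locus(spec: SynthSpec):
    """Forward-simulate one locus.

    Returns (sequence, ground-truth expression, truth record). The
    background is i.i.d. from base_freqs; each planted enhancer receives
    consensus activator sites plus consensus sites of its stripe's
    repressor at jittered, non-overlapping offsets and random strands.
    Ground truth is the weighted sum of each planted enhancer's
    thermodynamic readout under true_theta, clipped to [0, 1].
    """
    ss = np.random.SeedSequence([spec.seed, 2])
    rng = np.random.default_rng(ss)
    background = gen_random_sequence(
        spec.locus_length, spec.base_freqs,
        np.random.SeedSequence([spec.seed, 3]), f"synthetic_locus_{spec.seed}",
    )
    residues = list(background.residues)
    ctx = gen_tf_context(spec)
    pwms = gen_motifs(spec)
    theta = spec.true_theta

    planted_sites = []
    for start, length, stripe in spec.planted_enhancers:
        rep_tf = 1 + stripe
        kinds = [0] * spec.act_sites_per_enhancer + [rep_tf] * spec.rep_sites_per_enhancer
        rng.shuffle(kinds)
        n_sites = len(kinds)
        if n_sites * (spec.motif_length + 2) > length:
            raise ValueError("planted sites exceed the enhancer length")
        slot = length / n_sites
        for k, tf_idx in enumerate(kinds):
            jitter = rng.integers(0, max(1, int(slot) - spec.motif_length))
            pos = start + int(k * slot) + int(jitter)
            word = pwms[tf_idx].consensus
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                word = revcomp(word)
            residues[pos : pos + spec.motif_length] = word
            planted_sites.append(
                {"tf": spec.tf_names[tf_idx], "start": pos,
                 "length": spec.motif_length, "strand": strand,
                 "enhancer": (start, length)}
            )
        _neutralize_confounders(
            residues, start, length, 1 + stripe, planted_sites, pwms, rng
        )
    locus = Sequence(background.id, "".join(residues))

    axis = ctx.axis
    basal = theta.q_btm / (1.0 + theta.q_btm)
    if not spec.planted_enhancers:
        expression = AxisProfile(np.full(spec.axis_bins, basal), axis)
        readouts = []
    else:
        readouts = []
        total = np.zeros(spec.axis_bins)
        for (start, length, stripe), w in zip(
            spec.planted_enhancers, spec.true_weights
        ):
            sub = Sequence(f"enh_{start}", locus.residues[start : start + length])
            readout = predict_expression(
                sub, theta, ctx, pwms=pwms,
                rel_affinity_threshold=spec.rel_affinity_threshold,
            )
            readouts.append(readout.values)
            total += w * readout.values
        expression = AxisProfile(np.clip(total, 0.0, 1.0), axis)

    truth = {
        "spec": spec,
        "ctx": ctx,
        "pwms": pwms,
        "theta": theta,
        "weights": list(spec.true_weights),
        "enhancers": [(s, ln) for s, ln, _ in spec.planted_enhancers],
        "planted_sites": planted_sites,
        "enhancer_readouts": readouts,
    }
    return locus, expression, truth


@dataclass
class SynthDataset:
    """Everything one synthetic study needs, bundled."""

    spec: SynthSpec
    locus: Sequence
    expression: AxisProfile
    ctx: TFContext
    pwms: list[PWM]
    theta: ThermoParams
    truth: dict


def generate_dataset(spec: SynthSpec) -> SynthDataset:
    locus, expression, truth = gen_synthetic_locus(spec)
    return SynthDataset(
        spec, locus, expression, truth["ctx"], truth["pwms"], truth["theta"], truth
    )


def perturbed_theta(theta: ThermoParams, seed: int,
                    max_fold: float = 1.4) -> ThermoParams:
    """Theta multiplied by seeded log-uniform factors within max_fold.

    The generator's stand-in for pre-training on an external enhancer
    panel: approximately right parameters that the two-fold constrained box
    around them still brackets the truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    lf = np.log(max_fold)

    def jiggle(x):
        return float(x * np.exp(rng.uniform(-lf, lf)))

    out = theta.copy()
    for p in out.per_tf:
        p.K = jiggle(p.K)
        a = jiggle(p.alpha)
        p.alpha = max(a, 1.0) if p.role == "activator" else min(a, 1.0)
        p.omega = max(jiggle(p.omega), 1.0)
    out.q_btm = jiggle(out.q_btm)
    return out


def _uniform_composition(total: int, k: int, rng: np.random.Generator,
                         min_part: int = 1) -> np.ndarray:
    """Uniformly random composition of `total` into k parts >= min_part."""
    rest = total - k * min_part
    if rest < 0:
        raise ValueError(f"cannot split {total} into {k} parts >= {min_part}")
    if k == 1:
        return np.array([total])
    # stars and bars: choose k-1 bar positions among rest + k - 1 slots
    bars = np.sort(rng.choice(rest + k - 1, size=k - 1, replace=False))
    cuts = np.concatenate([[-1], bars, [rest + k - 1]])
    return np.diff(cuts) - 1 + min_part


def gen_random_expression(
    real_profile: AxisProfile,
    on_threshold: float = 0.5,
    seed: int = 0,
    smooth: bool = True,
    edge_steepness: float = 100.0,
) -> AxisProfile:
    """A random striped pattern matched to the real profile's ON budget.

    The stripe count is uniform between half the real stripe count and the
    real count; random positive stripe widths sum to the real ON-bin count
    K and random gap widths (leading/trailing gaps may be empty) sum to the
    OFF count, laid out gap/stripe alternately from the anterior. Before
    smoothing the ON-bin count equals K exactly; ``smooth=False`` returns
    that raw binary pattern, otherwise the edges are softened by logistic
    flanks.
    """
    stripes = decompose_stripes(real_profile, on_threshold)
    n_stripes = len(stripes)
    on = real_profile.values >= on_threshold
    K = int(on.sum())
    if K == 0:
        raise ValueError("real profile has no ON bins")
    K0 = len(on) - K
    rng = np.random.default_rng(seed)
    s_count = int(rng.integers(int(np.ceil(n_stripes / 2)), n_stripes + 1))
    widths = _uniform_composition(K, s_count, rng, min_part=1)
    # s_count + 1 gaps; interior gaps at least 1 bin, terminal gaps may be 0
    interior = max(s_count - 1, 0)
    if K0 < interior:
        raise ValueError("not enough OFF bins to separate the stripes")
    gaps = _uniform_composition(K0 + 2, s_count + 1, rng, min_part=1) - np.array(
        [1] + [0] * (s_count - 1) + [1]
    )

    raw = np.zeros(len(on))
    pos = 0
    for g, w in zip(gaps[:-1], widths):
        pos += int(g)
        raw[pos : pos + int(w)] = 1.0
        pos += int(w)
    axis = real_profile.axis
    if not smooth:
        return AxisProfile(raw, axis)

    smooth_v = np.zeros_like(raw)
    pos = 0
    for g, w in zip(gaps[:-1], widths):
        pos += int(g)
        a, b = axis[pos], axis[min(pos + int(w), len(axis)) - 1]
        smooth_v += logistic(edge_steepness * (axis - a)) * logistic(
            edge_steepness * (b - axis)
        )
        pos += int(w)
    return AxisProfile(np.clip(smooth_v, 0.0, 1.0), axis)


CONTROL_MODES = ("swap_locus", "random_expression", "random_sequence",
                 "shuffled_sites")


def run_negative_controls(
    locus: Sequence,
    gene_profile: AxisProfile,
    ctx: TFContext,
    init_theta: ThermoParams,
    cfg: TrainConfig,
    mode: str,
    seed: int,
    pwms: list[PWM] | None = None,
    alt_locus: Sequence | None = None,
) -> tuple[GLModel, float]:
    """Fit one negative control with unconstrained parameter estimation.

    Modes: 'swap_locus' fits a different gene's locus (``alt_locus``) to
    this gene's profile; 'random_expression' fits the real locus to a
    random pattern with the real ON budget; 'random_sequence' fits an
    i.i.d. random sequence of the same length and base composition;
    'shuffled_sites' relocates every annotated site uniformly within the
    locus. Returns (fitted model, its w-PGP score).
    """
    if mode not in CONTROL_MODES:
        raise ValueError(f"unknown control mode {mode!r}")
    if pwms is None:
        raise ValueError("pwms are required to annotate control sequences")
    target = gene_profile
    annotation = None
    fit_seq = locus
    if mode == "swap_locus":
        if alt_locus is None:
            raise ValueError("swap_locus mode needs alt_locus")
        fit_seq = alt_locus
    elif mode == "random_expression":
        target = gen_random_expression(gene_profile, cfg.on_threshold, seed)
    elif mode == "random_sequence":
        fit_seq = gen_random_sequence(
            len(locus), base_composition(locus), seed, locus.id + "|random"
        )
    elif mode == "shuffled_sites":
        scanned = scan_sites(locus, pwms, cfg.rel_affinity_threshold)
        annotation = shuffle_site_positions(scanned, len(locus), seed)
    model = fit_locus(
        fit_seq, target, ctx, init_theta, cfg=cfg, pwms=pwms,
        annotation=annotation, constrained=False,
    )
    return model, model.score
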