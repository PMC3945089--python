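"""Model / Results front end.

``LocusExpressionModel`` holds the data of one locus-level study (locus
sequence, target expression profile, trans context, motifs); ``fit()``
runs the two-tiered training and returns a ``LocusExpressionResults``
carrying the selected windows, their weights, the fitted thermodynamic
parameters and the fit score, with the downstream analyses (prediction,
knockdowns, network inference, architecture sampling, cross-talk) as
methods. ``EnhancerPanelModel`` is the enhancer-level analogue used for
panel pre-training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import analysis as _analysis
from .gltrain import (
    GLModel,
    TrainConfig,
    decompose_stripes,
    fit_locus,
    predict_gene_expression,
)
from .io import (
    AxisProfile,
    PWM,
    Sequence,
    TFContext,
    save_json,
    write_windows_bed,
)
from .scoring import wpgp
from .sites import SiteAnnotation, scan_sites
from .thermo import ThermoParams, fit_enhancer_set, predict_expression


class EnhancerPanelModel:
    """Thermodynamic model of a panel of enhancers with known readouts."""

    def __init__(self, enhancers, ctx: TFContext, pwms: list[PWM] | None = None,
                 rel_affinity_threshold: float = 0.01):
        self.enhancers = list(enhancers)
        self.ctx = ctx
        self.pwms = pwms
        self.rel_affinity_threshold = rel_affinity_threshold

    def fit(self, init: ThermoParams, bounds_mode: str = "constrained",
            seed: int = 0, n_restarts: int = 5) -> "EnhancerPanelResults":
        theta = fit_enhancer_set(
            self.enhancers, self.ctx, init, bounds_mode=bounds_mode,
            pwms=self.pwms, rel_affinity_threshold=self.rel_affinity_threshold,
            seed=seed, n_restarts=n_restarts,
        )
        return EnhancerPanelResults(self, theta)


class EnhancerPanelResults:
    def __init__(self, model: EnhancerPanelModel, params: ThermoParams):
        self.model = model
        self.params = params

    def predict(self, enhancer_index: int = 0) -> AxisProfile:
        seq, _ = self.model.enhancers[enhancer_index]
        return predict_expression(
            seq, self.params, self.model.ctx, pwms=self.model.pwms,
            rel_affinity_threshold=self.model.rel_affinity_threshold,
        )

    @property
    def scores(self) -> list[float]:
        return [
            wpgp(self.predict(i), profile).score
            for i, (_, profile) in enumerate(self.model.enhancers)
        ]

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.scores))

    def summary(self) -> str:
        lines = [
            "Enhancer panel thermodynamic fit",
            "=" * 40,
            f"enhancers: {len(self.model.enhancers)}    "
            f"mean w-PGP: {self.mean_score:.4f}",
            f"mode: {self.params.mode}    q_btm: {self.params.q_btm:.4g}",
            "",
            f"{'TF':<10}{'role':<12}{'K':>10}{'alpha':>10}{'omega':>10}",
        ]
        for name, p in zip(self.model.ctx.tf_names, self.params.per_tf):
            lines.append(
                f"{name:<10}{p.role:<12}{p.K:>10.4g}{p.alpha:>10.4g}{p.omega:>10.4g}"
            )
        return "\n".join(lines)


class LocusExpressionModel:
    """Two-tiered model of a gene's expression pattern from its locus.

    Parameters
    ----------
    locus : Sequence or SiteAnnotation
        The gene's intergenic region (or a pre-computed site annotation).
    expression : AxisProfile
        The target expression profile on the context's axis grid, in [0, 1].
    ctx : TFContext
        TF concentration profiles and roles.
    pwms : list of PWM, optional
        Motifs (required when ``locus`` is a raw sequence).
    config : TrainConfig, optional
        Training settings (window grid, candidate count, outer iterations).
    """

    def __init__(self, locus, expression: AxisProfile, ctx: TFContext,
                 pwms: list[PWM] | None = None,
                 config: TrainConfig | None = None):
        self.config = config or TrainConfig()
        if isinstance(locus, SiteAnnotation):
            self.annotation = locus
            self.locus = None
        else:
            if pwms is None:
                raise ValueError("pwms required for a raw locus sequence")
            self.annotation = scan_sites(
                locus, pwms, self.config.rel_affinity_threshold
            )
            self.locus = locus
        self.expression = expression
        self.ctx = ctx
        self.pwms = pwms

    def fit(self, init_theta: ThermoParams,
            constrained: bool = True) -> "LocusExpressionResults":
        glmodel = fit_locus(
            self.annotation, self.expression, self.ctx, init_theta,
            cfg=self.config, annotation=self.annotation, constrained=constrained,
        )
        return LocusExpressionResults(self, glmodel)


@dataclass
class LocusExpressionResults:
    """Fitted two-tiered model plus its downstream analyses."""

    model: LocusExpressionModel
    glmodel: GLModel

    @property
    def windows(self):
        return self.glmodel.windows

    @property
    def weights(self) -> np.ndarray:
        return self.glmodel.weights

    @property
    def params(self) -> ThermoParams:
        return self.glmodel.theta

    @property
    def score(self) -> float:
        return self.glmodel.score

    @property
    def stripes(self):
        return decompose_stripes(
            self.model.expression, self.model.config.on_threshold
        )

    def predict(self, ctx: TFContext | None = None) -> AxisProfile:
        return predict_gene_expression(self.glmodel, ctx or self.model.ctx)

    def knockdown(self, tf: str) -> AxisProfile:
        return _analysis.knockdown_tf(self.glmodel, self.model.ctx, tf)

    def infer_network(self):
        return _analysis.infer_network(self.glmodel, self.model.ctx, self.stripes)

    def sample_architectures(self, n_samples: int = 10000, seed: int = 0):
        return _analysis.mcmc_sample(
            self.model.annotation, self.model.expression, self.glmodel.theta,
            self.model.ctx, cfg=self.model.config, n_samples=n_samples,
            rng_seed=seed,
        )

    def crosstalk(self, max_block: int = 5, refit_theta_box: bool = True):
        return _analysis.crosstalk_hypergraph(
            self.glmodel, self.model.ctx, self.model.expression,
            max_block=max_block, refit_theta_box=refit_theta_box,
        )

    def save(self, path) -> None:
        save_json(path, self.glmodel.to_dict())

    def write_bed(self, path, chrom: str = "locus", locus_start: int = 0) -> None:
        from types import SimpleNamespace

        rows = [
            SimpleNamespace(start=w.start, length=w.length, weight=float(wt))
            for w, wt in zip(self.glmodel.windows, self.glmodel.weights)
        ]
        write_windows_bed(path, rows, chrom, locus_start)

    def summary(self) -> str:
        g = self.glmodel
        lines = [
            "Two-tiered locus expression model",
            "=" * 52,
            f"locus: {g.annotation.sequence_id}   "
            f"length: {g.annotation.seq_length} bp   sites: {len(g.annotation)}",
            f"w-PGP score: {g.score:.4f}   windows: {len(g.windows)}   "
            f"outer iterations: {len(g.history)}",
            f"mode: {g.theta.mode}   q_btm: {g.theta.q_btm:.4g}",
            "",
            f"{'window':<10}{'start':>8}{'end':>8}{'length':>8}{'weight':>10}",
        ]
        for k, (w, wt) in enumerate(zip(g.windows, g.weights)):
            lines.append(
                f"window_{k:<3}{w.start:>8}{w.end:>8}{w.length:>8}{wt:>10.4f}"
            )
        lines += ["", f"{'TF':<10}{'role':<12}{'K':>10}{'alpha':>10}{'omega':>10}"]
        for name, p in zip(g.annotation.tf_names, g.theta.per_tf):
            lines.append(
                f"{name:<10}{p.role:<12}{p.K:>10.4g}{p.alpha:>10.4g}{p.omega:>10.4g}"
            )
        return "\n".join(lines)

    def plot(self, path=None, ax=None):
        """Predicted vs target profile (and per-window readouts, faint)."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        axis = self.model.expression.axis
        ax.plot(axis, self.model.expression.values, "r-", label="target")
        ax.plot(axis, self.predict().values, "g-", label="model")
        ax.set_xlabel("fraction of A/P axis")
        ax.set_ylabel("relative expression")
        ax.legend(frameon=False)
        if path is not None:
            ax.figure.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(ax.figure)
        return ax
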