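import numpy as np
import pytest

from cistherm.analysis import (
    classify_knockdown_effect,
    crosstalk_hypergraph,
    hypergraph_to_graph,
    infer_network,
    knockdown_tf,
    mcmc_sample,
    propose_bits,
    two_enhancer_combined_readout,
    Hyperedge,
)
from cistherm.gltrain import GLModel, StripeProfile, Window, decompose_stripes
from cistherm.io import AxisProfile


class TestProposal:
    def test_hamming_distance_marginals(self):
        rng = np.random.default_rng(0)
        bits = np.zeros(8, dtype=bool)
        bits[[1, 4]] = True
        n = 10000
        dist = np.array([
            int(np.sum(propose_bits(bits, rng) != bits)) for _ in range(n)
        ])
        for d, p in ((0, 0.25), (1, 0.5), (2, 0.25)):
            freq = np.mean(dist == d)
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(freq - p) <= 3 * sigma

    def test_uniform_over_equal_distance_vectors(self):
        rng = np.random.default_rng(1)
        bits = np.zeros(4, dtype=bool)
        counts = np.zeros(4)
        n = 20000
        for _ in range(n):
            new = propose_bits(bits, rng)
            flipped = np.nonzero(new != bits)[0]
            if len(flipped) == 1:
                counts[flipped[0]] += 1
        frac = counts / counts.sum()
        assert np.allclose(frac, 0.25, atol=0.02)


class TestMcmc:
    def test_determinism(self):
        rng = np.random.default_rng(0)
        readouts = [rng.random(20) for _ in range(3)]
        target = AxisProfile(rng.random(20), np.linspace(0, 1, 20))
        windows = [Window(i * 600, 500) for i in range(3)]
        out1 = mcmc_sample(None, target, None, None, n_samples=500, rng_seed=7,
                           windows=windows, readouts=readouts)
        out2 = mcmc_sample(None, target, None, None, n_samples=500, rng_seed=7,
                           windows=windows, readouts=readouts)
        assert np.allclose(out1[1], out2[1])
        assert [s.score for s in out1[0]] == [s.score for s in out2[0]]

    def test_sample_invariants(self):
        rng = np.random.default_rng(2)
        readouts = [np.clip(rng.random(30), 0, 1) for _ in range(4)]
        target = AxisProfile(np.clip(rng.random(30), 0, 1),
                             np.linspace(0, 1, 30))
        windows = [Window(i * 600, 500) for i in range(4)]
        samples, avg, _ = mcmc_sample(None, target, None, None,
                                      n_samples=2000, rng_seed=1,
                                      windows=windows, readouts=readouts)
        for s in samples[::100]:
            assert np.all(s.active_weights > 0)
            if len(s.active_weights):
                assert np.isclose(s.active_weights.sum(), 1.0)
            bits = s.bits()
            assert np.array_equal(np.nonzero(bits)[0], s.active_indices)
            assert 0 < s.score <= 1.0
        assert np.all(avg >= 0) and np.all(avg <= 1)

    def test_invalid_sample_count_rejected(self):
        with pytest.raises(ValueError):
            mcmc_sample(None, None, None, None, n_samples=0,
                        windows=[Window(0, 500)], readouts=[np.ones(5)])

    def test_average_weight_peaks_on_planted_enhancers(self, std_dataset,
                                                       std_annotation):
        from cistherm.gltrain import TrainConfig

        cfg = TrainConfig(len_step=500)  # coarser grid keeps the chain short
        samples, avg, windows = mcmc_sample(
            std_annotation, std_dataset.expression, std_dataset.theta,
            std_dataset.ctx, cfg=cfg, n_samples=4000, rng_seed=3,
        )
        planted = std_dataset.truth["enhancers"]

        def overlaps_truth(w):
            return any(
                min(w.end, s + ln) - max(w.start, s) >= 0.5 * ln
                for s, ln in planted
            )

        order = np.argsort(avg)[::-1]
        top_decile = order[: max(1, len(windows) // 10)]
        frac = np.mean([overlaps_truth(windows[i]) for i in top_decile])
        assert frac >= 0.5


@pytest.fixture
def toy_single_activator_model(std_dataset, std_annotation):
    """Truth-model over the first planted enhancer only."""
    start, length, _ = std_dataset.spec.planted_enhancers[0]
    return GLModel([Window(start, length)], np.ones(1), std_dataset.theta,
                   1.0, std_annotation, std_dataset.ctx.axis,
                   std_dataset.expression)


class TestKnockdown:
    def test_absent_tf_has_no_effect(self, toy_single_activator_model,
                                     std_dataset):
        # with every R3 site removed from the annotation, knocking R3 down
        # cannot change the readout
        model = toy_single_activator_model
        ann = model.annotation
        r3 = ann.tf_names.index("R3")
        model = GLModel(
            model.windows, model.weights, model.theta, model.score,
            ann.with_sites([s for s in ann.sites if s.tf_index != r3]),
            model.axis, model.gene_profile,
        )
        kd = knockdown_tf(model, std_dataset.ctx, "R3")
        from cistherm.gltrain import predict_gene_expression

        ref = predict_gene_expression(model, std_dataset.ctx)
        assert np.array_equal(kd.values, ref.values)

    def test_activator_knockdown_lowers_everywhere(
        self, toy_single_activator_model, std_dataset
    ):
        from cistherm.gltrain import predict_gene_expression

        ref = predict_gene_expression(toy_single_activator_model,
                                      std_dataset.ctx)
        kd = knockdown_tf(toy_single_activator_model, std_dataset.ctx, "ACT")
        assert np.all(kd.values <= ref.values + 1e-15)
        assert kd.values.max() < ref.values.max()

    def test_restore_reproduces_baseline_exactly(
        self, toy_single_activator_model, std_dataset
    ):
        from cistherm.gltrain import predict_gene_expression

        before = predict_gene_expression(toy_single_activator_model,
                                         std_dataset.ctx)
        knockdown_tf(toy_single_activator_model, std_dataset.ctx, "ACT")
        after = predict_gene_expression(toy_single_activator_model,
                                        std_dataset.ctx)
        assert np.array_equal(before.values, after.values)

    def test_unknown_tf_rejected(self, toy_single_activator_model,
                                 std_dataset):
        with pytest.raises(KeyError):
            knockdown_tf(toy_single_activator_model, std_dataset.ctx, "nope")


class TestEdgeClassification:
    def _stripe(self, axis, lo, hi, values):
        masked = np.zeros_like(values)
        masked[lo:hi] = values[lo:hi]
        return StripeProfile(0, AxisProfile(masked, axis), (lo, hi))

    def test_subthreshold_changes_emit_no_edge(self):
        axis = np.linspace(0, 1, 100)
        base = np.exp(-((axis - 0.5) ** 2) / 0.005)
        # 1.9% peak change, boundary shift ~0.5% of the axis
        knocked = 1.019 * np.exp(-((axis - 0.505) ** 2) / 0.005)
        stripe = self._stripe(axis, 35, 65, base)
        call = classify_knockdown_effect(
            AxisProfile(np.clip(base, 0, 1), axis),
            AxisProfile(np.clip(knocked, 0, 1), axis), stripe,
        )
        assert call is None

    def test_weakening_calls_activation(self):
        axis = np.linspace(0, 1, 100)
        base = 0.9 * np.exp(-((axis - 0.5) ** 2) / 0.005)
        stripe = self._stripe(axis, 35, 65, base)
        call = classify_knockdown_effect(
            AxisProfile(base, axis), AxisProfile(0.8 * base, axis), stripe
        )
        assert call is not None and call[0] == "activation"
        assert call[1]["level_change_pct"] == pytest.approx(-20.0, abs=0.1)

    def test_boundary_shift_calls_repression(self):
        axis = np.linspace(0, 1, 100)
        base = 0.9 * np.exp(-((axis - 0.5) ** 2) / 0.005)
        knocked = 0.9 * np.exp(-((axis - 0.5) ** 2) / 0.009)  # broader stripe
        stripe = self._stripe(axis, 30, 70, base)
        call = classify_knockdown_effect(
            AxisProfile(base, axis), AxisProfile(knocked, axis), stripe
        )
        assert call is not None and call[0] == "repression"
        assert call[1]["boundary_shift_pct"] >= 1.0

    def test_zero_peak_skipped_with_warning(self):
        axis = np.linspace(0, 1, 10)
        zero = AxisProfile(np.zeros(10), axis)
        stripe = self._stripe(axis, 2, 5, np.zeros(10))
        with pytest.warns(UserWarning):
            assert classify_knockdown_effect(zero, zero, stripe) is None


class TestInferNetwork:
    def test_planted_edges_recovered_on_two_stripe_gene(self,
                                                        two_stripe_scenario):
        ds, model, stripes = two_stripe_scenario
        edges = infer_network(model, ds.ctx, stripes)
        signs = {(e.tf, e.stripe_index): e.sign for e in edges}
        assert signs.get(("ACT", 0)) == "activation"
        assert signs.get(("ACT", 1)) == "activation"
        assert signs.get(("R1", 0)) == "repression"
        assert signs.get(("R2", 1)) == "repression"

    def test_invariant_to_tf_order(self, two_stripe_scenario):
        ds, model, stripes = two_stripe_scenario
        from cistherm.io import TFContext

        perm = [2, 0, 1]
        ctx2 = TFContext(
            [ds.ctx.tf_names[i] for i in perm],
            [ds.ctx.profiles[i] for i in perm],
            [ds.ctx.roles[i] for i in perm],
        )
        e1 = {(e.tf, e.stripe_index, e.sign)
              for e in infer_network(model, ds.ctx, stripes)}
        e2 = {(e.tf, e.stripe_index, e.sign)
              for e in infer_network(model, ctx2, stripes)}
        assert e1 == e2

    def test_all_tf_knockdown_gives_basal_profile(self, two_stripe_scenario):
        ds, model, _ = two_stripe_scenario
        ctx = ds.ctx
        for tf in ds.ctx.tf_names:
            ctx = ctx.with_knockdown(tf)
        from cistherm.gltrain import predict_gene_expression

        pred = predict_gene_expression(model, ctx)
        basal = model.theta.q_btm / (1 + model.theta.q_btm)
        # aggregate of two unit-weight basal windows
        assert np.allclose(pred.values, 2 * basal, atol=1e-12)


class TestCrosstalk:
    def test_single_window_model_warns_empty(self, std_dataset,
                                             std_annotation):
        model = GLModel([Window(1000, 1000)], np.ones(1), std_dataset.theta,
                        0.9, std_annotation, std_dataset.ctx.axis)
        with pytest.warns(UserWarning):
            assert crosstalk_hypergraph(model, std_dataset.ctx,
                                        std_dataset.expression) == []

    @pytest.fixture(scope="class")
    @staticmethod
    def two_enhancer_crosstalk(two_stripe_scenario):
        ds, model, _ = two_stripe_scenario
        edges = crosstalk_hypergraph(model, ds.ctx, ds.expression,
                                     max_block=2, refit_theta_box=False)
        return ds, model, edges

    def test_hyperedge_structure(self, two_enhancer_crosstalk):
        _, _, edges = two_enhancer_crosstalk
        assert edges
        for h in edges:
            assert h.donor_enhancer != h.acceptor_enhancer
            assert 1 <= len(h.donor_sites) <= 2
            assert -1.0 <= h.weight <= 1.0
            assert np.isfinite(h.weight)

    def test_repressor_block_into_foreign_stripe_is_avoided(
        self, two_enhancer_crosstalk
    ):
        # donating stripe-1's repressor sites into the stripe-2 enhancer adds
        # repression inside stripe 2's own cleared band at stripe-1 positions
        # where enhancer 2 is already off, but critically adds R1 repression
        # wherever R1 is high - including inside stripe 2. The fit worsens.
        ds, model, edges = two_enhancer_crosstalk
        starts, _, tf, _ = model.annotation.arrays()
        r1_sites = {i for i in range(len(tf)) if tf[i] == 1}
        donated = [
            h for h in edges
            if h.donor_enhancer == 0 and h.acceptor_enhancer == 1
            and set(h.donor_sites) <= r1_sites and len(h.donor_sites) == 2
        ]
        assert donated
        assert min(h.weight for h in donated) < 0

    def test_graph_mapping_properties(self):
        edges = [
            Hyperedge(0, (0, 1), 1, -0.2),
            Hyperedge(0, (1, 2), 1, -0.4),
            Hyperedge(1, (5,), 0, 0.1),
        ]
        df = hypergraph_to_graph(edges)
        assert df.loc["site_0", "enhancer_1"] == pytest.approx(-0.2)
        assert df.loc["site_1", "enhancer_1"] == pytest.approx(-0.3)
        assert df.loc["site_2", "enhancer_1"] == pytest.approx(-0.4)
        assert df.loc["site_5", "enhancer_0"] == pytest.approx(0.1)
        # sites never donated towards an enhancer (incl. their own) read 0
        assert df.loc["site_0", "enhancer_0"] == 0.0

    def test_single_hyperedge_block_shares_weight(self):
        df = hypergraph_to_graph([Hyperedge(0, (3, 4, 5), 2, 0.7)])
        assert np.allclose(df["enhancer_2"].to_numpy(), 0.7)

    def test_empty_hyperedges_rejected(self):
        with pytest.raises(ValueError):
            hypergraph_to_graph([])


class TestTwoEnhancerTheory:
    def test_endpoints(self):
        assert two_enhancer_combined_readout(0.0) == 0.0
        assert two_enhancer_combined_readout(1.0) == pytest.approx(1.0)

    def test_closed_form_value(self):
        assert two_enhancer_combined_readout(0.2) == pytest.approx(1 / 3)

    def test_small_p_matches_additive_within_20pct(self):
        p = np.linspace(0.001, 0.199, 50)
        rel = np.abs(two_enhancer_combined_readout(p) - 2 * p) / (2 * p)
        assert np.all(rel < 0.2)

    def test_bounded_by_both_approximations(self):
        # exact ordering: 2p >= 1-(1-p)^2 >= 2p/(1+p) on (0, 1)
        p = np.linspace(0.01, 0.99, 99)
        combined = two_enhancer_combined_readout(p)
        indep_or = 1 - (1 - p) ** 2
        assert np.all(2 * p >= indep_or - 1e-12)
        assert np.all(indep_or >= combined - 1e-12)

    def test_independent_or_is_closer_for_large_p(self):
        p = np.linspace(0.3, 0.99, 30)
        combined = two_enhancer_combined_readout(p)
        assert np.all(
            np.abs(combined - (1 - (1 - p) ** 2)) < np.abs(combined - 2 * p)
        )

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            two_enhancer_combined_readout(1.2)
        with pytest.raises(ValueError):
            two_enhancer_combined_readout(-0.1)
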