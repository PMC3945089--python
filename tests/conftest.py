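import numpy as np
import pytest

from cistherm import gltrain, synth
from cistherm.io import PWM, AxisProfile, Sequence, TFContext
from cistherm.sites import Site, SiteAnnotation, scan_sites
from cistherm.thermo import TFParams, ThermoParams


@pytest.fixture
def uniform_pwm():
    return PWM("uniform", np.full((4, 4), 0.25))


@pytest.fixture
def sharp_pwm():
    """Motif strongly preferring the word ACGT."""
    probs = np.full((4, 4), 0.05)
    for i, base in enumerate([0, 1, 2, 3]):  # A C G T
        probs[i, base] = 0.85
    return PWM("acgt", probs)


def make_annotation(sites, tf_names, seq_length):
    """Toy annotation from (tf, start, length, affinity) tuples."""
    site_objs = [
        Site(tf, start, length, "+", float(np.log(aff)), aff)
        for tf, start, length, aff in sites
    ]
    return SiteAnnotation("toy", site_objs, tf_names, {}, seq_length)


@pytest.fixture
def toy_annotation_factory():
    return make_annotation


def make_theta(n_tfs, roles=None, mode="direct", K=1.0, alpha_act=4.0,
               alpha_rep=0.2, omega=1.0, q_btm=0.1, coop_dist=50,
               srr_range=150, srr_beta=0.8):
    roles = roles or ["activator"] * n_tfs
    per_tf = [
        TFParams(
            K=K,
            alpha=alpha_act if r == "activator" else alpha_rep,
            omega=omega,
            srr_beta=srr_beta if r == "repressor" else 0.0,
            role=r,
        )
        for r in roles
    ]
    return ThermoParams(per_tf, q_btm=q_btm, mode=mode,
                        coop_dist=coop_dist, srr_range=srr_range)


@pytest.fixture
def theta_factory():
    return make_theta


def make_ctx(tf_names, values_list, roles, axis=None):
    axis = axis if axis is not None else np.linspace(0, 1, len(values_list[0]))
    return TFContext(
        tf_names, [AxisProfile(np.asarray(v, float), axis) for v in values_list], roles
    )


@pytest.fixture
def ctx_factory():
    return make_ctx


def random_instance(rng, n_sites, n_tfs=3, mode="direct", omega_on=True,
                    seq_length=400):
    """One randomised annotation/theta/concentration triple for oracle checks."""
    roles = ["activator" if rng.random() < 0.6 else "repressor"
             for _ in range(n_tfs)]
    roles[0] = "activator"
    per_tf = [
        TFParams(
            K=float(rng.uniform(0.2, 3.0)),
            alpha=float(rng.uniform(1.0, 10.0)) if r == "activator"
            else float(rng.uniform(0.02, 1.0)),
            omega=float(rng.uniform(1.0, 5.0)) if omega_on else 1.0,
            srr_beta=float(rng.uniform(0.0, 1.0)) if r == "repressor" else 0.0,
            role=r,
        )
        for r in roles
    ]
    theta = ThermoParams(per_tf, q_btm=float(rng.uniform(0.01, 1.0)), mode=mode,
                         coop_dist=60, srr_range=120)
    sites = []
    for _ in range(n_sites):
        length = int(rng.integers(6, 12))
        start = int(rng.integers(0, seq_length - length))
        sites.append(Site(int(rng.integers(0, n_tfs)), start, length,
                          "+" if rng.random() < 0.5 else "-",
                          0.0, float(rng.uniform(0.05, 1.0))))
    ann = SiteAnnotation("rand", sites, [f"tf{i}" for i in range(n_tfs)], {},
                         seq_length)
    conc = rng.uniform(0.0, 2.0, size=n_tfs)
    return ann, theta, conc


@pytest.fixture
def random_instance_factory():
    return random_instance


# ---------------------------------------------------------------------------
# shared heavy fixtures: one standard synthetic study and one trained model

@pytest.fixture(scope="session")
def std_dataset():
    return synth.generate_dataset(synth.SynthSpec(seed=1))


@pytest.fixture(scope="session")
def std_annotation(std_dataset):
    return scan_sites(std_dataset.locus, std_dataset.pwms, 0.01)


@pytest.fixture(scope="session")
def std_init_theta(std_dataset):
    return synth.perturbed_theta(std_dataset.theta, seed=1)


@pytest.fixture(scope="session")
def std_fit(std_dataset, std_annotation, std_init_theta):
    """One full locus fit at reduced outer iterations, shared across tests."""
    cfg = gltrain.TrainConfig(outer_iters=5)
    return gltrain.fit_locus(
        std_annotation, std_dataset.expression, std_dataset.ctx,
        std_init_theta, cfg=cfg, annotation=std_annotation,
    )


@pytest.fixture(scope="session")
def two_stripe_scenario():
    """A 2-stripe gene built from its ground-truth model (no fitting).

    Each planted enhancer carries activator sites plus its own stripe's
    repressor sites, so the repressors set their stripes' borders.
    """
    spec = synth.SynthSpec(
        seed=5, n_tfs=3, locus_length=5000,
        planted_enhancers=[(800, 1000, 0), (3000, 1000, 1)],
    )
    ds = synth.generate_dataset(spec)
    ann = scan_sites(ds.locus, ds.pwms, 0.01)
    model = gltrain.GLModel(
        windows=[gltrain.Window(s, ln) for s, ln, _ in spec.planted_enhancers],
        weights=np.ones(2),
        theta=ds.theta,
        score=1.0,
        annotation=ann,
        axis=ds.ctx.axis,
        gene_profile=ds.expression,
    )
    stripes = gltrain.decompose_stripes(ds.expression)
    return ds, model, stripes
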