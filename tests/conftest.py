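import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from spcdn import (
    AnalysisConfig,
    HomeostasisSpec,
    SPCNetwork,
    analyze_model,
    generate_naturalistic_images,
    whiten_images,
)
from spcdn.learning import TrainingConfig, train
from spcdn.network import IterationConfig


@pytest.fixture(scope="session")
def reference_cc_spec():
    """The concave-convex homeostasis with the reference parameter set."""
    return HomeostasisSpec(
        "concave_convex", {"lam": 0.5, "x0": 0.5, "sigma": 0.5, "n": 4.0}
    )


@pytest.fixture(scope="session")
def image_set():
    """One whitened synthetic image set shared across tests."""
    return whiten_images(generate_naturalistic_images(count=10, edge=128, seed=0))


@pytest.fixture(scope="session")
def desk_model(image_set):
    """The desk-scale trained model: M=64 units, 16x16 patches, 3000 batches.

    Trained with the L1 (power-law, alpha=1) sparsity homeostasis; shared by
    the receptive-field and contrast-response acceptance tests.
    """
    hspec = HomeostasisSpec("power_prior", {"lam": 0.3, "alpha": 1.0})
    tcfg = TrainingConfig(
        eta_a=0.2,
        n_batches=3000,
        batch_size=100,
        n_units=64,
        patch_edge=16,
        seed=0,
        iteration=IterationConfig(eta_s=0.02, max_iter=400, tol=1e-5),
    )
    net, report = train(image_set, tcfg, hspec)
    return net, report


@pytest.fixture(scope="session")
def cc_analysis(desk_model, reference_cc_spec):
    """Contrast-response analysis of the desk model under the concave-convex H."""
    net, _ = desk_model
    net_cc = SPCNetwork(A=net.A, hspec=reference_cc_spec, nonnegative=True)
    return analyze_model(net_cc, AnalysisConfig())


@pytest.fixture(scope="session")
def l1_analysis(desk_model):
    """Contrast-response analysis of the desk model under its own (L1) H."""
    net, _ = desk_model
    return analyze_model(net, AnalysisConfig())
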