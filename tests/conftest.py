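import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ommnet import synthetic as syn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_design():
    return syn.default_design(seed=0)


@pytest.fixture(scope="session")
def noiseless_design():
    return syn.default_design(seed=0, noise=syn.NoiseSpec(0.0, 0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def coculture_fit(default_design):
    """Interaction network fitted to one simulated co-culture experiment."""
    from ommnet.network import CocultureModel

    obs, truth = syn.simulate_cocultures(default_design, seed=11)
    return CocultureModel(obs).fit(alpha=0.05)


@pytest.fixture(scope="session")
def spent_media_results(default_design):
    from ommnet.growth import SpentMediaModel

    od, truth = syn.simulate_spent_media_experiment(default_design, seed=12)
    return SpentMediaModel(od).fit(), truth


@pytest.fixture(scope="session")
def depletion_results(default_design):
    from ommnet.metabolomics import DepletionModel

    table = syn.simulate_feature_table(default_design, seed=13)
    return DepletionModel(table).fit(alpha=0.05)


def small_decoupled_design(mus, caps=None, **kwargs):
    """Helper: an S-strain design with no cross-interactions or resources."""
    mus = np.asarray(mus, dtype=float)
    caps = np.ones_like(mus) if caps is None else np.asarray(caps, dtype=float)
    S = len(mus)
    strains = [
        syn.StrainSpec(f"S{i}", float(mus[i]), float(caps[i])) for i in range(S)
    ]
    return syn.SyntheticDesign(
        strains=strains,
        feature_usage=np.zeros((S, 4), dtype=bool),
        depletion_depth=np.zeros(4),
        production_profile=np.zeros((S, 4), dtype=bool),
        interactions=np.diag(-mus / caps),
        bacteriocin=np.zeros((S, S)),
        noise=kwargs.pop("noise", syn.NoiseSpec(0.0, 0.0, 0.0, 0.0)),
        **kwargs,
    )
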