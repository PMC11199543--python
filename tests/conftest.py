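import numpy as np
import pytest

from oclnet.io import normalize_intensity
from oclnet.losses import combined_loss, downsample_mask, evaluate_pair
from oclnet.model import NetConfig, build_model
from oclnet.nn import Adam, Context
from oclnet.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def phantom32():
    """One deterministic 32-cube phantom pair (image, mask)."""
    return generate_phantom(PhantomParams(shape=(32, 32, 32), seed=1))


@pytest.fixture(scope="session")
def tiny_net_config():
    """Smallest buildable config for fast forward/backward tests."""
    return NetConfig(
        num_levels=2, base_channels=4, attention_scales=1, input_shape=(8, 8, 8)
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_net_config):
    return build_model(tiny_net_config, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def overfit_run(phantom32):
    """Train the desk-scale model to convergence on a single phantom.

    Shared by the attention-focus check and the overfit acceptance test so
    the 200-step optimization runs once per session.  Returns the trained
    model, the per-step combined-loss trace, and the final training dice.
    """
    vol, mask = phantom32
    cfg = NetConfig.test_preset()
    model = build_model(cfg, seed=0)
    x = normalize_intensity(vol.data)
    y = mask.data
    ctx = Context(training=True, rng=np.random.default_rng(0))
    opt = Adam(model.parameters(), lr=1e-2)
    trace = []
    for _ in range(200):
        res = model.forward(x, ctx)
        deep = [
            [
                (m.reshape(*m.shape[1:]), downsample_mask(y, 2**k))
                for k, m in zip(cfg.attention_ks, res.attention_maps)
            ]
        ]
        lv = combined_loss([(res.prob, y)], deep_outputs=deep)
        opt.zero_grad()
        lv.total.backward()
        opt.step()
        trace.append(lv.total.item())
    final = model.forward(x, Context(training=False))
    report = evaluate_pair(np.asarray(final.prob.data, dtype=np.float64), y)
    return model, trace, report.dice
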