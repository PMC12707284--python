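import numpy as np
import pytest

from backflow.synthetic_data import make_toy_backbone
from backflow.trunk import TrunkConfig, TrunkModel


@pytest.fixture(scope="session")
def hairpin36():
    return make_toy_backbone(36, "hairpin", seed=1)


@pytest.fixture(scope="session")
def toy_model():
    """A small trunk with slightly perturbed weights (non-degenerate logits)."""
    model = TrunkModel(TrunkConfig.toy(seed=3))
    rng = np.random.default_rng(17)
    for _, p in model.named_parameters():
        p.data = p.data + rng.normal(0.0, 0.02, p.data.shape)
    return model


def random_rigid(rng):
    """A uniformly random rotation matrix and a translation vector."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-30.0, 30.0, size=3)


def rigid_move(bb, rot, trans):
    from dataclasses import replace

    new = {name: getattr(bb, name) @ rot.T + trans
           for name in ("coords_N", "coords_CA", "coords_C", "coords_O")}
    return replace(bb, **new)
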