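import numpy as np
import pytest

from gtvseg.nn.unet import NetworkConfig
from gtvseg.study import source_domain_spec, target_domain_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_net_cfg():
    return NetworkConfig(input_size=16, depth=2, base_channels=2, seed=0)


@pytest.fixture
def source_spec():
    return source_domain_spec()


@pytest.fixture
def target_spec():
    return target_domain_spec()


def random_mask(rng, shape=(8, 8), p=0.4):
    return (rng.random(shape) < p).astype(np.uint8)


def brute_force_confusion(pred, ref):
    """Exhaustive per-pixel double loop; the independent metric oracle."""
    tp = fp = fn = tn = 0
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    for idx in np.ndindex(pred.shape):
        p, r = bool(pred[idx]), bool(ref[idx])
        if p and r:
            tp += 1
        elif p and not r:
            fp += 1
        elif not p and r:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn
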