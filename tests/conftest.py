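import numpy as np
import pandas as pd
import pytest

from nodulenet.manifest import BBox


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_manifest():
    """Six-row manifest with a known small/large box mix."""
    rows = [
        ("P1", "images/a.png", 1, "train", [BBox(10, 10, 30, 30)]),
        ("P1", "images/b.png", 0, "train", []),
        ("P2", "images/c.png", 1, "val", [BBox(50, 40, 69, 120)]),  # small: width 69
        ("P3", "images/d.png", 1, "test", [BBox(5, 5, 70, 70)]),  # excluded: exactly 70
        ("P4", "images/e.png", 1, "test", [BBox(0, 0, 100, 100), BBox(30, 60, 20, 90)]),
        ("P5", "images/f.png", 0, "test", []),
    ]
    return pd.DataFrame(rows, columns=["patient_id", "image_path", "label", "split", "boxes"])


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central finite differences of scalar-valued f with respect to x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
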