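import numpy as np
import pandas as pd
import pytest

from lungcyto.synth import CLASS_NAMES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_manifest(per_class_counts: dict[str, int]) -> pd.DataFrame:
    """Path-only manifest (no image files) for split arithmetic."""
    rows = []
    for label, n in per_class_counts.items():
        for i in range(n):
            rows.append({"path": f"{label}/{label}_{i:05d}.png",
                         "label": label, "split": "", "fold": pd.NA})
    df = pd.DataFrame(rows, columns=["path", "label", "split", "fold"])
    df["fold"] = df["fold"].astype("Int64")
    return df


@pytest.fixture
def balanced_manifest():
    return make_manifest({c: 40 for c in CLASS_NAMES})
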