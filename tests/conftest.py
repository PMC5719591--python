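import numpy as np
import pytest

from kinflate import FamilyDesign, build_family_relatedness


@pytest.fixture(scope="session")
def trio_design():
    return FamilyDesign(1, 1, 1)


@pytest.fixture(scope="session")
def sfs1_design():
    return FamilyDesign(43, 1, 1)


@pytest.fixture(scope="session")
def sfs2_design():
    return FamilyDesign(333, 1, 1)


@pytest.fixture(scope="session")
def sfs3_design():
    return FamilyDesign(111, 2, 3)


@pytest.fixture(scope="session")
def sfs1_matrix(sfs1_design):
    return build_family_relatedness(sfs1_design)


@pytest.fixture(scope="session")
def sfs3_matrix(sfs3_design):
    return build_family_relatedness(sfs3_design)


def brute_force_lambda(s: np.ndarray, G: np.ndarray, r2_h: float) -> float:
    """Independent loop-based evaluation of the per-SNP inflation factor
    (ordered pairs j != i)."""
    s = np.asarray(s, dtype=float)
    n = len(s)
    sbar = s.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            if j != i:
                num += G[i, j] * (sbar**2 - 2 * sbar * s[i] + s[i] * s[j])
    return 1.0 + r2_h * num / ((s - sbar) ** 2).sum()
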