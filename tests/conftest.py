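import numpy as np
import pandas as pd
import pytest

from mucocosm import phyloreg
from mucocosm.abundance import AbundanceTable


@pytest.fixture
def hand_tree():
    """Three-taxon tree with hand-checkable path lengths."""
    return phyloreg.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree_factory():
    def make(n, length=1.0):
        labels = [f"T{i}" for i in range(n)]
        text = "(" + ",".join(f"{l}:{length}" for l in labels) + ");"
        return phyloreg.parse_newick(text), labels
    return make


def make_table(rel, cov=None, meta=None):
    """AbundanceTable from dicts: rel[sample][strain] etc."""
    ra = pd.DataFrame(rel)
    hc = pd.DataFrame(cov) if cov is not None else ra.where(ra == 0, 0.99)
    samples = pd.DataFrame(meta if meta is not None else
                           {"condition": ["x"] * ra.shape[1]},
                           index=ra.columns)
    return AbundanceTable(ra, hc, samples)


@pytest.fixture
def table_factory():
    return make_table


def brute_force_gls(y, x, C):
    """Independent PGLS oracle via explicit C^{-1} normal equations."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    Ci = np.linalg.inv(C)
    XtCiX = X.T @ Ci @ X
    bhat = np.linalg.solve(XtCiX, X.T @ Ci @ y)
    resid = y - X @ bhat
    sigma2 = (resid @ Ci @ resid) / (n - 2)
    se = np.sqrt(sigma2 * np.linalg.inv(XtCiX)[1, 1])
    from scipy import stats
    t = bhat[1] / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return bhat[1], se, p
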