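import math

import numpy as np
import pytest
from scipy.stats import hypergeom
from scipy.stats import t as tdist

from cpgoe.seqstats import GeneStat


def make_stats(values, prefix="g"):
    """Wrap raw CpG_o/e values as passing GeneStats (test convenience)."""
    return [
        GeneStat(f"{prefix}{i}", 1000, float(v), None, True, "none")
        for i, v in enumerate(values)
    ]


def welch_oracle(x, y):
    """Textbook Welch t-test formula, coded independently of scipy's routine."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def pearson_oracle(x, y):
    """Covariance-formula Pearson r and its t, coded independently."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    p = 2 * tdist.sf(abs(t), n - 2)
    return r, t, p


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    ks = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = hypergeom.pmf(ks, n, r1, c1)
    p_obs = pmf[ks == a][0]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


def fisher_enumeration_check(n_max):
    """Assert scipy's Fisher p equals enumeration for every table with n <= n_max.

    Iterates distinct margin triples and sweeps the table cell a over its
    support, so each pmf vector is computed once.
    """
    from scipy.stats import fisher_exact

    for n in range(2, n_max + 1):
        for r1 in range(1, n):
            for c1 in range(1, n):
                ks = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
                pmf = hypergeom.pmf(ks, n, r1, c1)
                for a, p_a in zip(ks, pmf):
                    expected = min(1.0, pmf[pmf <= p_a * (1 + 1e-9)].sum())
                    _, p = fisher_exact(
                        [[a, r1 - a], [c1 - a, n - r1 - c1 + a]]
                    )
                    assert abs(p - expected) < 1e-8, (n, r1, c1, a)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def bimodal_values(rng):
    """2000 draws from an even two-component mixture (0.5 and 1.0, sd 0.07)."""
    lo = rng.normal(0.5, 0.07, 1000)
    hi = rng.normal(1.0, 0.07, 1000)
    return np.clip(np.concatenate([lo, hi]), 0.01, 1.99)


@pytest.fixture
def unimodal_values(rng):
    return np.clip(rng.normal(0.7, 0.1, 1000), 0.01, 1.99)
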