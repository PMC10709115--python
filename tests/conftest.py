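import numpy as np
import pandas as pd
import pytest

import adexpr as ax
from adexpr.models import ModelParams


@pytest.fixture
def three_tip():
    return ax.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def two_tip():
    return ax.parse_newick("(A:1,B:1);")


@pytest.fixture
def two_tip_traits():
    vals = pd.Series({"A": 0.0, "B": 2.0})
    return ax.TraitVector(vals, pd.Series(0.0, index=vals.index))


def make_traits(mapping, se=0.0):
    vals = pd.Series(mapping, dtype=float)
    if np.isscalar(se):
        se = pd.Series(float(se), index=vals.index)
    else:
        se = pd.Series(se)
    return ax.TraitVector(vals, se)


def model_cov_bruteforce(tree, params: ModelParams, se=None):
    """Brute-force model covariance straight from the process formulas.

    Built from the MRCA-depth matrix of the *original* tree and the
    closed-form variances/covariances of each process — independent of the
    unit-tree/contrasts code path it is used to check.
    """
    labels, C = ax.phylo_vcv(tree)
    depths = np.diag(C).copy()
    if params.model == "BM":
        V = params.sigsq * C
    elif params.model == "OU":
        a = params.alpha
        if a == 0:
            V = params.sigsq * C
        else:
            Ti = depths[:, None]
            Tj = depths[None, :]
            V = np.exp(-a * (Ti + Tj - 2 * C)) * params.sigsq / (2 * a) \
                * (1 - np.exp(-2 * a * C))
    else:  # EB
        r = params.r
        V = params.sigsq * C if r == 0 else params.sigsq * (1 - np.exp(-r * C)) / r
    if se is not None:
        V = V + np.diag([float(se[l]) ** 2 for l in labels])
    return labels, V


def mvn_loglik_bruteforce(tree, traits, params: ModelParams):
    """Dense multivariate-normal log-density oracle for model_loglik."""
    from scipy.stats import multivariate_normal

    labels, V = model_cov_bruteforce(tree, params, traits.se)
    x = traits.values.reindex(labels).to_numpy()
    return float(multivariate_normal(
        mean=np.full(len(labels), params.z0), cov=V,
        allow_singular=False).logpdf(x))
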