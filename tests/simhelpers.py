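"""Shared simulation shortcuts for the statistical tests."""

import numpy as np

from binkat.binning import Bin, madsen_browning_weights
from binkat.variant_io import GenotypeMatrix


def random_rare_bin(n, m, rng, maf_range=(0.001, 0.049)):
    """A bin of m rare variants with Madsen-Browning weights on n samples.

    Monomorphic draws are rejected column-wise, so the returned bin may be
    slightly smaller than m.
    """
    maf = rng.uniform(*maf_range, m)
    G = rng.binomial(2, maf, size=(n, m)).astype(float)
    emp = G.mean(axis=0) / 2
    keep = (emp > 0) & (emp < 0.5)
    G = G[:, keep]
    w = madsen_browning_weights(G.mean(axis=0) / 2)
    bin_ = Bin("feat", "gene", np.arange(G.shape[1]), w)
    geno = GenotypeMatrix(G, np.zeros_like(G, dtype=bool), [f"S{i}" for i in range(n)])
    return bin_, geno, G


def covariate_design(n, n_covars, rng, effects=None):
    """Intercept + standard-normal covariates, and a null phenotype draw."""
    X = np.column_stack([np.ones(n), rng.standard_normal((n, n_covars))])
    coefs = np.zeros(1 + n_covars) if effects is None else np.asarray(effects)
    y = X @ coefs + rng.standard_normal(n)
    return X, y
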