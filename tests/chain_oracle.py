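"""Independent re-implementation of the tiny-instance generative chain.

Samples each conditional distribution directly with scipy.stats (a code path
disjoint from the package's numpy-Generator implementation) for a
two-species community, so the simulator can be checked distributionally.
"""

import numpy as np
from scipy import stats

TINY = dict(lam=(1.0, 1.0), a=(1.0, 0.5), volume=1.0,
            n_pcr1=2, pi=1.0, n_pcr2=1, index_eff=0.9, n_reads=10)


def sample_oracle_chain(n_draws: int, seed: int):
    """Return (W0, Y0) arrays for species 0 under the tiny instance.

    With two species the multinomial marginal for species 0 is binomial,
    sampled via scipy.  Replicates whose amplicon pool dies out entirely get
    zero reads for both species.
    """
    rs = np.random.RandomState(seed)
    cfg = TINY
    lam = np.asarray(cfg["lam"])
    growth1 = (1.0 + np.asarray(cfg["a"])) ** cfg["n_pcr1"]
    growth2 = (1.0 + cfg["index_eff"]) ** cfg["n_pcr2"]

    W = stats.poisson.rvs(lam * cfg["volume"], size=(n_draws, 2), random_state=rs)
    X1 = stats.poisson.rvs(W * growth1, random_state=rs)
    X2 = X1 if cfg["pi"] == 1.0 else stats.binom.rvs(X1, cfg["pi"], random_state=rs)
    X3 = stats.poisson.rvs(X2 * growth2, random_state=rs)
    total = X3.sum(axis=1)
    Y0 = np.zeros(n_draws, dtype=int)
    live = total > 0
    p0 = X3[live, 0] / total[live]
    Y0[live] = stats.binom.rvs(cfg["n_reads"], p0, random_state=rs)
    return W[:, 0], Y0


def bin_outcomes(W0, Y0):
    """Joint (W0 capped at 3, Y0 binned) contingency counts, flattened."""
    w = np.minimum(W0, 3)
    y = np.digitize(Y0, [1, 4, 7, 10])  # bins: 0, 1-3, 4-6, 7-9, 10
    counts = np.zeros((4, 5), dtype=int)
    np.add.at(counts, (w, y), 1)
    return counts.ravel()
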