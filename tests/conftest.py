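import numpy as np
import pandas as pd
import pytest

from borealgrowth.mixedmodel import LOG2PI, MixedModelSpec, validate_panel
from borealgrowth.synthetic import SyntheticConfig, gen_ring_panel


def dense_reml_loglik(spec: MixedModelSpec, panel: pd.DataFrame) -> float:
    """Brute-force restricted likelihood via the explicit full covariance matrix.

    Builds V = Σ_levels Z G Zᵀ + σ²R (AR(1) correlation φ^|Δyear| within each
    tree) densely and evaluates −½[log|V| + log|XᵀV⁻¹X| + rᵀV⁻¹r + (n−p)log2π]
    directly.  Independent of the package's Woodbury likelihood path.
    """
    panel = validate_panel(panel)
    X = np.column_stack([np.ones(len(panel)), panel["gpp"], panel["drought"]])
    y = panel["index"].to_numpy(float)
    n = len(y)
    V = np.zeros((n, n))
    for _, sgrp in panel.groupby("site_id"):
        si = sgrp.index.to_numpy()
        V[np.ix_(si, si)] += X[si] @ np.diag(spec.sd_site**2) @ X[si].T
        for _, tgrp in sgrp.groupby("tree_id"):
            ti = tgrp.index.to_numpy()
            V[np.ix_(ti, ti)] += X[ti] @ np.diag(spec.sd_tree**2) @ X[ti].T
            yrs = tgrp["year"].to_numpy(float)
            R = spec.phi ** np.abs(yrs[:, None] - yrs[None, :])
            V[np.ix_(ti, ti)] += spec.sigma**2 * R
    _, ldV = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    _, ldA = np.linalg.slogdet(A)
    return float(-0.5 * (ldV + ldA + r @ Vi @ r + (n - 3) * LOG2PI))


@pytest.fixture(scope="session")
def tiny_panel() -> pd.DataFrame:
    """2 sites × 2 trees × 20 years from the default-truth generator."""
    cfg = SyntheticConfig(n_sites=2, trees_per_site=2, year_start=1991, year_end=2010, seed=7)
    return gen_ring_panel(cfg)


@pytest.fixture(scope="session")
def small_recovery_fit():
    """One REML fit of a 10-site × 5-tree × 40-year default-truth panel."""
    from borealgrowth.mixedmodel import fit_reml

    cfg = SyntheticConfig(n_sites=10, trees_per_site=5, year_start=1971, year_end=2010, seed=3)
    panel = gen_ring_panel(cfg)
    return cfg, panel, fit_reml(panel, seed=3)
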