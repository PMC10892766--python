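"""CNV-derived genomic relationship matrix.

The GRM is a VanRaden-style centered cross-product on the three-state
CNVR codes: with C the column-mean-centered code matrix,

    G = C C' / s,    s = sum_j var_j,

where var_j is the (population, denominator n) variance of column j.
Zero-variance columns carry no relationship information and are dropped.
Centering makes the row sums of G exactly zero and the normalization
makes the mean diagonal exactly 1.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import GenotypeMatrix, GrmMatrix

logger = logging.getLogger(__name__)

DEFAULT_RIDGE = 1e-6


def compute_grm(gm: GenotypeMatrix) -> GrmMatrix:
    """Centered cross-product GRM from a coded genotype matrix.

    Raises
    ------
    ValueError
        If there are fewer than two samples or no column has nonzero
        variance ("no informative CNVRs").
    """
    if gm.n_samples < 2:
        raise ValueError("GRM needs at least two samples")
    codes = gm.codes.astype(float)
    variances = codes.var(axis=0)  # denominator n
    informative = variances > 0
    n_dropped = int((~informative).sum())
    if n_dropped:
        logger.info("dropped %d zero-variance CNVR column(s) from the GRM", n_dropped)
    if not informative.any():
        raise ValueError("no informative CNVRs: every column has zero variance")
    c = codes[:, informative]
    c = c - c.mean(axis=0, keepdims=True)
    s = variances[informative].sum()
    g = (c @ c.T) / s
    g = (g + g.T) / 2.0  # scrub asymmetric rounding noise
    return GrmMatrix(sample_ids=list(gm.sample_ids), values=g)


def add_ridge(grm: GrmMatrix, ridge: float = DEFAULT_RIDGE) -> GrmMatrix:
    """Return a copy with ``ridge`` added to the diagonal.

    CNV GRMs built from few columns can be rank-deficient; a small ridge
    keeps the downstream mixed-model solves well-posed.
    """
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    return GrmMatrix(
        sample_ids=list(grm.sample_ids),
        values=grm.values + ridge * np.eye(grm.n),
    )


def grm_diagnostics(grm: GrmMatrix) -> dict[str, float]:
    """Mean diagonal, mean off-diagonal and minimum eigenvalue of G."""
    g = grm.values
    n = grm.n
    diag = np.diag(g)
    off_mask = ~np.eye(n, dtype=bool)
    eigvals = np.linalg.eigvalsh(g)
    return {
        "mean_diagonal": float(diag.mean()),
        "mean_off_diagonal": float(g[off_mask].mean()) if n > 1 else 0.0,
        "min_eigenvalue": float(eigvals.min()),
    }
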