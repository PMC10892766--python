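"""Mixed linear model association testing for CNVRs.

The model for one quantitative trait is

    y = mu + W g + Z u + e,     u ~ N(0, G sigma2_a),  e ~ N(0, I sigma2_e)

with one record per individual (Z = I), G the CNV-derived relationship
matrix, and g the fixed effect of one tested CNVR column of W at a time.

Variance components are estimated once under the null model (no CNVR
term) by restricted maximum likelihood on the eigendecomposition of G:
writing G = U D U' and rotating y and the fixed-effect design by U', the
covariance becomes diagonal, sigma2_p * Lambda(h2) with
lambda_i = h2 * d_i + (1 - h2), and the restricted likelihood is profiled
down to a scalar optimization over h2. Each CNVR is then tested by
generalized least squares with the variance *ratio* fixed at the null
estimate and the total scale re-profiled per marker (EMMAX-style, one
decomposition for the whole scan); the test statistic is the Wald
chi-square with 1 df. With sigma2_a = 0 this collapses exactly to
ordinary least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .types import Cnvr, GenotypeMatrix, GrmMatrix

logger = logging.getLogger(__name__)

H2_BOUNDS = (1e-6, 1.0 - 1e-6)
H2_TOL = 1e-8
MIN_SAMPLES = 30
#: Median of the chi-square(1 df) distribution, the null median for lambda_GC.
CHI2_1_MEDIAN = 0.4549364231195728


@dataclass
class MixedModelSpec:
    """Phenotype vector and fixed-effect design for one trait.

    ``y`` holds the retained (non-missing) observations, aligned with
    ``sample_ids``; ``covariates`` is an optional n x k matrix of extra
    fixed effects (the intercept is always included implicitly).
    """

    trait_name: str
    sample_ids: list[str]
    y: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if len(self.y) != len(self.sample_ids):
            raise ValueError("y length does not match sample_ids")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, float))
            if self.covariates.shape[0] != len(self.y):
                raise ValueError("covariate rows do not match y")

    def fixed_design(self) -> np.ndarray:
        """Intercept column plus any covariates."""
        x = np.ones((len(self.y), 1))
        if self.covariates is not None:
            x = np.hstack([x, self.covariates])
        return x


@dataclass
class VarianceComponents:
    """REML estimates of the polygenic and residual variances."""

    sigma2_a: float
    sigma2_e: float
    h2: float
    reml_loglik: float

    def __post_init__(self) -> None:
        if self.sigma2_a < 0 or self.sigma2_e <= 0:
            raise ValueError("variance components out of range")
        expected = self.sigma2_a / (self.sigma2_a + self.sigma2_e)
        if abs(expected - self.h2) > 1e-8:
            raise ValueError("h2 inconsistent with variance components")


@dataclass
class AssociationResult:
    """Wald test of one CNVR: effect, standard error, chi-square, p-value."""

    cnvr_id: str
    beta: float
    se: float
    wald_chi2: float
    p_value: float
    n_used: int
    significant: bool = False
    degenerate: bool = False


@dataclass
class EigenGrm:
    """Cached eigendecomposition G = U diag(d) U'."""

    sample_ids: list[str]
    d: np.ndarray
    u: np.ndarray


@dataclass
class GwasRun:
    """Scan output: per-CNVR results plus the null fit and threshold used."""

    trait: str
    results: list[AssociationResult]
    variance_components: VarianceComponents
    threshold: float
    n_used: int
    method: str = "bonferroni"
    qvalues: np.ndarray | None = field(default=None, repr=False)


def eigendecompose(grm: GrmMatrix) -> EigenGrm:
    """Symmetric eigendecomposition of G, tiny negative eigenvalues clipped."""
    d, u = np.linalg.eigh(grm.values)
    if d.min() < -1e-6:
        logger.warning("GRM has eigenvalue %.3g < 0; clipping to 0", d.min())
    return EigenGrm(sample_ids=list(grm.sample_ids), d=np.clip(d, 0.0, None), u=u)


def _reml_loglik(h2: float, d: np.ndarray, ystar: np.ndarray,
                 xstar: np.ndarray) -> float:
    """Restricted log-likelihood at heritability h2, total variance profiled out."""
    n, p = xstar.shape
    lam = h2 * d + (1.0 - h2)
    w = 1.0 / lam
    xtx = xstar.T @ (xstar * w[:, None])
    xty = xstar.T @ (ystar * w)
    beta = np.linalg.solve(xtx, xty)
    resid = ystar - xstar @ beta
    rss = float(resid @ (resid * w))
    sigma2 = rss / (n - p)
    _, logdet_xtx = np.linalg.slogdet(xtx)
    _, logdet_xx = np.linalg.slogdet(xstar.T @ xstar)
    ll = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0)
        + float(np.log(lam).sum())
        + logdet_xtx
        - logdet_xx
    )
    return ll


def fit_null_reml(spec: MixedModelSpec, grm: GrmMatrix | EigenGrm) -> VarianceComponents:
    """REML fit of the null model y = mu (+covariates) + u + e.

    The likelihood is maximized over h2 in [1e-6, 1-1e-6] by a coarse
    grid followed by bounded scalar optimization (tolerance 1e-8 on h2)
    on the rotated, diagonalized problem.
    """
    n = len(spec.y)
    if n < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} samples after missing-data "
                         f"deletion, got {n}")
    if np.var(spec.y) == 0:
        raise ValueError("zero phenotypic variance")
    eig = grm if isinstance(grm, EigenGrm) else eigendecompose(grm)
    if eig.sample_ids != spec.sample_ids:
        raise ValueError("GRM samples do not match the model spec")
    ystar = eig.u.T @ spec.y
    xstar = eig.u.T @ spec.fixed_design()

    lo, hi = H2_BOUNDS
    grid = np.linspace(lo, hi, 64)
    ll_grid = np.array([_reml_loglik(h, eig.d, ystar, xstar) for h in grid])
    if not np.all(np.isfinite(ll_grid)):
        raise ValueError("non-finite restricted likelihood on the h2 grid")
    k = int(np.argmax(ll_grid))
    bl = grid[max(k - 1, 0)]
    bh = grid[min(k + 1, len(grid) - 1)]
    opt = minimize_scalar(
        lambda h: -_reml_loglik(h, eig.d, ystar, xstar),
        bounds=(bl, bh), method="bounded",
        options={"xatol": H2_TOL},
    )
    h2 = float(np.clip(opt.x, lo, hi))
    ll = _reml_loglik(h2, eig.d, ystar, xstar)
    if not np.isfinite(ll):
        raise ValueError("non-finite restricted likelihood at the optimum")
    # recover the profiled total variance at the optimum
    lam = h2 * eig.d + (1.0 - h2)
    w = 1.0 / lam
    xtx = xstar.T @ (xstar * w[:, None])
    beta = np.linalg.solve(xtx, xstar.T @ (ystar * w))
    resid = ystar - xstar @ beta
    sigma2_p = float(resid @ (resid * w)) / (n - xstar.shape[1])
    return VarianceComponents(
        sigma2_a=h2 * sigma2_p,
        sigma2_e=(1.0 - h2) * sigma2_p,
        h2=h2,
        reml_loglik=float(ll),
    )


def _gls_marker(ystar: np.ndarray, xstar: np.ndarray, wstar: np.ndarray,
                lam: np.ndarray) -> tuple[float, float]:
    """Weighted LS of ystar on [xstar, wstar]; returns (beta_w, se_w).

    The residual scale is re-profiled per marker with df = n - p, so the
    h2 = 0 limit reproduces ordinary least squares exactly.
    """
    design = np.hstack([xstar, wstar[:, None]])
    n, p = design.shape
    w = 1.0 / lam
    xtx = design.T @ (design * w[:, None])
    xty = design.T @ (ystar * w)
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ xty
    resid = ystar - design @ beta
    sigma2 = float(resid @ (resid * w)) / (n - p)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    return float(beta[-1]), se


def test_cnvr(
    spec: MixedModelSpec,
    vc: VarianceComponents,
    eig: EigenGrm,
    w: np.ndarray,
    cnvr_id: str = "",
    exact: bool = False,
) -> AssociationResult:
    """Wald test of one CNVR code vector under the fitted mixed model.

    With ``exact=True`` the heritability is re-estimated by REML with the
    marker in the fixed effects before the Wald test (slow; cross-check
    of the one-decomposition fast path).
    """
    w = np.asarray(w, dtype=float).ravel()
    n = len(spec.y)
    if len(w) != n:
        raise ValueError("marker vector length does not match y")
    if np.all(w == w[0]):
        return AssociationResult(
            cnvr_id=cnvr_id, beta=0.0, se=np.inf, wald_chi2=0.0,
            p_value=1.0, n_used=n, degenerate=True,
        )
    ystar = eig.u.T @ spec.y
    xstar = eig.u.T @ spec.fixed_design()
    wstar = eig.u.T @ w
    h2 = vc.h2
    if exact:
        design = np.hstack([spec.fixed_design(), w[:, None]])
        dstar = eig.u.T @ design
        lo, hi = H2_BOUNDS
        opt = minimize_scalar(
            lambda h: -_reml_loglik(h, eig.d, ystar, dstar),
            bounds=(lo, hi), method="bounded", options={"xatol": H2_TOL},
        )
        h2 = float(np.clip(opt.x, lo, hi))
    lam = h2 * eig.d + (1.0 - h2)
    beta, se = _gls_marker(ystar, xstar, wstar, lam)
    chi2 = (beta / se) ** 2
    p = float(stats.chi2.sf(chi2, df=1))
    return AssociationResult(
        cnvr_id=cnvr_id, beta=beta, se=se, wald_chi2=float(chi2),
        p_value=max(p, np.nextafter(0, 1)), n_used=n,
    )


def significance_threshold(n_cnvr: int, alpha: float = 0.05) -> float:
    """Bonferroni genome-wide threshold alpha / N for N tested CNVRs."""
    if n_cnvr < 1:
        raise ValueError("n_cnvr must be >= 1")
    return alpha / n_cnvr


def bh_qvalues(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (FDR q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_gwas(
    gm: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    trait: str,
    grm: GrmMatrix,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
    method: str = "bonferroni",
    exact: bool = False,
) -> GwasRun:
    """Scan every CNVR column against one trait.

    Samples are reconciled by id; samples missing the trait are dropped
    listwise and the GRM/genotype rows are subset before the (single)
    eigendecomposition. The significance flag uses Bonferroni alpha/N by
    default, or BH-FDR at level alpha with ``method='fdr_bh'``.
    """
    if trait not in phenotypes.columns:
        raise ValueError(f"trait {trait!r} not in phenotype table")
    if method not in ("bonferroni", "fdr_bh"):
        raise ValueError(f"unknown multiple-testing method {method!r}")
    phen = phenotypes[trait]
    keep_idx = [
        i for i, s in enumerate(gm.sample_ids)
        if s in phen.index and np.isfinite(phen.loc[s])
    ]
    if not keep_idx:
        raise ValueError(f"no samples with non-missing {trait!r}")
    kept = [gm.sample_ids[i] for i in keep_idx]
    y = phen.loc[kept].to_numpy(dtype=float)
    grm_order = {s: i for i, s in enumerate(grm.sample_ids)}
    try:
        gsel = [grm_order[s] for s in kept]
    except KeyError as e:
        raise ValueError(f"sample {e} missing from the GRM") from None
    gsub = GrmMatrix(sample_ids=kept, values=grm.values[np.ix_(gsel, gsel)])
    cov = None if covariates is None else np.asarray(covariates)[keep_idx]
    spec = MixedModelSpec(trait_name=trait, sample_ids=kept, y=y, covariates=cov)
    eig = eigendecompose(gsub)
    vc = fit_null_reml(spec, eig)
    codes = gm.codes[keep_idx, :]
    results = [
        test_cnvr(spec, vc, eig, codes[:, j], cnvr_id=cid, exact=exact)
        for j, cid in enumerate(gm.cnvr_ids)
    ]
    pvals = np.array([r.p_value for r in results])
    qvals = None
    if method == "bonferroni":
        threshold = significance_threshold(len(results), alpha)
        for r in results:
            r.significant = (not r.degenerate) and r.p_value < threshold
    else:
        qvals = bh_qvalues(pvals)
        threshold = alpha  # on the q-value scale
        for r, q in zip(results, qvals):
            r.significant = (not r.degenerate) and q < alpha
    logger.info(
        "GWAS %s: n=%d, m=%d, h2=%.3f, %d significant (%s)",
        trait, len(kept), len(results), vc.h2,
        sum(r.significant for r in results), method,
    )
    return GwasRun(
        trait=trait, results=results, variance_components=vc,
        threshold=threshold, n_used=len(kept), method=method, qvalues=qvals,
    )


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def manhattan_qq_data(
    results: list[AssociationResult], cnvrs: list[Cnvr]
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Plot-ready Manhattan table, QQ pairs, and genomic inflation lambda_GC.

    The Manhattan table has one row per tested CNVR with its chromosome,
    midpoint position, cumulative genome position and -log10 p. QQ
    expected quantiles are -log10((i - 0.5) / m); lambda_GC is the median
    Wald chi-square over its null median 0.4549. Degenerate tests are
    excluded from both.
    """
    region = {c.cnvr_id: c for c in cnvrs}
    missing = [r.cnvr_id for r in results if r.cnvr_id not in region]
    if missing:
        raise ValueError(f"results without a CNVR: {missing[:5]}")
    usable = [r for r in results if not r.degenerate]
    rows = []
    for r in usable:
        c = region[r.cnvr_id]
        rows.append({
            "cnvr_id": r.cnvr_id,
            "chrom": c.chrom,
            "pos": (c.start + c.end) / 2.0,
            "minus_log10_p": -np.log10(r.p_value),
            "wald_chi2": r.wald_chi2,
        })
    mh = pd.DataFrame(rows, columns=["cnvr_id", "chrom", "pos",
                                     "minus_log10_p", "wald_chi2"])
    if len(mh):
        mh = mh.sort_values(
            by=["chrom", "pos"],
            key=lambda col: (col.map(_chrom_sort_key)
                             if col.name == "chrom" else col),
        ).reset_index(drop=True)
        offset, offsets = 0.0, {}
        for chrom in mh["chrom"].drop_duplicates():
            offsets[chrom] = offset
            offset += float(mh.loc[mh["chrom"] == chrom, "pos"].max()) + 1.0
        mh["cum_pos"] = mh["pos"] + mh["chrom"].map(offsets)
    else:
        mh["cum_pos"] = []
    m = len(usable)
    if m:
        observed = np.sort([-np.log10(r.p_value) for r in usable])[::-1]
        expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
        qq = pd.DataFrame({"expected": expected, "observed": observed})
        lambda_gc = float(
            np.median([r.wald_chi2 for r in usable]) / CHI2_1_MEDIAN
        )
    else:
        qq = pd.DataFrame({"expected": [], "observed": []})
        lambda_gc = float("nan")
    return mh, qq, lambda_gc


def association_table(
    run: GwasRun, cnvrs: list[Cnvr],
    proximal: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-CNVR association TSV schema: trait, region, p-value, significance."""
    region = {c.cnvr_id: c for c in cnvrs}
    rows = []
    for r in run.results:
        c = region.get(r.cnvr_id)
        rows.append({
            "trait": run.trait,
            "cnvr_id": r.cnvr_id,
            "type": c.cnvr_type.value if c else "",
            "chrom": c.chrom if c else "",
            "start": c.start if c else -1,
            "end": c.end if c else -1,
            "beta": r.beta,
            "se": r.se,
            "p_value": r.p_value,
            "significant": r.significant,
            "proximal_genes": ",".join((proximal or {}).get(r.cnvr_id, [])),
        })
    return pd.DataFrame(rows)
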