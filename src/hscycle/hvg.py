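"""Spike-in calibrated technical-noise model and highly-variable-gene test.

Across cells, the squared coefficient of variation of a spike-in species
with normalized mean expression mu follows the two-parameter law

    CV2_tech(mu) = a1 / mu + alpha0,

the sum of a shot-noise term and an asymptotic technical CV2.  The
parameters are estimated from the spike-ins by a gamma-family GLM with
identity link on (CV2, 1/mu), restricted to species above a data-driven
mean cutoff.  A biological gene is called highly variable when its sample
variance significantly exceeds the technical expectation plus a minimal
biological dispersion margin, via a chi-square test:

    c    = alpha0 + minBiolDisp + alpha0 * minBiolDisp
    d_i  = (mu_i * psi + mu_i^2 * c) / (1 + c / minBiolDisp)
    T_i  = (m - 1) * v_i / d_i ~ chi2(m - 1) under the boundary null,

with minBiolDisp the squared minimal biological CV (default CV = 0.5) and
psi the shot-noise scale combining the mean inverse spike-in size factor
with a1 rescaled by the spike-in/biological size-factor ratio:

    xi  = mean(1 / s_ercc)
    psi = xi + (a1 - xi) * mean(s_ercc / s_cell).

Setting ``min_biol_cv = 0`` removes the margin entirely and tests the
fitted technical law itself (d_i = mu_i * psi + mu_i^2 * alpha0); in that
mode the p-values are calibrated (approximately uniform) on data with no
biological variability, which is the package's calibration check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import DataError
from .normalize import SizeFactors

MIN_SPIKEINS = 10


@dataclass
class TechNoiseFit:
    """Fitted technical-noise parameters from spike-ins."""

    a1: float
    alpha0: float
    psi: float
    min_mean_for_fit: float
    n_spikeins_used: int
    alpha0_clamped: bool = False

    def cv2_tech(self, mu: np.ndarray) -> np.ndarray:
        return self.a1 / np.asarray(mu, dtype=float) + self.alpha0


def _row_stats(norm: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = norm.to_numpy(dtype=float)
    mu = x.mean(axis=1)
    v = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mu > 0, v / mu**2, np.nan)
    return mu, v, cv2


def fit_technical_noise(
    norm_spikeins: pd.DataFrame,
    sf: SizeFactors,
    min_mean_for_fit: float | None = None,
    cv2_floor_for_cutoff: float = 0.3,
    cutoff_quantile: float = 0.8,
) -> TechNoiseFit:
    """Fit CV2_tech(mu) = a1/mu + alpha0 on spike-in rows.

    ``norm_spikeins`` is the spike-in submatrix normalized by spike-in size
    factors (genes x cells).  When ``min_mean_for_fit`` is not given it
    defaults to the ``cutoff_quantile`` of spike-in means among spike-ins
    with CV2 above ``cv2_floor_for_cutoff``.  A negative fitted alpha0 is
    clamped to 0 with a warning.
    """
    if norm_spikeins.shape[1] < 2:
        raise DataError("technical-noise fit requires at least 2 cells")
    mu, _, cv2 = _row_stats(norm_spikeins)
    ok = np.isfinite(cv2) & (mu > 0)
    if min_mean_for_fit is None:
        noisy = ok & (cv2 > cv2_floor_for_cutoff)
        if not noisy.any():
            min_mean_for_fit = 0.0
        else:
            min_mean_for_fit = float(np.quantile(mu[noisy], cutoff_quantile))
    use = ok & (mu >= min_mean_for_fit)
    n_used = int(use.sum())
    if n_used < MIN_SPIKEINS:
        raise DataError(
            f"only {n_used} usable spike-ins above the fit cutoff "
            f"(need >= {MIN_SPIKEINS})"
        )
    X = np.column_stack([np.ones(n_used), 1.0 / mu[use]])
    y = cv2[use]
    # OLS start keeps the identity-link gamma fit off zero/negative means
    start = np.linalg.lstsq(X, y, rcond=None)[0]
    start[1] = max(start[1], 1e-6)
    start[0] = max(start[0], 1e-9)
    with warnings.catch_warnings():
        # identity-link gamma is the standard choice for this fit
        warnings.simplefilter("ignore")
        model = sm.GLM(
            y, X, family=sm.families.Gamma(link=sm.families.links.Identity())
        )
    try:
        res = model.fit(start_params=start, maxiter=200)
    except Exception as exc:  # pragma: no cover - convergence pathology
        raise DataError(f"technical-noise GLM did not converge: {exc}") from exc
    alpha0, a1 = float(res.params[0]), float(res.params[1])
    clamped = False
    if alpha0 < 0:
        warnings.warn(f"fitted alpha0 = {alpha0:.4g} < 0; clamped to 0")
        alpha0, clamped = 0.0, True
    if a1 <= 0:
        raise DataError(f"fitted a1 = {a1:.4g} is not positive")
    ercc = np.asarray(sf.ercc_series(), dtype=float)
    cellf = np.asarray(sf.cell_series(), dtype=float)
    xi = float(np.mean(1.0 / ercc))
    psi = xi + (a1 - xi) * float(np.mean(ercc / cellf))
    return TechNoiseFit(
        a1=a1,
        alpha0=alpha0,
        psi=psi,
        min_mean_for_fit=float(min_mean_for_fit),
        n_spikeins_used=n_used,
        alpha0_clamped=clamped,
    )


def test_highly_variable(
    norm_genes: pd.DataFrame,
    fit: TechNoiseFit,
    min_biol_cv: float = 0.5,
    padj_threshold: float = 0.1,
) -> pd.DataFrame:
    """Chi-square excess-variability test per biological gene.

    Returns a DataFrame indexed by gene with columns ``mean``, ``variance``,
    ``cv2``, ``statistic``, ``p_value``, ``p_adjusted`` (Benjamini-Hochberg
    across genes with positive mean) and ``highly_variable``.  Genes with
    zero mean get p = 1 and are excluded from the multiplicity count.
    """
    m = norm_genes.shape[1]
    if m < 2:
        raise DataError("HVG test requires at least 2 cells")
    mu, v, cv2 = _row_stats(norm_genes)
    dof = m - 1
    if min_biol_cv > 0:
        min_biol_disp = min_biol_cv**2
        c = fit.alpha0 + min_biol_disp + fit.alpha0 * min_biol_disp
        denom = (mu * fit.psi + mu**2 * c) / (1.0 + c / min_biol_disp)
    else:
        # margin-free mode: test the technical noise law directly
        denom = mu * fit.psi + mu**2 * fit.alpha0
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(mu > 0, dof * v / denom, 0.0)
    p = np.where(mu > 0, stats.chi2.sf(T, dof), 1.0)
    padj = np.ones_like(p)
    tested = mu > 0
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "mean": mu,
            "variance": v,
            "cv2": cv2,
            "statistic": T,
            "p_value": p,
            "p_adjusted": padj,
            "highly_variable": padj < padj_threshold,
        },
        index=norm_genes.index,
    )
    return out
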