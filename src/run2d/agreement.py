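"""Agreement statistics between two sets of joint-angle waveforms.

Comparing a markerless and a marker-based measurement of the same 101-point
gait curves (or the same markerless method under two clothing conditions)
uses four quantities:

* the per-percent mean absolute error across participants;
* the per-participant RMSE over the percent grid;
* the Šidák family-wise alpha adjustment for testing several joints;
* a one-dimensional two-way repeated-measures ANOVA over the cycle, with a
  family-wise critical threshold on the F trajectory — statistical
  parametric mapping on curves.  The default threshold comes from the
  permutation distribution of the maximum F statistic (sign flips of the
  within-participant contrast, exact for a 2x2 within design); a parametric
  random-field-theory threshold is available as an alternative.

Supra-threshold clusters — maximal runs of cycle percentages where F
exceeds the critical value — are where the two systems differ beyond what
chance allows at the family-wise alpha.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "CurvePanel",
    "SPMResult",
    "mae_curve",
    "rmse_per_participant",
    "sidak_alpha",
    "spm_rm_anova_2way",
]

logger = logging.getLogger(__name__)


class AgreementError(ValueError):
    pass


@dataclass
class CurvePanel:
    """Balanced 2x2 within-participant panel of 101-point curves, one joint.

    ``data`` has shape ``(n_participants, 2, 2, n_points)``; axis 1 is the
    factor of interest (e.g. system: marker, markerless; or clothing: lab,
    running) and axis 2 the secondary factor (e.g. speed: 2.5, 3.6 m/s).
    """

    data: np.ndarray
    factor_a: tuple = ("marker", "markerless")
    factor_b: tuple = ("2.5", "3.6")
    joint: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[1] != 2 or self.data.shape[2] != 2:
            raise AgreementError(
                "panel data must have shape (participants, 2, 2, points)"
            )
        if self.data.shape[0] < 2:
            raise AgreementError("need >= 2 participants")
        if np.isnan(self.data).any():
            raise AgreementError("panel has missing cells; the design must be complete")

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def n_points(self) -> int:
        return self.data.shape[3]


@dataclass
class SPMResult:
    """F trajectories, family-wise thresholds and supra-threshold clusters."""

    F_main: np.ndarray
    F_interaction: np.ndarray
    threshold_main: float
    threshold_interaction: float
    clusters_main: list
    clusters_interaction: list
    p_main: float
    p_interaction: float
    alpha: float
    method: str
    df: tuple
    n_permutations: int | None = None
    seed: int | None = None
    warnings: list = field(default_factory=list)
    normality_min_p: float | None = None


def mae_curve(panel_a: np.ndarray, panel_b: np.ndarray) -> np.ndarray:
    """Mean over participants of the point-wise absolute error between curves."""
    a = np.asarray(panel_a, dtype=float)
    b = np.asarray(panel_b, dtype=float)
    if a.shape != b.shape:
        raise AgreementError(f"shape mismatch: {a.shape} vs {b.shape}")
    return np.abs(a - b).mean(axis=0)


def rmse_per_participant(a: np.ndarray, b: np.ndarray) -> float | np.ndarray:
    """RMSE between two curves on a common percent grid (degrees).

    Accepts single curves (returns a scalar) or stacked ``(n, points)``
    panels (returns one RMSE per participant).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise AgreementError(f"shape mismatch: {a.shape} vs {b.shape}")
    out = np.sqrt(np.mean((a - b) ** 2, axis=-1))
    return float(out) if out.ndim == 0 else out


def sidak_alpha(family_alpha: float, m: int) -> float:
    """Šidák-adjusted per-test alpha: ``1 - (1 - alpha)**(1/m)``."""
    if not 0 < family_alpha < 1:
        raise AgreementError("family_alpha must lie in (0, 1)")
    if m < 1:
        raise AgreementError("m must be >= 1")
    return 1.0 - (1.0 - family_alpha) ** (1.0 / m)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA machinery


def _rm_anova_f(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Point-wise two-way within-participant ANOVA F statistics.

    ``data``: (n, a, b, q).  Returns (F_A, F_AxB, (df_num, df_den)) with the
    classical sums-of-squares partition; error terms are the factor-by-
    subject interactions.
    """
    n, a, b, q = data.shape
    m = data.mean(axis=(0, 1, 2))
    m_a = data.mean(axis=(0, 2))  # (a, q)
    m_b = data.mean(axis=(0, 1))  # (b, q)
    m_s = data.mean(axis=(1, 2))  # (n, q)
    m_ab = data.mean(axis=0)  # (a, b, q)
    m_as = data.mean(axis=2)  # (n, a, q)
    m_bs = data.mean(axis=1)  # (n, b, q)

    ss_a = n * b * ((m_a - m) ** 2).sum(axis=0)
    ss_as = b * ((m_as - m_a[None] - m_s[:, None] + m) ** 2).sum(axis=(0, 1))
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None] + m) ** 2).sum(axis=(0, 1))
    resid = (
        data
        - m_ab[None]
        - m_as[:, :, None]
        - m_bs[:, None]
        + m_a[None, :, None]
        + m_b[None, None]
        + m_s[:, None, None]
        - m
    )
    ss_abs = (resid**2).sum(axis=(0, 1, 2))

    df_a = a - 1
    df_as = (a - 1) * (n - 1)
    df_ab = (a - 1) * (b - 1)
    df_abs = (a - 1) * (b - 1) * (n - 1)
    # effect SS at rounding-noise level (e.g. identical factor levels) is zero
    tol = 1e-12 * ((data - m) ** 2).sum(axis=(0, 1, 2)) + 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        f_a = np.where(ss_a < tol, 0.0, (ss_a / df_a) / (ss_as / df_as))
        f_ab = np.where(ss_ab < tol, 0.0, (ss_ab / df_ab) / (ss_abs / df_abs))
    return np.nan_to_num(f_a), np.nan_to_num(f_ab), (df_a, df_as)


def _contrasts(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-participant contrasts whose paired t^2 equal the 2x2 RM-ANOVA F."""
    d_main = data[:, 1].mean(axis=1) - data[:, 0].mean(axis=1)  # (n, q)
    d_inter = (data[:, 1, 1] - data[:, 1, 0]) - (data[:, 0, 1] - data[:, 0, 0])
    return d_main, d_inter


def _perm_max_distribution(d: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Max-over-nodes t^2 under per-participant sign flips (identity included)."""
    n = d.shape[0]
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    signs[0] = 1.0
    flipped_mean = signs @ d / n  # (n_perm, q)
    sq = (d**2).sum(axis=0)  # invariant under sign flips
    var = (sq[None, :] - n * flipped_mean**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = n * flipped_mean**2 / var
    return np.nan_to_num(f).max(axis=1)


def _clusters(f: np.ndarray, threshold: float, grid: np.ndarray) -> list:
    """Maximal supra-threshold runs as (start_percent, end_percent) pairs."""
    above = f > threshold
    out = []
    i = 0
    q = len(f)
    while i < q:
        if above[i]:
            j = i
            while j + 1 < q and above[j + 1]:
                j += 1
            out.append((float(grid[i]), float(grid[j])))
            i = j + 1
        else:
            i += 1
    return out


def _estimate_fwhm(residuals: np.ndarray) -> float:
    """Smoothness (FWHM, in nodes) from normalized residual gradients."""
    ssq = (residuals**2).sum(axis=0)
    ssq = np.where(ssq < 1e-30, 1e-30, ssq)
    u = residuals / np.sqrt(ssq)[None, :]
    grad = np.gradient(u, axis=1)
    lam = (grad**2).sum(axis=0).mean()
    if lam <= 0:
        return float(residuals.shape[1])
    return float(math.sqrt(4.0 * math.log(2.0) / lam))


def _rft_threshold(alpha: float, df: tuple, resels: float) -> float:
    """Critical F for a smooth 1D F field via expected-Euler-characteristic
    densities (Worsley), solving ``rho0(u) + resels * rho1(u) = alpha``."""
    v1, v2 = df

    def rho1(u: float) -> float:
        lg = (
            math.lgamma((v1 + v2 - 1) / 2.0)
            - math.lgamma(v1 / 2.0)
            - math.lgamma(v2 / 2.0)
        )
        k = v1 * u / v2
        return (
            math.sqrt(4.0 * math.log(2.0))
            / (2.0 * math.pi)
            * math.exp(lg)
            * math.sqrt(2.0)
            * k ** ((v1 - 1) / 2.0)
            * (1.0 + k) ** (-(v1 + v2 - 2) / 2.0)
        )

    def excursion(u: float) -> float:
        return stats.f.sf(u, v1, v2) + resels * rho1(u)

    lo = stats.f.isf(alpha, v1, v2)
    hi = lo
    while excursion(hi) > alpha:
        hi *= 2.0
        if hi > 1e9:
            break
    return float(brentq(lambda u: excursion(u) - alpha, lo, hi)) if hi > lo else lo


def spm_rm_anova_2way(
    panel: CurvePanel,
    alpha: float = 0.05,
    method: str = "permutation",
    n_permutations: int = 1000,
    seed: int | None = None,
) -> SPMResult:
    """1D two-way repeated-measures ANOVA over the cycle with family-wise
    thresholds for the factor-A main effect and the AxB interaction.

    ``method="permutation"`` (default) thresholds each F trajectory at the
    ``1 - alpha`` quantile of the maximum-statistic distribution under
    per-participant sign flips of the within-participant contrast (the
    observed labelling is always included, so the test is not anti-
    conservative); ``method="rft"`` uses the parametric random-field-theory
    threshold with smoothness estimated from the residuals.
    """
    if method not in ("permutation", "rft"):
        raise AgreementError(f"unknown method {method!r}")
    data = panel.data
    f_main, f_inter, df = _rm_anova_f(data)
    d_main, d_inter = _contrasts(data)

    warnings_: list[str] = []
    normality_p = float(
        min(
            stats.normaltest(d_main, axis=0).pvalue.min(),
            stats.normaltest(d_inter, axis=0).pvalue.min(),
        )
    )
    logger.debug("minimum per-node normality p-value: %.4g", normality_p)

    if method == "permutation":
        if n_permutations < 100:
            warnings_.append(
                f"only {n_permutations} permutations; threshold estimate is coarse"
            )
        if seed is None:
            raise AgreementError("a permutation seed is required for reproducibility")
        rng = np.random.default_rng(seed)
        thresholds, pvals = [], []
        for d, f_obs in ((d_main, f_main), (d_inter, f_inter)):
            max_dist = _perm_max_distribution(d, n_permutations, rng)
            thresholds.append(float(np.quantile(max_dist, 1.0 - alpha, method="higher")))
            pvals.append(float(np.mean(max_dist >= f_obs.max())))
        thr_main, thr_inter = thresholds
        p_main, p_inter = pvals
    else:
        n = panel.n_participants
        thr, pv = [], []
        for d, f_obs in ((d_main, f_main), (d_inter, f_inter)):
            resid = d - d.mean(axis=0)
            fwhm = _estimate_fwhm(resid)
            resels = (panel.n_points - 1) / fwhm
            u = _rft_threshold(alpha, (1, n - 1), resels)
            thr.append(u)
            pv.append(float(min(1.0, stats.f.sf(f_obs.max(), 1, n - 1) * (1 + resels))))
        thr_main, thr_inter = thr
        p_main, p_inter = pv

    grid = np.linspace(0.0, 100.0, panel.n_points)
    return SPMResult(
        F_main=f_main,
        F_interaction=f_inter,
        threshold_main=thr_main,
        threshold_interaction=thr_inter,
        clusters_main=_clusters(f_main, thr_main, grid),
        clusters_interaction=_clusters(f_inter, thr_inter, grid),
        p_main=p_main,
        p_interaction=p_inter,
        alpha=alpha,
        method=method,
        df=df,
        n_permutations=n_permutations if method == "permutation" else None,
        seed=seed,
        warnings=warnings_,
        normality_min_p=normality_p,
    )
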