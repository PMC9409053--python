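"""Clonogenic survival analysis: surviving fractions, linear and
linear-quadratic fits, iso-effect doses and RBE.

Survival follows SF(D) = exp(−αD − βD²); the linear model is the β = 0
special case used for high-LET (alpha) exposures.  Fitting is done as
(weighted) least squares of −ln SF on (D, D²) through the origin with
α, β ≥ 0 enforced (radiobiological convention).  When colony counts are
available, weights are the inverse binomial variances of −ln SF,
var ≈ (1 − c/n)/c for c colonies of n seeded cells; otherwise the fit is
unweighted.

A dose cutoff may exclude the high-dose tail before fitting (used for
alpha-emitter data whose high-dose points are distorted by heterogeneous
cellular uptake); excluded and zero-SF points are counted in the fit's
bookkeeping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientDataError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColonyAssayRecord:
    activity_bq: float
    dose_gy: float
    colonies: int
    cells_seeded: int = 1000
    replicate: str = "r1"

    def __post_init__(self):
        if self.cells_seeded <= 0:
            raise DomainError("cells_seeded must be positive")
        if not 0 <= self.colonies <= self.cells_seeded:
            raise DomainError("colonies must lie in [0, cells_seeded]")
        if self.activity_bq < 0 or self.dose_gy < 0:
            raise DomainError("activity and dose must be non-negative")


@dataclass(frozen=True)
class SurvivalFit:
    model: str  # "linear" or "linear_quadratic"
    alpha: float  # 1/Gy
    beta: float  # 1/Gy²; exactly 0 for the linear model
    covariance: np.ndarray  # 2×2 (beta row/col zero for linear)
    dose_cutoff_gy: float | None
    n_points_used: int
    n_points_excluded: int = 0


@dataclass(frozen=True)
class RBEResult:
    level: float
    dose_ref_gy: float
    dose_test_gy: float
    rbe: float
    ci95: tuple[float, float] | None = None


def surviving_fraction(record: ColonyAssayRecord, plating_efficiency: float) -> float:
    """SF = (colonies / seeded) / plating efficiency.

    Values above 1 are possible under sampling noise and are logged, as are
    zero-colony wells (SF = 0 needs special handling in log-domain fits).
    """
    if plating_efficiency <= 0:
        raise DomainError("plating efficiency must be positive")
    sf = (record.colonies / record.cells_seeded) / plating_efficiency
    if sf > 1.0:
        log.warning("surviving fraction %.3f > 1 (sampling noise?) at dose %.3g Gy",
                    sf, record.dose_gy)
    if sf == 0.0:
        log.warning("zero colonies at dose %.3g Gy; SF = 0 excluded from log-domain fits",
                    record.dose_gy)
    return sf


def plating_efficiency(control_records) -> float:
    """Pooled colonies/seeded over untreated control wells."""
    recs = list(control_records)
    if not recs:
        raise InsufficientDataError("no control records")
    seeded = sum(r.cells_seeded for r in recs)
    colonies = sum(r.colonies for r in recs)
    if colonies == 0:
        raise DomainError("control wells produced no colonies; plating efficiency is zero")
    return colonies / seeded


def fit_survival(
    data,
    model: str = "linear_quadratic",
    dose_cutoff_gy: float | None = None,
    counts=None,
) -> SurvivalFit:
    """Fit SF = exp(−αD − βD²) to (dose, SF) pairs.

    ``counts`` may give (colonies, cells_seeded) per point to enable inverse-
    variance weighting.  Points above the cutoff or with SF ≤ 0 are dropped
    (and counted); the fit needs ≥ 2 (linear) or ≥ 3 (LQ) retained points.
    """
    if model not in ("linear", "linear_quadratic"):
        raise DomainError(f"unknown survival model {model!r}")
    pairs = [(float(d), float(sf)) for d, sf in data]
    n_total = len(pairs)
    keep = []
    w = []
    for i, (d, sf) in enumerate(pairs):
        if dose_cutoff_gy is not None and d > dose_cutoff_gy:
            continue
        if sf <= 0.0:
            log.warning("dropping non-positive SF point at dose %.3g Gy", d)
            continue
        keep.append((d, sf))
        if counts is not None:
            c, n = counts[i]
            # inverse of var(-ln SF) ≈ (1 - c/n)/c; continuity-guarded at c = n
            w.append(c / max(1.0 - c / n, 0.5 / n) if c > 0 else 0.0)
        else:
            w.append(1.0)
    n_min = 2 if model == "linear" else 3
    if len(keep) < n_min:
        raise InsufficientDataError(
            f"{model} fit needs >= {n_min} retained points with SF > 0, got {len(keep)}"
        )
    d = np.array([p[0] for p in keep])
    y = -np.log([p[1] for p in keep])
    wt = np.array(w)
    if model == "linear":
        X = d[:, None]
    else:
        X = np.column_stack([d, d * d])
    sw = np.sqrt(wt)
    Xw = X * sw[:, None]
    yw = y * sw
    from scipy.optimize import nnls

    coef, _ = nnls(Xw, yw)
    # covariance from the unconstrained normal equations (constraint rarely
    # binds away from the boundary); weights are inverse variances when
    # counts were given, else scaled by the residual variance
    xtx = Xw.T @ Xw
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        xtx_inv = np.full_like(xtx, np.nan)
    if counts is None:
        dof = max(1, len(keep) - X.shape[1])
        sigma2 = float(np.sum((yw - Xw @ coef) ** 2) / dof)
        cov_small = xtx_inv * sigma2
    else:
        cov_small = xtx_inv
    cov = np.zeros((2, 2))
    alpha = float(coef[0])
    beta = 0.0
    cov[0, 0] = cov_small[0, 0]
    if model == "linear_quadratic":
        beta = float(coef[1])
        cov[:2, :2] = cov_small
    return SurvivalFit(model=model, alpha=alpha, beta=beta, covariance=cov,
                       dose_cutoff_gy=dose_cutoff_gy, n_points_used=len(keep),
                       n_points_excluded=n_total - len(keep))


def dose_at_survival(fit: SurvivalFit, level: float) -> float:
    """Iso-effect dose: the D with SF(D) = level (e.g. D10 at level 0.10)."""
    if not 0.0 < level <= 1.0:
        raise DomainError("survival level must be in (0, 1]")
    if level == 1.0:
        return 0.0
    a, b = fit.alpha, fit.beta
    if a <= 0.0 and b <= 0.0:
        raise DomainError("alpha and beta are both zero; iso-effect dose undefined")
    ln_l = math.log(level)
    if b <= 0.0:
        return -ln_l / a
    # βD² + αD + ln(level) = 0, positive root
    return (-a + math.sqrt(a * a - 4.0 * b * ln_l)) / (2.0 * b)


def rbe_at_level(
    fit_ref: SurvivalFit,
    fit_test: SurvivalFit,
    level: float = 0.10,
    bootstrap: tuple | None = None,
) -> RBEResult:
    """RBE = (reference dose)/(test dose) at equal surviving fraction.

    ``bootstrap=(data_ref, data_test, n_reps, seed)`` resamples residuals of
    both −ln SF fits to attach a percentile 95% CI.
    """
    d_ref = dose_at_survival(fit_ref, level)
    d_test = dose_at_survival(fit_test, level)
    ci = None
    if bootstrap is not None:
        data_ref, data_test, n_reps, seed = bootstrap
        rng = np.random.default_rng(seed)
        vals = []
        for _ in range(n_reps):
            try:
                fr = _refit_resampled(fit_ref, data_ref, rng)
                ft = _refit_resampled(fit_test, data_test, rng)
                vals.append(dose_at_survival(fr, level) / dose_at_survival(ft, level))
            except (DomainError, InsufficientDataError):
                continue
        if vals:
            ci = tuple(np.percentile(vals, [2.5, 97.5]))
    return RBEResult(level=level, dose_ref_gy=d_ref, dose_test_gy=d_test,
                     rbe=d_ref / d_test, ci95=ci)


def _refit_resampled(fit: SurvivalFit, data, rng) -> SurvivalFit:
    pairs = [(float(d), float(sf)) for d, sf in data if sf > 0
             and (fit.dose_cutoff_gy is None or d <= fit.dose_cutoff_gy)]
    d = np.array([p[0] for p in pairs])
    y = -np.log([p[1] for p in pairs])
    pred = fit.alpha * d + fit.beta * d * d
    resid = y - pred
    y_new = pred + rng.choice(resid, size=len(resid), replace=True)
    sf_new = np.exp(-y_new)
    return fit_survival(list(zip(d, sf_new)), model=fit.model,
                        dose_cutoff_gy=fit.dose_cutoff_gy)
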