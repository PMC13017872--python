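"""Clonogenic-assay analysis: plating efficiency, surviving fraction,
linear-quadratic fitting and relative biological effectiveness.

The linear-quadratic (LQ) survival model is

    SF(D) = exp(-(alpha*D + beta*D^2))

fitted on the log scale, ``ln SF = -(alpha*D + beta*D^2)``, by weighted
linear least squares with the physical constraint ``beta >= 0``.  The
untreated control enters as a (0 Gy, SF = 1) point carrying the control's
propagated uncertainty, not as an exact constraint.  RBE at a survival
endpoint is the ratio of the reference-radiation isoeffect dose to the
test-radiation isoeffect dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ColonyRecord",
    "SurvivalPoint",
    "PlatingEfficiency",
    "LQFit",
    "plating_efficiency",
    "surviving_fraction",
    "survival_points_from_records",
    "fit_lq",
    "fit_lq_from_records",
    "dose_at_sf",
    "rbe",
    "read_colony_csv",
    "records_to_frame",
]

COLONY_CSV_COLUMNS = ["sample_id", "cell_line", "exposure_days", "dose_Gy",
                      "replicate", "cells_seeded", "colonies", "is_control"]


@dataclass(frozen=True)
class ColonyRecord:
    """One dish of a colony-formation assay."""

    sample_id: str
    dose_gy: float
    exposure_days: float
    cells_seeded: int
    colonies: int
    is_control: bool = False
    replicate: int = 0
    cell_line: str = ""

    def __post_init__(self) -> None:
        if self.cells_seeded < 0 or self.colonies < 0:
            raise ValueError("counts must be non-negative")
        if self.colonies > self.cells_seeded:
            raise ValueError(
                f"colonies ({self.colonies}) exceed seeded cells "
                f"({self.cells_seeded}) in {self.sample_id}")
        if self.dose_gy < 0:
            raise ValueError("dose must be non-negative")


@dataclass(frozen=True)
class PlatingEfficiency:
    """Condition-level plating efficiency: per-dish values, pooled mean
    and standard error of the mean (None with a single replicate)."""

    per_dish: tuple[float, ...]
    mean: float
    se: float | None


@dataclass(frozen=True)
class SurvivalPoint:
    dose_gy: float
    surviving_fraction: float
    se: float | None = None

    def __post_init__(self) -> None:
        if self.surviving_fraction < 0:
            raise ValueError("surviving fraction must be non-negative")
        if self.se is not None and self.se < 0:
            raise ValueError("standard error must be non-negative")


@dataclass(frozen=True)
class LQFit:
    """Fitted linear-quadratic parameters.

    ``beta_bound_active`` flags fits where the beta >= 0 constraint is
    binding (the unconstrained optimum had beta < 0), the situation
    reported for the LNCaP survival curves.
    """

    alpha: float          # Gy⁻¹
    beta: float           # Gy⁻²
    alpha_se: float       # Gy⁻¹
    beta_se: float        # Gy⁻²
    n_points: int
    beta_bound_active: bool = False
    weighted: bool = True

    def sf(self, dose_gy: float | np.ndarray) -> float | np.ndarray:
        """Predicted surviving fraction at a dose."""
        d = np.asarray(dose_gy, dtype=float)
        out = np.exp(-(self.alpha * d + self.beta * d ** 2))
        return float(out) if np.isscalar(dose_gy) else out

    def as_dict(self) -> dict:
        return {
            "alpha_per_Gy": self.alpha,
            "beta_per_Gy2": self.beta,
            "alpha_se": self.alpha_se,
            "beta_se": self.beta_se,
            "n_points": self.n_points,
            "beta_bound_active": self.beta_bound_active,
            "weighted": self.weighted,
        }


def plating_efficiency(records: Sequence[ColonyRecord]) -> PlatingEfficiency:
    """Plating efficiency of one condition: colonies / cells seeded per
    dish, pooled as mean over replicate dishes with SE = sample SD / sqrt(n).

    A single replicate yields ``se=None`` (undefined, not zero).
    """
    if not records:
        raise ValueError("no colony records supplied")
    per_dish = []
    for r in records:
        if r.cells_seeded == 0:
            raise ValueError(f"zero cells seeded in {r.sample_id}")
        per_dish.append(r.colonies / r.cells_seeded)
    n = len(per_dish)
    mean = float(np.mean(per_dish))
    se = float(np.std(per_dish, ddof=1) / math.sqrt(n)) if n > 1 else None
    return PlatingEfficiency(tuple(per_dish), mean, se)


def surviving_fraction(pe_treated: PlatingEfficiency,
                       pe_control: PlatingEfficiency,
                       dose_gy: float = 0.0) -> SurvivalPoint:
    """SF = PE_treated / PE_control, with the SE propagated in quadrature
    of the relative errors.  Each exposure arm must be normalised against
    its own control."""
    if pe_control.mean <= 0:
        raise ValueError("control plating efficiency must be positive")
    sf = pe_treated.mean / pe_control.mean
    se = None
    if pe_treated.se is not None and pe_control.se is not None and pe_treated.mean > 0:
        rel = math.hypot(pe_treated.se / pe_treated.mean,
                         pe_control.se / pe_control.mean)
        se = sf * rel
    return SurvivalPoint(dose_gy, sf, se)


def survival_points_from_records(
        records: Iterable[ColonyRecord],
        include_control_point: bool = True) -> list[SurvivalPoint]:
    """Group dishes by dose, normalise against the 0 Gy / control dishes
    of the same table, and return one survival point per dose.

    The control itself is included as (0 Gy, SF = 1) with its propagated
    relative SE unless ``include_control_point`` is false.
    """
    records = list(records)
    controls = [r for r in records if r.is_control or r.dose_gy == 0]
    if not controls:
        raise ValueError("no control (0 Gy) dishes found")
    pe_c = plating_efficiency(controls)
    points = []
    if include_control_point:
        se = None
        if pe_c.se is not None:
            se = math.sqrt(2.0) * pe_c.se / pe_c.mean  # SF=1 with both rel errors
        points.append(SurvivalPoint(0.0, 1.0, se))
    doses = sorted({r.dose_gy for r in records if r not in controls and r.dose_gy > 0})
    for d in doses:
        group = [r for r in records if r.dose_gy == d and not r.is_control]
        points.append(surviving_fraction(plating_efficiency(group), pe_c, d))
    return points


def fit_lq(points: Sequence[SurvivalPoint], weighted: bool = True) -> LQFit:
    """Fit ln SF = -(alpha*D + beta*D^2) by (weighted) least squares with
    beta constrained to be non-negative.

    Weights are 1/se(ln SF)^2 with se(ln SF) = se(SF)/SF (delta method)
    when every point carries an SE; otherwise the fit is unweighted.
    Parameter covariance follows the standard practice of scaling
    (X'WX)^-1 by the reduced chi-square, so the reported SEs reflect the
    observed scatter.  Points with SF >= 1 are retained (their log is
    non-positive).  When the beta bound binds, alpha is refitted on the
    linear-only model and beta is reported as 0 with the one-sided
    uncertainty of the unconstrained estimate.
    """
    pts = [p for p in points if p.surviving_fraction > 0]
    if len(pts) < 2:
        raise ValueError("need at least 2 points with SF > 0")
    d = np.array([p.dose_gy for p in pts])
    if np.all(d == 0):
        raise ValueError("all points at dose 0: nothing to fit")
    y = np.log([p.surviving_fraction for p in pts])
    ses = [p.se for p in pts]
    use_w = weighted and all(s is not None and s > 0 for s in ses)
    if use_w:
        sigma = np.array([s / p.surviving_fraction for s, p in zip(ses, pts)])
        w = 1.0 / sigma
    else:
        w = np.ones_like(y)

    X = np.column_stack([-d, -d ** 2])
    Xw = X * w[:, None]
    yw = y * w
    # Unconstrained solution decides whether the beta >= 0 bound binds
    # (active-set step: with a single bound, the constrained optimum is
    # either the unconstrained one or the linear-only refit) and provides
    # the beta uncertainty in either case.
    coef_u, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    bound_active = coef_u[1] < 0
    cov_scale_dof = max(len(pts) - 2, 1)
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    resid_u = yw - Xw @ coef_u
    s2_u = float(resid_u @ resid_u) / cov_scale_dof
    beta_se = float(np.sqrt(s2_u * xtx_inv[1, 1]))

    if bound_active:
        beta = 0.0
        x1 = Xw[:, [0]]
        a = float(np.linalg.lstsq(x1, yw, rcond=None)[0][0])
        alpha = a
        resid = yw - x1[:, 0] * a
        dof = max(len(pts) - 1, 1)
        s2 = float(resid @ resid) / dof
        alpha_se = float(np.sqrt(s2 / float(x1[:, 0] @ x1[:, 0])))
    else:
        alpha, beta = coef_u
        alpha_se = float(np.sqrt(s2_u * xtx_inv[0, 0]))

    return LQFit(alpha=float(alpha), beta=float(beta), alpha_se=alpha_se,
                 beta_se=beta_se, n_points=len(pts),
                 beta_bound_active=bool(bound_active), weighted=bool(use_w))


def fit_lq_from_records(records: Sequence[ColonyRecord]) -> LQFit:
    """Fit the LQ model directly from colony counts by generalised least
    squares on ln SF with binomial count variances.

    Counts are pooled over replicate dishes per condition, so
    var(ln PE) = (1-p)/(N p) by the delta method.  Because every
    surviving fraction shares the same control plating efficiency in the
    denominator, the errors of ln SF are correlated: their covariance is
    Sigma = diag(v_i) + v_control.  The GLS fit accounts for that shared
    term, which a diagonal-weight fit would ignore, badly understating
    the parameter uncertainties.  The beta >= 0 bound is enforced by an
    active-set step as in :func:`fit_lq`.
    """
    records = list(records)
    controls = [r for r in records if r.is_control or r.dose_gy == 0]
    if not controls:
        raise ValueError("no control (0 Gy) dishes found")
    n_c = sum(r.cells_seeded for r in controls)
    k_c = sum(r.colonies for r in controls)
    if k_c == 0:
        raise ValueError("control plating efficiency is zero")
    p_c = k_c / n_c
    v_c = (1.0 - p_c) / (n_c * p_c)

    doses, y, v = [], [], []
    for dose in sorted({r.dose_gy for r in records if r.dose_gy > 0}):
        group = [r for r in records if r.dose_gy == dose and not r.is_control]
        n = sum(r.cells_seeded for r in group)
        k = sum(r.colonies for r in group)
        if k == 0:
            continue  # SF = 0 has no log; non-fittable point
        p = k / n
        doses.append(dose)
        y.append(math.log(p / p_c))
        v.append((1.0 - p) / (n * p))
    if len(doses) < 2:
        raise ValueError("need at least 2 doses with surviving colonies")
    d = np.asarray(doses)
    y = np.asarray(y)
    sigma = np.diag(v) + v_c
    sigma_inv = np.linalg.inv(sigma)
    X = np.column_stack([-d, -d ** 2])

    def gls(design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cov = np.linalg.inv(design.T @ sigma_inv @ design)
        return cov @ design.T @ sigma_inv @ y, cov

    coef, cov = gls(X)
    beta_se = float(np.sqrt(cov[1, 1]))
    bound_active = coef[1] < 0
    if bound_active:
        a, cov1 = gls(X[:, [0]])
        return LQFit(alpha=float(a[0]), beta=0.0,
                     alpha_se=float(np.sqrt(cov1[0, 0])), beta_se=beta_se,
                     n_points=len(doses), beta_bound_active=True)
    return LQFit(alpha=float(coef[0]), beta=float(coef[1]),
                 alpha_se=float(np.sqrt(cov[0, 0])), beta_se=beta_se,
                 n_points=len(doses), beta_bound_active=False)


def dose_at_sf(fit: LQFit | tuple[float, float], sf: float) -> float:
    """Isoeffect dose: the positive root of beta*D^2 + alpha*D + ln(sf) = 0.

    With beta > 0 the quadratic has exactly one positive root (the product
    of the roots, ln(sf)/beta, is negative); with beta = 0 the closed form
    is -ln(sf)/alpha.
    """
    if not 0 < sf < 1:
        raise ValueError("survival endpoint must be in (0, 1)")
    alpha, beta = (fit.alpha, fit.beta) if isinstance(fit, LQFit) else fit
    if alpha <= 0 and beta <= 0:
        raise ValueError("need alpha > 0 or beta > 0 to reach the endpoint")
    c = math.log(sf)  # negative
    if beta == 0:
        return -c / alpha
    # numerically stable quadratic: with c < 0 the discriminant exceeds
    # alpha^2, q = -(alpha + sqrt(disc))/2 < 0, and the unique positive
    # root is c/q (the companion root q/beta is negative); this form is
    # exact in the beta -> 0 limit where the naive formula cancels
    disc = alpha * alpha - 4.0 * beta * c
    q = -0.5 * (alpha + math.sqrt(disc))
    root = c / q
    assert root > 0 and q / beta <= 0, \
        "LQ isoeffect must have a unique positive root"
    return root


def rbe(fit_test: LQFit | tuple[float, float],
        fit_reference: LQFit | tuple[float, float], sf: float = 0.1) -> float:
    """Relative biological effectiveness at a survival endpoint:
    D_reference / D_test for the same surviving fraction."""
    return dose_at_sf(fit_reference, sf) / dose_at_sf(fit_test, sf)


def read_colony_csv(path: str | Path) -> list[ColonyRecord]:
    """Read a colony-count table.

    Expected columns: sample_id, cell_line, exposure_days, dose_Gy,
    replicate, cells_seeded, colonies, is_control.  Schema violations are
    reported with the offending row number.
    """
    df = pd.read_csv(path)
    missing = set(COLONY_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"colony CSV missing columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(ColonyRecord(
                sample_id=str(row["sample_id"]),
                cell_line=str(row["cell_line"]),
                exposure_days=float(row["exposure_days"]),
                dose_gy=float(row["dose_Gy"]),
                replicate=int(row["replicate"]),
                cells_seeded=int(row["cells_seeded"]),
                colonies=int(row["colonies"]),
                is_control=bool(row["is_control"]),
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {i + 2} of {path}: {exc}") from exc
    return records


def records_to_frame(records: Iterable[ColonyRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": r.sample_id,
        "cell_line": r.cell_line,
        "exposure_days": r.exposure_days,
        "dose_Gy": r.dose_gy,
        "replicate": r.replicate,
        "cells_seeded": r.cells_seeded,
        "colonies": r.colonies,
        "is_control": r.is_control,
    } for r in records], columns=COLONY_CSV_COLUMNS)
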