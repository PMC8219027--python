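"""Dose-response analysis: normalization, 4PL fitting, combination tables.

Covers the cell-based readouts around a DNA-repair inhibitor: percent
inhibition of damage-induced foci relative to vehicle control, fold change
in foci counts, four-parameter logistic (4PL) fits of IC50/GI50 on
log10 dose, and fixed-dose combination summaries (e.g. drug titrations at
several ionizing-radiation doses), where each arm gets its own midpoint and
a fold-shift relative to a reference arm.

The 4PL model on dose x (molar) is

    y(x) = lower + (upper - lower) / (1 + 10**(hill * (log10(mid) - log10(x))))

so ``upper`` is the high-dose plateau, ``lower`` the low-dose plateau and
``mid`` the midpoint (IC50/GI50). Responses are percentages of control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "FourPLParameters",
    "FourPLFit",
    "DoseResponseCurve",
    "four_pl",
    "percent_inhibition",
    "fold_change",
    "fit_4pl",
    "combination_table",
]


@dataclass(frozen=True)
class FourPLParameters:
    """4PL parameters: plateaus (response units), midpoint (molar), slope."""

    lower: float
    upper: float
    midpoint: float
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.midpoint <= 0:
            raise ValueError("midpoint must be > 0")
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("plateaus must be finite")


@dataclass
class FourPLFit:
    """A fitted 4PL curve with midpoint standard error and diagnostics."""

    params: FourPLParameters
    midpoint_se: float
    residual_sd: float
    converged: bool
    extrapolated: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class DoseResponseCurve:
    """Responses (% of control) on a dose grid, one row per replicate."""

    doses: np.ndarray
    responses: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if np.any(self.doses <= 0):
            raise ValueError("doses must be > 0")
        if self.responses.shape[1] != self.doses.size:
            raise ValueError("each replicate needs one response per dose")

    @property
    def n_replicates(self) -> int:
        return self.responses.shape[0]

    def mean_response(self) -> np.ndarray:
        return self.responses.mean(axis=0)


def four_pl(x, p: FourPLParameters):
    """Evaluate the four-parameter logistic at doses ``x`` (molar)."""
    x = np.asarray(x, dtype=float)
    logx = np.log10(x)
    out = p.lower + (p.upper - p.lower) / (
        1.0 + 10.0 ** (p.hill * (np.log10(p.midpoint) - logx))
    )
    return out if out.ndim else float(out)


def percent_inhibition(treated, control):
    """100 * (1 - treated/control); 0% when treated equals control."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if np.any(control <= 0):
        raise ValueError("control must be > 0")
    out = 100.0 * (1.0 - treated / control)
    return out if out.ndim else float(out)


def fold_change(treated_count, control_count):
    """Ratio of treated to control; 1 means no change."""
    treated_count = np.asarray(treated_count, dtype=float)
    control_count = np.asarray(control_count, dtype=float)
    if np.any(control_count <= 0):
        raise ValueError("control count must be > 0")
    out = treated_count / control_count
    return out if out.ndim else float(out)


def fit_4pl(
    curve: DoseResponseCurve,
    plateau_bounds: tuple[float, float] = (-10.0, 110.0),
    hill_bounds: tuple[float, float] = (0.2, 5.0),
    pool_replicates: bool = True,
) -> FourPLFit:
    """Least-squares 4PL fit on log10 dose.

    Replicates are fitted as pooled points by default (pass
    ``pool_replicates=False`` to fit the pointwise mean curve instead). The
    monotone direction is auto-detected from the dose-extreme responses and
    encoded in the plateau ordering; the hill slope stays positive. The
    plateau and slope bounds stabilize sparse 8-10 point curves. A midpoint
    outside the measured dose range is flagged ``extrapolated``.
    """
    if curve.doses.size < 5:
        raise ValueError("need >= 5 doses spanning the transition")
    if pool_replicates:
        x = np.tile(curve.doses, curve.n_replicates)
        y = curve.responses.ravel()
    else:
        x = curve.doses
        y = curve.mean_response()

    order = np.argsort(curve.doses)
    mean_curve = curve.mean_response()
    lo0, hi0 = mean_curve[order[0]], mean_curve[order[-1]]
    lo, hi = plateau_bounds
    mid_level = 0.5 * (lo0 + hi0)
    mid0 = curve.doses[order][
        np.argmin(np.abs(mean_curve[order] - mid_level))
    ]

    params = lmfit.Parameters()
    params.add("lower", value=np.clip(lo0, lo, hi), min=lo, max=hi)
    params.add("upper", value=np.clip(hi0, lo, hi), min=lo, max=hi)
    params.add(
        "log_mid",
        value=float(np.log10(mid0)),
        min=np.log10(curve.doses.min()) - 3.0,
        max=np.log10(curve.doses.max()) + 3.0,
    )
    params.add("hill", value=1.0, min=hill_bounds[0], max=hill_bounds[1])

    def residual(p):
        model = four_pl(
            x,
            FourPLParameters(
                lower=p["lower"].value,
                upper=p["upper"].value,
                midpoint=10.0 ** p["log_mid"].value,
                hill=p["hill"].value,
            ),
        )
        return model - y

    result = lmfit.minimize(residual, params, method="leastsq")
    mid = 10.0 ** result.params["log_mid"].value
    log_se = result.params["log_mid"].stderr
    mid_se = mid * np.log(10.0) * log_se if log_se is not None else np.nan
    fitted = FourPLParameters(
        lower=float(result.params["lower"].value),
        upper=float(result.params["upper"].value),
        midpoint=float(mid),
        hill=float(result.params["hill"].value),
    )
    flags: list[str] = []
    extrapolated = not (curve.doses.min() <= mid <= curve.doses.max())
    if extrapolated:
        flags.append("extrapolated_midpoint")
    if not result.success:
        flags.append("non_convergence")
    resid_sd = float(np.std(result.residual, ddof=min(4, y.size - 1)))
    # a transition must beat the noise and be non-negligible on the % scale
    if abs(fitted.upper - fitted.lower) < max(3.0 * resid_sd, 5.0):
        flags.append("flat_no_transition")
    return FourPLFit(
        params=fitted,
        midpoint_se=float(mid_se) if mid_se is not None else np.nan,
        residual_sd=resid_sd,
        converged=bool(result.success),
        extrapolated=extrapolated,
        flags=flags,
    )


def combination_table(
    arms: list[DoseResponseCurve], reference: str | None = None
) -> pd.DataFrame:
    """Per-arm 4PL midpoints and fold-shifts for a fixed-dose combination.

    All arms must share the dose grid. The reference arm (by label; default
    the first arm, conventionally the vehicle / 0-Gy arm) defines the shift
    baseline: ``fold_shift = midpoint_reference / midpoint_arm``, so values
    above 1 mean the combination sensitizes (midpoint moved lower). Arms
    whose fit is flat or fails are flagged and excluded from the shift
    column (NaN).
    """
    if len(arms) < 2:
        raise ValueError("need at least two arms")
    grid = arms[0].doses
    for arm in arms[1:]:
        if arm.doses.shape != grid.shape or not np.allclose(arm.doses, grid):
            raise ValueError("arms must share a dose grid")
    labels = [arm.label or f"arm{i}" for i, arm in enumerate(arms)]
    if reference is None:
        reference = labels[0]
    if reference not in labels:
        raise ValueError(f"reference arm {reference!r} not found")

    rows = []
    fits: dict[str, FourPLFit] = {}
    for label, arm in zip(labels, arms):
        fit = fit_4pl(arm)
        fits[label] = fit
        usable = fit.converged and "flat_no_transition" not in fit.flags
        rows.append(
            {
                "arm": label,
                "midpoint_M": fit.params.midpoint if usable else np.nan,
                "midpoint_se_M": fit.midpoint_se if usable else np.nan,
                "hill": fit.params.hill,
                "flags": ";".join(fit.flags),
                "usable": usable,
            }
        )
    table = pd.DataFrame(rows).set_index("arm")
    ref_mid = table.loc[reference, "midpoint_M"]
    if not np.isfinite(ref_mid):
        raise ValueError(f"reference arm {reference!r} has no usable fit")
    table["fold_shift"] = ref_mid / table["midpoint_M"]
    return table
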