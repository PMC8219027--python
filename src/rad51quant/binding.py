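"""Equilibrium binding models for fluorescence-polarization competition and ITC.

This module implements the closed-form mass-action models used to turn raw
binding data into dissociation constants:

* the two-state (protein + probe) quadratic equilibrium,
* the exact ternary (protein + probe + competitor) equilibrium, obtained as
  the physical root of the cubic in free protein,
* an affine polarization signal model,
* the 1:1 single-site isotherm for titration calorimetry with
  displacement-volume dilution bookkeeping,

together with the nonlinear least-squares fitters that estimate pKd
(-log10 Kd) from competition isotherms and (Kd, dH, n) from injection heats.

Concentrations are molar throughout; ITC volumes are litres and enthalpies
J/mol. Fits are parameterized on the pKd / log10(Kd) scale so that the
reported uncertainties are symmetric in log space, which is also the scale
on which replicate affinities are averaged (geometric mean of Kd).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import lmfit
import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AssayConstants",
    "CompetitionIsotherm",
    "BindingFit",
    "PkdSummary",
    "ITCParameters",
    "InjectionSchedule",
    "ITCFit",
    "direct_bound",
    "wang_competitive_bound",
    "fp_signal",
    "average_isotherms",
    "fit_competition_isotherm",
    "pkd_statistics",
    "itc_heats",
    "fit_itc",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayConstants:
    """Fixed constants of a competition FP assay.

    Defaults are the assay conditions used for RAD51:BRC4 competition:
    50 nM protein, 10 nM labelled BRC4 probe, probe Kd 4 nM (the
    FP-measured value; the ITC estimate for the same interaction is 6 nM).
    """

    protein_total: float = 50e-9
    probe_total: float = 10e-9
    probe_kd: float = 4e-9

    def __post_init__(self) -> None:
        for name in ("protein_total", "probe_total", "probe_kd"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"AssayConstants.{name} must be > 0")


@dataclass
class CompetitionIsotherm:
    """A competitor titration: polarization readings on a concentration grid.

    ``signals`` has shape (n_replicates, n_concentrations); replicate rows
    share the concentration grid.
    """

    concentrations: np.ndarray
    signals: np.ndarray
    assay: AssayConstants = field(default_factory=AssayConstants)
    n_averaged: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.concentrations.ndim != 1 or self.concentrations.size == 0:
            raise ValueError("concentrations must be a non-empty 1-D array")
        if np.any(self.concentrations <= 0):
            raise ValueError("competitor concentrations must be strictly positive")
        if self.signals.shape[1] != self.concentrations.size:
            raise ValueError(
                "each replicate must have one reading per concentration "
                f"(got {self.signals.shape[1]} readings for "
                f"{self.concentrations.size} concentrations)"
            )

    @property
    def n_replicates(self) -> int:
        return self.signals.shape[0]

    def mean_signal(self) -> np.ndarray:
        return self.signals.mean(axis=0)


@dataclass
class BindingFit:
    """Result of a competition-isotherm fit.

    ``pkd`` is -log10 of the competitor dissociation constant; ``pkd_sd`` is
    its standard error from the fit covariance, on the same scale.
    """

    pkd: float
    pkd_sd: float
    plateau_bound: float
    plateau_free: float
    residual_sd: float
    n_points: int
    n_isotherms: int = 1
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def kd(self) -> float:
        return 10.0 ** (-self.pkd)


@dataclass(frozen=True)
class PkdSummary:
    """Replicate summary on the pKd scale (geometric statistics of Kd)."""

    kd_geomean: float
    pkd_mean: float
    pkd_sd: float
    n: int


@dataclass(frozen=True)
class InjectionSchedule:
    """Injection volumes (litres) in the order they are delivered.

    ``numbers``, when given, are the recorded injection indices and must be
    strictly increasing — integrated heats only make sense in delivery order.
    """

    volumes_l: tuple
    numbers: tuple | None = None

    def __post_init__(self) -> None:
        vols = tuple(float(v) for v in self.volumes_l)
        object.__setattr__(self, "volumes_l", vols)
        if len(vols) == 0:
            raise ValueError("schedule must contain at least one injection")
        if any(v <= 0 for v in vols):
            raise ValueError("injection volumes must be positive")
        if self.numbers is not None:
            nums = tuple(int(n) for n in self.numbers)
            object.__setattr__(self, "numbers", nums)
            if len(nums) != len(vols):
                raise ValueError("numbers must match volumes in length")
            if any(b <= a for a, b in zip(nums, nums[1:])):
                raise ValueError(
                    "injection numbers must be strictly increasing "
                    "(injections out of delivery order)"
                )

    def __len__(self) -> int:
        return len(self.volumes_l)


@dataclass(frozen=True)
class ITCParameters:
    """Single-site titration model: thermodynamics plus cell geometry.

    kd: molar; delta_h: J/mol of complex formed; n: binding stoichiometry
    (sites per cell-species molecule); cell/syringe concentrations molar;
    cell volume litres.
    """

    kd: float
    delta_h: float
    n: float = 1.0
    cell_conc: float = 20e-6
    syringe_conc: float = 200e-6
    cell_volume_l: float = 200e-6

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        if self.n <= 0:
            raise ValueError("stoichiometry n must be > 0")
        for name in ("cell_conc", "syringe_conc", "cell_volume_l"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ITCFit:
    """Fitted single-site parameters with their standard errors."""

    params: ITCParameters
    stderr: dict
    converged: bool
    residual_sd: float
    n_fixed: bool = False


# ---------------------------------------------------------------------------
# closed-form equilibria
# ---------------------------------------------------------------------------

def direct_bound(P_t, L_t, K_L):
    """Bound-complex concentration for a two-state P + L <-> PL equilibrium.

    Returns the physical root of the mass-action quadratic,
    0 <= [PL] <= min(P_t, L_t). All arguments molar and > 0; broadcasts.
    """
    P_t = np.asarray(P_t, dtype=float)
    L_t = np.asarray(L_t, dtype=float)
    K_L = np.asarray(K_L, dtype=float)
    if np.any(P_t <= 0) or np.any(L_t <= 0) or np.any(K_L <= 0):
        raise ValueError("P_t, L_t and K_L must all be > 0")
    s = P_t + L_t + K_L
    # the smaller quadratic root is the physical one
    disc = np.sqrt(s * s - 4.0 * P_t * L_t)
    out = 0.5 * (s - disc)
    return out if out.ndim else float(out)


def _free_protein_newton(P0, A0, B0, KA, KB):
    """Free-protein concentration from the ternary-equilibrium cubic.

    Trigonometric closed form with Newton polishing; vectorized over B0.
    """
    a = KA + KB + A0 + B0 - P0
    b = KB * (A0 - P0) + KA * (B0 - P0) + KA * KB
    c = -KA * KB * P0
    p = a * a - 3.0 * b
    p = np.maximum(p, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = (-2.0 * a ** 3 + 9.0 * a * b - 27.0 * c) / (2.0 * np.sqrt(p ** 3))
    theta = np.arccos(np.clip(arg, -1.0, 1.0))
    P = (2.0 * np.sqrt(p) * np.cos(theta / 3.0) - a) / 3.0
    P = np.clip(P, 0.0, P0)
    # polish the root: the trig form loses precision at extreme ratios
    for _ in range(4):
        f = ((P + a) * P + b) * P + c
        fp = (3.0 * P + 2.0 * a) * P + b
        step = np.where(fp != 0.0, f / np.where(fp != 0.0, fp, 1.0), 0.0)
        P = np.clip(P - step, 0.0, P0)
    return P


def _mass_balance_residual(P, P0, A0, B0, KA, KB):
    return P + P * A0 / (KA + P) + P * B0 / (KB + P) - P0


def wang_competitive_bound(assay: AssayConstants, I_t, K_I):
    """Probe-bound fraction in the exact ternary competition equilibrium.

    Protein P is shared between a probe (totals and Kd from ``assay``) and a
    competitor at total concentration ``I_t`` with dissociation constant
    ``K_I``. The free-protein concentration is the unique physical root of
    the mass-action cubic; the bound probe fraction is [P]/(K_L + [P]).

    A bracketed numerical root replaces the closed form wherever the
    polished cubic root fails its own mass-balance residual check (the trig
    form is ill-conditioned at extreme concentration ratios).

    Returns values in [0, 1], non-increasing in ``I_t``; at I_t = 0 this
    equals ``direct_bound(...)/probe_total``. ``K_I = inf`` (inert
    competitor) is allowed.
    """
    I_t = np.asarray(I_t, dtype=float)
    scalar = I_t.ndim == 0
    I_t = np.atleast_1d(I_t)
    if np.any(I_t < 0):
        raise ValueError("competitor concentrations must be >= 0")
    if not K_I > 0:
        raise ValueError("K_I must be > 0")

    P0, A0, KA = assay.protein_total, assay.probe_total, assay.probe_kd
    if np.isinf(K_I):
        f0 = direct_bound(P0, A0, KA) / A0
        out = np.full_like(I_t, f0)
        return float(out[0]) if scalar else out

    P = _free_protein_newton(P0, A0, I_t, KA, K_I)
    resid = np.abs(_mass_balance_residual(P, P0, A0, I_t, KA, K_I)) / P0
    bad = ~(resid < 1e-9)
    for i in np.nonzero(bad)[0]:
        P[i] = brentq(
            _mass_balance_residual,
            0.0,
            P0,
            args=(P0, A0, I_t[i], KA, K_I),
            xtol=1e-30,
            rtol=8.9e-16,
        )
    frac = P / (KA + P)
    frac = np.clip(frac, 0.0, 1.0)
    return float(frac[0]) if scalar else frac


def fp_signal(bound_fraction, plateau_bound, plateau_free):
    """Affine map from bound fraction to polarization signal.

    Equals ``plateau_free`` at fraction 0 and ``plateau_bound`` at 1. The
    model is agnostic to whether readings are polarization or anisotropy
    units; both are affine in the bound fraction for a small probe.
    """
    f = np.asarray(bound_fraction, dtype=float)
    if np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
        raise ValueError("bound_fraction must lie in [0, 1]")
    out = plateau_free + (plateau_bound - plateau_free) * f
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# FP isotherm fitting
# ---------------------------------------------------------------------------

def average_isotherms(
    isotherms: CompetitionIsotherm | Sequence[CompetitionIsotherm],
) -> CompetitionIsotherm:
    """Pointwise mean curve over replicates (and over a list of isotherms).

    All inputs must share the concentration grid. The number of curves
    averaged is accumulated in ``n_averaged``.
    """
    if isinstance(isotherms, CompetitionIsotherm):
        isotherms = [isotherms]
    if len(isotherms) == 0:
        raise ValueError("no isotherms to average")
    grid = isotherms[0].concentrations
    for iso in isotherms[1:]:
        if iso.concentrations.shape != grid.shape or not np.allclose(
            iso.concentrations, grid
        ):
            raise ValueError("isotherms do not share a concentration grid")
    rows = np.vstack([iso.signals for iso in isotherms])
    n_avg = sum(iso.n_averaged * iso.n_replicates for iso in isotherms)
    return CompetitionIsotherm(
        concentrations=grid.copy(),
        signals=rows.mean(axis=0, keepdims=True),
        assay=isotherms[0].assay,
        n_averaged=n_avg,
        label=isotherms[0].label,
    )


def fit_competition_isotherm(
    iso: CompetitionIsotherm,
    pkd_bounds: tuple[float, float] = (0.0, 14.0),
) -> BindingFit:
    """Estimate competitor pKd from a competition isotherm.

    Nonlinear least squares over (pKd, plateau_bound, plateau_free) with the
    probe Kd fixed at its independently measured value (``iso.assay``).
    Replicate rows are fitted as pooled points. The pKd standard deviation
    comes from the fit covariance. A curve with no resolvable transition
    (amplitude indistinguishable from noise, or an unbounded pKd error) is
    flagged rather than silently reported.
    """
    if iso.concentrations.size < 5:
        raise ValueError("need >= 5 concentration points spanning the transition")
    conc = np.tile(iso.concentrations, iso.n_replicates)
    y = iso.signals.ravel()

    mean_curve = iso.mean_signal()
    order = np.argsort(iso.concentrations)
    y_lo, y_hi = mean_curve[order[0]], mean_curve[order[-1]]
    span = float(np.ptp(y)) or 1.0
    # curve falls from the bound plateau (low competitor) to the free plateau
    mid_level = 0.5 * (y_lo + y_hi)
    xs = iso.concentrations[order]
    ys = mean_curve[order]
    crossing = xs[np.argmin(np.abs(ys - mid_level))]
    pkd0 = float(np.clip(-np.log10(crossing), *pkd_bounds))

    params = lmfit.Parameters()
    params.add("pkd", value=pkd0, min=pkd_bounds[0], max=pkd_bounds[1])
    params.add("plateau_bound", value=y_lo, min=y.min() - span, max=y.max() + span)
    params.add("plateau_free", value=y_hi, min=y.min() - span, max=y.max() + span)

    def residual(p):
        frac = wang_competitive_bound(iso.assay, conc, 10.0 ** (-p["pkd"].value))
        model = fp_signal(frac, p["plateau_bound"].value, p["plateau_free"].value)
        return model - y

    result = lmfit.minimize(residual, params, method="leastsq")
    pk = result.params["pkd"]
    pb = result.params["plateau_bound"].value
    pf = result.params["plateau_free"].value
    resid_sd = float(np.std(result.residual, ddof=min(3, y.size - 1)))

    flags: list[str] = []
    pkd_sd = pk.stderr if pk.stderr is not None else np.inf
    if not result.success:
        flags.append("non_convergence")
    if abs(pb - pf) < 3.0 * resid_sd or not np.isfinite(pkd_sd):
        flags.append("no_transition_unbounded_pkd")
    return BindingFit(
        pkd=float(pk.value),
        pkd_sd=float(pkd_sd),
        plateau_bound=float(pb),
        plateau_free=float(pf),
        residual_sd=resid_sd,
        n_points=int(y.size),
        n_isotherms=iso.n_averaged,
        converged=bool(result.success) and not flags,
        flags=flags,
    )


def pkd_statistics(fits: Iterable[BindingFit | float]) -> PkdSummary:
    """Replicate summary: mean and SD on the pKd scale, geometric-mean Kd.

    Averaging pKd values and exponentiating the mean gives the geometric
    mean of the dissociation constants; the SD is reported in log10 units.
    """
    pkds = np.array(
        [f.pkd if isinstance(f, BindingFit) else float(f) for f in fits], dtype=float
    )
    if pkds.size == 0:
        raise ValueError("need at least one fit")
    mean = float(pkds.mean())
    sd = float(pkds.std(ddof=1)) if pkds.size > 1 else 0.0
    return PkdSummary(
        kd_geomean=10.0 ** (-mean), pkd_mean=mean, pkd_sd=sd, n=int(pkds.size)
    )


# ---------------------------------------------------------------------------
# ITC single-site model
# ---------------------------------------------------------------------------

def _bound_single_site(sites, ligand, kd):
    s = sites + ligand + kd
    return 0.5 * (s - np.sqrt(s * s - 4.0 * sites * ligand))


def itc_heats(params: ITCParameters, schedule: InjectionSchedule) -> np.ndarray:
    """Integrated heat (J) per injection for a 1:1 single-site titration.

    Each injection displaces an equal volume of cell contents before mixing
    (constant-volume perfusion cell): concentrations of both species are
    diluted by (1 - v/V0), the syringe species is topped up by c_syr*v/V0,
    and the heat is dH * V0 * (new bound - surviving previous bound).
    """
    V0 = params.cell_volume_l
    M = params.cell_conc
    X = 0.0
    B_prev = 0.0
    heats = np.empty(len(schedule))
    for i, v in enumerate(schedule.volumes_l):
        d = 1.0 - v / V0
        if d <= 0:
            raise ValueError("injection volume exceeds cell volume")
        M *= d
        X = X * d + params.syringe_conc * v / V0
        B = _bound_single_site(params.n * M, X, params.kd)
        heats[i] = params.delta_h * V0 * (B - B_prev * d)
        B_prev = B
    return heats


def fit_itc(
    heats,
    schedule: InjectionSchedule,
    cell_conc: float,
    syringe_conc: float,
    cell_volume_l: float,
    fix_n: float | None = None,
) -> ITCFit:
    """Least-squares fit of the single-site model to integrated heats.

    Fits (log10 Kd, dH, n); pass ``fix_n`` to hold the stoichiometry (the
    usual choice for weak binders, where n and dH are poorly separable).
    Needs >= 8 injections. Non-convergence is reported on the returned fit,
    never silently ignored.
    """
    heats = np.asarray(heats, dtype=float)
    if len(schedule) < 8:
        raise ValueError("need >= 8 injections to fit the single-site model")
    if heats.size != len(schedule):
        raise ValueError("one integrated heat per injection required")

    moles_cell = cell_conc * cell_volume_l
    dh0 = float(heats.sum() / moles_cell)
    if dh0 == 0.0:
        dh0 = 1.0

    params = lmfit.Parameters()
    params.add("log10_kd", value=np.log10(cell_conc / 10.0), min=-13.0, max=-1.0)
    params.add("delta_h", value=dh0)
    if fix_n is None:
        params.add("n", value=1.0, min=0.05, max=10.0)
    else:
        params.add("n", value=float(fix_n), vary=False)

    def residual(p):
        model = itc_heats(
            ITCParameters(
                kd=10.0 ** p["log10_kd"].value,
                delta_h=p["delta_h"].value,
                n=p["n"].value,
                cell_conc=cell_conc,
                syringe_conc=syringe_conc,
                cell_volume_l=cell_volume_l,
            ),
            schedule,
        )
        return model - heats

    result = lmfit.minimize(residual, params, method="leastsq")
    fitted = ITCParameters(
        kd=10.0 ** result.params["log10_kd"].value,
        delta_h=float(result.params["delta_h"].value),
        n=float(result.params["n"].value),
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        cell_volume_l=cell_volume_l,
    )
    stderr = {
        name: (par.stderr if par.stderr is not None else np.nan)
        for name, par in result.params.items()
    }
    return ITCFit(
        params=fitted,
        stderr=stderr,
        converged=bool(result.success),
        residual_sd=float(np.std(result.residual, ddof=1)) if heats.size > 1 else 0.0,
        n_fixed=fix_n is not None,
    )
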