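"""Synthetic data generators emulating the pipeline's raw inputs.

Every generator is the exact forward model of the corresponding fitter, so
zero-noise round trips recover parameters to numerical tolerance:

* :func:`simulate_localizations` builds d-STORM-like localization tables —
  clusters of labelled molecules (discs or filaments), several
  localizations per molecule from antibody blinking, lognormal photon
  counts, truncated-Gaussian precisions, uniform background — together with
  the planted ground truth;
* :func:`simulate_fp_plate` maps the exact ternary competition equilibrium
  through the affine polarization signal model and adds Gaussian well
  noise;
* :func:`simulate_itc` evaluates the single-site injection heats and adds
  Gaussian noise;
* :func:`simulate_dose_response` samples a 4PL curve with Gaussian noise.

All randomness flows through ``numpy.random.default_rng(seed)``: identical
(spec, seed) pairs give byte-identical outputs.

Default field geometry is a 256 x 256 pixel field at 160 nm/pixel
(40,960 nm square). Default cluster statistics emulate damage-site RAD51
biology: about 5-10 molecules per cluster, filaments a few hundred nm long,
a photon median of 2,000 with a lognormal spread so a tunable fraction
falls under the 1,000-photon cut, and ~10 nm localization precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import binding as _binding
from . import doseresponse as _dr

__all__ = [
    "FieldGeometry",
    "ClusterSpec",
    "GroundTruth",
    "simulate_localizations",
    "simulate_fp_plate",
    "simulate_itc",
    "simulate_dose_response",
]


@dataclass(frozen=True)
class FieldGeometry:
    """Imaging field: 256 x 256 pixels at 160 nm per pixel by default."""

    width_nm: float = 256 * 160.0
    height_nm: float = 256 * 160.0
    pixel_size_nm: float = 160.0

    def __post_init__(self) -> None:
        if min(self.width_nm, self.height_nm, self.pixel_size_nm) <= 0:
            raise ValueError("field dimensions and pixel size must be > 0")

    @property
    def area_nm2(self) -> float:
        return self.width_nm * self.height_nm


@dataclass(frozen=True)
class ClusterSpec:
    """Ground-truth model for a synthetic localization field.

    molecules_per_cluster_range, when set (the default: the 5-10 molecule
    scale of damage-induced RAD51 nanoclusters), draws counts uniformly
    from the closed integer range and overrides mean/dispersion. With the
    range set to ``None``, molecules_per_cluster_dispersion selects the
    count distribution: 0 = exactly the (integer) mean, 1 = Poisson, > 1 =
    negative binomial with variance mean * dispersion.
    localizations_per_molecule_dispersion:
    0 = exactly the (integer) mean, otherwise geometric (support >= 1) with
    the given mean — blinking re-activation treated as memoryless. The
    antibody-labelling stoichiometry distribution is not characterized
    experimentally; the geometric choice is a configurable stand-in.

    Photon counts are lognormal with the given median and log-scale sigma;
    precisions are Gaussian truncated below at ``precision_min_nm``. Each
    localization is jittered around its molecule by its own drawn precision.
    Cluster centres keep ``min_separation_nm`` between each other and a
    margin from the field edge so the planted cluster count is unambiguous.
    """

    n_clusters: int = 10
    molecules_per_cluster_range: tuple | None = (5, 10)
    molecules_per_cluster_mean: float = 7.0
    molecules_per_cluster_dispersion: float = 1.0
    cluster_shape: str = "disc"  # "disc" | "filament"
    disc_radius_nm: float = 25.0
    filament_length_nm: float = 400.0
    filament_width_nm: float = 30.0
    localizations_per_molecule_mean: float = 15.0
    localizations_per_molecule_dispersion: float = 1.0
    background_density_per_nm2: float = 1e-6
    photon_median: float = 2000.0
    photon_sigma_log: float = 0.5
    precision_mean_nm: float = 10.0
    precision_sd_nm: float = 3.0
    precision_min_nm: float = 2.0
    min_separation_nm: float = 500.0

    def __post_init__(self) -> None:
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if self.molecules_per_cluster_range is not None:
            lo, hi = self.molecules_per_cluster_range
            if not (0 <= lo <= hi):
                raise ValueError("molecules_per_cluster_range must satisfy 0 <= lo <= hi")
        if self.cluster_shape not in ("disc", "filament"):
            raise ValueError("cluster_shape must be 'disc' or 'filament'")
        if self.filament_length_nm <= self.filament_width_nm:
            raise ValueError("filament_length_nm must exceed filament_width_nm")
        if self.localizations_per_molecule_mean < 1:
            raise ValueError("localizations per molecule mean must be >= 1")
        if self.background_density_per_nm2 < 0:
            raise ValueError("background density must be >= 0")
        for name in (
            "molecules_per_cluster_mean",
            "disc_radius_nm",
            "photon_median",
            "photon_sigma_log",
            "precision_mean_nm",
            "precision_sd_nm",
            "precision_min_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"ClusterSpec.{name} must be > 0")


@dataclass
class GroundTruth:
    """Planted truth for a simulated field.

    ``labels`` gives, per table row, the cluster id (0..k-1) or -1 for
    background; ``clusters`` holds one row per planted cluster (centre,
    shape, orientation, true molecule and localization counts);
    ``localizations_per_molecule`` the per-molecule draw, cluster by
    cluster; ``epsilon_true`` the mean of the blinking distribution.
    """

    labels: np.ndarray
    clusters: pd.DataFrame
    localizations_per_molecule: list = field(default_factory=list)
    epsilon_true: float = np.nan


def _draw_counts(rng, mean, dispersion, size):
    if dispersion == 0:
        if abs(mean - round(mean)) > 1e-9:
            raise ValueError("zero dispersion requires an integer mean")
        return np.full(size, int(round(mean)), dtype=int)
    if dispersion == 1:
        return rng.poisson(mean, size)
    # negative binomial with variance = mean * dispersion
    r = mean / (dispersion - 1.0)
    p = 1.0 / dispersion
    return rng.negative_binomial(r, p, size)


def _draw_blinks(rng, mean, dispersion, size):
    if dispersion == 0:
        if abs(mean - round(mean)) > 1e-9:
            raise ValueError("zero dispersion requires an integer mean")
        return np.full(size, int(round(mean)), dtype=int)
    return rng.geometric(1.0 / mean, size)


def _truncated_normal(rng, mean, sd, lower, size):
    out = rng.normal(mean, sd, size)
    bad = out < lower
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < lower
    return out


def _place_centres(rng, spec: ClusterSpec, geom: FieldGeometry) -> np.ndarray:
    margin = (
        spec.disc_radius_nm
        if spec.cluster_shape == "disc"
        else spec.filament_length_nm / 2.0
    ) + 8.0 * spec.precision_mean_nm
    lo = margin
    hi_x, hi_y = geom.width_nm - margin, geom.height_nm - margin
    if hi_x <= lo or hi_y <= lo:
        raise ValueError("field too small for the requested cluster geometry")
    centres: list[np.ndarray] = []
    attempts = 0
    while len(centres) < spec.n_clusters:
        c = rng.uniform([lo, lo], [hi_x, hi_y])
        if all(
            np.hypot(*(c - prev)) >= spec.min_separation_nm for prev in centres
        ):
            centres.append(c)
        attempts += 1
        if attempts > 10000 * max(spec.n_clusters, 1):
            raise ValueError(
                "could not place clusters with the requested separation"
            )
    return np.array(centres) if centres else np.empty((0, 2))


def simulate_localizations(
    spec: ClusterSpec = ClusterSpec(),
    geom: FieldGeometry = FieldGeometry(),
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a localization table with planted ground truth.

    Returns ``(table, truth)`` where the table has the standard columns
    ``x_nm, y_nm, photons, precision_nm`` (cluster detections first, then
    background) and every detection lies inside the field. Deterministic
    for a fixed (spec, geom, seed).
    """
    rng = np.random.default_rng(seed)
    centres = _place_centres(rng, spec, geom)
    if spec.molecules_per_cluster_range is not None:
        lo, hi = spec.molecules_per_cluster_range
        n_molecules = rng.integers(lo, hi + 1, spec.n_clusters)
    else:
        n_molecules = _draw_counts(
            rng,
            spec.molecules_per_cluster_mean,
            spec.molecules_per_cluster_dispersion,
            spec.n_clusters,
        )

    xs, ys, labels = [], [], []
    cluster_rows = []
    blink_draws: list[np.ndarray] = []
    for cid in range(spec.n_clusters):
        centre = centres[cid]
        n_mol = int(n_molecules[cid])
        angle = rng.uniform(0.0, np.pi)
        if spec.cluster_shape == "disc":
            r = spec.disc_radius_nm * np.sqrt(rng.uniform(0, 1, n_mol))
            phi = rng.uniform(0, 2 * np.pi, n_mol)
            mol_xy = centre + np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        else:
            along = rng.uniform(
                -spec.filament_length_nm / 2.0, spec.filament_length_nm / 2.0, n_mol
            )
            # width is read as the full transverse width (~ +/- 2 sigma)
            across = rng.normal(0.0, spec.filament_width_nm / 4.0, n_mol)
            axis = np.array([np.cos(angle), np.sin(angle)])
            perp = np.array([-np.sin(angle), np.cos(angle)])
            mol_xy = centre + np.outer(along, axis) + np.outer(across, perp)
        blinks = _draw_blinks(
            rng,
            spec.localizations_per_molecule_mean,
            spec.localizations_per_molecule_dispersion,
            n_mol,
        )
        blink_draws.append(blinks)
        n_loc = int(blinks.sum())
        mol_pos = np.repeat(mol_xy, blinks, axis=0)
        xs.append(mol_pos[:, 0])
        ys.append(mol_pos[:, 1])
        labels.append(np.full(n_loc, cid))
        cluster_rows.append(
            {
                "cluster_id": cid,
                "shape": spec.cluster_shape,
                "x_c": float(centre[0]),
                "y_c": float(centre[1]),
                "angle_rad": float(angle),
                "length_nm": (
                    spec.filament_length_nm
                    if spec.cluster_shape == "filament"
                    else 2.0 * spec.disc_radius_nm
                ),
                "n_molecules": n_mol,
                "n_localizations": n_loc,
            }
        )

    n_background = rng.poisson(spec.background_density_per_nm2 * geom.area_nm2)
    if n_background:
        xs.append(rng.uniform(0.0, geom.width_nm, n_background))
        ys.append(rng.uniform(0.0, geom.height_nm, n_background))
        labels.append(np.full(n_background, -1))

    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        label = np.concatenate(labels).astype(int)
    else:
        x = y = np.empty(0)
        label = np.empty(0, dtype=int)

    n_total = x.size
    precision = _truncated_normal(
        rng, spec.precision_mean_nm, spec.precision_sd_nm, spec.precision_min_nm,
        n_total,
    )
    photons = rng.lognormal(np.log(spec.photon_median), spec.photon_sigma_log, n_total)
    # localization error: isotropic Gaussian with each detection's precision
    jitter = rng.normal(0.0, 1.0, (n_total, 2)) * precision[:, None]
    is_cluster = label >= 0
    x = x + np.where(is_cluster, jitter[:, 0], 0.0)
    y = y + np.where(is_cluster, jitter[:, 1], 0.0)
    # keep every detection inside the field (margins make clipping rare)
    x = np.clip(x, 0.0, geom.width_nm)
    y = np.clip(y, 0.0, geom.height_nm)

    table = pd.DataFrame(
        {"x_nm": x, "y_nm": y, "photons": photons, "precision_nm": precision}
    )
    truth = GroundTruth(
        labels=label,
        clusters=pd.DataFrame(
            cluster_rows,
            columns=[
                "cluster_id", "shape", "x_c", "y_c", "angle_rad", "length_nm",
                "n_molecules", "n_localizations",
            ],
        ).set_index("cluster_id") if cluster_rows else pd.DataFrame(
            columns=[
                "shape", "x_c", "y_c", "angle_rad", "length_nm",
                "n_molecules", "n_localizations",
            ]
        ),
        localizations_per_molecule=blink_draws,
        epsilon_true=spec.localizations_per_molecule_mean,
    )
    return table, truth


def simulate_fp_plate(
    assay: _binding.AssayConstants,
    competitor_pkd: float,
    concentrations,
    noise_sd: float = 5.0,
    n_replicates: int = 2,
    seed: int = 0,
    plateau_bound: float = 200.0,
    plateau_free: float = 50.0,
) -> _binding.CompetitionIsotherm:
    """Simulate a competition FP plate for one compound.

    The mean curve is the exact ternary equilibrium mapped through the
    affine signal model; Gaussian noise of ``noise_sd`` (signal units, e.g.
    mP) is added independently per replicate well. ``competitor_pkd`` of
    -inf means no binding (flat curve at the bound-probe plateau).
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if concentrations.size == 0:
        raise ValueError("concentration list must not be empty")
    rng = np.random.default_rng(seed)
    k_i = np.inf if np.isneginf(competitor_pkd) else 10.0 ** (-competitor_pkd)
    frac = _binding.wang_competitive_bound(assay, concentrations, k_i)
    mean_curve = _binding.fp_signal(frac, plateau_bound, plateau_free)
    noise = rng.normal(0.0, noise_sd, (n_replicates, concentrations.size)) \
        if noise_sd > 0 else np.zeros((n_replicates, concentrations.size))
    return _binding.CompetitionIsotherm(
        concentrations=concentrations,
        signals=mean_curve[None, :] + noise,
        assay=assay,
    )


def simulate_itc(
    params: _binding.ITCParameters,
    schedule: _binding.InjectionSchedule,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Integrated injection heats from the single-site model plus noise."""
    rng = np.random.default_rng(seed)
    heats = _binding.itc_heats(params, schedule)
    if noise_sd > 0:
        heats = heats + rng.normal(0.0, noise_sd, heats.size)
    return heats


def simulate_dose_response(
    p4: _dr.FourPLParameters,
    doses,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    label: str = "",
) -> _dr.DoseResponseCurve:
    """Sample a 4PL curve with Gaussian noise (% units) per replicate."""
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("dose list must not be empty")
    rng = np.random.default_rng(seed)
    mean_curve = _dr.four_pl(doses, p4)
    noise = rng.normal(0.0, noise_sd, (n_replicates, doses.size)) \
        if noise_sd > 0 else np.zeros((n_replicates, doses.size))
    return _dr.DoseResponseCurve(
        doses=doses, responses=mean_curve[None, :] + noise, label=label
    )
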