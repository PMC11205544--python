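"""Assembly of the heterogeneous viscosity field mu_loc(h, x).

The channel is split into three streamwise sections:

* **Section 1 — homogeneous inlet** (``x <= x0``): particles are still
  uniformly distributed, so the viscosity is the rheometer bulk value
  ``mu_rheo`` everywhere in height.
* **Section 2 — CFL development** (``x0 < x < x_star``): the cell-free
  layer grows as H_CFL(x).  At each station the height profile is a step:
  carrier viscosity inside the CFL bands, a single elevated core value
  outside, chosen so the height-averaged viscosity stays exactly at
  ``mu_rheo`` (the particles expelled from the bands crowd the core).
* **Section 3 — steady state** (``x >= x_star``): either the same step
  construction at the steady CFL height (*step* submodel) or a
  fourth-degree polynomial fitted to a measured viscosity profile in the
  core (*local-distribution* submodel), rescaled by an adjustment factor so
  the same height-average constraint holds.

The core step viscosity follows the mass-consistency formula

    mu_step = (H * mu_rheo - H_cfl_total * mu_carrier) / (H - H_cfl_total)

where ``H_cfl_total`` is the combined thickness of both wall bands.  A
per-wall reading of the same formula is available behind
``convention="per-wall"`` for sensitivity studies, but it does not conserve
the height average and is not the default.

Discrete representation: the field is stored cell-wise on a uniform
wall-normal grid (values are cell averages on ``n_h`` bins).  Cells
straddling a CFL edge receive the exact partial-volume average, so the
height-average constraint holds to machine precision at every station
without any grid alignment requirement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import CFLDevelopment, ParticleProfile, hcfl_profile
from .rheology import FluidSpec, einstein_roscoe

__all__ = [
    "FieldError",
    "ChannelGeometry",
    "GridSpec",
    "LocalDistributionSubmodel",
    "ViscosityField",
    "step_viscosity_at",
    "apply_adjustment",
    "fit_local_distribution",
    "assemble_field",
]

#: minimum number of wall-normal bins resolving the steady CFL band
MIN_CFL_BINS = 4


class FieldError(ValueError):
    """Invalid viscosity-field construction input."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Plane-channel gap geometry (µm).

    The plane-channel approximation assumes the width is large compared to
    the gap height (aspect ratio of at least 7); a narrower channel emits a
    warning because side walls would then shape the particle distribution.
    """

    H_um: float = 150.0
    W_um: float = 1200.0
    L_um: float = 10_000.0

    def __post_init__(self) -> None:
        if not self.H_um > 0:
            raise FieldError("H_um must be positive")
        if not self.L_um > 0:
            raise FieldError("L_um must be positive")
        if self.W_um / self.H_um < 7:
            warnings.warn(
                f"width-to-height ratio {self.W_um / self.H_um:.2f} < 7: "
                "plane-channel approximation is questionable",
                UserWarning,
                stacklevel=2,
            )

    @property
    def H_m(self) -> float:
        return self.H_um * 1e-6

    @property
    def L_m(self) -> float:
        return self.L_um * 1e-6


@dataclass(frozen=True)
class GridSpec:
    """Discretisation of the field: uniform in h, piecewise-uniform in x
    (fine during CFL development, coarse in the steady section)."""

    n_h: int = 256
    n_x_dev: int = 64
    n_x_steady: int = 16

    def __post_init__(self) -> None:
        if self.n_h < 8 or self.n_x_dev < 2 or self.n_x_steady < 2:
            raise FieldError("grid too coarse: need n_h >= 8 and >= 2 x-stations per section")


@dataclass
class LocalDistributionSubmodel:
    """Steady-state core-viscosity submodel: fourth-degree polynomial in h
    (coefficients in ascending powers, h in µm, mu in Pa·s) plus the
    multiplicative adjustment factor applied to its excess over the carrier
    viscosity."""

    poly_coeffs: np.ndarray
    adjustment_factor: float
    h_cfl_um: tuple[float, float]

    def raw_core_mu(self, h_um) -> np.ndarray:
        """Un-adjusted polynomial viscosity at height(s) ``h_um``."""
        return np.polynomial.polynomial.polyval(np.asarray(h_um, float), self.poly_coeffs)


def _core_fractions(edges_um: np.ndarray, h_bot: float, h_top: float, H: float) -> np.ndarray:
    """Fraction of each cell lying in the particle-laden core
    ``[h_bot, H - h_top]`` (exact partial-volume overlap)."""
    lo, hi = edges_um[:-1], edges_um[1:]
    core_lo, core_hi = h_bot, H - h_top
    overlap = np.clip(np.minimum(hi, core_hi) - np.maximum(lo, core_lo), 0.0, None)
    return overlap / (hi - lo)


def step_viscosity_at(
    x_um: float,
    fluid: FluidSpec,
    geom: ChannelGeometry,
    dev: CFLDevelopment,
    convention: str = "total",
) -> float:
    """Core viscosity of the step profile at station ``x_um`` (Pa·s).

    With ``convention="total"`` the CFL thickness entering the formula is
    the combined thickness of both wall bands, which makes the
    height-average of the step profile equal ``mu_rheo`` exactly.  The
    ``"per-wall"`` reading uses the single-wall height and breaks that
    consistency; it exists only for sensitivity studies.
    """
    h_wall = hcfl_profile(x_um, dev)
    h_total = 2.0 * h_wall
    if h_total >= geom.H_um:
        raise FieldError("cell-free layer exceeds channel height")
    h_eff = h_total if convention == "total" else h_wall
    if convention not in ("total", "per-wall"):
        raise FieldError(f"unknown convention {convention!r}")
    H = geom.H_um
    return (H * fluid.mu_rheo - h_eff * fluid.mu_carrier) / (H - h_eff)


def apply_adjustment(
    mu_raw: np.ndarray, fluid: FluidSpec
) -> tuple[np.ndarray, float]:
    """Rescale a cell-wise viscosity profile so its height average equals
    ``mu_rheo``.

    The unique factor ``beta >= 0`` multiplies the excess over the carrier
    viscosity, ``mu = mu_carrier + beta * (mu_raw - mu_carrier)``, leaving
    any cells already at the carrier value (the CFL bands) untouched.

    Returns the adjusted profile and ``beta``.  ``beta`` is below one when
    the raw profile (e.g. an Einstein–Roscoe prediction) over-predicts the
    rheometer bulk viscosity, and above one when it under-predicts.
    """
    mu_raw = np.asarray(mu_raw, dtype=float)
    if np.any(mu_raw < fluid.mu_carrier * (1 - 1e-12)):
        raise FieldError("raw profile dips below the carrier viscosity")
    excess_mean = float(np.mean(mu_raw)) - fluid.mu_carrier
    target = fluid.mu_rheo - fluid.mu_carrier
    if target == 0:
        return np.full_like(mu_raw, fluid.mu_carrier), 1.0 if excess_mean == 0 else 0.0
    if excess_mean <= 0:
        raise FieldError(
            "inconsistent inputs: profile carries no excess over the carrier "
            "viscosity but mu_rheo > mu_carrier"
        )
    beta = target / excess_mean
    return fluid.mu_carrier + beta * (mu_raw - fluid.mu_carrier), float(beta)


def fit_local_distribution(
    h_um: np.ndarray,
    mu: np.ndarray,
    fluid: FluidSpec,
    geom: ChannelGeometry,
    h_cfl_um: tuple[float, float],
    grid: GridSpec | None = None,
) -> LocalDistributionSubmodel:
    """Fit the local-distribution submodel to a core viscosity profile.

    ``(h_um, mu)`` are viscosity samples inside the particle-laden core
    (between the CFL bands); at least five support points are required for
    the fourth-degree fit.  The polynomial is floored at the carrier
    viscosity (with a warning) if it dips below it, and the adjustment
    factor is computed on the assembled cell-wise profile so the height
    average equals ``mu_rheo`` exactly.
    """
    grid = grid or GridSpec()
    h_bot, h_top = h_cfl_um
    h = np.asarray(h_um, dtype=float)
    m = np.asarray(mu, dtype=float)
    core = (h >= h_bot) & (h <= geom.H_um - h_top)
    if np.count_nonzero(core) < 5:
        raise FieldError(
            "need >= 5 support points inside the core for a fourth-degree fit"
        )
    coeffs = np.polynomial.polynomial.polyfit(h[core], m[core], deg=4)
    submodel = LocalDistributionSubmodel(
        poly_coeffs=coeffs, adjustment_factor=1.0, h_cfl_um=(h_bot, h_top)
    )
    raw = _local_distribution_column(submodel, fluid, geom, grid.n_h, adjusted=False)
    _, beta = apply_adjustment(raw, fluid)
    submodel.adjustment_factor = beta
    return submodel


def _centers(H_um: float, n: int) -> np.ndarray:
    edges = np.linspace(0.0, H_um, n + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def _step_column(
    fluid: FluidSpec,
    geom: ChannelGeometry,
    h_wall_um: float,
    n_h: int,
    convention: str = "total",
) -> np.ndarray:
    """Cell-wise step profile at one station (exact partial-volume)."""
    H = geom.H_um
    if 2 * h_wall_um >= H:
        raise FieldError("cell-free layer exceeds channel height")
    edges = np.linspace(0.0, H, n_h + 1)
    frac = _core_fractions(edges, h_wall_um, h_wall_um, H)
    h_eff = 2 * h_wall_um if convention == "total" else h_wall_um
    core_mu = (H * fluid.mu_rheo - h_eff * fluid.mu_carrier) / (H - h_eff)
    return fluid.mu_carrier + (core_mu - fluid.mu_carrier) * frac


def _local_distribution_column(
    submodel: LocalDistributionSubmodel,
    fluid: FluidSpec,
    geom: ChannelGeometry,
    n_h: int,
    adjusted: bool = True,
) -> np.ndarray:
    """Cell-wise steady column for the local-distribution submodel."""
    H = geom.H_um
    h_bot, h_top = submodel.h_cfl_um
    centers = _centers(H, n_h)
    mu = submodel.raw_core_mu(centers)
    if np.any(mu[(centers >= h_bot) & (centers <= H - h_top)] < fluid.mu_carrier):
        warnings.warn(
            "fitted polynomial dips below the carrier viscosity on the core; "
            "flooring at mu_carrier before adjustment",
            UserWarning,
            stacklevel=2,
        )
    mu = np.maximum(mu, fluid.mu_carrier)
    in_band = (centers < h_bot) | (centers > H - h_top)
    mu[in_band] = fluid.mu_carrier
    if adjusted:
        mu = fluid.mu_carrier + submodel.adjustment_factor * (mu - fluid.mu_carrier)
    return mu


@dataclass
class ViscosityField:
    """Local viscosity mu_loc(h, x) on a rectangular grid.

    ``mu`` has shape ``(n_h, n_x)``; ``h_um`` holds wall-normal cell
    centres (uniform bins over ``[0, H]``), ``x_um`` the streamwise
    stations, and ``section`` the per-station label
    (homogeneous / development / steady).
    """

    x_um: np.ndarray
    h_um: np.ndarray
    mu: np.ndarray
    section: np.ndarray
    fluid: FluidSpec
    geom: ChannelGeometry
    submodel: str = "step"
    convention: str = "total"

    @property
    def h_edges_um(self) -> np.ndarray:
        n = self.h_um.size
        return np.linspace(0.0, self.geom.H_um, n + 1)

    def height_average(self) -> np.ndarray:
        """Height-averaged viscosity at every station (cell average, exact
        for the cell-wise representation)."""
        return self.mu.mean(axis=0)

    def conservation_error(self) -> float:
        """Max relative deviation of the height average from mu_rheo."""
        avg = self.height_average()
        return float(np.max(np.abs(avg - self.fluid.mu_rheo)) / self.fluid.mu_rheo)

    def column(self, x_um: float) -> np.ndarray:
        """Viscosity column at the station nearest to ``x_um``."""
        idx = int(np.argmin(np.abs(self.x_um - x_um)))
        return self.mu[:, idx]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: x_um, h_um, mu_Pa_s, section."""
        X, H = np.meshgrid(self.x_um, self.h_um)
        sec = np.broadcast_to(self.section, self.mu.shape)
        return pd.DataFrame(
            {
                "x_um": X.ravel(),
                "h_um": H.ravel(),
                "mu_Pa_s": self.mu.ravel(),
                "section": sec.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fluid: FluidSpec, geom: ChannelGeometry) -> "ViscosityField":
        df = pd.read_csv(path)
        x = np.unique(df["x_um"].to_numpy())
        h = np.unique(df["h_um"].to_numpy())
        piv = df.pivot_table(index="h_um", columns="x_um", values="mu_Pa_s")
        sec = df.drop_duplicates("x_um").sort_values("x_um")["section"].to_numpy()
        return cls(
            x_um=x, h_um=h, mu=piv.to_numpy(), section=sec, fluid=fluid, geom=geom
        )


def _x_stations(geom: ChannelGeometry, dev: CFLDevelopment, grid: GridSpec):
    """Station grid with section labels; section boundaries are stations."""
    x0, xs, L = dev.x0_um, dev.x_star_um, geom.L_um
    xs_list: list[np.ndarray] = [np.array([0.0, min(x0, L)])]
    labels: list[np.ndarray] = [np.array(["homogeneous"] * 2)]
    if L > x0:
        if L < xs:
            warnings.warn(
                "channel ends inside the CFL development section",
                UserWarning,
                stacklevel=3,
            )
        dev_end = min(xs, L)
        x_dev = np.linspace(x0, dev_end, grid.n_x_dev)[1:]
        xs_list.append(x_dev)
        labels.append(np.array(["development"] * x_dev.size))
        if L > xs:
            x_st = np.linspace(xs, L, grid.n_x_steady)
            xs_list.append(x_st)
            labels.append(np.array(["steady"] * x_st.size))
    return np.concatenate(xs_list), np.concatenate(labels)


def assemble_field(
    fluid: FluidSpec,
    geom: ChannelGeometry,
    dev: CFLDevelopment,
    submodel: str = "step",
    steady_profile: ParticleProfile | None = None,
    grid: GridSpec | None = None,
    convention: str = "total",
    epsilon: float = 1e-4,
) -> ViscosityField:
    """Assemble the full mu_loc(h, x) field across the three sections.

    Parameters
    ----------
    submodel : {"step", "local_distribution"}
        Steady-section closure.  ``local_distribution`` requires
        ``steady_profile``, a measured/synthetic particle profile from
        which the core polynomial is fitted (the CFL bands are detected
        from the same profile with threshold ``epsilon``).
    convention : {"total", "per-wall"}
        Reading of the CFL thickness in the step formula; only ``total``
        conserves the height-averaged viscosity.
    """
    grid = grid or GridSpec()
    if submodel not in ("step", "local_distribution"):
        raise FieldError(f"unknown submodel {submodel!r}")
    if dev.h_ss_um and dev.h_ss_um > 0:
        dh = geom.H_um / grid.n_h
        if dev.h_ss_um < MIN_CFL_BINS * dh:
            need = int(np.ceil(MIN_CFL_BINS * geom.H_um / dev.h_ss_um))
            raise FieldError(
                f"grid too coarse: steady CFL of {dev.h_ss_um:g} µm spans fewer "
                f"than {MIN_CFL_BINS} bins; use n_h >= {need}"
            )
        if 2 * dev.h_ss_um >= geom.H_um:
            raise FieldError("cell-free layer exceeds channel height")

    x, labels = _x_stations(geom, dev, grid)
    n_h = grid.n_h
    mu = np.empty((n_h, x.size))

    ld: LocalDistributionSubmodel | None = None
    if submodel == "local_distribution":
        if steady_profile is None:
            raise FieldError("local_distribution submodel requires steady_profile")
        from .kinematics import detect_cfl_height

        h_cfl = detect_cfl_height(steady_profile, epsilon=epsilon)
        core_mask = (steady_profile.h_um >= h_cfl[0]) & (
            steady_profile.h_um <= geom.H_um - h_cfl[1]
        )
        mu_meas = einstein_roscoe(steady_profile.phi, fluid.mu_carrier)
        ld = fit_local_distribution(
            steady_profile.h_um[core_mask],
            np.asarray(mu_meas)[core_mask],
            fluid,
            geom,
            h_cfl,
            grid=grid,
        )

    steady_col: np.ndarray | None = None
    for j, (xj, lab) in enumerate(zip(x, labels)):
        if lab == "homogeneous":
            mu[:, j] = fluid.mu_rheo
        elif lab == "development":
            mu[:, j] = _step_column(fluid, geom, hcfl_profile(xj, dev), n_h, convention)
        else:
            if steady_col is None:
                if submodel == "step":
                    steady_col = _step_column(fluid, geom, dev.h_ss_um, n_h, convention)
                else:
                    steady_col = _local_distribution_column(ld, fluid, geom, n_h)
            mu[:, j] = steady_col

    return ViscosityField(
        x_um=x,
        h_um=_centers(geom.H_um, n_h),
        mu=mu,
        section=labels,
        fluid=fluid,
        geom=geom,
        submodel=submodel,
        convention=convention,
    )
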