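"""Synthetic particle-distribution profiles and measurement uncertainty.

Emulates the wall-normal concentration profiles an astigmatism
particle-tracking (APTV) campaign would deliver for a particle-laden gap
flow: particle-free bands of prescribed thickness at both walls, a
particle-laden core (flat plateau or a mid-plane-peaked quartic bump), and
optional per-bin sampling noise.  The noiseless skeleton conserves mass
exactly — the height average of the local volume fraction equals the bulk
fraction — mirroring the consistency constraint the viscosity model
enforces on the viscosity profile.

Also implements the pressure-measurement uncertainty budget
``u_x = x_s + t * s_mean`` combining a systematic bound ``x_s`` with a
Student-t confidence limit on the mean of repeated measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .field import ChannelGeometry
from .kinematics import CFLDevelopment, ParticleProfile, hcfl_profile
from .rheology import FluidSpec

__all__ = [
    "SyntheticError",
    "ProfileScenario",
    "UncertaintyResult",
    "generate_profile",
    "generate_development_planes",
    "measurement_uncertainty",
    "presets",
]

#: default systematic pressure-error bound, Pa
DEFAULT_SYSTEMATIC_ERROR_PA = 2000.0
#: default two-sided confidence level of the random-error term
DEFAULT_CONFIDENCE = 0.95


class SyntheticError(ValueError):
    """Invalid synthetic-data scenario."""


@dataclass(frozen=True)
class ProfileScenario:
    """Recipe for one synthetic particle-distribution profile.

    ``h_cfl_um`` are the (bottom, top) particle-free band thicknesses;
    ``core_shape`` is "plateau" (uniform core) or "quartic-bump"
    (mid-plane-peaked symmetric fourth-degree polynomial, zero at the band
    edges); ``noise_sd`` is the absolute per-bin volume-fraction noise of a
    truncated-Gaussian sampling model; ``measurement_planes_um`` are the
    streamwise stations of the development-calibration planes.
    """

    phi_bulk: float = 0.03
    h_cfl_um: tuple[float, float] = (20.0, 20.0)
    core_shape: str = "plateau"
    noise_sd: float = 0.0
    n_bins: int = 150
    seed: int = 0
    measurement_planes_um: tuple[float, ...] = (401.0, 1601.0)

    def __post_init__(self) -> None:
        if self.core_shape not in ("plateau", "quartic-bump"):
            raise SyntheticError(f"unknown core_shape {self.core_shape!r}")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be >= 0")
        if self.n_bins < 16:
            raise SyntheticError("n_bins must be >= 16")
        if not 0 <= self.phi_bulk < 1:
            raise SyntheticError("phi_bulk must lie in [0, 1)")
        if min(self.h_cfl_um) < 0:
            raise SyntheticError("CFL band thickness must be >= 0")


@dataclass(frozen=True)
class UncertaintyResult:
    """Total measurement uncertainty u_x = x_s + t * s_mean (Pa)."""

    mean: float
    s_mean: float
    t_factor: float
    x_s: float
    u_x: float
    n: int


def _band_overlap(edges: np.ndarray, core_lo: float, core_hi: float) -> np.ndarray:
    lo, hi = edges[:-1], edges[1:]
    return np.clip(np.minimum(hi, core_hi) - np.maximum(lo, core_lo), 0.0, None)


def _quartic_cell_averages(
    edges: np.ndarray, core_lo: float, core_hi: float
) -> np.ndarray:
    """Exact cell averages of the unit quartic bump (1 - z^2)^2 mapped onto
    the core, via its antiderivative z - 2z^3/3 + z^5/5."""
    mid = 0.5 * (core_lo + core_hi)
    half = 0.5 * (core_hi - core_lo)

    def Q(z):
        z = np.clip(z, -1.0, 1.0)
        return z - 2 * z**3 / 3 + z**5 / 5

    zl = (edges[:-1] - mid) / half
    zr = (edges[1:] - mid) / half
    widths = np.diff(edges)
    return half * (Q(zr) - Q(zl)) / widths


def generate_profile(
    scenario: ProfileScenario,
    geom: ChannelGeometry,
    x_station_um: float = float("nan"),
    rng: np.random.Generator | None = None,
    h_cfl_um: tuple[float, float] | None = None,
) -> ParticleProfile:
    """Generate one wall-normal particle profile.

    The noiseless skeleton has phi = 0 inside the CFL bands (exact
    partial-volume on straddling bins) and a core scaled so the bin-average
    of phi equals ``phi_bulk`` exactly.  Noise, when requested, is additive
    Gaussian per bin truncated at zero, drawn from ``rng`` (or a generator
    seeded with ``scenario.seed``).
    """
    h_cfl = h_cfl_um if h_cfl_um is not None else scenario.h_cfl_um
    H = geom.H_um
    if sum(h_cfl) >= H:
        raise SyntheticError("CFL bands exceed the channel height")
    n = scenario.n_bins
    edges = np.linspace(0.0, H, n + 1)
    widths = np.diff(edges)
    core_lo, core_hi = h_cfl[0], H - h_cfl[1]

    if scenario.core_shape == "plateau":
        plateau = scenario.phi_bulk * H / (core_hi - core_lo)
        phi = plateau * _band_overlap(edges, core_lo, core_hi) / widths
    else:
        # peak amplitude so that the bump integrates to phi_bulk * H:
        # integral of (1-z^2)^2 over the core is (16/15) * half-width
        half = 0.5 * (core_hi - core_lo)
        peak = scenario.phi_bulk * H / (16.0 / 15.0 * half)
        phi = peak * _quartic_cell_averages(edges, core_lo, core_hi)

    if scenario.noise_sd > 0:
        rng = rng or np.random.default_rng(scenario.seed)
        phi = np.clip(phi + rng.normal(0.0, scenario.noise_sd, size=n), 0.0, None)

    return ParticleProfile(
        h_um=0.5 * (edges[:-1] + edges[1:]),
        phi=phi,
        H_um=H,
        x_station_um=x_station_um,
    )


def generate_development_planes(
    scenario: ProfileScenario,
    geom: ChannelGeometry,
    dev: CFLDevelopment,
    stations_um: tuple[float, ...] | None = None,
) -> list[tuple[float, ParticleProfile]]:
    """Profiles at the development-calibration stations.

    Each plane's CFL band thickness follows the growth law at its station
    (uniform profile upstream of onset); feeding the detected heights of
    two noiseless planes back into the parabola calibration recovers the
    configured widening coefficient (closure property).  Noise realisations
    are independent but reproducible: plane ``i`` uses a generator seeded
    with ``(scenario.seed, i)``.
    """
    stations = stations_um if stations_um is not None else scenario.measurement_planes_um
    planes = []
    for i, x in enumerate(stations):
        if not 0 <= x <= geom.L_um:
            raise SyntheticError(f"station {x} µm outside the channel [0, {geom.L_um}]")
        h = hcfl_profile(x, dev)
        rng = np.random.default_rng([scenario.seed, i])
        prof = generate_profile(
            scenario, geom, x_station_um=x, rng=rng, h_cfl_um=(h, h)
        )
        planes.append((float(x), prof))
    return planes


def measurement_uncertainty(
    measurements,
    x_s: float = DEFAULT_SYSTEMATIC_ERROR_PA,
    confidence: float = DEFAULT_CONFIDENCE,
) -> UncertaintyResult:
    """Total uncertainty of a repeated pressure measurement (Pa).

    ``u_x = x_s + t * s_mean`` with ``s_mean`` the standard deviation of
    the mean and ``t`` the two-sided Student-t coverage factor at the given
    confidence with n-1 degrees of freedom.  With identical measurements
    the random term vanishes and ``u_x`` equals the systematic bound.
    """
    x = np.asarray(measurements, dtype=float)
    if x.size < 2:
        raise SyntheticError("cannot estimate dispersion from fewer than 2 measurements")
    if x_s < 0:
        raise SyntheticError("x_s must be >= 0")
    if not 0 < confidence < 1:
        raise SyntheticError("confidence must lie in (0, 1)")
    n = x.size
    s_mean = float(np.std(x, ddof=1) / np.sqrt(n))
    t_factor = float(stats.t.ppf(0.5 * (1 + confidence), df=n - 1))
    u_x = x_s + t_factor * s_mean
    return UncertaintyResult(
        mean=float(np.mean(x)),
        s_mean=s_mean,
        t_factor=t_factor,
        x_s=x_s,
        u_x=u_x,
        n=n,
    )


def presets() -> dict:
    """Catalog of reference fluids and profile scenarios.

    Fluids (viscosities from rheometer measurements reported for the
    modelled campaigns; densities are documented defaults, 1050 kg/m³ for
    blood-like fluids, as no measured densities accompany the viscosities):

    * ``baf_carrier`` — blood-analog carrier (PEG-water), 2.85 mPa·s
    * ``baf_5pct``    — blood-analog fluid at phi = 5 %, 5.95 mPa·s
    * ``plasma``      — porcine plasma, 1.38 mPa·s
    * ``blood_5pct``  — porcine blood at hematocrit 5 %, 1.45 mPa·s
    * ``blood_45pct`` — hypothetical high-hematocrit scenario, 3.63 mPa·s
      (outside the validated phi range; constructing it warns)

    Scenarios tag the measured blood-analog configurations (phi in
    {1, 3, 5} %) with the observed 20 µm per-wall steady CFL in the 150 µm
    gap.  The calibration-plane stations are synthetic placeholders chosen
    to be consistent with a widening coefficient a = 0.5 µm^(1/2) and the
    20 µm steady height; no measured station coordinates are available.
    """
    fluids = {
        "baf_carrier": FluidSpec.from_mpas(2.85, 2.85, 0.0, label="BAF carrier"),
        "baf_5pct": FluidSpec.from_mpas(2.85, 5.95, 0.05, label="BAF 5%"),
        "plasma": FluidSpec.from_mpas(1.38, 1.38, 0.0, label="plasma"),
        "blood_5pct": FluidSpec.from_mpas(1.38, 1.45, 0.05, label="blood 5%"),
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        fluids["blood_45pct"] = FluidSpec.from_mpas(
            1.38, 3.63, 0.45, label="blood 45% (hypothetical)"
        )
    scenarios = {
        f"baf_{tag}pct": ProfileScenario(
            phi_bulk=tag / 100.0, h_cfl_um=(20.0, 20.0)
        )
        for tag in (1, 3, 5)
    }
    geometry = ChannelGeometry(H_um=150.0, W_um=1200.0, L_um=10_000.0)
    development = CFLDevelopment(a=0.5, x0_um=1.0, h_ss_um=20.0)
    return {
        "fluids": fluids,
        "scenarios": scenarios,
        "geometry": geometry,
        "development": development,
    }
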