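"""Streamwise evolution of the cell-free layer (CFL).

Particles in a pressure-driven gap flow migrate away from the walls; the
particle-depleted near-wall band (the cell-free layer) grows with streamwise
distance until lateral migration equilibrates.  The development is modelled
as a tilted parabola

    H_CFL(x) = a * (x - x0) ** p        for x0 < x < x_star,

with the parabola axis along the flow direction (``p = 0.5`` by default; the
exponent is exposed for sensitivity studies), zero height in the short
homogeneous inlet section ``x <= x0``, and a clamp at the steady-state
height for ``x >= x_star``.  The widening coefficient ``a`` is calibrated
from CFL heights observed at two streamwise measurement planes.

Lengths here are micrometres, matching how gap geometries and particle
profiles are reported; the flow solver converts to SI internally.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KinematicsError",
    "ParticleProfile",
    "CFLDevelopment",
    "hcfl_profile",
    "completion_station",
    "calibrate_parabola",
    "detect_cfl_height",
]

#: default relative-growth threshold declaring CFL development complete
COMPLETION_REL_TOL = 1e-3
#: default streamwise increment (µm) over which the threshold is assessed
COMPLETION_DELTA_X_UM = 1.0


class KinematicsError(ValueError):
    """Invalid CFL-kinematics input."""


@dataclass
class ParticleProfile:
    """Wall-normal particle-concentration profile at one streamwise station.

    The profile is a cell-wise (binned) representation: ``h_um`` holds bin
    centres on a uniform grid spanning ``[0, H_um]`` and ``phi`` the local
    volume fraction of each bin, mirroring how particle-tracking
    measurements are reported.
    """

    h_um: np.ndarray
    phi: np.ndarray
    H_um: float
    x_station_um: float = float("nan")
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.h_um = np.asarray(self.h_um, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.h_um.ndim != 1 or self.h_um.shape != self.phi.shape:
            raise KinematicsError("h_um and phi must be 1-D arrays of equal length")
        if np.any(np.diff(self.h_um) <= 0):
            raise KinematicsError("h_um must be strictly increasing")
        if np.any(self.phi < 0):
            raise KinematicsError("phi must be non-negative")
        if not self.H_um > 0:
            raise KinematicsError("H_um must be positive")

    @property
    def n_bins(self) -> int:
        return self.h_um.size

    @property
    def edges_um(self) -> np.ndarray:
        """Uniform bin edges spanning [0, H_um]."""
        return np.linspace(0.0, self.H_um, self.n_bins + 1)

    @property
    def phi_mean(self) -> float:
        """Height-averaged volume fraction (exact for uniform bins)."""
        return float(np.mean(self.phi))

    def to_csv(self, path) -> None:
        """Write as delimited text with station metadata in a comment line."""
        header = f"# x_station_um={self.x_station_um} H_um={self.H_um}\n"
        df = pd.DataFrame({"h_um": self.h_um, "phi": self.phi})
        if self.counts is not None:
            df["count"] = self.counts
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ParticleProfile":
        with open(path) as fh:
            first = fh.readline()
            meta = {}
            if first.startswith("#"):
                for token in first[1:].split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        meta[k] = float(v)
                body = fh.read()
            else:
                body = first + fh.read()
        df = pd.read_csv(_io.StringIO(body))
        h = df["h_um"].to_numpy()
        H = meta.get("H_um", 2 * h[-1] - h[-2] if h.size > 1 else 2 * h[-1])
        return cls(
            h_um=h,
            phi=df["phi"].to_numpy(),
            H_um=H,
            x_station_um=meta.get("x_station_um", float("nan")),
            counts=df["count"].to_numpy() if "count" in df else None,
        )


@dataclass
class CFLDevelopment:
    """Parameters of the streamwise CFL growth law.

    Exactly one of ``x_star_um`` / ``h_ss_um`` may be given; the other is
    derived from the parabola.  If neither is given, the completion station
    is computed from the relative-growth criterion (growth over
    ``delta_x`` below 0.1 %).

    Attributes
    ----------
    a : float
        Widening coefficient of the parabola, µm^(1-exponent).
    x0_um : float
        Length of the homogeneous inlet section, µm (default 1).
    x_star_um : float
        Station where development is complete and the height clamps.
    h_ss_um : float
        Steady-state per-wall CFL height, µm.
    exponent : float
        Growth exponent ``p`` (0.5 = tilted parabola).
    calibration_residual_um : float
        RMS residual of the plane calibration that produced ``a`` (0 when
        the parameters were set directly).
    """

    a: float
    x0_um: float = 1.0
    x_star_um: float | None = None
    h_ss_um: float | None = None
    exponent: float = 0.5
    calibration_residual_um: float = 0.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise KinematicsError("parabola coefficient a must be >= 0")
        if not 0 < self.exponent <= 1:
            raise KinematicsError("exponent must lie in (0, 1]")
        if self.x_star_um is not None and self.h_ss_um is not None:
            implied = self.a * (self.x_star_um - self.x0_um) ** self.exponent
            if not np.isclose(implied, self.h_ss_um, rtol=1e-9, atol=1e-9):
                raise KinematicsError(
                    "x_star_um and h_ss_um are inconsistent with the parabola"
                )
        if self.x_star_um is None and self.h_ss_um is not None:
            if self.a == 0 and self.h_ss_um > 0:
                raise KinematicsError("a=0 cannot reach a positive steady height")
            self.x_star_um = (
                self.x0_um
                if self.a == 0
                else self.x0_um + (self.h_ss_um / self.a) ** (1.0 / self.exponent)
            )
        if self.x_star_um is None:
            self.x_star_um = completion_station(self)
        if self.x_star_um < self.x0_um:
            raise KinematicsError("x_star_um must be >= x0_um")
        if self.h_ss_um is None:
            self.h_ss_um = float(
                self.a * (self.x_star_um - self.x0_um) ** self.exponent
            )

    def hcfl(self, x_um):
        """Per-wall CFL height at streamwise position(s) ``x_um``."""
        return hcfl_profile(x_um, self)


def hcfl_profile(x_um, dev: CFLDevelopment):
    """Per-wall CFL height H_CFL(x) in µm: 0 in the inlet section, parabolic
    growth during development, clamped at the steady height past x_star.

    Continuous and nondecreasing in x; accepts scalars or arrays.
    """
    x = np.asarray(x_um, dtype=float)
    if np.any(x < 0):
        raise KinematicsError("x must be >= 0")
    u = np.clip(x - dev.x0_um, 0.0, None)
    h = dev.a * u**dev.exponent
    h = np.minimum(h, dev.h_ss_um)
    if np.isscalar(x_um) or np.ndim(x_um) == 0:
        return float(h)
    return h


def completion_station(
    dev: CFLDevelopment,
    delta_x_um: float = COMPLETION_DELTA_X_UM,
    rel_tol: float = COMPLETION_REL_TOL,
) -> float:
    """Smallest x where the relative CFL growth over ``delta_x_um`` drops
    below ``rel_tol`` (default 0.1 % per µm).

    For the power-law form the criterion
    ``(H(x+dx) - H(x)) / H(x) < tol`` is equivalent to
    ``x - x0 > dx / ((1+tol)**(1/p) - 1)``, solved in closed form.  With the
    default square-root growth and dx -> 0 this tends to ``x0 + dx/(2 tol)``.
    Returns ``x0`` immediately when a = 0 (no migration).
    """
    if delta_x_um <= 0:
        raise KinematicsError("delta_x_um must be positive")
    if rel_tol <= 0:
        raise KinematicsError("rel_tol must be positive")
    if dev.a == 0:
        return float(dev.x0_um)
    u_min = delta_x_um / ((1.0 + rel_tol) ** (1.0 / dev.exponent) - 1.0)
    return float(dev.x0_um + u_min)


def calibrate_parabola(
    plane1: tuple[float, float],
    plane2: tuple[float, float],
    x0_um: float = 1.0,
    H_um: float | None = None,
    exponent: float = 0.5,
    h_ss_um: float | None = None,
) -> CFLDevelopment:
    """Fit the widening coefficient ``a`` from two measurement planes.

    Each plane is a ``(x_um, H_CFL_um)`` pair.  The least-squares solution
    ``a = sum(h_i s_i) / sum(s_i^2)`` with ``s_i = (x_i - x0)**p`` is exact
    when the two planes lie on a single parabola; otherwise the RMS residual
    is recorded on the returned object.

    Parameters
    ----------
    h_ss_um : float, optional
        Independently known steady-state height (e.g. from a fully
        developed profile); when omitted, the completion criterion fixes
        the clamp station.
    """
    (x1, h1), (x2, h2) = plane1, plane2
    if x1 == x2:
        raise KinematicsError("measurement planes must be at distinct stations")
    if min(x1, x2) <= x0_um:
        raise KinematicsError("both planes must lie downstream of x0")
    if h1 < 0 or h2 < 0:
        raise KinematicsError("CFL heights must be >= 0")
    if H_um is not None and max(h1, h2) >= H_um / 2:
        raise KinematicsError("per-wall CFL height >= H/2 is unphysical")
    if (x2 - x1) * (h2 - h1) < 0:
        raise KinematicsError("CFL height must not decrease downstream")
    s = np.array([(x1 - x0_um) ** exponent, (x2 - x0_um) ** exponent])
    h = np.array([h1, h2])
    a = float(s @ h / (s @ s)) if np.any(h > 0) else 0.0
    resid = float(np.sqrt(np.mean((h - a * s) ** 2)))
    return CFLDevelopment(
        a=a,
        x0_um=x0_um,
        exponent=exponent,
        h_ss_um=h_ss_um,
        calibration_residual_um=resid,
    )


def detect_cfl_height(
    profile: ParticleProfile, epsilon: float = 1e-4
) -> tuple[float, float]:
    """Per-wall CFL heights (bottom, top) in µm from a particle profile.

    The bottom height is the extent of the contiguous run of near-wall bins
    whose volume fraction does not exceed ``epsilon`` (absolute); the top
    height is detected symmetrically from the opposite wall.  Returns
    ``(0, 0)`` for a uniform particle-laden profile.

    Raises
    ------
    KinematicsError
        If every bin is below ``epsilon`` (no particle-laden core).
    """
    if epsilon < 0:
        raise KinematicsError("epsilon must be >= 0")
    laden = profile.phi > epsilon
    if not np.any(laden):
        raise KinematicsError("no particle-laden core: profile is empty")
    edges = profile.edges_um
    first = int(np.argmax(laden))
    last = int(profile.n_bins - 1 - np.argmax(laden[::-1]))
    bottom = float(edges[first])
    top = float(profile.H_um - edges[last + 1])
    return bottom, top
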