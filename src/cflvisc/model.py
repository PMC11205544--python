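"""High-level modelling surface: a model object built from fluid, geometry
and CFL-development data whose ``fit`` returns a results object with the
wall-shear and pressure-loss observables and a ``summary`` table.

This mirrors the statsmodels idiom: construct → fit → results.  "Fitting"
here is deterministic forward evaluation after an optional calibration
stage (parabola coefficient from measurement planes, polynomial core fit
from a steady profile); the results object carries, per Reynolds number,
the model run, the single-phase run of the same fluid, and the
carrier-only reference used for normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .field import ChannelGeometry, GridSpec, ViscosityField, assemble_field
from .flow import (
    FlowConditions,
    FlowSolution,
    march_pressure_loss,
    normalized_cp,
)
from .kinematics import (
    CFLDevelopment,
    ParticleProfile,
    calibrate_parabola,
    detect_cfl_height,
)
from .rheology import FluidSpec

__all__ = ["GapFlowModel", "GapFlowResults"]


class GapFlowModel:
    """Cell-free-layer viscosity model for a narrow-gap channel flow.

    Parameters
    ----------
    fluid : FluidSpec
        Carrier and bulk rheology of the working fluid.
    geometry : ChannelGeometry
        Gap height / width / length in µm.
    development : CFLDevelopment
        Streamwise CFL growth law (use :meth:`from_planes` to calibrate it
        from measurement-plane data).
    submodel : {"step", "local_distribution"}
        Steady-section viscosity closure.
    steady_profile : ParticleProfile, optional
        Measured or synthetic steady-state particle profile; required by
        the local-distribution submodel.
    grid : GridSpec, optional
        Field discretisation.
    convention : {"total", "per-wall"}
        Reading of the CFL thickness in the step formula ("total"
        conserves the height-averaged viscosity and is the default).
    """

    def __init__(
        self,
        fluid: FluidSpec,
        geometry: ChannelGeometry,
        development: CFLDevelopment,
        submodel: str = "step",
        steady_profile: ParticleProfile | None = None,
        grid: GridSpec | None = None,
        convention: str = "total",
    ) -> None:
        self.fluid = fluid
        self.geometry = geometry
        self.development = development
        self.submodel = submodel
        self.steady_profile = steady_profile
        self.grid = grid or GridSpec()
        self.convention = convention

    @classmethod
    def from_planes(
        cls,
        fluid: FluidSpec,
        geometry: ChannelGeometry,
        planes: list[tuple[float, ParticleProfile]],
        x0_um: float = 1.0,
        epsilon: float = 1e-4,
        h_ss_um: float | None = None,
        **kwargs,
    ) -> "GapFlowModel":
        """Calibrate the growth law from two measurement planes.

        Each plane is ``(x_station_um, ParticleProfile)``; the per-wall CFL
        height of each plane is detected from its particle profile (mean of
        the two walls) and the widening coefficient fitted through them.
        """
        if len(planes) < 2:
            raise ValueError("need two measurement planes for calibration")
        pts = []
        for x, prof in planes[:2]:
            hb, ht = detect_cfl_height(prof, epsilon=epsilon)
            pts.append((x, 0.5 * (hb + ht)))
        dev = calibrate_parabola(
            pts[0], pts[1], x0_um=x0_um, H_um=geometry.H_um, h_ss_um=h_ss_um
        )
        return cls(fluid, geometry, dev, **kwargs)

    def build_field(self) -> ViscosityField:
        """Assemble the heterogeneous viscosity field mu_loc(h, x)."""
        return assemble_field(
            self.fluid,
            self.geometry,
            self.development,
            submodel=self.submodel,
            steady_profile=self.steady_profile,
            grid=self.grid,
            convention=self.convention,
        )

    def fit(self, reynolds=(100.0,), char_length: str = "H") -> "GapFlowResults":
        """Solve the channel flow at the given Reynolds numbers.

        For each Re three runs are computed at identical Re: the CFL-model
        field, the uniform single-phase field of the same fluid, and the
        carrier-only reference fluid (uniform field) used for the
        cp-normalisation.
        """
        field = self.build_field()
        carrier = self.fluid.carrier_only()
        uniform_dev = CFLDevelopment(a=0.0, x0_um=self.development.x0_um)
        single_field = assemble_field(
            self.fluid, self.geometry, uniform_dev, submodel="step", grid=self.grid
        )
        carrier_field = assemble_field(
            carrier, self.geometry, uniform_dev, submodel="step", grid=self.grid
        )
        rows = []
        runs: list[tuple[FlowSolution, FlowSolution, FlowSolution]] = []
        for re in np.atleast_1d(reynolds):
            cond = FlowConditions(reynolds=float(re), char_length=char_length)
            run_m = march_pressure_loss(field, cond, self.geometry, label="cfl-model")
            run_s = march_pressure_loss(
                single_field, cond, self.geometry, label="single-phase"
            )
            run_c = march_pressure_loss(
                carrier_field, cond, self.geometry, label="carrier-reference"
            )
            runs.append((run_m, run_s, run_c))
            rows.append(
                {
                    "reynolds": run_m.reynolds,
                    "bulk_velocity_m_s": run_m.bulk_velocity,
                    "delta_p_model_Pa": run_m.delta_p,
                    "delta_p_single_Pa": run_s.delta_p,
                    "cp_model": run_m.cp,
                    "cp_single": run_s.cp,
                    "cp_carrier_ref": run_c.cp,
                    "cp_ratio_model": normalized_cp(run_m, run_c),
                    "cp_ratio_single": normalized_cp(run_s, run_c),
                    "tau_w_model_Pa": run_m.tau_w_steady,
                    "tau_w_single_Pa": run_s.tau_w_steady,
                    "wss_ratio": run_m.tau_w_steady / run_s.tau_w_steady,
                }
            )
        return GapFlowResults(
            model=self, field=field, table=pd.DataFrame(rows), runs=runs
        )


@dataclass
class GapFlowResults:
    """Results of a :class:`GapFlowModel` fit.

    ``table`` holds one row per Reynolds number with pressure losses,
    pressure-loss coefficients, their normalised ratios cp/cp_carrier, and
    steady-section wall shear stresses of the model versus the single-phase
    run.  ``runs`` keeps the underlying per-station flow solutions as
    ``(model, single_phase, carrier_reference)`` triples.
    """

    model: GapFlowModel
    field: ViscosityField
    table: pd.DataFrame
    runs: list = dc_field(default_factory=list)

    @property
    def cp_ratio(self) -> np.ndarray:
        """cp/cp_carrier of the model run, one value per Reynolds number."""
        return self.table["cp_ratio_model"].to_numpy()

    @property
    def wss_ratio(self) -> np.ndarray:
        """Steady wall-shear ratio model/single-phase per Reynolds number."""
        return self.table["wss_ratio"].to_numpy()

    def to_dataframe(self) -> pd.DataFrame:
        return self.table.copy()

    def summary(self) -> str:
        m = self.model
        dev = m.development
        head = [
            "Cell-free-layer gap-flow model",
            "=" * 46,
            f"fluid            : {m.fluid.label or 'unnamed'}"
            f"  (mu_carrier={m.fluid.mu_carrier * 1e3:.4g} mPa.s,"
            f" mu_rheo={m.fluid.mu_rheo * 1e3:.4g} mPa.s,"
            f" phi={m.fluid.phi_bulk:.3g})",
            f"geometry         : H={m.geometry.H_um:g} um, W={m.geometry.W_um:g} um,"
            f" L={m.geometry.L_um:g} um",
            f"development      : a={dev.a:.6g} um^(1-p), p={dev.exponent:g},"
            f" x0={dev.x0_um:g} um, x*={dev.x_star_um:.6g} um,"
            f" h_cfl_ss={dev.h_ss_um:.6g} um/wall",
            f"submodel         : {m.submodel}"
            + (" (single-phase equivalent field)" if dev.a == 0 else ""),
            f"CFL thickness convention : {m.convention}"
            "  |  Re length scale : H",
            "",
        ]
        with pd.option_context("display.width", 120, "display.float_format", "{:.6g}".format):
            body = self.table[
                [
                    "reynolds",
                    "bulk_velocity_m_s",
                    "delta_p_model_Pa",
                    "cp_ratio_model",
                    "cp_ratio_single",
                    "tau_w_model_Pa",
                    "tau_w_single_Pa",
                    "wss_ratio",
                ]
            ].to_string(index=False)
        return "\n".join(head) + "\n" + body

    def plot_field(self, ax=None):
        """Pseudocolour plot of mu_loc(h, x) (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pcm = ax.pcolormesh(
            self.field.x_um, self.field.h_um, self.field.mu * 1e3, shading="nearest"
        )
        ax.set_xlabel("x (µm)")
        ax.set_ylabel("h (µm)")
        plt.colorbar(pcm, ax=ax, label="µ_loc (mPa·s)")
        return ax

    def plot_cp_ratio(self, ax=None):
        """cp/cp_carrier versus Reynolds number (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.table["reynolds"], self.table["cp_ratio_model"], "o-", label="CFL model")
        ax.plot(
            self.table["reynolds"],
            self.table["cp_ratio_single"],
            "s--",
            label="single-phase",
        )
        ax.set_xlabel("Re")
        ax.set_ylabel("cp / cp(carrier)")
        ax.legend()
        return ax
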