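"""High-level model/results interface.

:class:`BrainTransportModel` bundles a geometry, a compound and the flow,
transport, bolus and time settings; :meth:`~BrainTransportModel.solve` runs
the steady flow and transient transport stages and returns a
:class:`TransportResults` carrying the fields, the domain-mean summaries, the
mass-conservation diagnostics and plotting helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compounds import CompoundRecord
from .flow import FlowParameters, PressureSolution, solve_flow
from .geometry import GeometryRecipe, TissueModel, VesselNetwork, generate_geometry
from .postprocess import ConcentrationSummary, summarize
from .transport import (
    BolusProfile,
    FieldSolution,
    TimeSettings,
    TransportParameters,
    assemble_transport_operators,
    run_transport,
)

logger = logging.getLogger(__name__)

__all__ = ["BrainTransportModel", "TransportResults"]


@dataclass
class TransportResults:
    """Results of one transport solve."""

    model: "BrainTransportModel"
    compound: CompoundRecord | None
    flow: PressureSolution
    solution: FieldSolution
    concentration: ConcentrationSummary

    @property
    def times(self) -> np.ndarray:
        return self.solution.times

    @property
    def mean_tissue(self) -> np.ndarray:
        return self.concentration.mean_tissue

    @property
    def mean_capillary(self) -> np.ndarray:
        return self.concentration.mean_capillary

    def auc(self, domain: str = "tissue") -> float:
        """Time integral (mol s / L) of the domain-mean concentration."""
        series = {"tissue": self.mean_tissue, "capillary": self.mean_capillary}[domain]
        return float(np.trapezoid(series, self.times))

    @property
    def max_ledger_residual(self) -> float:
        led = self.solution.mass_ledger
        scale = max(float(np.abs(led[["inflow", "outflow", "storage_change"]]).to_numpy().max()), 1e-300)
        return float(np.abs(led["residual"]).max() / scale)

    def summary(self) -> pd.DataFrame:
        """One-row table of the headline quantities of this run."""
        row = {
            "compound": self.compound.name if self.compound else "(none)",
            "peak_tissue_time_s": self.concentration.peak_time["tissue"],
            "peak_tissue_conc_M": self.concentration.peak_value["tissue"],
            "peak_capillary_time_s": self.concentration.peak_time["capillary"],
            "peak_capillary_conc_M": self.concentration.peak_value["capillary"],
            "tissue_auc_Ms": self.auc("tissue"),
            "final_tissue_conc_M": float(self.mean_tissue[-1]),
            "mass_balance_residual_rel": self.max_ledger_residual,
        }
        return pd.DataFrame([row])

    def plot(self, ax=None):
        """Plot the mean concentration evolution of both continuum domains."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ax.plot(self.times, self.mean_capillary, label="capillary domain")
        ax.plot(self.times, self.mean_tissue, label="tissue domain")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("mean concentration (mol/L)")
        title = self.compound.name if self.compound else "transport run"
        ax.set_title(title)
        ax.legend()
        return ax


@dataclass
class BrainTransportModel:
    """Coupled 1D-3D perfusion-transport model of a vascularized tissue block."""

    network: VesselNetwork
    tissue: TissueModel
    compound: CompoundRecord | None = None
    flow_params: FlowParameters = field(default_factory=FlowParameters)
    transport_params: TransportParameters | None = None
    bolus: BolusProfile = field(default_factory=BolusProfile)
    times: TimeSettings = field(default_factory=TimeSettings)
    tissue_density_kg_per_l: float = 1.0
    _flow_cache: PressureSolution | None = field(default=None, repr=False)

    @classmethod
    def from_recipe(cls, recipe: GeometryRecipe, compound: CompoundRecord | None = None,
                    **kwargs) -> "BrainTransportModel":
        """Generate the synthetic geometry for ``recipe`` and build the model."""
        network, tissue = generate_geometry(recipe)
        return cls(network=network, tissue=tissue, compound=compound, **kwargs)

    def _transport_params(self) -> TransportParameters:
        if self.transport_params is not None:
            return self.transport_params
        if self.compound is not None:
            return TransportParameters.for_compound(
                self.compound, self.tissue_density_kg_per_l,
                leakage_coefficient=self.flow_params.leakage_coefficient,
            )
        return TransportParameters(leakage_coefficient=self.flow_params.leakage_coefficient)

    def solve_flow(self) -> PressureSolution:
        """Steady pressure solve; cached because it is compound-independent."""
        if self._flow_cache is None:
            self._flow_cache = solve_flow(self.network, self.tissue, self.flow_params)
        return self._flow_cache

    def solve(self, compound: CompoundRecord | None = None) -> TransportResults:
        """Run flow + transport (optionally overriding the compound)."""
        active = compound or self.compound
        if compound is not None:
            params = TransportParameters.for_compound(
                compound, self.tissue_density_kg_per_l,
                leakage_coefficient=self.flow_params.leakage_coefficient,
            )
        else:
            params = self._transport_params()
        flow = self.solve_flow()
        ops = assemble_transport_operators(self.tissue, self.network, flow, params)
        solution = run_transport(ops, self.bolus, self.times)
        concentration = summarize(solution, self.tissue)
        return TransportResults(
            model=self, compound=active, flow=flow, solution=solution,
            concentration=concentration,
        )
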