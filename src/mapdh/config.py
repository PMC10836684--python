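"""Run configuration: optics, simulation probabilities, swelling parameters.

Every tunable that the virtual instrument or the renderer consumes lives
here so that a run is fully described by (protocol, RunConfig, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from .protocol import HardwareProfile

__all__ = [
    "OpticsConfig",
    "RunConfig",
    "SimulationConfig",
    "SwellingConfig",
    "observed_size_bias",
]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticsConfig(_Model):
    """Rendering optics for synthetic micrographs.

    ``gain`` converts strand concentration (nM) to intensity counts;
    ``background`` and ``noise_sigma`` define the additive Gaussian noise
    model (counts).
    """

    pixel_size_um: float = Field(default=1.0, gt=0)
    background: float = Field(default=100.0, ge=0)
    noise_sigma: float = Field(default=5.0, ge=0)
    gain: float = Field(default=1.0, gt=0)


class SwellingConfig(_Model):
    """Saturating-exponential swelling law parameters.

    A free edge of a domain whose crosslink system has received its signal
    follows ``dL/L0(t) = A * (1 - exp(-t / tau))``; edges constrained by a
    neighboring domain are scaled by ``constrained_edge_factor``. The
    amplitudes are calibration inputs (equilibrium relative swelling per
    system), tau is an order-of-magnitude anchor, not fitted kinetics.
    """

    amplitude: dict[str, float] = Field(
        default_factory=lambda: {"S1": 0.51, "S2": 0.6}
    )
    tau_h: float = Field(default=8.0, gt=0)
    constrained_edge_factor: float = Field(default=0.5, ge=0, le=1)
    signal_conc_uM: float = Field(default=20.0, gt=0)


def observed_size_bias() -> dict[float, float]:
    """Additive polymerized-size offsets (um) by nominal mask size.

    Purely descriptive calibration of observed mean patterned sizes for
    50 / 20 / 10 um square masks — not a physical model. The default
    simulation bias is zero.
    """
    return {50.0: 1.5, 20.0: 7.1, 10.0: 3.69}


class SimulationConfig(_Model):
    """Stochastic and kinetic knobs of the virtual chamber.

    ``p_washoff`` — per-wash probability that an anchored hydrogel cluster
    patterned in an earlier round detaches prematurely (lost to waste);
    only meaningful when a sacrificial layer is present.
    ``p_collect`` — probability that a lifted-off free cluster is recovered
    during COLLECT.
    ``hybridization_rate_per_nM_h`` — first-order quenching/hybridization
    rate constant per nM of free strand per hour.
    ``size_bias_um`` — nominal mask size (um) → additive polymerized-size
    offset (um); nearest-size lookup, empty means zero bias.
    """

    flow_rate_ul_s: float = Field(default=1.0, gt=0)
    p_washoff: float = Field(default=0.0, ge=0, le=1)
    p_collect: float = Field(default=1.0, ge=0, le=1)
    hybridization_rate_per_nM_h: float = Field(default=0.01, gt=0)
    size_bias_um: dict[float, float] = Field(default_factory=dict)

    def bias_for(self, nominal_um: float) -> float:
        if not self.size_bias_um:
            return 0.0
        key = min(self.size_bias_um, key=lambda s: abs(s - nominal_um))
        return self.size_bias_um[key]


class RunConfig(_Model):
    """Complete configuration of a virtual run."""

    hardware: HardwareProfile = Field(default_factory=HardwareProfile)
    optics: OpticsConfig = Field(default_factory=OpticsConfig)
    swelling: SwellingConfig = Field(default_factory=SwellingConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    seed: int = 0
    output_dir: Optional[str] = None

    def config_hash(self) -> str:
        """Stable hash of the configuration for provenance records."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.model_dump(mode="json"), indent=2))

    @classmethod
    def load_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))
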