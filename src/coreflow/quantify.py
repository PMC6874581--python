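"""Virtual-core volume and per-population abundance with propagated errors.

The volume of the virtual core is not measured directly: it is the analyzed
sample volume (flow rate x acquisition duration) scaled by the fraction of
detected particles accepted as OPP.  Cell abundance is population count over
core volume; its standard error reflects the flow-rate calibration
uncertainty (delta method: relative SE is preserved through the product).
Poisson counting error is computed as well but kept in a separate field,
never folded into the calibration-based SE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["VirtualCoreVolume", "virtual_core_volume", "abundance"]

DEFAULT_FLOW_SE_FRACTION = 0.05


@dataclass(frozen=True)
class VirtualCoreVolume:
    file_id: str
    opp_ratio: float
    sample_volume: float  # uL
    core_volume: float    # uL
    core_volume_se: float

    def __post_init__(self):
        if self.core_volume > self.sample_volume * (1 + 1e-12):
            raise ValueError("core volume cannot exceed sample volume")
        if self.core_volume_se < 0:
            raise ValueError("core volume SE must be >= 0")


def virtual_core_volume(ratio: float, meta) -> VirtualCoreVolume:
    """Core volume (uL) for one file from its OPP ratio and metadata row.

    ``meta`` needs file_id, flow_rate (mL/min), flow_rate_se and duration (s).
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"opp ratio must lie in [0, 1], got {ratio}")
    flow = float(meta["flow_rate"])
    duration = float(meta["duration"])
    if flow <= 0 or duration <= 0:
        raise ValueError("flow_rate and duration must be positive")
    se_frac = float(meta["flow_rate_se"]) / flow
    sample_ul = flow * 1000.0 / 60.0 * duration
    core = ratio * sample_ul
    return VirtualCoreVolume(file_id=str(meta["file_id"]), opp_ratio=float(ratio),
                             sample_volume=sample_ul, core_volume=core,
                             core_volume_se=core * se_frac)


def abundance(count: int, core: VirtualCoreVolume) -> tuple[float, float, float]:
    """(cells per uL, calibration SE, Poisson counting SE) for one population."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if core.core_volume <= 0:
        raise ValueError("core volume must be positive")
    ab = count / core.core_volume
    se = ab * (core.core_volume_se / core.core_volume)
    se_poisson = math.sqrt(count) / core.core_volume
    return ab, se, se_poisson
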