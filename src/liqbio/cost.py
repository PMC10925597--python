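"""Clinical assay cost and turnaround time for a biomarker panel.

Only protein biomarker assays are charged: the six routinely available
biomarkers (AFP, CA 19-9, CA 125, CEA, Prolactin, CA 15-3) at $2 per test,
specialized biomarkers at $5.5, and 2.5 h of laboratory time per biomarker.
Clinical covariates and the omega score carry no assay cost here (the omega
score's sequencing cost is outside this model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .data_model import FeatureMeta
from .errors import ConfigError

#: The six biomarkers in routine clinical use.
ROUTINE_BIOMARKERS = ("AFP", "CA 19-9", "CA 125", "CEA", "Prolactin", "CA 15-3")


@dataclass(frozen=True)
class CostConfig:
    routine_cost: float = 2.0      # USD per routine biomarker test
    other_cost: float = 5.5        # USD per specialized biomarker test
    hours_per_biomarker: float = 2.5

    def __post_init__(self) -> None:
        if min(self.routine_cost, self.other_cost, self.hours_per_biomarker) <= 0:
            raise ConfigError("cost model parameters must be positive")


def panel_cost(
    features: Iterable[FeatureMeta], config: CostConfig = CostConfig()
) -> tuple[float, float]:
    """Total (cost in USD, time in hours) for assaying the panel's biomarkers."""
    biomarkers = [f for f in features if f.kind == "biomarker"]
    n_routine = sum(1 for f in biomarkers if f.routine)
    n_other = len(biomarkers) - n_routine
    cost = config.routine_cost * n_routine + config.other_cost * n_other
    time = config.hours_per_biomarker * len(biomarkers)
    return cost, time
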