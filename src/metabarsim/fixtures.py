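"""Synthetic mock-community fixtures with known ground truth.

The generator drives the generative core (it is not an independent model):
a fixed community with user-chosen efficiencies and concentrations is
simulated for a number of technical replicates, yielding a long-format read
table, a known-input table, and a truth table carrying the generating
``a``/``lambda`` values for parameter-recovery tests.  Optionally named
replicates can be sabotaged with a shallow sequencing depth so QC filters
have something to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import CommunityProfile, ProtocolParams, ReadDepthRule, simulate_replicate
from .errors import InvalidParameterError

__all__ = ["FixtureSpec", "generate_fixture"]


@dataclass
class FixtureSpec:
    """Design of one synthetic mock community.

    ``shallow_replicates`` maps replicate labels to a forced (low) sequencing
    depth, emulating failed libraries for QC tests.
    """

    efficiencies: list[float]
    lambdas: list[float]
    n_replicates: int = 3
    sample_id: str = "mock1"
    min_reads: int = 60_000
    max_reads: int = 140_000
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    shallow_replicates: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.efficiencies) != len(self.lambdas):
            raise InvalidParameterError("efficiencies and lambdas must align")
        if len(self.efficiencies) < 1:
            raise InvalidParameterError("need at least one species")
        if self.n_replicates < 1:
            raise InvalidParameterError("need at least one replicate")
        if any(l <= 0 for l in self.lambdas):
            raise InvalidParameterError("fixture concentrations must be > 0")


def generate_fixture(
    spec: FixtureSpec,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the fixture; returns (read_table, mock_inputs, truth).

    Deterministic for a given seed.  ``truth`` has columns species, a,
    lambda; ``mock_inputs`` the species, copies_per_uL pairs the estimator
    consumes.
    """
    rng = np.random.default_rng(seed)
    I = len(spec.efficiencies)
    species = [f"sp{i + 1:03d}" for i in range(I)]
    community = CommunityProfile(species, np.asarray(spec.lambdas, float),
                                 np.asarray(spec.efficiencies, float))
    depth_rule = ReadDepthRule(spec.min_reads, spec.max_reads)
    base_protocol = replace(spec.protocol, depth_rule=depth_rule)

    rows = []
    for j in range(spec.n_replicates):
        rep_id = f"rep{j + 1}"
        protocol = base_protocol
        if rep_id in spec.shallow_replicates:
            d = int(spec.shallow_replicates[rep_id])
            protocol = replace(base_protocol, depth_rule=ReadDepthRule(d, d))
        result = simulate_replicate(community, protocol, rng, replicate_id=rep_id)
        for sp, y in zip(species, result.Y):
            rows.append({"sample_id": spec.sample_id, "replicate_id": rep_id,
                         "species_id": sp, "reads": int(y)})

    read_table = pd.DataFrame(rows)
    mock_inputs = pd.DataFrame({"species": species,
                                "copies_per_uL": list(spec.lambdas)})
    truth = pd.DataFrame({"species": species, "a": list(spec.efficiencies),
                          "lambda": list(spec.lambdas)})
    return read_table, mock_inputs, truth
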