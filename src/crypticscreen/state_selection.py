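"""Selection of docking-target states from an ensemble.

Docking against every state of a Markov state model is wasteful: lowly
populated states contribute little weight to an equilibrium average, and
a compound would need an implausibly high affinity for a rare state to
matter.  The selector therefore keeps only states that (a) contain the
target pocket cluster, (b) carry at least a minimum equilibrium
population, and (c) rank among the top-N most populated — by default the
published choice of 15 states at a 0.004% floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .core_io import StructureEnsemble
from .errors import ConfigError, ContractError


@dataclass(frozen=True)
class StateSelectionParams:
    #: Minimum equilibrium population (fraction); default 0.004%.
    population_threshold: float = 4e-5
    #: Keep at most this many states (most populated first).
    max_states: int = 15

    def __post_init__(self) -> None:
        if not 0 <= self.population_threshold <= 1:
            raise ConfigError("population_threshold must be in [0, 1]")
        if self.max_states < 1:
            raise ConfigError("max_states must be >= 1")


def select_target_states(
    ensemble: StructureEnsemble,
    pocket_states: Iterable[str],
    params: StateSelectionParams | None = None,
) -> StructureEnsemble:
    """Pick the docking targets: pocket-containing, populated, capped.

    Returns a sub-ensemble sorted by descending population and truncated
    to ``max_states``; the threshold is inclusive (population ≥ threshold
    qualifies).  Original populations are retained without renormalizing —
    Boltzmann weights are scale-invariant, so renormalization would not
    change any downstream ranking.
    """
    params = params or StateSelectionParams()
    pocket_states = set(pocket_states)
    unknown = pocket_states - set(ensemble.state_ids)
    if unknown:
        raise ContractError(f"pocket_states not in ensemble: {sorted(unknown)}")

    qualifying = [
        s
        for s in ensemble
        if s.state_id in pocket_states and s.population >= params.population_threshold
    ]
    # ties at the cap boundary broken by state_id for determinism
    qualifying.sort(key=lambda s: (-s.population, s.state_id))
    selected = qualifying[: params.max_states]
    if not selected:
        raise ContractError(
            "no qualifying states: none of the pocket-containing states reach "
            f"population {params.population_threshold:g}"
        )
    return StructureEnsemble(tuple(selected))
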