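"""Three-valued logical steady-state analysis (LSSA).

Each node of a signed interaction network is assigned one of three states
at steady state: inactive (0), active (1) or undetermined (NaN).  A
*scenario* fixes the two experimental handles of the p53 system — the
DNA-damage input (ON/OFF) and the p53 status (wild-type or null).  The
model prediction ``E_mod`` for a node between two scenarios is the
three-valued state change, in {-1, 0, +1}.

Update semantics
----------------
The propagation rule is inhibitor-dominant Kleene logic, evaluated
cautiously so the update is monotone in the information order
(NaN below 0 and 1) and the least fixpoint is reached in at most |V|
sweeps from the all-NaN start:

* a node becomes **1** when at least one activator is 1 and *every*
  inhibitor has resolved to 0 (vacuously true without inhibitors);
* a node becomes **0** when some inhibitor is 1, or all of its regulators
  have resolved to 0;
* otherwise it stays **NaN** — in particular, cycles such as the
  TP53-MDM2 negative feedback remain undetermined unless an outside
  signal forces them.

Source nodes other than the designated input are uncontrolled and stay
NaN.  A p53-null scenario clamps the p53 node to 0 before iteration
(loss of function), so downstream logic sees an inactive node while the
graph structure is unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

from .network import InteractionNetwork

__all__ = [
    "Scenario",
    "SteadyState",
    "compute_steady_state",
    "derive_emod",
    "emod_value",
    "SCENARIOS",
]


@dataclass(frozen=True)
class Scenario:
    """One simulation condition: p53 status x DNA-damage input."""

    p53_status: Literal["wt", "null"] = "wt"
    dna_damage: Literal["ON", "OFF"] = "OFF"

    def __post_init__(self) -> None:
        if self.p53_status not in ("wt", "null"):
            raise ValueError(f"p53_status must be 'wt' or 'null', got {self.p53_status!r}")
        if self.dna_damage not in ("ON", "OFF"):
            raise ValueError(f"dna_damage must be 'ON' or 'OFF', got {self.dna_damage!r}")

    def __str__(self) -> str:  # e.g. "TP53 wt, DNA damage ON"
        return f"p53 {self.p53_status}, DNA damage {self.dna_damage}"


#: The four possible scenarios.
SCENARIOS: tuple[Scenario, ...] = (
    Scenario("wt", "OFF"),
    Scenario("wt", "ON"),
    Scenario("null", "OFF"),
    Scenario("null", "ON"),
)

NAN = float("nan")


@dataclass
class SteadyState:
    """Per-node three-valued state {0, NaN, 1} for one scenario."""

    scenario: Scenario
    states: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, node: str) -> float:
        return self.states[node]


def _is_nan(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


def compute_steady_state(net: InteractionNetwork, scenario: Scenario) -> SteadyState:
    """Least-fixpoint three-valued steady state of *net* under *scenario*.

    Deterministic; converges in at most ``|V|`` sweeps because the cautious
    update is monotone in the information order and each sweep can only
    refine NaN states to determined ones.
    """
    states: dict[str, float] = {v: NAN for v in net.nodes}
    clamped: set[str] = {net.input_node}
    states[net.input_node] = 1.0 if scenario.dna_damage == "ON" else 0.0
    if scenario.p53_status == "null":
        states[net.p53_node] = 0.0
        clamped.add(net.p53_node)

    regulators = {v: net.regulators(v) for v in net.nodes}

    for _ in range(len(net.nodes)):
        changed = False
        for v in net.nodes:
            if v in clamped or not _is_nan(states[v]):
                continue  # determined states never change (monotone update)
            regs = regulators[v]
            if not regs:
                continue  # uncontrolled source: stays NaN
            activator_on = any(s > 0 and states[u] == 1.0 for u, s in regs)
            inhibitor_on = any(s < 0 and states[u] == 1.0 for u, s in regs)
            inhibitors_off = all(states[u] == 0.0 for u, s in regs if s < 0)
            all_regs_off = all(states[u] == 0.0 for u, _ in regs)
            if inhibitor_on or all_regs_off:
                states[v] = 0.0
                changed = True
            elif activator_on and inhibitors_off:
                states[v] = 1.0
                changed = True
        if not changed:
            break
    return SteadyState(scenario=scenario, states=states)


_EMOD_TABLE: dict[tuple[str, str], int] = {
    ("1", "0"): -1,
    ("1", "NaN"): -1,
    ("NaN", "0"): -1,
    ("1", "1"): 0,
    ("0", "0"): 0,
    ("NaN", "NaN"): 0,
    ("0", "1"): +1,
    ("NaN", "1"): +1,
    ("0", "NaN"): +1,
}


def _key(x: float) -> str:
    if _is_nan(x):
        return "NaN"
    if x == 0.0:
        return "0"
    if x == 1.0:
        return "1"
    raise ValueError(f"invalid three-valued state {x!r}")


def emod_value(s1: float, s2: float) -> int:
    """Model-predicted state change between two three-valued states.

    The nine-case table: any move toward activity (0->1, 0->NaN, NaN->1)
    is up-regulation (+1), any move away (1->0, 1->NaN, NaN->0) is
    down-regulation (-1), and no move is 0.
    """
    return _EMOD_TABLE[(_key(s1), _key(s2))]


def derive_emod(state1: SteadyState, state2: SteadyState) -> dict[str, int]:
    """Per-node ``E_mod`` between two steady states over the same node set."""
    if set(state1.states) != set(state2.states):
        raise ValueError("steady states are defined over different node sets")
    return {v: emod_value(state1.states[v], state2.states[v]) for v in state1.states}
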