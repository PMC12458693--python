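"""Free-energy cycle assembly and closure-error accounting.

Orientation convention (frozen here, printed in every report):

                dG_wet  (A -> B, waters present)
       [A, wet] ------------------------------> [B, wet]
          ^                                        ^
          | dG_net(A)                              | dG_net(B)
          |   (bind n waters, ligand A)            |   (bind n waters, ligand B)
       [A, dry] ------------------------------> [B, dry]
                dG_dry  (A -> B, waters absent)

Around the cycle, dG_wet + dG_net(A) - dG_dry - dG_net(B) = 0 for consistent
and converged legs; the closure error is the absolute value of that sum.
All four legs must refer to the same retained water set of ``retained_n``
molecules (waters displaced by a substituent are excluded from the network
legs on both sides).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alchemical import AlchemicalLeg
from .titration import NetworkFreeEnergy

__all__ = [
    "FreeEnergyCycle",
    "closure_error",
    "solvent_contribution",
    "relative_binding_free_energy",
    "render_cycle",
]


@dataclass
class FreeEnergyCycle:
    """Two alchemical legs plus two GCMC network legs."""

    leg_alchemical_wet: AlchemicalLeg
    leg_alchemical_dry: AlchemicalLeg
    leg_network_a: NetworkFreeEnergy
    leg_network_b: NetworkFreeEnergy
    retained_n: int
    label_a: str = "A"
    label_b: str = "B"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for leg, env in (
            (self.leg_alchemical_wet, "waters-present"),
            (self.leg_alchemical_dry, "waters-absent"),
        ):
            if leg.dg is None:
                raise ValueError("alchemical legs must be estimated before cycle assembly")
            if leg.environment != env:
                raise ValueError(f"expected a {env} leg, got {leg.environment!r}")
        if abs(self.leg_network_a.b_equil - self.leg_network_b.b_equil) > 1e-9:
            raise ValueError("network legs must share B_equil (same bulk reference)")


def closure_error(cycle: FreeEnergyCycle) -> tuple[float, float]:
    """|dG_wet + dG_net(A) - dG_dry - dG_net(B)| with root-sum-square error."""
    signed = (
        cycle.leg_alchemical_wet.dg
        + cycle.leg_network_a.dg
        - cycle.leg_alchemical_dry.dg
        - cycle.leg_network_b.dg
    )
    err = float(
        np.sqrt(
            (cycle.leg_alchemical_wet.dg_err or 0.0) ** 2
            + (cycle.leg_alchemical_dry.dg_err or 0.0) ** 2
            + cycle.leg_network_a.se**2
            + cycle.leg_network_b.se**2
        )
    )
    return abs(signed), err


def solvent_contribution(cycle: FreeEnergyCycle) -> tuple[float, float]:
    """dG_wet - dG_dry: the water network's net effect on the transformation.

    Positive values mean the network opposes the A -> B transformation (the
    change is less favorable with the waters present).  By the cycle identity
    this equals dG_net(B) - dG_net(A) up to the closure error.
    """
    d = cycle.leg_alchemical_wet.dg - cycle.leg_alchemical_dry.dg
    err = float(
        np.hypot(
            cycle.leg_alchemical_wet.dg_err or 0.0, cycle.leg_alchemical_dry.dg_err or 0.0
        )
    )
    return float(d), err


def relative_binding_free_energy(
    leg_bound: AlchemicalLeg, leg_solvent: AlchemicalLeg
) -> tuple[float, float]:
    """ddG_bind = dG_bound - dG_solvent for the same A -> B transformation."""
    if leg_bound.dg is None or leg_solvent.dg is None:
        raise ValueError("legs must be estimated first")
    if leg_solvent.environment != "bulk":
        raise ValueError("solvent leg must carry the 'bulk' environment tag")
    if len(leg_bound.lambdas) != len(leg_solvent.lambdas) or not np.allclose(
        leg_bound.lambdas, leg_solvent.lambdas
    ):
        raise ValueError("legs use different lambda ladders (different transformations?)")
    d = leg_bound.dg - leg_solvent.dg
    err = float(np.hypot(leg_bound.dg_err or 0.0, leg_solvent.dg_err or 0.0))
    return float(d), err


def render_cycle(cycle: FreeEnergyCycle) -> str:
    """Four-arrow text diagram with the closure error in the center box."""
    close, cerr = closure_error(cycle)
    wet, dry = cycle.leg_alchemical_wet, cycle.leg_alchemical_dry
    na, nb = cycle.leg_network_a, cycle.leg_network_b
    a, b = cycle.label_a, cycle.label_b
    lines = [
        f"              dG_wet = {wet.dg:+.2f} +/- {wet.dg_err:.2f} kcal/mol",
        f"  [{a}, wet] ----------------------------------------> [{b}, wet]",
        "      ^                                                    ^",
        f"      | dG_net({a}) = {na.dg:+.2f} +/- {na.se:.2f}"
        f"            | dG_net({b}) = {nb.dg:+.2f} +/- {nb.se:.2f}",
        f"      |              +------------------+                 |",
        f"      |              | closure = {close:5.2f}  |                 |",
        f"      |              |       +/- {cerr:5.2f}  |                 |",
        f"      |              +------------------+                 |",
        f"  [{a}, dry] ----------------------------------------> [{b}, dry]",
        f"              dG_dry = {dry.dg:+.2f} +/- {dry.dg_err:.2f} kcal/mol",
        f"  retained water set: n = {cycle.retained_n}",
        "  convention: closure = |dG_wet + dG_net(A) - dG_dry - dG_net(B)|",
    ]
    return "\n".join(lines)
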