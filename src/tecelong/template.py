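"""DNA template geometry and chromatin-barrier landscapes.

The experimental template stalls a ternary elongation complex (TEC) at
transcript position +58 by nucleotide deprivation; restart then drives RNA
synthesis to the template end at +231.  Downstream of the stall, a tandem
histone positioning sequence binds a row of histone dimers, each protecting
~30 bp of DNA.  Because the polymerase itself occludes ~20 bp ahead of the
RNA 3' end, the leading edge of the TEC first collides with chromatin when
the nascent RNA is ~70 nt long, and again every 30 nt thereafter
(~100, 130, 160, 190).

Coordinates throughout are 1-based transcript positions in nucleotides from
the transcription start site (the "+58 / +231" convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

__all__ = [
    "TemplateDesign",
    "ChromatinLandscape",
    "default_template",
    "barrier_encounter_positions",
    "make_landscape",
    "VARIANT_REGISTRY",
]


@dataclass(frozen=True)
class TemplateDesign:
    """Geometry of the transcription template.

    Parameters
    ----------
    stall_pos : int
        Transcript length (nt) of the stalled TEC; elongation restarts here.
    full_length : int
        Transcript length at the template end (absorbing state).
    hps_start : int
        Template coordinate (nt) where the first bound histone dimer begins.
    dimer_footprint : int
        DNA protected per histone dimer (nt); sets barrier periodicity.
    n_dimers : int
        Number of consecutively bound dimers downstream of the stall.
    rnap_footprint : int
        DNA occluded by the polymerase (nt); informational.
    leading_edge_offset : int
        Distance (nt) from the RNA 3'-end position to the RNAP leading edge.
        The first barrier encounter is at ``hps_start - leading_edge_offset``.
    """

    stall_pos: int = 58
    full_length: int = 231
    hps_start: int = 82
    dimer_footprint: int = 30
    n_dimers: int = 5
    rnap_footprint: int = 20
    leading_edge_offset: int = 12

    def __post_init__(self) -> None:
        if self.full_length <= self.stall_pos:
            raise ValueError("full_length must exceed stall_pos")
        if self.dimer_footprint <= 0:
            raise ValueError("dimer_footprint must be positive")
        if self.n_dimers < 0:
            raise ValueError("n_dimers must be non-negative")
        first = self.hps_start - self.leading_edge_offset
        if self.n_dimers > 0 and first <= self.stall_pos:
            raise ValueError(
                "first barrier encounter must lie downstream of the stall "
                f"(got {first} <= {self.stall_pos})"
            )

    @property
    def first_encounter(self) -> int:
        """Transcript position of the first TEC-chromatin collision."""
        return self.hps_start - self.leading_edge_offset

    @property
    def n_states(self) -> int:
        """Number of transcript lengths from the stall to the end, inclusive."""
        return self.full_length - self.stall_pos + 1

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TemplateDesign":
        return cls(**json.loads(text))


def default_template() -> TemplateDesign:
    """The study template: stall at +58, end at +231, five 30-nt barriers
    first encountered at +70."""
    return TemplateDesign()


def barrier_encounter_positions(template: TemplateDesign) -> list[int]:
    """Transcript positions at which the TEC leading edge meets a histone dimer.

    An arithmetic progression from the first encounter with step
    ``dimer_footprint``, one entry per bound dimer, clipped to the template
    end.  For the default template this is [70, 100, 130, 160, 190].
    """
    first = template.first_encounter
    positions = [
        first + i * template.dimer_footprint for i in range(template.n_dimers)
    ]
    return [p for p in positions if p <= template.full_length]


@dataclass(frozen=True)
class ChromatinLandscape:
    """Barrier positions with per-barrier strength multipliers.

    ``barrier_factors[i]`` (beta >= 1) divides the single-nucleotide addition
    rate at ``barrier_positions[i]``; beta = 1 means no effective barrier.
    """

    variant_name: str
    barrier_positions: tuple[int, ...]
    barrier_factors: tuple[float, ...]
    first_only: bool = True

    def __post_init__(self) -> None:
        if len(self.barrier_positions) != len(self.barrier_factors):
            raise ValueError(
                f"{len(self.barrier_factors)} barrier factors for "
                f"{len(self.barrier_positions)} positions"
            )
        if any(b <= 0 for b in self.barrier_factors):
            raise ValueError("barrier factors must be positive")
        if any(b < 1 for b in self.barrier_factors):
            raise ValueError("barrier factors must be >= 1 (1 = no barrier)")
        pos = self.barrier_positions
        if any(b >= a for b, a in zip(pos, pos[1:])):
            raise ValueError("barrier positions must be strictly increasing")

    def factor_at(self, position: int) -> float:
        """Barrier multiplier applying to the step *into* ``position``."""
        try:
            i = self.barrier_positions.index(position)
        except ValueError:
            return 1.0
        return self.barrier_factors[i]

    def to_json(self) -> str:
        return json.dumps(
            {
                "variant_name": self.variant_name,
                "barrier_positions": list(self.barrier_positions),
                "barrier_factors": list(self.barrier_factors),
                "first_only": self.first_only,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ChromatinLandscape":
        d = json.loads(text)
        return cls(
            variant_name=d["variant_name"],
            barrier_positions=tuple(d["barrier_positions"]),
            barrier_factors=tuple(d["barrier_factors"]),
            first_only=d.get("first_only", True),
        )


# Illustrative first-barrier strengths per histone variant, ordered by the
# qualitative elongation-rate ranking (histone-free fastest, the double
# charge-gain mutant slowest).  These are free parameters of the simulator,
# not measured quantities.
VARIANT_REGISTRY: dict[str, float] = {
    "HTkA-free": 1.0,
    "T55L": 15.0,
    "R20S": 18.0,
    "E3A": 20.0,
    "WT": 60.0,
    "G52K": 100.0,
    "E34A": 400.0,
    "G17D": 600.0,
    "E19K": 900.0,
    "E19K/G52K": 5000.0,
}


def make_landscape(
    template: TemplateDesign,
    variant_name: str,
    barrier_factors: float | Sequence[float] | None = None,
    first_only: bool = True,
) -> ChromatinLandscape:
    """Build a landscape for ``variant_name`` on ``template``.

    ``barrier_factors`` may be a scalar (applied to every barrier), a full
    list (one per encounter position), or None to use the registry default
    for a known variant.  With ``first_only`` (the default, reflecting the
    observation that only the first collision produces a substantial pause),
    factors beyond the first barrier are forced to 1.
    """
    positions = barrier_encounter_positions(template)
    if barrier_factors is None:
        if variant_name not in VARIANT_REGISTRY:
            raise KeyError(
                f"unknown variant {variant_name!r}; supply barrier_factors "
                f"or one of {sorted(VARIANT_REGISTRY)}"
            )
        barrier_factors = VARIANT_REGISTRY[variant_name]
    if isinstance(barrier_factors, (int, float)):
        factors = [float(barrier_factors)] * len(positions)
    else:
        factors = [float(b) for b in barrier_factors]
        if len(factors) != len(positions):
            raise ValueError(
                f"{len(factors)} barrier factors for {len(positions)} "
                "encounter positions"
            )
    if any(b <= 0 for b in factors):
        raise ValueError("barrier factors must be positive")
    if first_only:
        factors = [factors[0]] + [1.0] * (len(factors) - 1) if factors else []
    return ChromatinLandscape(
        variant_name=variant_name,
        barrier_positions=tuple(positions),
        barrier_factors=tuple(factors),
        first_only=first_only,
    )
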