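"""Report record model and controlled vocabularies.

A :class:`ReportRecord` is one community-verified observation of a large
carnivore (brown bear or grey wolf) in or near a built-up area: species,
timestamp, WGS84 location, one of six exclusive behavioural event types,
the set of potential attractants recorded within 100 m, whether a foraging
attempt succeeded, and whether a person was present outdoors.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import FrozenSet, Optional

SPECIES = ("bear", "wolf")

EVENT_TYPES = (
    "depredation_domestic",   # killing/injuring livestock or companion animals
    "beehive_damage",
    "property_damage",
    "foraging_anthropogenic",
    "foraging_natural",
    "other",
)

ATTRACTANTS = (
    "livestock",
    "beehives",
    "fruit_trees_shrubs",
    "wild_ungulates",
    "dogs",
    "waste",
)

FORAGING_SUCCESS = ("success", "failure", "not_applicable")


class ValidationError(ValueError):
    """A record field violates the controlled vocabulary or invariants."""


@dataclass(frozen=True)
class ReportRecord:
    record_id: str
    species: str
    timestamp: dt.datetime          # timezone-aware
    lon: float
    lat: float
    event_type: str
    attractants: FrozenSet[str] = field(default_factory=frozenset)
    foraging_success: str = "not_applicable"
    human_present: bool = False
    municipality_id: Optional[str] = None

    def validate(self) -> "ReportRecord":
        if self.species not in SPECIES:
            raise ValidationError(f"unknown species {self.species!r}")
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event_type {self.event_type!r}")
        unknown = set(self.attractants) - set(ATTRACTANTS)
        if unknown:
            raise ValidationError(f"unknown attractants {sorted(unknown)!r}")
        if self.foraging_success not in FORAGING_SUCCESS:
            raise ValidationError(
                f"unknown foraging_success {self.foraging_success!r}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"lon {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"lat {self.lat} outside [-90, 90]")
        if self.timestamp.tzinfo is None:
            raise ValidationError("timestamp must carry a UTC offset")
        # success/failure is only meaningful where a food-attractant
        # context was recorded; without attractants it must be N/A
        if not self.attractants and self.foraging_success != "not_applicable":
            raise ValidationError(
                "foraging_success must be not_applicable when no attractant "
                "context is recorded")
        return self
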