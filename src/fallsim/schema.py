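"""Structure of the six-state fall-prevention microsimulation model.

The model's health states are care *settings* — the only way to keep states
mutually exclusive and exhaustive when the same person can simultaneously
have, say, a hip fracture and be hospitalized.  Clinical detail lives in
*tracked events* recorded on each individual's history (falls, specific
injuries, ED visits, hip-fracture surgery), which a microsimulation can
carry without multiplying states.

Six settings: community, residential aged care, hospital, rehabilitation
hospital, death due to a fall, and death from any other cause.  The two
death states are absorbing and kept distinct for reporting.  Admission to
hospital from a living setting is gated on an emergency-department visit in
the same cycle, mirroring how community-dwelling older adults enter acute
care after a fall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml

__all__ = [
    "Setting",
    "InjuryType",
    "EventKind",
    "TrackedEvent",
    "AttributeDescriptor",
    "AttributeRegistry",
    "TransitionTopology",
    "ModelSchema",
    "default_schema",
    "validate_schema",
    "allowed_transitions",
    "incorporation_report",
    "TABLE6_INCLUDED_ITEMS",
    "EXPECTED_ATTRIBUTE_COUNT",
]


class Setting(str, Enum):
    """Mutually exclusive, exhaustive care settings (the model states)."""

    COMMUNITY = "COMMUNITY"
    RESIDENTIAL_AGED_CARE = "RESIDENTIAL_AGED_CARE"
    HOSPITAL = "HOSPITAL"
    REHAB_HOSPITAL = "REHAB_HOSPITAL"
    DEATH_FALL = "DEATH_FALL"
    DEATH_OTHER = "DEATH_OTHER"


ABSORBING_SETTINGS = frozenset({Setting.DEATH_FALL, Setting.DEATH_OTHER})
LIVING_SETTINGS = tuple(s for s in Setting if s not in ABSORBING_SETTINGS)


class InjuryType(str, Enum):
    """Injury sustained in a fall; at most one per fall.

    HEAD_INJURY denotes an intracranial bleed specifically.  MODERATE covers
    dislocations and fractures not otherwise listed; MINOR covers soft-tissue
    injuries (cuts, scrapes, bruises, sprains).
    """

    HIP_FRACTURE = "HIP_FRACTURE"
    VERTEBRAL_FRACTURE = "VERTEBRAL_FRACTURE"
    WRIST_FRACTURE = "WRIST_FRACTURE"
    HEAD_INJURY = "HEAD_INJURY"
    MODERATE = "MODERATE"
    MINOR = "MINOR"
    NONE = "NONE"

    @property
    def severity_rank(self) -> int:
        return _SEVERITY_RANK[self]


_SEVERITY_RANK = {
    InjuryType.HEAD_INJURY: 0,
    InjuryType.HIP_FRACTURE: 1,
    InjuryType.VERTEBRAL_FRACTURE: 2,
    InjuryType.WRIST_FRACTURE: 3,
    InjuryType.MODERATE: 4,
    InjuryType.MINOR: 5,
    InjuryType.NONE: 6,
}


class EventKind(str, Enum):
    """Tracked events plus bookkeeping events recorded on history."""

    FALL = "FALL"
    INJURY = "INJURY"
    ED_VISIT = "ED_VISIT"
    HOSPITAL_ADMISSION = "HOSPITAL_ADMISSION"
    HIP_SURGERY = "HIP_SURGERY"
    REHAB_ADMISSION = "REHAB_ADMISSION"
    RELOCATION = "RELOCATION"
    DEATH = "DEATH"


@dataclass(frozen=True)
class TrackedEvent:
    event_kind: EventKind
    cycle_index: int
    detail: str = ""

    def __post_init__(self) -> None:
        if self.cycle_index < 0:
            raise ValueError("cycle_index must be >= 0")


@dataclass(frozen=True)
class AttributeDescriptor:
    id: str
    label: str
    value_kind: str = "binary"  # binary | count | continuous
    modeled: bool = False

    def __post_init__(self) -> None:
        if self.value_kind not in ("binary", "count", "continuous"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")


EXPECTED_ATTRIBUTE_COUNT = 26

# The 26 patient attributes on which the expert panel reached high
# agreement across both survey rounds.  Value kinds default to binary
# flags; age is continuous and polypharmacy a medication count.
_DEFAULT_ATTRIBUTES: tuple[tuple[str, str, str, bool], ...] = (
    ("gait_balance_mobility", "Gait, balance, or mobility difficulties", "binary", True),
    ("history_of_falls", "History of falls/previous falls", "binary", True),
    ("impaired_vision", "Impaired vision", "binary", False),
    ("older_age", "Age, older age", "continuous", True),
    ("dementia_biological", "Dementia/cognitive impairment (biological factor)", "binary", True),
    ("physical_inactivity", "Physical inactivity", "binary", False),
    ("fear_of_falling_attr", "Fear of falling", "binary", False),
    ("substance_use", "Substance use", "binary", False),
    ("certain_medications", "Use of certain medications", "binary", True),
    ("transfer_assistance", "Need for transfer assistance", "binary", False),
    ("home_hazards", "Home hazards", "binary", False),
    ("use_of_restraints", "Use of restraints", "binary", False),
    ("frailty", "Overall frailty, older age", "binary", True),
    ("parkinsons", "Parkinson's disease", "binary", False),
    ("stroke", "Stroke", "binary", False),
    ("dementia_condition", "Dementia/cognitive impairment (health condition)", "binary", False),
    ("multiple_sclerosis", "Multiple sclerosis", "binary", False),
    ("osteoporosis", "Osteoporosis", "binary", False),
    ("incorrect_assistive_device_use", "Incorrect use of assistive devices", "binary", False),
    ("unsupportive_footwear", "Wearing unsupportive footwear", "binary", False),
    ("polypharmacy", "Polypharmacy", "count", True),
    ("prolonged_hospital_stay", "Prolonged hospital stay", "binary", False),
    ("cannot_afford_footwear", "Unable to afford supportive footwear", "binary", False),
    ("social_isolation", "No social supports, isolated", "binary", False),
    ("cannot_afford_medications", "Unable to afford certain medications, nutritious food", "binary", False),
    ("psychiatric_illness", "Psychiatric illness (including depression)", "binary", False),
)


@dataclass
class AttributeRegistry:
    attributes: tuple[AttributeDescriptor, ...]

    @classmethod
    def default(cls) -> "AttributeRegistry":
        return cls(
            attributes=tuple(
                AttributeDescriptor(*row) for row in _DEFAULT_ATTRIBUTES
            )
        )

    def ids(self) -> list[str]:
        return [a.id for a in self.attributes]

    def __len__(self) -> int:
        return len(self.attributes)

    def __getitem__(self, attr_id: str) -> AttributeDescriptor:
        for a in self.attributes:
            if a.id == attr_id:
                return a
        raise KeyError(attr_id)


@dataclass
class TransitionTopology:
    """Directed adjacency over settings plus within-cycle pathway rules."""

    edges: dict[Setting, frozenset[Setting]]
    ed_gated: frozenset[Setting] = frozenset(
        {Setting.COMMUNITY, Setting.RESIDENTIAL_AGED_CARE}
    )  # settings from which HOSPITAL entry requires a same-cycle ED visit
    fall_settings: frozenset[Setting] = frozenset(
        {Setting.COMMUNITY, Setting.RESIDENTIAL_AGED_CARE}
    )

    @classmethod
    def default(cls) -> "TransitionTopology":
        deaths = {Setting.DEATH_FALL, Setting.DEATH_OTHER}
        edges = {
            Setting.COMMUNITY: frozenset(
                {Setting.RESIDENTIAL_AGED_CARE, Setting.HOSPITAL} | deaths
            ),
            Setting.RESIDENTIAL_AGED_CARE: frozenset(
                {Setting.COMMUNITY, Setting.HOSPITAL} | deaths
            ),
            Setting.HOSPITAL: frozenset(
                {Setting.REHAB_HOSPITAL, Setting.COMMUNITY,
                 Setting.RESIDENTIAL_AGED_CARE} | deaths
            ),
            Setting.REHAB_HOSPITAL: frozenset(
                {Setting.COMMUNITY, Setting.RESIDENTIAL_AGED_CARE} | deaths
            ),
            Setting.DEATH_FALL: frozenset(),
            Setting.DEATH_OTHER: frozenset(),
        }
        return cls(edges=edges)


@dataclass
class ModelSchema:
    settings: tuple[Setting, ...]
    injury_types: tuple[InjuryType, ...]
    event_kinds: tuple[EventKind, ...]
    attributes: AttributeRegistry
    topology: TransitionTopology

    @classmethod
    def default(cls) -> "ModelSchema":
        return cls(
            settings=tuple(Setting),
            injury_types=tuple(InjuryType),
            event_kinds=tuple(EventKind),
            attributes=AttributeRegistry.default(),
            topology=TransitionTopology.default(),
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "settings": [s.value for s in self.settings],
            "injury_types": [i.value for i in self.injury_types],
            "event_kinds": [e.value for e in self.event_kinds],
            "attributes": [
                {"id": a.id, "label": a.label, "value_kind": a.value_kind,
                 "modeled": a.modeled}
                for a in self.attributes.attributes
            ],
            "topology": {
                "edges": {
                    s.value: sorted(t.value for t in targets)
                    for s, targets in self.topology.edges.items()
                },
                "ed_gated": sorted(s.value for s in self.topology.ed_gated),
                "fall_settings": sorted(s.value for s in self.topology.fall_settings),
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSchema":
        topo = data["topology"]
        return cls(
            settings=tuple(Setting(s) for s in data["settings"]),
            injury_types=tuple(InjuryType(i) for i in data["injury_types"]),
            event_kinds=tuple(EventKind(e) for e in data["event_kinds"]),
            attributes=AttributeRegistry(
                attributes=tuple(
                    AttributeDescriptor(
                        id=a["id"], label=a["label"],
                        value_kind=a["value_kind"], modeled=a["modeled"],
                    )
                    for a in data["attributes"]
                )
            ),
            topology=TransitionTopology(
                edges={
                    Setting(s): frozenset(Setting(t) for t in targets)
                    for s, targets in topo["edges"].items()
                },
                ed_gated=frozenset(Setting(s) for s in topo["ed_gated"]),
                fall_settings=frozenset(Setting(s) for s in topo["fall_settings"]),
            ),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ModelSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_schema() -> ModelSchema:
    return ModelSchema.default()


def validate_schema(schema: ModelSchema) -> list[str]:
    """Check all structural invariants; violations are returned, not raised."""
    violations: list[str] = []
    if set(schema.settings) != set(Setting) or len(schema.settings) != 6:
        violations.append("settings must be exactly the 6 canonical settings")
    if set(schema.injury_types) != set(InjuryType):
        violations.append("injury taxonomy must cover all injury types exactly once")
    if set(schema.event_kinds) != set(EventKind):
        violations.append("event kinds must cover all tracked/bookkeeping events")
    if len(schema.attributes) != EXPECTED_ATTRIBUTE_COUNT:
        violations.append(
            f"attribute registry size != {EXPECTED_ATTRIBUTE_COUNT} "
            f"(got {len(schema.attributes)})"
        )
    ids = schema.attributes.ids()
    if len(set(ids)) != len(ids):
        violations.append("duplicate attribute ids")

    edges = schema.topology.edges
    for setting in Setting:
        if setting not in edges:
            violations.append(f"no adjacency entry for {setting.value}")
    for dead in ABSORBING_SETTINGS:
        if edges.get(dead):
            violations.append(
                f"absorbing state has outgoing edge: {dead.value}"
            )
    for src, targets in edges.items():
        if src in targets:
            violations.append(f"self-loop edge on {src.value}")
    # rehab only reachable from hospital
    for src, targets in edges.items():
        if Setting.REHAB_HOSPITAL in targets and src != Setting.HOSPITAL:
            violations.append(
                f"REHAB_HOSPITAL entered from {src.value}, must be HOSPITAL only"
            )
    # hospital entry from living settings must be ED-gated
    for src, targets in edges.items():
        if Setting.HOSPITAL in targets and src not in schema.topology.ed_gated:
            violations.append(
                f"HOSPITAL entry from {src.value} is not ED-gated"
            )
    # discharge destinations from inpatient settings
    for src in (Setting.HOSPITAL, Setting.REHAB_HOSPITAL):
        targets = edges.get(src, frozenset())
        living_targets = targets - ABSORBING_SETTINGS - {Setting.REHAB_HOSPITAL}
        bad = living_targets - {Setting.COMMUNITY, Setting.RESIDENTIAL_AGED_CARE}
        if bad:
            violations.append(
                f"{src.value} discharges to {sorted(s.value for s in bad)}; "
                "must be COMMUNITY or RESIDENTIAL_AGED_CARE"
            )
    return violations


def allowed_transitions(
    setting: Setting, topology: TransitionTopology | None = None
) -> frozenset[Setting]:
    """Successor settings reachable from ``setting`` in one cycle."""
    topology = topology or TransitionTopology.default()
    setting = Setting(setting)
    if setting not in topology.edges:
        raise KeyError(f"unknown setting {setting!r}")
    return topology.edges[setting]


# ---------------------------------------------------------------------------
# Mapping the consensus item set onto the model structure

# The 14 health states/events the panel selected across both rounds, and the
# role each plays in the model.  Five become setting states, seven become
# tracked events (12 incorporated).  "Post-fall" is folded into event
# history (a recent-fall recency flag rather than a state); specialized
# dementia care is folded into the community setting and so not separately
# incorporated.
_ITEM_ROLES: dict[str, tuple[str, str]] = {
    "independent_housing": ("state", Setting.COMMUNITY.value),
    "long_term_care": ("state", Setting.RESIDENTIAL_AGED_CARE.value),
    "hospitalization": ("state", Setting.HOSPITAL.value),
    "rehab_hospitalization": ("state", Setting.REHAB_HOSPITAL.value),
    "death_due_to_fall": ("state", Setting.DEATH_FALL.value),
    "fall": ("tracked_event", EventKind.FALL.value),
    "hip_fracture": ("tracked_event", InjuryType.HIP_FRACTURE.value),
    "vertebral_fracture": ("tracked_event", InjuryType.VERTEBRAL_FRACTURE.value),
    "wrist_fracture": ("tracked_event", InjuryType.WRIST_FRACTURE.value),
    "head_injury": ("tracked_event", InjuryType.HEAD_INJURY.value),
    "hip_fracture_surgery": ("tracked_event", EventKind.HIP_SURGERY.value),
    "ed_visit": ("tracked_event", EventKind.ED_VISIT.value),
    "post_fall": ("folded", "recent-fall recency flag on event history"),
    "specialized_dementia_care": ("excluded", "folded into COMMUNITY setting"),
}

TABLE6_INCLUDED_ITEMS = frozenset(_ITEM_ROLES)


def incorporation_report(
    included_items: set[str], schema: ModelSchema | None = None
) -> dict:
    """Map consensus-included items onto their role in the model structure.

    Returns per-item roles plus counts, including the headline count of
    items incorporated as either a state or a tracked event.
    """
    roles: dict[str, dict[str, str]] = {}
    counts = {"state": 0, "tracked_event": 0, "folded": 0, "excluded": 0,
              "unknown": 0}
    for item in sorted(included_items):
        if item in _ITEM_ROLES:
            role, target = _ITEM_ROLES[item]
        else:
            role, target = "unknown", ""
        roles[item] = {"role": role, "maps_to": target}
        counts[role] += 1
    counts["incorporated"] = counts["state"] + counts["tracked_event"]
    return {"items": roles, "counts": counts}
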