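"""Disease-attribute taxonomy for the sickle cell disease model.

The model tracks four parallel dimensions of disease — chronic pain, acute
events, chronic disorders, and treatment complications.  Acute events are
instantaneous within a model cycle; subacute disorders can remit (claims-side
presence requires a qualifying claim within a two-year lookback); chronic
disorders are absorbing.  The default registry ships 13 acute events and 13
chronic disorders (7 subacute including chronic pain, 6 chronic), 26 disease
conditions in total, plus the complication attributes associated with
hydroxyurea, transfusion, transplant, and gene therapy.

Chronic pain is stored alongside the other attributes but carries its own
dimension tag so the simulator can evaluate it in parallel with everything
else, and so the 26-condition disease set still partitions cleanly into
dimensions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "Dimension",
    "Persistence",
    "DiseaseAttribute",
    "CaseDefinition",
    "AttributeRegistry",
    "load_registry",
    "save_registry",
    "default_registry",
    "normalize_code",
]


class Dimension(str, enum.Enum):
    CHRONIC_PAIN = "chronic_pain"
    ACUTE_EVENT = "acute_event"
    CHRONIC_DISORDER = "chronic_disorder"
    TREATMENT_COMPLICATION = "treatment_complication"


class Persistence(str, enum.Enum):
    INSTANTANEOUS = "instantaneous"
    SUBACUTE = "subacute"
    CHRONIC = "chronic"


class Edition(str, enum.Enum):
    ICD9 = "icd9"
    ICD10 = "icd10"


def normalize_code(code: str) -> str:
    """Normalize an ICD code: strip dots and whitespace, uppercase."""
    return code.replace(".", "").strip().upper()


@dataclass(frozen=True)
class DiseaseAttribute:
    """One condition tracked by the model.

    ``severity_marker`` flags attributes whose history counts toward the
    "severe SCD" eligibility rule for curative therapy.
    """

    name: str
    dimension: Dimension
    persistence: Persistence
    icd9_codes: frozenset[str] = frozenset()
    icd10_codes: frozenset[str] = frozenset()
    severity_marker: bool = False

    def __post_init__(self) -> None:
        if (self.persistence is Persistence.INSTANTANEOUS) != (
            self.dimension is Dimension.ACUTE_EVENT
        ):
            raise ValueError(
                f"attribute {self.name!r}: persistence must be instantaneous "
                f"iff dimension is acute_event (got {self.dimension.value}/"
                f"{self.persistence.value})"
            )
        if self.dimension is Dimension.CHRONIC_PAIN and (
            self.persistence is not Persistence.SUBACUTE
        ):
            raise ValueError("the chronic-pain attribute must be subacute")

    def codes(self, edition: Edition | str) -> frozenset[str]:
        edition = Edition(edition)
        return self.icd9_codes if edition is Edition.ICD9 else self.icd10_codes

    def matches(self, code: str, edition: Edition | str) -> bool:
        """Prefix match of a normalized claim code against this attribute."""
        norm = normalize_code(code)
        return any(norm.startswith(normalize_code(c)) for c in self.codes(edition))


@dataclass(frozen=True)
class CaseDefinition:
    """Inclusion/exclusion code stems defining an SCD case.

    Matching is prefix-based on normalized codes with exclusions applied
    after inclusions, so a stem such as ``D57`` covers its children while the
    sickle cell trait codes remain excluded.
    """

    icd9_include: frozenset[str]
    icd9_exclude: frozenset[str]
    icd10_include: frozenset[str]
    icd10_exclude: frozenset[str]

    def is_scd_code(self, code: str, edition: Edition | str) -> bool:
        if not code:
            raise ValueError("empty code")
        edition = Edition(edition)
        norm = normalize_code(code)
        if edition is Edition.ICD9:
            include, exclude = self.icd9_include, self.icd9_exclude
        else:
            include, exclude = self.icd10_include, self.icd10_exclude
        if not any(norm.startswith(normalize_code(c)) for c in include):
            return False
        return not any(norm.startswith(normalize_code(c)) for c in exclude)


@dataclass
class AttributeRegistry:
    """The attribute taxonomy plus per-therapy complication sets."""

    attributes: dict[str, DiseaseAttribute]
    therapy_complications: dict[str, frozenset[str]]
    case_definition: CaseDefinition
    source: dict = field(default_factory=dict, repr=False)

    # -- views ---------------------------------------------------------
    def by_dimension(self, dimension: Dimension | str) -> list[DiseaseAttribute]:
        dimension = Dimension(dimension)
        return [a for a in self.attributes.values() if a.dimension is dimension]

    @property
    def disease_attributes(self) -> list[DiseaseAttribute]:
        """The disease conditions (everything except therapy complications)."""
        return [
            a
            for a in self.attributes.values()
            if a.dimension is not Dimension.TREATMENT_COMPLICATION
        ]

    @property
    def complication_attributes(self) -> list[DiseaseAttribute]:
        return self.by_dimension(Dimension.TREATMENT_COMPLICATION)

    @property
    def acute_events(self) -> list[DiseaseAttribute]:
        return self.by_dimension(Dimension.ACUTE_EVENT)

    @property
    def subacute_disorders(self) -> list[DiseaseAttribute]:
        """Subacute disease attributes, chronic pain included."""
        return [
            a
            for a in self.disease_attributes
            if a.persistence is Persistence.SUBACUTE
        ]

    @property
    def chronic_disorders(self) -> list[DiseaseAttribute]:
        return [
            a
            for a in self.disease_attributes
            if a.persistence is Persistence.CHRONIC
        ]

    @property
    def severity_markers(self) -> frozenset[str]:
        return frozenset(
            a.name for a in self.attributes.values() if a.severity_marker
        )

    def is_scd_code(self, code: str, edition: Edition | str) -> bool:
        return self.case_definition.is_scd_code(code, edition)

    def attribute_for_code(self, code: str, edition: Edition | str) -> str | None:
        """Name of the first attribute (registry order) matching a claim code."""
        for a in self.attributes.values():
            if a.matches(code, edition):
                return a.name
        return None

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        names = list(self.attributes)
        if len(names) != len(set(names)):
            raise ValueError("duplicate attribute names")
        for therapy, comp_names in self.therapy_complications.items():
            missing = set(comp_names) - set(names)
            if missing:
                raise ValueError(
                    f"therapy {therapy!r} references undefined attributes: "
                    f"{sorted(missing)}"
                )
        # attribute codes must never collide with the trait exclusion stems
        for a in self.attributes.values():
            for code in a.icd9_codes:
                if any(
                    normalize_code(code).startswith(normalize_code(x))
                    for x in self.case_definition.icd9_exclude
                ):
                    raise ValueError(f"{a.name}: code {code} is a trait code")
            for code in a.icd10_codes:
                if any(
                    normalize_code(code).startswith(normalize_code(x))
                    for x in self.case_definition.icd10_exclude
                ):
                    raise ValueError(f"{a.name}: code {code} is a trait code")


# ---------------------------------------------------------------------------
# loading / saving


def _parse_attribute(entry: Mapping) -> DiseaseAttribute:
    try:
        dimension = Dimension(entry["dimension"])
    except ValueError:
        raise ValueError(f"unknown dimension {entry.get('dimension')!r}") from None
    try:
        persistence = Persistence(entry["persistence"])
    except ValueError:
        raise ValueError(
            f"unknown persistence {entry.get('persistence')!r}"
        ) from None
    return DiseaseAttribute(
        name=entry["name"],
        dimension=dimension,
        persistence=persistence,
        icd9_codes=frozenset(entry.get("icd9", ())),
        icd10_codes=frozenset(entry.get("icd10", ())),
        severity_marker=bool(entry.get("severity_marker", False)),
    )


def load_registry(source: str | Path | Mapping | None = None) -> AttributeRegistry:
    """Build a validated registry from a YAML file, a mapping, or the default.

    Raises ``ValueError`` on duplicate attribute names, unknown dimension or
    persistence values, or a therapy set referencing an undefined attribute.
    """
    if source is None:
        ref = resources.files("scdsim.data") / "default_registry.yaml"
        spec = yaml.safe_load(ref.read_text())
    elif isinstance(source, Mapping):
        spec = source
    else:
        spec = yaml.safe_load(Path(source).read_text())

    attributes: dict[str, DiseaseAttribute] = {}
    for entry in spec["attributes"]:
        attr = _parse_attribute(entry)
        if attr.name in attributes:
            raise ValueError(f"duplicate attribute name {attr.name!r}")
        attributes[attr.name] = attr

    therapies = {
        therapy: frozenset(names)
        for therapy, names in (spec.get("therapies") or {}).items()
    }

    cd = spec["scd_case_definition"]
    case_definition = CaseDefinition(
        icd9_include=frozenset(cd["icd9"]["include"]),
        icd9_exclude=frozenset(cd["icd9"].get("exclude", ())),
        icd10_include=frozenset(cd["icd10"]["include"]),
        icd10_exclude=frozenset(cd["icd10"].get("exclude", ())),
    )

    registry = AttributeRegistry(
        attributes=attributes,
        therapy_complications=therapies,
        case_definition=case_definition,
        source=dict(spec),
    )
    registry.validate()
    return registry


def save_registry(registry: AttributeRegistry, path: str | Path) -> None:
    """Write a registry back to YAML so that load(save(r)) == r."""
    spec = {
        "attributes": [
            {
                "name": a.name,
                "dimension": a.dimension.value,
                "persistence": a.persistence.value,
                "icd9": sorted(a.icd9_codes),
                "icd10": sorted(a.icd10_codes),
                "severity_marker": a.severity_marker,
            }
            for a in registry.attributes.values()
        ],
        "therapies": {
            t: sorted(names)
            for t, names in registry.therapy_complications.items()
        },
        "scd_case_definition": {
            "icd9": {
                "include": sorted(registry.case_definition.icd9_include),
                "exclude": sorted(registry.case_definition.icd9_exclude),
            },
            "icd10": {
                "include": sorted(registry.case_definition.icd10_include),
                "exclude": sorted(registry.case_definition.icd10_exclude),
            },
        },
    }
    Path(path).write_text(yaml.safe_dump(spec, sort_keys=False))


def default_registry() -> AttributeRegistry:
    return load_registry(None)
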