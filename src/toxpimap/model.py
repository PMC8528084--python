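"""ToxPi model definition: domains, slices, weights, component membership.

A ToxPi model is the analysis recipe. Heterogeneous indicators (components)
are grouped into *slices* — the sectors of the radar glyph — and slices are
grouped into *domains* (color families). Each slice carries a positive
weight ``w_i`` that sets both its contribution to the overall score and its
angular width in the glyph; each component carries a scaling direction and a
within-slice weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from .errors import ConfigurationError


class Direction(str, Enum):
    """Whether larger raw values mean more of the hazard being indexed."""

    HIGHER_IS_WORSE = "higher_is_worse"
    LOWER_IS_WORSE = "lower_is_worse"


@dataclass(frozen=True)
class ComponentDefinition:
    name: str
    direction: Direction = Direction.HIGHER_IS_WORSE
    weight: float = 1.0  # weight within the slice

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))
        if self.weight <= 0:
            raise ConfigurationError(
                f"component {self.name!r}: within-slice weight must be > 0"
            )


@dataclass(frozen=True)
class SliceDefinition:
    name: str
    domain: str
    weight: float
    color: str
    components: tuple[ComponentDefinition, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if self.weight <= 0:
            raise ConfigurationError(f"slice {self.name!r}: weight must be > 0")
        if not self.components:
            raise ConfigurationError(f"slice {self.name!r} has no components")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ConfigurationError(
                f"slice {self.name!r}: duplicate component names"
            )


@dataclass(frozen=True)
class ToxPiModel:
    """An ordered collection of slices; validates global uniqueness."""

    name: str
    slices: tuple[SliceDefinition, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "slices", tuple(self.slices))
        if not self.slices:
            raise ConfigurationError("model must define at least one slice")
        snames = [s.name for s in self.slices]
        if len(set(snames)) != len(snames):
            raise ConfigurationError("slice names must be unique within a model")
        seen: dict[str, str] = {}
        for s in self.slices:
            for c in s.components:
                if c.name in seen:
                    raise ConfigurationError(
                        f"component {c.name!r} appears in slices "
                        f"{seen[c.name]!r} and {s.name!r}; membership must be unique"
                    )
                seen[c.name] = s.name

    # -- derived views ---------------------------------------------------
    @property
    def slice_names(self) -> list[str]:
        return [s.name for s in self.slices]

    @property
    def domains(self) -> list[str]:
        """Distinct domain names in first-appearance order."""
        out: list[str] = []
        for s in self.slices:
            if s.domain not in out:
                out.append(s.domain)
        return out

    @property
    def weights(self) -> list[float]:
        return [s.weight for s in self.slices]

    @property
    def component_names(self) -> list[str]:
        return [c.name for s in self.slices for c in s.components]

    def subset(self, slice_names: Iterable[str]) -> "ToxPiModel":
        """Model restricted to the named slices (original order kept)."""
        wanted = list(slice_names)
        unknown = sorted(set(wanted) - set(self.slice_names))
        if unknown:
            raise ConfigurationError(f"unknown slice names: {unknown}")
        kept = tuple(s for s in self.slices if s.name in set(wanted))
        return ToxPiModel(name=f"{self.name}[subset]", slices=kept)

    # -- (de)serialization -----------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "ToxPiModel":
        try:
            slices = tuple(
                SliceDefinition(
                    name=s["name"],
                    domain=s["domain"],
                    weight=float(s["weight"]),
                    color=s.get("color", "#808080"),
                    components=tuple(
                        ComponentDefinition(
                            name=c["name"],
                            direction=Direction(c.get("direction", "higher_is_worse")),
                            weight=float(c.get("weight", 1.0)),
                        )
                        for c in s["components"]
                    ),
                )
                for s in data["slices"]
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"malformed model definition: {exc}") from exc
        return cls(name=data.get("name", "unnamed"), slices=slices)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "slices": [
                {
                    "name": s.name,
                    "domain": s.domain,
                    "weight": s.weight,
                    "color": s.color,
                    "components": [
                        {"name": c.name, "direction": c.direction.value, "weight": c.weight}
                        for c in s.components
                    ],
                }
                for s in self.slices
            ],
        }

    @classmethod
    def from_json(cls, path) -> "ToxPiModel":
        try:
            data = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"model file {path}: invalid JSON: {exc}") from exc
        return cls.from_dict(data)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
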