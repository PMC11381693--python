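"""Condition registry: the catalogue of long-term conditions (LTC).

The default registry packages 53 LTC categories covering cardiovascular,
respiratory, neurological, psychiatric, musculoskeletal, cancer and other
chronic diagnoses. One condition (endometriosis) is structurally restricted to
women. The registry is data, not code: users may supply their own JSON file
with the same schema to analyse an alternative condition list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

DEFAULT_REGISTRY_SIZE = 53


class RegistrySchemaError(ValueError):
    """Raised when a registry file violates the registry schema."""


@dataclass(frozen=True)
class ConditionDef:
    """A single long-term condition category."""

    condition_id: str
    display_name: str
    sex_restricted: Optional[Literal["female", "male"]] = None


@dataclass(frozen=True)
class ConditionRegistry:
    """Ordered collection of :class:`ConditionDef` entries.

    Order is meaningful: it fixes the feature order of the tree learner and
    the deterministic tie-breaks used throughout the pipeline.
    """

    entries: tuple[ConditionDef, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [e.condition_id for e in self.entries]
        dupes = {c for c in ids if ids.count(c) > 1}
        if dupes:
            raise RegistrySchemaError(
                f"duplicate condition_id values: {sorted(dupes)}"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def condition_ids(self) -> list[str]:
        return [e.condition_id for e in self.entries]

    def index_of(self, condition_id: str) -> int:
        """Registry position of a condition (used for deterministic tie-breaks)."""
        try:
            return self.condition_ids.index(condition_id)
        except ValueError:
            raise KeyError(f"unknown condition_id: {condition_id!r}") from None

    def __getitem__(self, condition_id: str) -> ConditionDef:
        return self.entries[self.index_of(condition_id)]

    def __contains__(self, condition_id: str) -> bool:
        return condition_id in self.condition_ids

    def restricted_ids(self, sex: str) -> list[str]:
        """Conditions that cannot occur for the given sex ('F' or 'M')."""
        excluded = "female" if sex == "M" else "male"
        return [e.condition_id for e in self.entries if e.sex_restricted == excluded]

    def drop(self, condition_id: str) -> "ConditionRegistry":
        """Registry view without one condition (used by sensitivity analyses)."""
        if condition_id not in self:
            raise KeyError(f"unknown condition_id: {condition_id!r}")
        return ConditionRegistry(
            tuple(e for e in self.entries if e.condition_id != condition_id)
        )

    def sorted_conditions(self, conditions: Sequence[str]) -> tuple[str, ...]:
        """Sort a condition set into registry order."""
        return tuple(sorted(conditions, key=self.index_of))


def _parse_entries(raw: list) -> tuple[ConditionDef, ...]:
    entries = []
    for item in raw:
        if not isinstance(item, dict):
            raise RegistrySchemaError(f"registry entry is not an object: {item!r}")
        missing = {"condition_id", "display_name"} - set(item)
        if missing:
            raise RegistrySchemaError(f"registry entry missing keys {missing}: {item!r}")
        sr = item.get("sex_restricted")
        if sr not in (None, "female", "male"):
            raise RegistrySchemaError(f"invalid sex_restricted value: {sr!r}")
        entries.append(
            ConditionDef(
                condition_id=str(item["condition_id"]),
                display_name=str(item["display_name"]),
                sex_restricted=sr,
            )
        )
    return tuple(entries)


def load_registry(
    path: Union[str, Path, None] = None, *, allow_any_size: bool = False
) -> ConditionRegistry:
    """Load a condition registry from JSON.

    Parameters
    ----------
    path:
        Path to a registry JSON file (a list of
        ``{"condition_id", "display_name", "sex_restricted"}`` objects).
        ``None`` loads the packaged 53-condition default.
    allow_any_size:
        The packaged analysis expects exactly 53 conditions; a user registry
        of a different size is accepted only with this explicit override.
    """
    if path is None:
        raw = json.loads(
            resources.files("ltcmine.data").joinpath("registry.json").read_text()
        )
    else:
        raw = json.loads(Path(path).read_text())
    registry = ConditionRegistry(_parse_entries(raw))
    if len(registry) != DEFAULT_REGISTRY_SIZE and not allow_any_size:
        raise RegistrySchemaError(
            f"registry has {len(registry)} entries, expected "
            f"{DEFAULT_REGISTRY_SIZE}; pass allow_any_size=True to accept"
        )
    return registry


def save_registry(registry: ConditionRegistry, path: Union[str, Path]) -> None:
    """Write a registry back to JSON (round-trips with :func:`load_registry`)."""
    payload = [
        {
            "condition_id": e.condition_id,
            "display_name": e.display_name,
            "sex_restricted": e.sex_restricted,
        }
        for e in registry
    ]
    Path(path).write_text(json.dumps(payload, indent=1))
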