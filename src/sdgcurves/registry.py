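"""Indicator registry: the WHO health-related SDG indicator set.

The built-in registry holds the 38 health-related SDG indicators monitored on
the WHO platform, grouped into seven health themes, each with a direction of
improvement (``+1`` when higher values are better, e.g. service coverage;
``-1`` when lower values are better, e.g. mortality rates) and a flag marking
whether the indicator has the multi-period, MDG-era history that supports
panel estimation.

Custom registries can be loaded from CSV and are validated against the same
schema, so every direction and eligibility flag is overridable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "THEMES",
    "IndicatorMeta",
    "ThemeRegistry",
    "RegistryError",
    "load_registry",
    "direction_of",
]

#: The seven health themes, in presentation order.
THEMES: tuple[str, ...] = (
    "Maternal and reproductive health",
    "Newborn and child health",
    "Infectious diseases",
    "Non-communicable diseases",
    "Injuries and violence",
    "Environmental risks",
    "Health system coverage",
)


class RegistryError(ValueError):
    """Raised for malformed registry sources or unknown indicator codes."""


@dataclass(frozen=True)
class IndicatorMeta:
    """Metadata for one indicator.

    Attributes
    ----------
    code:
        Short identifier, e.g. ``"311"`` (maternal mortality ratio) or
        ``"3b1a"`` (DTP3 immunization coverage).
    name:
        Human-readable indicator name.
    theme:
        One of the seven labels in :data:`THEMES`.
    direction:
        ``+1`` if higher values mean improvement, ``-1`` if lower values do.
    panel_eligible:
        True for indicators with a long, multi-period series for which
        two-way fixed-effects panel estimation is appropriate; False for
        SDG-era indicators observed in essentially a single period.
    """

    code: str
    name: str
    theme: str
    direction: int
    panel_eligible: bool


class ThemeRegistry:
    """Queryable collection of :class:`IndicatorMeta` entries."""

    def __init__(self, entries: Iterable[IndicatorMeta]):
        self.entries: tuple[IndicatorMeta, ...] = tuple(entries)
        self._by_code: dict[str, IndicatorMeta] = {}
        for row, meta in enumerate(self.entries, start=2):  # row 1 = header
            if meta.code in self._by_code:
                raise RegistryError(
                    f"duplicate indicator code {meta.code!r} (row {row})"
                )
            if meta.theme not in THEMES:
                raise RegistryError(
                    f"unknown theme {meta.theme!r} for code {meta.code!r} (row {row})"
                )
            if meta.direction not in (1, -1):
                raise RegistryError(
                    f"invalid direction {meta.direction!r} for code {meta.code!r} "
                    f"(row {row}); must be +1 or -1"
                )
            self._by_code[meta.code] = meta

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __iter__(self):
        return iter(self.entries)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(m.code for m in self.entries)

    @property
    def theme_sizes(self) -> Mapping[str, int]:
        """Number of member indicators per theme (full theme size)."""
        sizes: dict[str, int] = {}
        for meta in self.entries:
            sizes[meta.theme] = sizes.get(meta.theme, 0) + 1
        return sizes

    def meta(self, code: str) -> IndicatorMeta:
        try:
            return self._by_code[code]
        except KeyError:
            raise RegistryError(f"unknown indicator code {code!r}") from None

    def direction_of(self, code: str) -> int:
        return self.meta(code).direction

    def theme_of(self, code: str) -> str:
        return self.meta(code).theme

    def members(self, theme: str) -> tuple[IndicatorMeta, ...]:
        if theme not in THEMES:
            raise RegistryError(f"unknown theme {theme!r}")
        return tuple(m for m in self.entries if m.theme == theme)


def _parse_row(row: dict, rownum: int) -> IndicatorMeta:
    try:
        direction = int(row["direction"])
    except (TypeError, ValueError):
        raise RegistryError(
            f"invalid direction {row.get('direction')!r} in row {rownum}"
        ) from None
    flag = str(row.get("panel_eligible", "")).strip().lower()
    if flag not in {"true", "false", "1", "0"}:
        raise RegistryError(
            f"invalid panel_eligible {row.get('panel_eligible')!r} in row {rownum}"
        )
    return IndicatorMeta(
        code=str(row["code"]).strip(),
        name=str(row["name"]).strip(),
        theme=str(row["theme"]).strip(),
        direction=direction,
        panel_eligible=flag in {"true", "1"},
    )


def load_registry(source: str | Path | None = None) -> ThemeRegistry:
    """Load the indicator registry.

    Parameters
    ----------
    source:
        Path to a registry CSV with columns
        ``code,name,theme,direction,panel_eligible``. When omitted the
        built-in 38-indicator registry is used.
    """
    if source is None:
        text = (
            resources.files("sdgcurves.data").joinpath("indicators.csv").read_text("utf-8")
        )
        lines = text.splitlines()
    else:
        lines = Path(source).read_text("utf-8").splitlines()
    reader = csv.DictReader(lines)
    required = {"code", "name", "theme", "direction", "panel_eligible"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        missing = sorted(required - set(reader.fieldnames or []))
        raise RegistryError(f"registry CSV missing columns: {missing}")
    entries = [_parse_row(row, i) for i, row in enumerate(reader, start=2)]
    return ThemeRegistry(entries)


def direction_of(registry: ThemeRegistry, code: str) -> int:
    """Sign of improvement for *code*: +1 higher-is-better, -1 lower-is-better."""
    return registry.direction_of(code)
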