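"""Figure style settings and their JSON persistence.

All aesthetic knobs live in one serializable :class:`StyleSettings` object so
a figure's appearance can be retained and shared as a small JSON document:
independent colors for positive and negative correlation ribbons, background
color, domain-label font size and truncation width, ribbon stroke-width
range, inter-domain gap, and canvas size.

Default ribbon colors are the Okabe–Ito colorblind-safe blue (positive) and
vermilion (negative), chosen so that the sign encoding survives the common
forms of color-vision deficiency.
"""

from __future__ import annotations

import json
import logging
import math
import os
import re
from dataclasses import asdict, dataclass, fields
from typing import IO, Any, Union

from .errors import MalformedSettings

logger = logging.getLogger(__name__)

_HEX_COLOR = re.compile(r"^#?[0-9a-fA-F]{6}$")

PathOrStream = Union[str, os.PathLike, IO[str]]


def _normalize_color(value: Any, key: str) -> str:
    if not isinstance(value, str) or not _HEX_COLOR.match(value.strip()):
        raise MalformedSettings(
            f"{key}: expected a 6-digit hex color like '#1f77b4', got {value!r}"
        )
    v = value.strip().lower()
    return v if v.startswith("#") else "#" + v


@dataclass(frozen=True)
class StyleSettings:
    """Every aesthetic knob of a globe figure, in one unit.

    Attributes
    ----------
    positive_color, negative_color:
        Stroke colors for ribbons with positive / negative coefficients
        (6-digit hex; normalized to lowercase ``#rrggbb``).
    background_color:
        Canvas fill.
    font_size:
        Domain-label font size in points (> 0).
    label_max_chars:
        Labels longer than this are cut and given a trailing ellipsis.
    ribbon_min_width, ribbon_max_width:
        Stroke-width range in pixels; a ribbon of absolute coefficient ``c``
        is drawn at ``min + (max - min) * c``, so setting min == max gives
        constant-width ribbons.
    domain_gap_degrees:
        Angular gap between adjacent domain arcs (must also satisfy
        ``n_domains * gap < 360`` at layout time).
    figure_size_px:
        Edge of the square canvas, in pixels.
    """

    positive_color: str = "#0072b2"
    negative_color: str = "#d55e00"
    background_color: str = "#ffffff"
    font_size: float = 11.0
    label_max_chars: int = 18
    ribbon_min_width: float = 1.0
    ribbon_max_width: float = 8.0
    domain_gap_degrees: float = 2.0
    figure_size_px: int = 800

    def __post_init__(self) -> None:
        for key in ("positive_color", "negative_color", "background_color"):
            object.__setattr__(self, key, _normalize_color(getattr(self, key), key))
        self._require_positive_finite("font_size", self.font_size)
        if not isinstance(self.label_max_chars, int) or isinstance(self.label_max_chars, bool) \
                or self.label_max_chars < 1:
            raise MalformedSettings(
                f"label_max_chars: expected a positive integer, got {self.label_max_chars!r}"
            )
        for key in ("ribbon_min_width", "ribbon_max_width"):
            v = getattr(self, key)
            if not isinstance(v, (int, float)) or isinstance(v, bool) \
                    or not math.isfinite(v) or v < 0:
                raise MalformedSettings(f"{key}: expected a non-negative number, got {v!r}")
            object.__setattr__(self, key, float(v))
        if self.ribbon_min_width > self.ribbon_max_width:
            raise MalformedSettings(
                f"ribbon_min_width ({self.ribbon_min_width}) exceeds "
                f"ribbon_max_width ({self.ribbon_max_width})"
            )
        self._require_positive_finite("domain_gap_degrees", self.domain_gap_degrees)
        if self.domain_gap_degrees >= 360:
            raise MalformedSettings("domain_gap_degrees must be below 360")
        if not isinstance(self.figure_size_px, int) or isinstance(self.figure_size_px, bool) \
                or self.figure_size_px < 1:
            raise MalformedSettings(
                f"figure_size_px: expected a positive integer, got {self.figure_size_px!r}"
            )
        object.__setattr__(self, "font_size", float(self.font_size))
        object.__setattr__(self, "domain_gap_degrees", float(self.domain_gap_degrees))

    def _require_positive_finite(self, key: str, v: Any) -> None:
        if not isinstance(v, (int, float)) or isinstance(v, bool) \
                or not math.isfinite(v) or v <= 0:
            raise MalformedSettings(f"{key}: expected a positive number, got {v!r}")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def replace(self, **overrides: Any) -> "StyleSettings":
        """A copy with the given fields replaced (validation re-runs)."""
        d = self.to_dict()
        d.update(overrides)
        return StyleSettings(**d)


_KNOWN_KEYS = {f.name for f in fields(StyleSettings)}


def settings_from_dict(data: dict[str, Any]) -> StyleSettings:
    """Build settings from a plain dict; unknown keys warn, missing default."""
    if not isinstance(data, dict):
        raise MalformedSettings(f"settings document must be a JSON object, got {type(data).__name__}")
    known: dict[str, Any] = {}
    for key, value in data.items():
        if key not in _KNOWN_KEYS:
            logger.warning("UNKNOWN_SETTING key %r ignored", key)
            continue
        known[key] = value
    # JSON has no int/float distinction worth fighting over: accept integral
    # floats for the integer fields.
    for key in ("label_max_chars", "figure_size_px"):
        v = known.get(key)
        if isinstance(v, float) and v.is_integer():
            known[key] = int(v)
    return StyleSettings(**known)


def read_settings(source: PathOrStream) -> StyleSettings:
    """Load a :class:`StyleSettings` from a JSON document.

    Unknown keys are ignored with a warning; missing keys take the defaults
    documented on :class:`StyleSettings`.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = source.read()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise MalformedSettings(f"not valid JSON: {exc}") from None
    return settings_from_dict(data)


def write_settings(settings: StyleSettings, sink: PathOrStream) -> None:
    """Serialize settings as a JSON object (stable key order)."""
    text = json.dumps(settings.to_dict(), indent=2, sort_keys=True) + "\n"
    if isinstance(sink, (str, os.PathLike)):
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        sink.write(text)
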