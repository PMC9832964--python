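"""Exception hierarchy.

Every error raised by this package derives from :class:`CorrGlobeError`, so
callers (including the CLI) can catch one base class. Errors that point at a
specific place in an input file carry a 1-based ``line`` attribute counting
the header line as line 1.
"""

from __future__ import annotations


class CorrGlobeError(Exception):
    """Base class for all corrglobe errors."""


class HeaderMismatch(CorrGlobeError):
    """The CSV header line is not the required five-column contract."""

    def __init__(self, got: tuple[str, ...]):
        self.got = tuple(got)
        super().__init__(
            "not a correlation-globe CSV: header must be exactly "
            "'variable1,var1_domain,variable2,var2_domain,coef', got "
            + repr(list(got))
        )


class MalformedRow(CorrGlobeError):
    """A data row has the wrong number of fields or an empty label."""

    def __init__(self, line: int, reason: str):
        self.line = line
        super().__init__(f"line {line}: {reason}")


class BadCoefficient(CorrGlobeError):
    """A coefficient is non-numeric, non-finite, or out of [-1, 1]."""

    def __init__(self, line: int, raw: str, reason: str):
        self.line = line
        self.raw = raw
        super().__init__(f"line {line}: bad coefficient {raw!r} ({reason})")


class EmptyTable(CorrGlobeError):
    """A correlation file contained a header but no data rows."""


class MalformedSettings(CorrGlobeError):
    """A settings document is not valid JSON or has an invalid value."""


class DomainConflict(CorrGlobeError):
    """The same variable label appears under two different domains."""

    def __init__(self, variable: str, domain_a: str, domain_b: str):
        self.variable = variable
        self.domains = (domain_a, domain_b)
        super().__init__(
            f"variable {variable!r} is assigned to two domains: "
            f"{domain_a!r} and {domain_b!r}"
        )


class EmptyGlobe(CorrGlobeError):
    """No record survived filtering; carries per-cause drop counts."""

    def __init__(self, counts):
        self.counts = counts
        super().__init__(
            "no correlation survives filtering: "
            f"{counts.n_input} read, {counts.self_pairs} self-pairs, "
            f"{counts.duplicates} duplicates, {counts.below_threshold} at/below "
            f"threshold, {counts.excluded} touching excluded domains"
        )


class BadExplicitOrder(CorrGlobeError):
    """An explicit domain order is not a permutation of the present domains."""


class GapTooLarge(CorrGlobeError):
    """n_domains x gap_degrees leaves no room for the domain arcs."""


class DegenerateRibbon(CorrGlobeError):
    """Both ribbon anchors coincide (cannot happen for distinct variables)."""


class InconsistentInput(CorrGlobeError):
    """A model and layout passed to the renderer do not describe the same globe."""


class UnsupportedFormat(CorrGlobeError):
    """Requested export format is not one of svg/png/jpg/pdf."""


class ConversionFailure(CorrGlobeError):
    """Raster/PDF conversion failed; SVG export never raises this."""
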