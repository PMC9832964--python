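"""From a raw correlation table to a validated globe model.

A :class:`GlobeModel` is the deduplicated, filtered view of a correlation
table that the layout and renderer consume: the domains (categories) that
will sit on the rim, each with its member variables in first-appearance
order, and the surviving ribbons (pairwise correlations).

Filtering is applied in a fixed order so drop-count reports are
deterministic and each dropped record is attributed to exactly one cause:

1. self-pairs (a variable correlated with itself) are dropped;
2. duplicate unordered pairs keep their first occurrence;
3. records whose absolute coefficient is not strictly above the threshold
   are dropped — the cutoff is strict (``|coef| > t``), so a coefficient of
   exactly 0 never renders (its sign, hence its color, is undefined);
4. records touching an excluded domain are dropped.

Domains whose ribbons are all filtered away are pruned from the rim, keeping
arc lengths proportional to visible content. Dropped rows are reported
through the module logger with machine-readable codes (``SELF_PAIR``,
``DUP_PAIR``, ``COEF_CONFLICT``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import DomainConflict, EmptyGlobe
from .io import CorrelationRecord, CorrelationTable

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class Domain:
    """A rim group: a named category and its member variables in order."""

    name: str
    variables: tuple[str, ...]

    @property
    def size(self) -> int:
        """Number of distinct member variables (rim slots needed)."""
        return len(self.variables)


@dataclass(frozen=True)
class Ribbon:
    """One surviving pairwise correlation, to be drawn across the globe."""

    variable1: str
    domain1: str
    variable2: str
    domain2: str
    coef: float
    row_index: int

    @property
    def sign(self) -> str:
        return POSITIVE if self.coef > 0 else NEGATIVE

    @property
    def intra_domain(self) -> bool:
        return self.domain1 == self.domain2


@dataclass(frozen=True)
class DropCounts:
    """Per-cause accounting of what filtering removed.

    Satisfies the conservation identity
    ``kept + self_pairs + duplicates + below_threshold + excluded == n_input``.
    """

    n_input: int
    self_pairs: int
    duplicates: int
    below_threshold: int
    excluded: int
    kept: int

    def __post_init__(self) -> None:
        total = (self.self_pairs + self.duplicates + self.below_threshold
                 + self.excluded + self.kept)
        assert total == self.n_input, "drop accounting must conserve records"


@dataclass(frozen=True)
class GlobeModel:
    """Deduplicated, filtered view of a correlation table."""

    domains: tuple[Domain, ...]
    ribbons: tuple[Ribbon, ...]
    threshold: float
    excluded_domains: frozenset[str] = frozenset()
    drop_counts: DropCounts | None = field(default=None, compare=False)

    @property
    def domain_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.domains)

    def domain(self, name: str) -> Domain:
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(name)


def _check_domain_membership(records: Iterable[CorrelationRecord]) -> None:
    seen: dict[str, tuple[str, int]] = {}
    for rec in records:
        for var, dom in ((rec.variable1, rec.domain1), (rec.variable2, rec.domain2)):
            prev = seen.get(var)
            if prev is None:
                seen[var] = (dom, rec.row_index)
            elif prev[0] != dom:
                raise DomainConflict(var, prev[0], dom)


def build_globe(
    table: CorrelationTable,
    threshold: float = 0.0,
    excluded: Iterable[str] = (),
) -> GlobeModel:
    """Filter and group a correlation table into a :class:`GlobeModel`.

    Parameters
    ----------
    table:
        Validated correlation table (see :func:`corrglobe.io.read_correlations`).
    threshold:
        Absolute-value cutoff in [0, 1]; a record survives iff
        ``|coef| > threshold`` (strict).
    excluded:
        Domain labels whose records are removed from the globe.

    Raises
    ------
    DomainConflict
        The same variable label appears under two different domains anywhere
        in the input — the file is internally inconsistent.
    EmptyGlobe
        Nothing survives; the error carries the per-cause drop counts.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    excluded_set = frozenset(excluded)

    _check_domain_membership(table.records)

    n_self = n_dup = n_thresh = n_excl = 0
    seen_pairs: dict[frozenset, CorrelationRecord] = {}
    kept: list[Ribbon] = []
    for rec in table.records:
        line = rec.row_index + 2  # 1-based file line, header is line 1
        if rec.variable1 == rec.variable2:
            n_self += 1
            logger.warning("SELF_PAIR line %d: %r correlated with itself, dropped",
                           line, rec.variable1)
            continue
        key = rec.endpoints()
        first = seen_pairs.get(key)
        if first is not None:
            n_dup += 1
            if first.coef != rec.coef:
                logger.warning(
                    "COEF_CONFLICT lines %d and %d: pair (%r, %r) repeated with "
                    "coefficients %r and %r; first occurrence kept",
                    first.row_index + 2, line, rec.variable1, rec.variable2,
                    first.coef, rec.coef,
                )
            else:
                logger.warning("DUP_PAIR line %d: duplicate of line %d dropped",
                               line, first.row_index + 2)
            continue
        seen_pairs[key] = rec
        if not abs(rec.coef) > threshold:
            n_thresh += 1
            continue
        if rec.domain1 in excluded_set or rec.domain2 in excluded_set:
            n_excl += 1
            continue
        kept.append(Ribbon(rec.variable1, rec.domain1, rec.variable2,
                           rec.domain2, rec.coef, rec.row_index))

    counts = DropCounts(
        n_input=len(table.records), self_pairs=n_self, duplicates=n_dup,
        below_threshold=n_thresh, excluded=n_excl, kept=len(kept),
    )
    if not kept:
        raise EmptyGlobe(counts)

    # Domains and member variables in first-appearance order over survivors,
    # scanning endpoint1 before endpoint2 within each record.
    members: dict[str, list[str]] = {}
    for rb in kept:
        for var, dom in ((rb.variable1, rb.domain1), (rb.variable2, rb.domain2)):
            bucket = members.setdefault(dom, [])
            if var not in bucket:
                bucket.append(var)
    domains = tuple(Domain(name, tuple(vs)) for name, vs in members.items())

    return GlobeModel(
        domains=domains, ribbons=tuple(kept), threshold=float(threshold),
        excluded_domains=excluded_set, drop_counts=counts,
    )


def domain_sizes(model: GlobeModel) -> Mapping[str, int]:
    """Domain label -> number of distinct member variables after filtering."""
    return {d.name: d.size for d in model.domains}
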