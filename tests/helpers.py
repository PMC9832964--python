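"""Shared test utilities: table builders and independent filter oracles."""

from __future__ import annotations

import numpy as np

from corrglobe import CorrelationRecord, CorrelationTable, FixtureSpec, generate


def table_from(rows, source="<test>"):
    """Build a CorrelationTable from (v1, d1, v2, d2, coef) tuples."""
    records = tuple(
        CorrelationRecord(v1, d1, v2, d2, float(coef), row_index=i)
        for i, (v1, d1, v2, d2, coef) in enumerate(rows)
    )
    return CorrelationTable(records, source_name=source)


def table_from_ribbons(ribbons):
    """Re-materialize a model's surviving ribbons as an input table."""
    return table_from(
        (rb.variable1, rb.domain1, rb.variable2, rb.domain2, rb.coef)
        for rb in ribbons
    )


def random_spec(rng: np.random.Generator, max_domains=4, max_vars=5) -> FixtureSpec:
    n = int(rng.integers(1, max_domains + 1))
    return FixtureSpec(
        seed=int(rng.integers(0, 2**31 - 1)),
        n_domains=n,
        vars_per_domain=tuple(int(rng.integers(1, max_vars + 1)) for _ in range(n)),
        intra_density=float(rng.uniform(0.3, 1.0)),
        inter_density=float(rng.uniform(0.1, 0.8)),
        coef_distribution=("uniform", "beta")[int(rng.integers(0, 2))],
        negative_fraction=float(rng.uniform(0.0, 1.0)),
    )


def random_table(rng: np.random.Generator, **kwargs) -> CorrelationTable:
    """A random non-empty synthetic table."""
    while True:
        table = generate(random_spec(rng, **kwargs))
        if len(table):
            return table


def ribbon_key(obj):
    """Identity of a pair: unordered endpoints + coefficient."""
    return (
        frozenset([(obj.variable1, obj.domain1), (obj.variable2, obj.domain2)]),
        obj.coef,
    )


def brute_force_surviving(table, threshold, excluded=()):
    """Independent oracle for the filter semantics.

    A plain scan over the record list: drop self-pairs, keep the first
    occurrence of each unordered pair, then keep records with
    |coef| > threshold whose domains are both unexcluded. Returns the set of
    ribbon keys.
    """
    excluded = set(excluded)
    seen = set()
    out = set()
    for rec in table.records:
        if rec.variable1 == rec.variable2:
            continue
        pair = frozenset([(rec.variable1, rec.domain1),
                          (rec.variable2, rec.domain2)])
        if pair in seen:
            continue
        seen.add(pair)
        if abs(rec.coef) > threshold and rec.domain1 not in excluded \
                and rec.domain2 not in excluded:
            out.add((pair, rec.coef))
    return out
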