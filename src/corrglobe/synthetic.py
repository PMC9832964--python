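"""Seeded synthetic correlation tables.

Real correlation globes are typically built from tables such as a gut
microbial co-occurrence network (taxa correlated with taxa) or a
microbiome-versus-contaminant analysis (taxa in one domain, chemical
measurements in others). This module generates tables with the same shape —
a handful of domains of unequal size, denser and mostly positive correlation
within domains than between them — so that every other module can be
exercised and demonstrated without any external dataset.

Generation is fully deterministic given the spec's required ``seed``; the
generator is numpy's default PCG64.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .io import CorrelationRecord, CorrelationTable

COEF_DISTRIBUTIONS = ("uniform", "beta")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic correlation table.

    Defaults emulate a small microbiome-style study: one larger taxa-like
    domain plus several metadata domains (30 variables in 5 domains),
    correlations denser inside domains (``intra_density`` 0.35) than across
    them (``inter_density`` 0.08), mostly positive (``negative_fraction``
    0.25), with magnitudes drawn from Beta(2, 4) — many weak and few strong
    coefficients, as pairwise correlation screens tend to produce.

    ``coef_distribution``: ``"beta"`` draws |coef| from
    Beta(*beta_shape*); ``"uniform"`` draws |coef| from Uniform(0, 1). The
    sign is assigned separately: negative with probability
    ``negative_fraction`` (so ``"uniform"`` with ``negative_fraction=0.5``
    is the symmetric Uniform(-1, 1)).
    """

    seed: int
    n_domains: int = 5
    vars_per_domain: tuple[int, ...] = (12, 6, 5, 4, 3)
    intra_density: float = 0.35
    inter_density: float = 0.08
    coef_distribution: str = "beta"
    beta_shape: tuple[float, float] = (2.0, 4.0)
    negative_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.n_domains < 1:
            raise ValueError("n_domains must be positive")
        if len(self.vars_per_domain) != self.n_domains:
            raise ValueError(
                f"vars_per_domain has {len(self.vars_per_domain)} entries "
                f"for {self.n_domains} domains"
            )
        if any(v < 1 for v in self.vars_per_domain):
            raise ValueError("every domain needs at least one variable")
        for name in ("intra_density", "inter_density", "negative_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.coef_distribution not in COEF_DISTRIBUTIONS:
            raise ValueError(
                f"coef_distribution must be one of {COEF_DISTRIBUTIONS}, "
                f"got {self.coef_distribution!r}"
            )
        if any(s <= 0 for s in self.beta_shape):
            raise ValueError("beta_shape parameters must be positive")


def _variables(spec: FixtureSpec) -> list[tuple[str, str]]:
    """All (domain, variable) labels, domain-major, as D{i}_v{j}."""
    out = []
    for i, n in enumerate(spec.vars_per_domain, start=1):
        for j in range(1, n + 1):
            out.append((f"D{i}", f"D{i}_v{j}"))
    return out


def _draw_magnitude(rng: np.random.Generator, spec: FixtureSpec) -> float:
    while True:
        if spec.coef_distribution == "uniform":
            m = float(rng.uniform(0.0, 1.0))
        else:
            m = float(rng.beta(*spec.beta_shape))
        if 0.0 < m <= 1.0 and math.isfinite(m):
            return m


def generate(spec: FixtureSpec) -> CorrelationTable:
    """Generate a correlation table from a :class:`FixtureSpec`.

    Every unordered pair of variables is considered once, in deterministic
    domain-major order: pairs within a domain are included with probability
    ``intra_density``, pairs across domains with ``inter_density``. There
    are no self-pairs and no duplicates, so the table passes the reader's
    validation and survives :func:`corrglobe.model.build_globe` untouched
    by the dedup stages.
    """
    rng = np.random.default_rng(spec.seed)
    variables = _variables(spec)
    records: list[CorrelationRecord] = []
    for a in range(len(variables)):
        dom_a, var_a = variables[a]
        for b in range(a + 1, len(variables)):
            dom_b, var_b = variables[b]
            density = spec.intra_density if dom_a == dom_b else spec.inter_density
            if rng.random() >= density:
                continue
            coef = _draw_magnitude(rng, spec)
            if rng.random() < spec.negative_fraction:
                coef = -coef
            records.append(CorrelationRecord(
                var_a, dom_a, var_b, dom_b, coef, row_index=len(records)
            ))
    return CorrelationTable(tuple(records), source_name="<synthetic>")


def hub_negative_table(
    seed: int,
    spec: FixtureSpec | None = None,
    n_negative: int = 12,
) -> CorrelationTable:
    """A table in which one hub variable carries every negative correlation.

    This reproduces a structure seen in gut-microbiome co-occurrence
    networks, where one genus anchors all the negative associations while
    the rest of the network is positive. The hub is the first variable of
    the first domain (``D1_v1`` under the default spec). All non-hub pairs
    are positive; the hub receives ``n_negative`` negative partners with
    |coef| drawn from Uniform(0.45, 0.95) so they survive the commonly used
    display thresholds of 0.2 and 0.4.

    Useful as a regression fixture: after any amount of threshold filtering,
    every negative ribbon must still touch the hub.
    """
    base_spec = spec or FixtureSpec(
        seed=seed, coef_distribution="uniform", negative_fraction=0.0
    )
    base_spec = replace(base_spec, seed=seed, negative_fraction=0.0)
    base = generate(base_spec)
    hub_dom, hub_var = _variables(base_spec)[0]

    records = [r for r in base.records
               if hub_var not in (r.variable1, r.variable2)]

    rng = np.random.default_rng((seed, 0x9E3779B9))  # distinct stream from generate()
    partners = [(d, v) for d, v in _variables(base_spec) if v != hub_var]
    n_negative = min(n_negative, len(partners))
    chosen = rng.choice(len(partners), size=n_negative, replace=False)
    for idx in sorted(int(i) for i in chosen):
        dom, var = partners[idx]
        coef = -float(rng.uniform(0.45, 0.95))
        records.append(CorrelationRecord(hub_var, hub_dom, var, dom, coef, 0))

    records = tuple(
        CorrelationRecord(r.variable1, r.domain1, r.variable2, r.domain2,
                          r.coef, row_index=i)
        for i, r in enumerate(records)
    )
    return CorrelationTable(records, source_name="<synthetic:hub-negative>")


def hub_variable(spec: FixtureSpec | None = None) -> str:
    """The hub variable label used by :func:`hub_negative_table`."""
    return _variables(spec or FixtureSpec(seed=0))[0][1]
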