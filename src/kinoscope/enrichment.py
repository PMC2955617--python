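"""Pathway over-representation of active kinases.

A transparent hypergeometric test replaces proprietary knowledge-base
scoring: for a pathway with K members in a universe of M kinases and an
active set of size N, the p-value is the upper tail P(X >= overlap) for
X ~ Hypergeometric(M, K, N). All reports label the statistic as
hypergeometric over-representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .annotation_io import PathwayAnnotation
from .errors import ParameterError, ValidationError


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    overlap: int
    pathway_size: int
    active_set_size: int
    universe_size: int
    expected_overlap: float
    p: float
    fdr: float
    rank: int


def enrich(
    active_kinases: Iterable[str],
    pathways: PathwayAnnotation,
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Rank pathways by upper-tail hypergeometric over-representation.

    Sorted by p ascending, ties broken by larger overlap then pathway id;
    BH-adjusted q-values computed across all tested pathways. An empty
    active set yields p = 1 everywhere (with a warning); an empty universe
    is an error.
    """
    from .differential import bh_fdr  # local import avoids a cycle at import time

    universe = set(universe)
    if not universe:
        raise ParameterError("empty kinase universe")
    active = set(active_kinases)
    stray = active - universe
    if stray:
        raise ValidationError(f"active kinases outside universe: {sorted(stray)[:5]}")
    for pw, members in pathways.members.items():
        if not members <= universe:
            raise ValidationError(f"pathway {pw!r} has members outside the universe")
    if not active:
        warnings.warn("empty active set: all enrichment p-values are 1", stacklevel=2)

    M, N = len(universe), len(active)
    rows = []
    for pw, members in pathways.members.items():
        K = len(members)
        k = len(members & active)
        expected = N * K / M
        p = 1.0 if N == 0 else float(stats.hypergeom.sf(k - 1, M, K, N))
        p = min(max(p, 0.0), 1.0)
        rows.append((pw, k, K, p, expected))
    rows.sort(key=lambda r: (r[3], -r[1], r[0]))
    q = bh_fdr([r[3] for r in rows])
    return [
        EnrichmentResult(
            pathway_id=pw,
            overlap=k,
            pathway_size=K,
            active_set_size=N,
            universe_size=M,
            expected_overlap=expected,
            p=p,
            fdr=float(qv),
            rank=i + 1,
        )
        for i, ((pw, k, K, p, expected), qv) in enumerate(zip(rows, q))
    ]


def top_pathways(results: Sequence[EnrichmentResult], k: int = 5) -> list[EnrichmentResult]:
    """First ``k`` ranked pathways (fewer when fewer exist; ``k=0`` -> [])."""
    if k < 0:
        raise ParameterError("k must be >= 0")
    return list(results[:k])


def enrichment_table(results: Sequence[EnrichmentResult], pathways: PathwayAnnotation) -> pd.DataFrame:
    """Tabular report with pathway display names and the test's statistics."""
    return pd.DataFrame(
        [
            (
                r.rank,
                r.pathway_id,
                pathways.names.get(r.pathway_id, r.pathway_id),
                r.overlap,
                r.pathway_size,
                r.expected_overlap,
                r.p,
                r.fdr,
            )
            for r in results
        ],
        columns=["rank", "pathway_id", "pathway_name", "overlap", "pathway_size",
                 "expected_overlap", "p_hypergeometric", "fdr"],
    )
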