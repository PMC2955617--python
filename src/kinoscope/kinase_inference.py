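"""Upstream kinase activity ranking from top-phosphorylated substrates.

The readout mirrors the classic chip report: average the cohort's
substrate profiles, take the N most intense substrates, attribute each to
its annotated kinase(s), and rank kinases by the mean intensity of their
hits (hit count breaking ties). A substrate recognized by several kinases
contributes fully to each — which is why a published ranking can show two
kinases sharing one intensity value.

``score_kinases`` reports every kinase with at least one hit (the printed
table includes single-hit rows). The default cohort-level ranking
(:func:`infer_kinase_activity`) additionally requires ``min_hits=2``
substrates of evidence: a single spot's intensity is a noise-dominated
activity estimate, and a minimum substrate count is the standard guard in
upstream kinase inference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation_io import KinaseRecord, SubstrateAnnotation
from .errors import ParameterError
from .preprocess import SubstrateProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KinaseActivity:
    """One row of the activity ranking."""

    kinase_id: str
    n_hits: int
    mean_intensity: float
    rank: int


def group_average(profiles: Sequence[SubstrateProfile]) -> SubstrateProfile:
    """Arithmetic per-substrate mean over the samples where the substrate
    passed QC; substrates failing QC everywhere are omitted."""
    if not profiles:
        raise ParameterError("group_average needs at least one profile")
    if len(profiles) == 1:
        return profiles[0]
    df = pd.concat({p.sample_id: p.values for p in profiles}, axis=1)
    mean = df.mean(axis=1, skipna=True).dropna()
    return SubstrateProfile(sample_id="group_mean", values=mean, qc={"n_samples": len(profiles)})


def select_top_substrates(profile: SubstrateProfile, n: int = 100) -> list[str]:
    """The ``n`` most intense substrates, descending; ties broken by
    lexicographic substrate id so the cut is deterministic. ``n`` larger
    than the profile returns everything."""
    if profile.values.empty:
        raise ParameterError("cannot select from an empty profile")
    order = sorted(profile.values.items(), key=lambda kv: (-kv[1], kv[0]))
    return [sub for sub, _ in order[:n]]


def score_kinases(
    top_substrates: Sequence[str],
    profile: SubstrateProfile,
    annotation: SubstrateAnnotation,
    min_hits: int = 1,
) -> list[KinaseActivity]:
    """Aggregate top substrates into a ranked kinase activity table.

    Per kinase with >= ``min_hits`` annotated substrates in the top list:
    ``n_hits`` = that count, ``mean_intensity`` = mean of those substrates'
    intensities. Sorted by mean intensity descending, ties by hit count
    descending then kinase id. Kinases without hits are omitted.
    """
    hits: dict[str, list[float]] = {}
    for sub in top_substrates:
        val = float(profile.values.get(sub, np.nan))
        if np.isnan(val):
            continue
        for kin in annotation.kinases_of(sub):
            hits.setdefault(kin, []).append(val)
    rows = [
        (kin, len(vals), float(np.mean(vals)))
        for kin, vals in hits.items()
        if len(vals) >= min_hits
    ]
    rows.sort(key=lambda r: (-r[2], -r[1], r[0]))
    return [
        KinaseActivity(kinase_id=k, n_hits=n, mean_intensity=m, rank=i + 1)
        for i, (k, n, m) in enumerate(rows)
    ]


def filter_kinases(
    activities: Sequence[KinaseActivity],
    exclude_categories: Iterable[str],
    kinase_table: Sequence[KinaseRecord],
) -> list[KinaseActivity]:
    """Drop kinases bearing any excluded category tag and recompute ranks.

    The category-exclusion rerun (e.g. dropping cell-cycle kinases that may
    be artificially upregulated by culturing) keeps the original relative
    order of the survivors.
    """
    exclude = set(exclude_categories)
    if not exclude:
        return list(activities)
    known_tags: set[str] = set()
    for rec in kinase_table:
        known_tags |= rec.categories
    unknown = exclude - known_tags
    if unknown:
        raise ParameterError(
            f"unknown categories {sorted(unknown)}; known tags: {sorted(known_tags)}"
        )
    tags = {rec.kinase_id: rec.categories for rec in kinase_table}
    survivors = [
        a for a in activities if not (tags.get(a.kinase_id, frozenset()) & exclude)
    ]
    if not survivors:
        warnings.warn("all kinases excluded by category filter", stacklevel=2)
    return [
        KinaseActivity(a.kinase_id, a.n_hits, a.mean_intensity, rank=i + 1)
        for i, a in enumerate(survivors)
    ]


def infer_kinase_activity(
    profiles: Sequence[SubstrateProfile],
    annotation: SubstrateAnnotation,
    *,
    top_n: int = 100,
    min_hits: int = 2,
    exclude_categories: Iterable[str] = (),
    kinase_table: Sequence[KinaseRecord] = (),
) -> list[KinaseActivity]:
    """Default cohort flow: group-average, select top-N substrates, score,
    optionally exclude categories. ``min_hits=2`` demands at least two
    concordant substrate hits before a kinase is called active."""
    avg = group_average(list(profiles))
    top = select_top_substrates(avg, n=top_n)
    acts = score_kinases(top, avg, annotation, min_hits=min_hits)
    if exclude_categories:
        acts = filter_kinases(acts, exclude_categories, kinase_table)
    return acts


def per_sample_hit_frequency(
    profiles: Sequence[SubstrateProfile],
    annotation: SubstrateAnnotation,
    top_n: int = 100,
) -> pd.DataFrame:
    """Alternative readout: top-N per sample, then cross-sample hit counts.

    Returns a DataFrame indexed by kinase with ``n_samples`` (samples in
    which the kinase had >=1 top-N hit), ``total_hits`` and
    ``mean_intensity`` over all its hits.
    """
    rows: dict[str, list[float]] = {}
    sample_sets: dict[str, set[str]] = {}
    for p in profiles:
        top = select_top_substrates(p, n=top_n)
        for sub in top:
            for kin in annotation.kinases_of(sub):
                rows.setdefault(kin, []).append(float(p.values[sub]))
                sample_sets.setdefault(kin, set()).add(p.sample_id)
    out = pd.DataFrame(
        {
            "n_samples": {k: len(v) for k, v in sample_sets.items()},
            "total_hits": {k: len(v) for k, v in rows.items()},
            "mean_intensity": {k: float(np.mean(v)) for k, v in rows.items()},
        }
    )
    return out.sort_values(["n_samples", "mean_intensity"], ascending=False)


def activity_table(
    activities: Sequence[KinaseActivity],
    kinase_table: Sequence[KinaseRecord] = (),
) -> pd.DataFrame:
    """Render activities in the published table shape:
    rank / intensity / kinase / n_hits / description / drugs."""
    meta = {r.kinase_id: r for r in kinase_table}
    rows = []
    for a in activities:
        rec = meta.get(a.kinase_id)
        rows.append(
            (
                a.rank,
                a.mean_intensity,
                a.kinase_id,
                a.n_hits,
                rec.description if rec else "",
                ", ".join(rec.known_drugs) if rec else "",
            )
        )
    return pd.DataFrame(rows, columns=["rank", "intensity", "kinase", "n_hits", "description", "drugs"])
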