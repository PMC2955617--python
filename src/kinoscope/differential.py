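"""Empirical-Bayes moderated t contrast between two sample groups.

Per-substrate two-sample contrasts on log2 intensities, with the pooled
variance shrunk toward a chip-wide prior estimated by moment matching on
the log sample variances (the hierarchical model s^2 ~ s0^2 * F(df, d0)).
The shrunken variance is

    s_tilde^2 = (d0 * s0^2 + df * s^2) / (d0 + df)

and the moderated t has df + d0 degrees of freedom, so that d0 = 0
recovers the ordinary pooled t and d0 = infinity pins every substrate's
variance at s0^2. Multiplicity is controlled by Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ParameterError, ValidationError
from .preprocess import SubstrateProfile

#: Sentinel prior degrees of freedom for "no residual variance dispersion".
INFINITE_D0 = math.inf


@dataclass(frozen=True)
class PriorEstimate:
    """Shrinkage hyperparameters: prior df ``d0`` (may be inf) and prior
    variance ``s0_sq``."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ParameterError("d0 must be >= 0")
        if not self.s0_sq > 0:
            raise ParameterError("s0_sq must be positive")


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the asymptotic start x ~ 1/y + 1/2 and the update from the
    monotone transform used in empirical-Bayes variance moderation.
    """
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(variances: Sequence[float] | np.ndarray, df: float) -> PriorEstimate:
    """Moment-match (d0, s0_sq) from per-substrate sample variances.

    The mean and variance of ``log(s^2)`` are matched to the theoretical
    moments of a log scaled-F variate: ``var(log s^2)`` in excess of
    ``trigamma(df/2)`` determines d0 via the inverse trigamma; the mean then
    determines s0_sq. When the observed dispersion does not exceed what
    sampling alone explains, d0 is the infinity sentinel and s0_sq is the
    arithmetic mean of the variances.
    """
    v = np.asarray(variances, float)
    if df <= 0:
        raise ParameterError("residual df must be positive")
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 2:
        raise ValidationError("need at least 2 positive variances to estimate a prior")
    e = np.log(v)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(
            emean
            - float(special.digamma(df / 2)) + math.log(df / 2)
            + float(special.digamma(d0 / 2)) - math.log(d0 / 2)
        )
    else:
        d0 = INFINITE_D0
        s0_sq = float(v.mean())
    return PriorEstimate(d0=d0, s0_sq=s0_sq)


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity.

    Stable under input reordering: the returned array is aligned with the
    input. Raises for p outside [0, 1].
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _group_matrix(profiles: Sequence[SubstrateProfile] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    return pd.concat({p.sample_id: p.values for p in profiles}, axis=1)


def moderated_t(
    group_a: Sequence[SubstrateProfile] | pd.DataFrame,
    group_b: Sequence[SubstrateProfile] | pd.DataFrame,
    prior: PriorEstimate | None = None,
    log_offset: float = 1.0,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Moderated two-sample contrast per substrate (group A minus group B).

    Inputs are cohorts of normalized profiles (or substrate x sample
    DataFrames). Intensities are log2(x + ``log_offset``) transformed so
    background-corrected zeros are tolerated. When ``prior`` is omitted it
    is estimated from the pooled per-substrate variances.

    Returns a DataFrame indexed by substrate with columns ``log_fc, t_mod,
    df_total, p, fdr``, sorted by p ascending.
    """
    a = _group_matrix(group_a)
    b = _group_matrix(group_b)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ParameterError("each group needs at least 2 samples")
    common = a.index.intersection(b.index)
    a = a.loc[common].to_numpy(float)
    b = b.loc[common].to_numpy(float)
    keep = ~(np.isnan(a).any(axis=1) | np.isnan(b).any(axis=1))
    a, b = a[keep], b[keep]
    index = common[keep]
    if log_transform:
        if (a < 0).any() or (b < 0).any():
            raise ValidationError("negative intensities; profiles must be background-corrected >= 0")
        a = np.log2(a + log_offset)
        b = np.log2(b + log_offset)

    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    log_fc = a.mean(axis=1) - b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / df

    if prior is None:
        prior = estimate_prior(s2, df)

    if math.isinf(prior.d0):
        s2_tilde = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s2_tilde = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = df + prior.d0

    se = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log_fc / se
    t_mod[~np.isfinite(t_mod)] = 0.0
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    out = pd.DataFrame(
        {
            "log_fc": log_fc,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "fdr": bh_fdr(p),
        },
        index=index,
    )
    out.index.name = "substrate_id"
    return out.sort_values("p", kind="mergesort")


def tumor_specific_substrates(
    results: pd.DataFrame, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Substrates significantly higher in group A (the tumor group):
    q < threshold and positive log fold change."""
    return results[(results["fdr"] < q_threshold) & (results["log_fc"] > 0)]
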