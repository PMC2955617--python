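"""Array preprocessing: acquisition QC, replicate QC, background correction,
median-of-triplicate summarization, and cross-array quantile normalization.

The default cohort flow is::

    acquisition_qc -> replicate_qc -> background_correct
        -> summarize_triplicates -> quantile_normalize (on summarized profiles)

Normalizing summarized profiles (rather than raw spots) is robust to spot
dropout; the spot-level order is available via
``preprocess_cohort(..., normalize_before_summarize=True)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import ChipLayout
from .errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)

SPOT_COLUMNS = ["spot_id", "substrate_id", "replicate_idx", "control_type", "intensity", "flagged"]


@dataclass
class ArrayScan:
    """One sample's quantified chip: a spot table plus acquisition metadata.

    ``spots`` has columns ``spot_id, substrate_id, replicate_idx,
    control_type, intensity, flagged``; controls carry an empty
    ``substrate_id``. ``total_hits`` is the summed intensity collected for
    the array (the acquisition "hit" count).
    """

    sample_id: str
    condition: str
    spots: pd.DataFrame
    total_hits: float
    metadata: dict = field(default_factory=dict)
    qc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise ValidationError(f"scan {self.sample_id!r}: spot table missing columns {missing}")
        if (self.spots["intensity"] < 0).any():
            raise ValidationError(f"scan {self.sample_id!r}: negative spot intensities")
        if self.total_hits < 0:
            raise ValidationError(f"scan {self.sample_id!r}: negative total_hits")

    def validate_against(self, layout: ChipLayout) -> None:
        layout_ids = {s.spot_id for s in layout.spots} | {c.spot_id for c in layout.controls}
        stray = set(self.spots["spot_id"]) - layout_ids
        if stray:
            raise ValidationError(
                f"scan {self.sample_id!r}: {len(stray)} spot ids absent from layout "
                f"(e.g. {sorted(stray)[:3]})"
            )

    def substrate_spots(self) -> pd.DataFrame:
        return self.spots[self.spots["control_type"] == "none"]

    def control_intensities(self, control_type: str) -> np.ndarray:
        sel = self.spots["control_type"] == control_type
        return self.spots.loc[sel, "intensity"].to_numpy(float)


@dataclass
class QCResult:
    passed: bool
    reason: str = ""


@dataclass
class SubstrateProfile:
    """Per-sample summarized intensities: one value per surviving substrate."""

    sample_id: str
    values: pd.Series  # index: substrate_id; summarized intensity >= 0
    qc: dict = field(default_factory=dict)  # keys: dropout, high_cv, imputed (sets)

    def __post_init__(self) -> None:
        vals = self.values.dropna()
        if (vals < 0).any():
            raise ValidationError(f"profile {self.sample_id!r}: negative summarized intensities")


# ---------------------------------------------------------------------------
# stage 1: acquisition QC

def acquisition_qc(scan: ArrayScan, min_total_hits: float = 1e6) -> QCResult:
    """Pass iff at least ``min_total_hits`` hits were collected (inclusive)."""
    if scan.total_hits >= min_total_hits:
        return QCResult(True)
    return QCResult(
        False,
        f"total_hits {scan.total_hits:.0f} below minimum {min_total_hits:.0f}",
    )


# ---------------------------------------------------------------------------
# stage 2: replicate QC

def replicate_qc(
    scan: ArrayScan,
    cv_threshold: float = 0.5,
    min_replicates: int = 2,
) -> ArrayScan:
    """Flag discordant replicates per substrate.

    For each substrate the coefficient of variation of its unflagged
    replicates is computed; when it exceeds ``cv_threshold`` the single
    replicate farthest from the replicate median is flagged and the CV is
    recomputed once (no second ejection). Substrates left with fewer than
    ``min_replicates`` unflagged replicates are marked ``dropout`` in the
    returned scan's ``qc`` table — a flag, never an error.
    """
    sub = scan.substrate_spots()
    wide = sub.pivot_table(index="substrate_id", columns="replicate_idx",
                           values="intensity", aggfunc="first")
    x = wide.to_numpy(float)  # NaN where a replicate is missing

    flag = np.zeros_like(x, dtype=bool)
    cv = _row_cv(x)
    bad = cv > cv_threshold
    if bad.any():
        med = np.nanmedian(x[bad], axis=1, keepdims=True)
        dist = np.abs(x[bad] - med)
        dist[np.isnan(dist)] = -np.inf  # never eject a missing replicate
        eject = np.argmax(dist, axis=1)
        rows = np.flatnonzero(bad)
        flag[rows, eject] = True
        x2 = x.copy()
        x2[rows, eject] = np.nan
        cv2 = _row_cv(x2)
        cv = cv.copy()
        cv[rows] = cv2[rows]

    surviving = (~np.isnan(x)) & ~flag
    n_surv = surviving.sum(axis=1)
    dropout = n_surv < min_replicates
    high_cv = bad

    qc = pd.DataFrame(
        {"cv": cv, "n_surviving": n_surv, "high_cv": high_cv, "dropout": dropout},
        index=wide.index,
    )
    n_flagged = int(flag.sum())
    if n_flagged or dropout.any():
        logger.info(
            "replicate_qc[%s]: %d replicates ejected, %d substrates dropped",
            scan.sample_id, n_flagged, int(dropout.sum()),
        )

    spots = scan.spots.copy()
    flag_lookup = {
        (wide.index[i], wide.columns[j]): True
        for i, j in zip(*np.nonzero(flag))
    }
    if flag_lookup:
        keys = list(zip(spots["substrate_id"], spots["replicate_idx"]))
        spots["flagged"] = spots["flagged"] | pd.Series(
            [flag_lookup.get(k, False) for k in keys], index=spots.index
        )
    return replace(scan, spots=spots, qc=qc)


def _row_cv(x: np.ndarray) -> np.ndarray:
    """Per-row population CV of non-missing entries; 0 where fewer than 2
    values or zero mean."""
    with np.errstate(invalid="ignore", divide="ignore"):
        n = (~np.isnan(x)).sum(axis=1)
        mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=1)
        sd = np.full(x.shape[0], np.nan)
        ok = n >= 2
        if ok.any():
            sd[ok] = np.nanstd(x[ok], axis=1, ddof=0)
        cv = sd / mean
    cv[~np.isfinite(cv)] = 0.0
    cv[n < 2] = 0.0
    return cv


# ---------------------------------------------------------------------------
# stage 3: background correction

def background_correct(scan: ArrayScan) -> ArrayScan:
    """Subtract the mean negative-control intensity from every substrate
    spot, clipping at zero. Control spots are left untouched."""
    neg = scan.control_intensities("negative")
    if neg.size == 0:
        raise ValidationError(
            f"scan {scan.sample_id!r}: no negative-control spots; "
            "disable background correction for chips without controls"
        )
    background = float(neg.mean())
    spots = scan.spots.copy()
    is_sub = spots["control_type"] == "none"
    spots.loc[is_sub, "intensity"] = (spots.loc[is_sub, "intensity"] - background).clip(lower=0.0)
    return replace(scan, spots=spots, metadata={**scan.metadata, "background": background})


# ---------------------------------------------------------------------------
# stage 4: summarization

def summarize_triplicates(scan: ArrayScan, min_replicates: int = 2) -> SubstrateProfile:
    """Median of each substrate's unflagged replicates.

    With exactly two survivors the median is their mean; substrates with
    fewer than ``min_replicates`` survivors (or flagged ``dropout`` by
    :func:`replicate_qc`) are omitted and recorded in the profile's QC sets.
    """
    sub = scan.substrate_spots()
    sub = sub[~sub["flagged"]]
    med = sub.groupby("substrate_id")["intensity"].median()
    counts = sub.groupby("substrate_id")["intensity"].size()
    dropout = set(counts.index[counts < min_replicates])
    high_cv: set[str] = set()
    if scan.qc is not None:
        dropout |= set(scan.qc.index[scan.qc["dropout"]])
        high_cv = set(scan.qc.index[scan.qc["high_cv"]])
    keep = med.index.difference(sorted(dropout))
    return SubstrateProfile(
        sample_id=scan.sample_id,
        values=med.loc[keep],
        qc={"dropout": dropout, "high_cv": high_cv},
    )


# ---------------------------------------------------------------------------
# stage 5: quantile normalization

def quantile_normalize(
    data: pd.DataFrame | Sequence[Sequence[float]],
    return_imputed: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Quantile-normalize arrays to a common reference distribution.

    ``data`` is substrates x arrays (a DataFrame, or a sequence of per-array
    vectors which is transposed into that shape). Each array's values are
    replaced by the across-array mean of order statistics at the value's
    rank; tied values within an array all receive the mean of their tied
    reference values, so within-array rank order of untied values is
    preserved and, absent missing values, all arrays end up with identical
    sorted vectors.

    Missing entries are imputed from the reference distribution at the
    substrate's mean empirical quantile across the arrays where it is
    present, and reported in the imputed mask (``return_imputed=True``).
    Substrates missing everywhere stay NaN.
    """
    if not isinstance(data, pd.DataFrame):
        arrays = [np.asarray(a, float) for a in data]
        if len({a.shape for a in arrays}) > 1:
            raise ParameterError("per-array vectors must have equal length")
        data = pd.DataFrame(np.column_stack(arrays)) if arrays else pd.DataFrame()
    if data.shape[1] < 2:
        raise ParameterError("quantile normalization needs at least 2 arrays")

    x = data.to_numpy(float)
    n, m = x.shape
    present = ~np.isnan(x)
    if not present.any():
        raise ParameterError("no observed values to normalize")

    # per-array quantile positions of each observed value (0..1, min-rank based
    # on sorted position; ties handled after mapping)
    grid = np.linspace(0.0, 1.0, n)
    ref = np.zeros(n)
    col_sorted: list[np.ndarray] = []
    col_pos: list[np.ndarray] = []
    for j in range(m):
        v = x[present[:, j], j]
        if v.size == 0:
            raise ParameterError(f"array {j} has no observed values")
        s = np.sort(v)
        pos = np.linspace(0.0, 1.0, s.size) if s.size > 1 else np.array([0.5])
        col_sorted.append(s)
        col_pos.append(pos)
        ref += np.interp(grid, pos, s)
    ref /= m

    out = np.full_like(x, np.nan)
    quantile_of = np.full_like(x, np.nan)  # each observed value's within-array quantile
    for j in range(m):
        idx = np.flatnonzero(present[:, j])
        v = x[idx, j]
        order = np.argsort(v, kind="mergesort")
        pos = col_pos[j]
        mapped = np.interp(pos, grid, ref)
        normalized = np.empty_like(v)
        normalized[order] = mapped
        q = np.empty_like(v)
        q[order] = pos
        # ties: average the reference values (and quantiles) of tied entries
        sv = v[order]
        tie_starts = np.flatnonzero(np.r_[True, sv[1:] != sv[:-1]])
        tie_ends = np.r_[tie_starts[1:], sv.size]
        for a, b in zip(tie_starts, tie_ends):
            if b - a > 1:
                sel = order[a:b]
                normalized[sel] = mapped[a:b].mean()
                q[sel] = pos[a:b].mean()
        out[idx, j] = normalized
        quantile_of[idx, j] = q

    imputed = np.zeros_like(present)
    some_missing = (~present).any(axis=1) & present.any(axis=1)
    if some_missing.any():
        with np.errstate(invalid="ignore"):
            mean_q = np.nanmean(np.where(present, quantile_of, np.nan), axis=1)
        for i in np.flatnonzero(some_missing):
            fill = float(np.interp(mean_q[i], grid, ref))
            for j in np.flatnonzero(~present[i]):
                out[i, j] = fill
                imputed[i, j] = True

    out_df = pd.DataFrame(out, index=data.index, columns=data.columns)
    if return_imputed:
        return out_df, pd.DataFrame(imputed, index=data.index, columns=data.columns)
    return out_df


def normalize_profiles(profiles: Sequence[SubstrateProfile]) -> list[SubstrateProfile]:
    """Quantile-normalize a cohort of summarized profiles (missing-tolerant)."""
    if len(profiles) < 2:
        raise ParameterError("quantile normalization needs at least 2 profiles")
    df = pd.concat({p.sample_id: p.values for p in profiles}, axis=1)
    norm, imputed = quantile_normalize(df, return_imputed=True)
    out = []
    for p in profiles:
        col = norm[p.sample_id]
        imp = set(imputed.index[imputed[p.sample_id]])
        out.append(
            SubstrateProfile(
                sample_id=p.sample_id,
                values=col.dropna(),
                qc={**p.qc, "imputed": imp},
            )
        )
    return out


# ---------------------------------------------------------------------------
# cohort driver

def preprocess_cohort(
    scans: Sequence[ArrayScan],
    layout: ChipLayout | None = None,
    *,
    min_total_hits: float = 1e6,
    cv_threshold: float = 0.5,
    min_replicates: int = 2,
    background: bool = True,
    normalize: bool = True,
    normalize_before_summarize: bool = False,
) -> tuple[list[SubstrateProfile], dict]:
    """Run the full preprocessing flow over a cohort of scans.

    Returns (profiles, report); arrays failing acquisition QC are excluded
    and listed in ``report["excluded"]`` with their reasons.
    """
    report: dict = {"excluded": {}, "n_input": len(scans)}
    kept: list[ArrayScan] = []
    for scan in scans:
        if layout is not None:
            scan.validate_against(layout)
        qc = acquisition_qc(scan, min_total_hits=min_total_hits)
        if not qc.passed:
            logger.info("excluding array %s: %s", scan.sample_id, qc.reason)
            report["excluded"][scan.sample_id] = qc.reason
            continue
        kept.append(scan)

    kept = [replicate_qc(s, cv_threshold=cv_threshold, min_replicates=min_replicates) for s in kept]
    if background:
        kept = [background_correct(s) for s in kept]

    if normalize and normalize_before_summarize:
        if len(kept) < 2:
            raise ParameterError("quantile normalization needs at least 2 passing arrays")
        sub_tables = []
        for s in kept:
            t = s.substrate_spots()
            t = t[~t["flagged"]]
            sub_tables.append(t.set_index("spot_id")["intensity"].rename(s.sample_id))
        df = pd.concat(sub_tables, axis=1)
        norm = quantile_normalize(df)
        new_kept = []
        for s in kept:
            spots = s.spots.copy()
            mapper = norm[s.sample_id]
            is_sub = (spots["control_type"] == "none") & ~spots["flagged"]
            vals = spots.loc[is_sub, "spot_id"].map(mapper)
            spots.loc[is_sub, "intensity"] = vals.fillna(spots.loc[is_sub, "intensity"])
            new_kept.append(replace(s, spots=spots))
        kept = new_kept

    profiles = [summarize_triplicates(s, min_replicates=min_replicates) for s in kept]
    if normalize and not normalize_before_summarize:
        profiles = normalize_profiles(profiles)

    report["n_passing"] = len(profiles)
    return profiles, report
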