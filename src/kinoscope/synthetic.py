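"""Ground-truth simulators for every pipeline stage.

Arrays are simulated from a multiplicative model: spot intensities are
log-normal background draws, substrates annotated to any planted active
kinase have their expected intensity multiplied by ``boost``, triplicates
are jittered at a fixed coefficient of variation, and spots drop out at a
small rate. Positive controls sit at the 99th percentile of background,
negative controls at the 1st, so QC behaviour is unambiguous. Intensities
are drawn independently per sample — persistent substrate-affinity
differences, spatial gradients and image artifacts are deliberately not
modelled.

Viability plates are simulated as raw absorbances around a decreasing 4PL
curve, with blank and vehicle wells included so plate normalization is
exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import (
    ChipLayout,
    KinaseRecord,
    PathwayAnnotation,
    SubstrateAnnotation,
    default_layout,
)
from .errors import ParameterError
from .preprocess import ArrayScan
from .viability import DASATINIB_DOSES_NM, TBB_DOSES_UM, four_pl

_Z99 = 2.3263478740408408  # standard normal 99th percentile


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for one simulated array cohort."""

    active_kinases: frozenset[str]
    boost: float = 3.0
    background_log_mean: float = 6.0
    background_log_sd: float = 0.5
    replicate_cv: float = 0.1
    dropout_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boost < 1:
            raise ParameterError("boost must be >= 1")
        if not 0 <= self.dropout_rate <= 1:
            raise ParameterError("dropout_rate must be in [0, 1]")
        if self.replicate_cv < 0 or self.background_log_sd < 0:
            raise ParameterError("noise parameters must be non-negative")


@dataclass(frozen=True)
class ViabilityTruth:
    """4PL parameters generating one drug's simulated plate."""

    lower: float
    upper: float
    ec50: float
    hill: float
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lower <= self.upper:
            raise ParameterError("need 0 <= lower <= upper")
        if self.ec50 <= 0 or self.hill <= 0:
            raise ParameterError("ec50 and hill must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# annotation generator

def generate_annotation(
    n_substrates: int,
    n_kinases: int,
    substrates_per_kinase: int,
    multi_map_rate: float,
    cell_cycle_fraction: float,
    seed: int,
    n_pathways: int = 20,
    pathway_size: int = 8,
    planted_pathway_kinases: frozenset[str] | set[str] | None = None,
) -> tuple[SubstrateAnnotation, list[KinaseRecord], PathwayAnnotation, str | None]:
    """Random but reproducible chip annotation with known structure.

    Every kinase receives ``substrates_per_kinase`` primary substrates
    (disjoint across kinases); each annotated substrate then gains a second,
    uniformly drawn kinase with probability ``multi_map_rate``, emulating
    shared recognition motifs. ``cell_cycle_fraction`` of kinases are tagged
    ``cell_cycle``. Pathways are random kinase subsets; when
    ``planted_pathway_kinases`` is given, one pathway covering exactly that
    set is planted and its id returned.
    """
    if n_substrates < n_kinases or n_kinases < 1:
        raise ParameterError("need n_substrates >= n_kinases >= 1")
    if substrates_per_kinase < 1:
        raise ParameterError("substrates_per_kinase must be >= 1")
    if substrates_per_kinase * n_kinases > n_substrates:
        raise ParameterError(
            f"{n_kinases} kinases x {substrates_per_kinase} substrates exceed "
            f"{n_substrates} available substrates under disjoint primary assignment"
        )
    if not 0 <= multi_map_rate <= 1 or not 0 <= cell_cycle_fraction <= 1:
        raise ParameterError("rates must be in [0, 1]")

    rng = np.random.default_rng(seed)
    substrate_ids = [f"S{i + 1:04d}" for i in range(n_substrates)]
    kinase_ids = [f"KIN{i + 1:03d}" for i in range(n_kinases)]

    perm = rng.permutation(n_substrates)
    mapping: dict[str, set[str]] = {}
    for k, kin in enumerate(kinase_ids):
        for s in perm[k * substrates_per_kinase:(k + 1) * substrates_per_kinase]:
            mapping.setdefault(substrate_ids[s], set()).add(kin)
    for sub in sorted(mapping):
        if rng.random() < multi_map_rate:
            extra = kinase_ids[int(rng.integers(n_kinases))]
            mapping[sub].add(extra)
    annotation = SubstrateAnnotation({s: frozenset(k) for s, k in sorted(mapping.items())})

    n_cc = int(round(cell_cycle_fraction * n_kinases))
    cc = set(rng.choice(n_kinases, size=n_cc, replace=False).tolist()) if n_cc else set()
    kinases = [
        KinaseRecord(
            kinase_id=kin,
            name=f"kinase {kin[3:]}",
            description=f"synthetic kinase {i + 1}",
            categories=frozenset({"cell_cycle"}) if i in cc else frozenset(),
        )
        for i, kin in enumerate(kinase_ids)
    ]

    members: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    total = n_pathways + (1 if planted_pathway_kinases else 0)
    planted_slot = int(rng.integers(total)) if planted_pathway_kinases else -1
    planted_id: str | None = None
    size = min(pathway_size, n_kinases)
    for i in range(total):
        pw = f"PW{i + 1:02d}"
        if i == planted_slot:
            members[pw] = frozenset(planted_pathway_kinases)
            planted_id = pw
        else:
            picks = rng.choice(n_kinases, size=size, replace=False)
            members[pw] = frozenset(kinase_ids[j] for j in picks)
        names[pw] = f"synthetic pathway {i + 1}"
    pathways = PathwayAnnotation(members, names)
    return annotation, kinases, pathways, planted_id


# ---------------------------------------------------------------------------
# array simulator

def simulate_arrays(
    layout: ChipLayout,
    annotation: SubstrateAnnotation,
    truth: SyntheticTruth,
    n_samples: int,
    condition: str = "normal_medium",
    sample_prefix: str = "sample",
) -> list[ArrayScan]:
    """Simulate ``n_samples`` chips under one planted truth.

    Substrates annotated to any active kinase draw log-normal intensities
    boosted by ``truth.boost``; triplicates share a substrate draw jittered
    at ``replicate_cv``; spots vanish independently at ``dropout_rate``.
    ``total_hits`` is the summed intensity of the emitted spots.
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    stray = truth.active_kinases - annotation.kinase_ids
    if stray:
        raise ParameterError(f"active kinases not in annotation: {sorted(stray)[:5]}")

    sub_ids = layout.substrate_ids
    sub_pos = {s: i for i, s in enumerate(sub_ids)}
    active = np.array(
        [bool(annotation.kinases_of(s) & truth.active_kinases) for s in sub_ids]
    )
    spot_sub = np.array([sub_pos[s.substrate_id] for s in layout.spots])
    mu = truth.background_log_mean
    sd = truth.background_log_sd
    sig_r = math.sqrt(math.log(1.0 + truth.replicate_cv ** 2))
    rng = np.random.default_rng(truth.seed)

    scans: list[ArrayScan] = []
    n_sub = len(sub_ids)
    n_spots = len(layout.spots)
    for i in range(n_samples):
        base = rng.lognormal(mu + np.log(truth.boost) * active, sd, n_sub)
        mult = rng.lognormal(-sig_r ** 2 / 2.0, sig_r, n_spots)
        intensities = base[spot_sub] * mult
        neg = np.exp(mu - _Z99 * sd) * rng.lognormal(-sig_r ** 2 / 2.0, sig_r,
                                                     len(layout.control_spots("negative")))
        pos = np.exp(mu + _Z99 * sd) * rng.lognormal(-sig_r ** 2 / 2.0, sig_r,
                                                     len(layout.control_spots("positive")))
        rows = []
        for j, spot in enumerate(layout.spots):
            rows.append((spot.spot_id, spot.substrate_id, spot.replicate_idx, "none", intensities[j]))
        for ctype, vals in (("negative", neg), ("positive", pos)):
            for spot, v in zip(layout.control_spots(ctype), vals):
                rows.append((spot.spot_id, "", spot.replicate_idx, ctype, v))
        df = pd.DataFrame(rows, columns=["spot_id", "substrate_id", "replicate_idx",
                                         "control_type", "intensity"])
        if truth.dropout_rate > 0:
            keep = rng.random(len(df)) >= truth.dropout_rate
            df = df[keep].reset_index(drop=True)
        df["flagged"] = False
        scans.append(
            ArrayScan(
                sample_id=f"{sample_prefix}{i + 1:02d}",
                condition=condition,
                spots=df,
                total_hits=float(df["intensity"].sum()),
                metadata={"seed": truth.seed, "boost": truth.boost},
            )
        )
    return scans


# ---------------------------------------------------------------------------
# viability simulator

def simulate_viability(
    dose_grid,
    truth: ViabilityTruth,
    n_replicates: int = 4,
    drug: str = "drug",
    unit: str = "nM",
    blank_absorbance: float = 0.08,
    dynamic_range: float = 1.0,
) -> pd.DataFrame:
    """Long-format raw plate table (well, drug, dose, unit, replicate,
    absorbance, role) around a 4PL curve; includes blank and vehicle wells
    so normalization is exercised. ``noise_sd`` is additive on the viability
    scale."""
    doses = np.asarray(dose_grid, float)
    if doses.size == 0 or (doses <= 0).any():
        raise ParameterError("doses must be positive")
    if not (np.diff(doses) > 0).all():
        raise ParameterError("doses must be strictly increasing")
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    rng = np.random.default_rng(truth.seed)
    span = dynamic_range
    rows = []
    well = 0
    for rep in range(n_replicates):
        rows.append((f"W{well:03d}", drug, 0.0, unit, rep, blank_absorbance
                     + span * rng.normal(0.0, truth.noise_sd), "blank"))
        well += 1
    for rep in range(n_replicates):
        rows.append((f"W{well:03d}", drug, 0.0, unit, rep, blank_absorbance + span
                     * (1.0 + rng.normal(0.0, truth.noise_sd)), "vehicle"))
        well += 1
    for dose in doses:
        v = float(four_pl(dose, truth.lower, truth.upper, truth.ec50, truth.hill))
        for rep in range(n_replicates):
            rows.append((f"W{well:03d}", drug, float(dose), unit, rep, blank_absorbance
                         + span * (v + rng.normal(0.0, truth.noise_sd)), "treated"))
            well += 1
    return pd.DataFrame(rows, columns=["well", "drug", "dose", "unit", "replicate",
                                       "absorbance", "role"])


def simulate_combination_viability(
    dose_grid,
    truth_a: ViabilityTruth,
    v_b_fixed: float,
    excess: float = 0.0,
    n_replicates: int = 4,
    drug: str = "combo",
    unit: str = "nM",
    blank_absorbance: float = 0.08,
) -> pd.DataFrame:
    """Combination plate for drug A titrated on fixed drug B: observed
    viability is the Bliss expectation ``v_a * v_b_fixed`` minus a planted
    ``excess``, clipped to [0, 1], plus replicate noise."""
    doses = np.asarray(dose_grid, float)
    if not 0 <= v_b_fixed <= 1:
        raise ParameterError("v_b_fixed must be in [0, 1]")
    rng = np.random.default_rng(truth_a.seed + 1)
    rows = []
    well = 0
    for rep in range(n_replicates):
        rows.append((f"C{well:03d}", drug, 0.0, unit, rep,
                     blank_absorbance + rng.normal(0.0, truth_a.noise_sd), "blank"))
        well += 1
    for rep in range(n_replicates):
        rows.append((f"C{well:03d}", drug, 0.0, unit, rep,
                     blank_absorbance + 1.0 + rng.normal(0.0, truth_a.noise_sd), "vehicle"))
        well += 1
    for dose in doses:
        va = float(four_pl(dose, truth_a.lower, truth_a.upper, truth_a.ec50, truth_a.hill))
        v = float(np.clip(va * v_b_fixed - excess, 0.0, 1.0))
        for rep in range(n_replicates):
            rows.append((f"C{well:03d}", drug, float(dose), unit, rep,
                         blank_absorbance + v + rng.normal(0.0, truth_a.noise_sd), "treated"))
            well += 1
    return pd.DataFrame(rows, columns=["well", "drug", "dose", "unit", "replicate",
                                       "absorbance", "role"])


# ---------------------------------------------------------------------------
# study-preset cohort

@dataclass
class Cohort:
    """A fully simulated study: chip design, annotation, planted truths,
    tumor and control scans, and viability plates."""

    layout: ChipLayout
    annotation: SubstrateAnnotation
    kinases: list[KinaseRecord]
    pathways: PathwayAnnotation
    planted_pathway_id: str | None
    truth_tumor: SyntheticTruth
    truth_control: SyntheticTruth
    tumor_scans: list[ArrayScan]
    control_scans: list[ArrayScan]
    viability_plates: dict[str, pd.DataFrame] = field(default_factory=dict)


def paper_cohort(
    seed: int = 0,
    n_tumor: int = 6,
    n_control: int = 2,
    n_planted: int = 6,
    boost: float = 3.0,
    with_viability: bool = True,
) -> Cohort:
    """The study-shaped default cohort.

    A 1024-substrate triplicate chip with 16+16 controls; 120 kinases with 8
    substrates each, 20% multi-mapping, 27% tagged cell-cycle; 6 tumor-like
    samples sharing one planted set of 6 active kinases (covered by a
    planted pathway) and 2 control-like samples under a disjoint planted
    set; viability plates on the two printed monotherapy dose grids, one
    drug plateauing above 50% viability (its IC50 censored) and one crossing
    it, plus an enhanced combination plate.
    """
    rng = np.random.default_rng(seed)
    layout = default_layout()
    kin_ids = [f"KIN{i + 1:03d}" for i in range(120)]
    picks = rng.choice(120, size=2 * n_planted, replace=False)
    planted_tumor = frozenset(kin_ids[i] for i in picks[:n_planted])
    planted_control = frozenset(kin_ids[i] for i in picks[n_planted:])
    annotation, kinases, pathways, planted_pw = generate_annotation(
        n_substrates=1024,
        n_kinases=120,
        substrates_per_kinase=8,
        multi_map_rate=0.2,
        cell_cycle_fraction=0.27,
        seed=int(rng.integers(2 ** 31)),
        planted_pathway_kinases=planted_tumor,
    )
    truth_tumor = SyntheticTruth(
        active_kinases=planted_tumor, boost=boost, seed=int(rng.integers(2 ** 31))
    )
    truth_control = SyntheticTruth(
        active_kinases=planted_control, boost=boost, seed=int(rng.integers(2 ** 31))
    )
    tumor = simulate_arrays(layout, annotation, truth_tumor, n_tumor,
                            condition="normal_medium", sample_prefix="mls")
    control = simulate_arrays(layout, annotation, truth_control, n_control,
                              condition="normal_medium", sample_prefix="msc")

    plates: dict[str, pd.DataFrame] = {}
    if with_viability:
        # drug A: mild responder plateauing at 60% viability -> censored IC50
        truth_a = ViabilityTruth(lower=0.60, upper=1.0, ec50=300.0, hill=1.2,
                                 seed=int(rng.integers(2 ** 31)))
        # drug B: strong responder crossing 50% inside its grid
        truth_b = ViabilityTruth(lower=0.15, upper=1.0, ec50=80.0, hill=1.5,
                                 seed=int(rng.integers(2 ** 31)))
        plates["drug_a"] = simulate_viability(DASATINIB_DOSES_NM, truth_a,
                                              n_replicates=4, drug="drug_a", unit="nM")
        plates["drug_b"] = simulate_viability(TBB_DOSES_UM, truth_b,
                                              n_replicates=4, drug="drug_b", unit="uM")
        plates["combo"] = simulate_combination_viability(
            DASATINIB_DOSES_NM, truth_a, v_b_fixed=0.5, excess=0.3,
            n_replicates=4, drug="combo", unit="nM",
        )
    return Cohort(
        layout=layout,
        annotation=annotation,
        kinases=kinases,
        pathways=pathways,
        planted_pathway_id=planted_pw,
        truth_tumor=truth_tumor,
        truth_control=truth_control,
        tumor_scans=tumor,
        control_scans=control,
        viability_plates=plates,
    )
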