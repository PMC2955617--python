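"""End-to-end orchestration: simulate -> preprocess -> kinases -> diff ->
enrich -> viability, under a single config with deterministic seeding and a
provenance manifest.

All stage outputs are plain TSV/JSON in the run directory; the manifest
records the config hash, seed, package version and per-stage row counts, so
an identical config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation_io import load_annotations, load_layout, write_annotations, write_layout
from .differential import moderated_t
from .enrichment import enrich, enrichment_table, top_pathways
from .errors import KinoscopeError, ParameterError
from .kinase_inference import activity_table, infer_kinase_activity
from .preprocess import ArrayScan, SubstrateProfile, preprocess_cohort
from .synthetic import paper_cohort
from .viability import analyze_combination, fit_4pl, normalize_plate, NOT_REACHED

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on. Paths may be omitted when
    ``simulate`` is true (inputs are then generated from ``seed``)."""

    seed: int = 0
    out_dir: str = "kinoscope_run"
    simulate: bool = True
    layout_path: str | None = None
    substrate_annotation_path: str | None = None
    kinase_table_path: str | None = None
    pathway_path: str | None = None
    spot_dir: str | None = None
    viability_dir: str | None = None
    # stage toggles
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "preprocess", "kinases", "diff", "enrich", "viability"
    ])
    # thresholds (defaults mirror the printed study settings)
    min_total_hits: float = 1e6
    cv_threshold: float = 0.5
    top_n: int = 100
    min_hits: int = 2
    exclude_categories: list[str] = field(default_factory=list)
    fdr_q: float = 0.05
    excess_threshold: float = 0.1
    active_set_size: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("layout_path", "substrate_annotation_path",
                         "kinase_table_path", "pathway_path", "spot_dir"):
                p = getattr(self, name)
                if p is None:
                    raise ParameterError(f"config without simulate=true must set {name}")
                if not Path(p).exists():
                    raise KinoscopeError(f"missing input: {name} = {p}")
        if self.top_n < 1:
            raise ParameterError("top_n must be >= 1")
        if not 0 < self.fdr_q < 1:
            raise ParameterError("fdr_q must be in (0, 1)")

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where outputs land, not what they are
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# scan / profile IO

def write_scan(scan: ArrayScan, path: str | Path) -> None:
    df = scan.spots.copy()
    df.insert(0, "sample_id", scan.sample_id)
    df.insert(1, "condition", scan.condition)
    df.to_csv(path, sep="\t", index=False)


def load_scan(path: str | Path) -> ArrayScan:
    df = pd.read_csv(path, sep="\t", dtype={"substrate_id": str}, keep_default_na=False)
    df["substrate_id"] = df["substrate_id"].fillna("")
    df["intensity"] = df["intensity"].astype(float)
    if "flagged" not in df.columns:
        df["flagged"] = False
    df["flagged"] = df["flagged"].astype(bool)
    sample_id = str(df["sample_id"].iloc[0])
    condition = str(df["condition"].iloc[0]) if "condition" in df.columns else ""
    spots = df[[c for c in df.columns if c not in ("sample_id", "condition")]]
    return ArrayScan(
        sample_id=sample_id,
        condition=condition,
        spots=spots.reset_index(drop=True),
        total_hits=float(spots["intensity"].sum()),
    )


def write_profiles(profiles: list[SubstrateProfile], path: str | Path) -> None:
    df = pd.concat({p.sample_id: p.values for p in profiles}, axis=1)
    df.index.name = "substrate_id"
    df.to_csv(path, sep="\t", float_format="%.6f")


def load_profiles(path: str | Path) -> list[SubstrateProfile]:
    df = pd.read_csv(path, sep="\t", index_col="substrate_id")
    return [SubstrateProfile(sample_id=c, values=df[c].dropna()) for c in df.columns]


# ---------------------------------------------------------------------------
# run

def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages in order; returns the manifest dict.

    Partial outputs are retained on stage failure and the manifest marks the
    failed stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "failed_stage": None,
    }
    state: dict = {}
    try:
        for stage in config.stages:
            n_rows = _STAGES[stage](config, out, state)
            manifest["stages"][stage] = {"rows": n_rows}
            logger.info("stage %s complete (%d rows)", stage, n_rows)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest(manifest, out)
        raise
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> int:
    if config.simulate:
        cohort = paper_cohort(seed=config.seed)
    else:
        raise ParameterError("simulate stage enabled but simulate=false; drop the stage")
    state["cohort"] = cohort
    write_layout(cohort.layout, out / "layout.tsv")
    write_annotations(
        cohort.annotation, cohort.kinases, cohort.pathways,
        out / "substrate_annotation.tsv", out / "kinase_table.tsv", out / "pathways.tsv",
    )
    spot_dir = out / "spots"
    spot_dir.mkdir(exist_ok=True)
    for scan in cohort.tumor_scans + cohort.control_scans:
        write_scan(scan, spot_dir / f"{scan.sample_id}.tsv")
    via_dir = out / "viability"
    via_dir.mkdir(exist_ok=True)
    for name, plate in cohort.viability_plates.items():
        plate.to_csv(via_dir / f"{name}.csv", index=False, float_format="%.6f")
    truth = {
        "active_kinases_tumor": sorted(cohort.truth_tumor.active_kinases),
        "active_kinases_control": sorted(cohort.truth_control.active_kinases),
        "planted_pathway": cohort.planted_pathway_id,
        "boost": cohort.truth_tumor.boost,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return len(cohort.tumor_scans) + len(cohort.control_scans)


def _load_inputs(config: RunConfig, state: dict) -> None:
    if "layout" in state:
        return
    if "cohort" in state:
        cohort = state["cohort"]
        state.update(
            layout=cohort.layout, annotation=cohort.annotation,
            kinases=cohort.kinases, pathways=cohort.pathways,
            tumor_scans=cohort.tumor_scans, control_scans=cohort.control_scans,
            plates=cohort.viability_plates,
        )
        return
    layout = load_layout(config.layout_path)
    annotation, kinases, pathways = load_annotations(
        config.substrate_annotation_path, config.kinase_table_path,
        config.pathway_path, layout=layout,
    )
    scans = [load_scan(p) for p in sorted(Path(config.spot_dir).glob("*.tsv"))]
    if not scans:
        raise KinoscopeError(f"no spot tables found in {config.spot_dir}")
    tumor = [s for s in scans if not s.sample_id.startswith("msc")]
    control = [s for s in scans if s.sample_id.startswith("msc")]
    plates = {}
    if config.viability_dir:
        for p in sorted(Path(config.viability_dir).glob("*.csv")):
            plates[p.stem] = pd.read_csv(p)
    state.update(layout=layout, annotation=annotation, kinases=kinases,
                 pathways=pathways, tumor_scans=tumor, control_scans=control,
                 plates=plates)


def _stage_preprocess(config: RunConfig, out: Path, state: dict) -> int:
    _load_inputs(config, state)
    tumor_profiles, rep_t = preprocess_cohort(
        state["tumor_scans"], state["layout"],
        min_total_hits=config.min_total_hits, cv_threshold=config.cv_threshold,
    )
    control_profiles, rep_c = preprocess_cohort(
        state["control_scans"], state["layout"],
        min_total_hits=config.min_total_hits, cv_threshold=config.cv_threshold,
    ) if state["control_scans"] else ([], {})
    state["tumor_profiles"] = tumor_profiles
    state["control_profiles"] = control_profiles
    write_profiles(tumor_profiles, out / "profiles_tumor.tsv")
    if control_profiles:
        write_profiles(control_profiles, out / "profiles_control.tsv")
    state["preprocess_report"] = {"tumor": rep_t, "control": rep_c}
    return sum(len(p.values) for p in tumor_profiles + control_profiles)


def _stage_kinases(config: RunConfig, out: Path, state: dict) -> int:
    acts = infer_kinase_activity(
        state["tumor_profiles"], state["annotation"],
        top_n=config.top_n, min_hits=config.min_hits,
        exclude_categories=config.exclude_categories, kinase_table=state["kinases"],
    )
    state["activities"] = acts
    table = activity_table(acts, state["kinases"])
    table.to_csv(out / "kinase_activity.tsv", sep="\t", index=False, float_format="%.3f")
    return len(acts)


def _stage_diff(config: RunConfig, out: Path, state: dict) -> int:
    if len(state.get("control_profiles", [])) < 2:
        logger.info("diff stage skipped: fewer than 2 control profiles")
        state["diff"] = None
        return 0
    res = moderated_t(state["tumor_profiles"], state["control_profiles"])
    state["diff"] = res
    res.to_csv(out / "differential.tsv", sep="\t", float_format="%.6g")
    return len(res)


def _stage_enrich(config: RunConfig, out: Path, state: dict) -> int:
    universe = {k.kinase_id for k in state["kinases"]}
    active = [a.kinase_id for a in state["activities"][: config.active_set_size]]
    results = enrich(active, state["pathways"], universe)
    state["enrichment"] = results
    state["top_pathways"] = top_pathways(results, k=5)
    enrichment_table(results, state["pathways"]).to_csv(
        out / "enrichment.tsv", sep="\t", index=False, float_format="%.4g"
    )
    return len(results)


def _stage_viability(config: RunConfig, out: Path, state: dict) -> int:
    plates = state.get("plates") or {}
    rows = []
    fits = {}
    for name, plate in plates.items():
        if name == "combo":
            continue
        dr = normalize_plate(plate)
        fit = fit_4pl(dr)
        fits[name] = (dr, fit)
        rows.append((name, dr.drug, fit.lower, fit.upper, fit.ec50, fit.hill,
                     "NOT_REACHED" if fit.ic50 is NOT_REACHED else f"{fit.ic50:.4g}",
                     fit.converged))
    if rows:
        pd.DataFrame(rows, columns=["plate", "drug", "lower", "upper", "ec50", "hill",
                                    "ic50", "converged"]).to_csv(
            out / "viability_fits.tsv", sep="\t", index=False, float_format="%.4f")
    if "combo" in plates and "drug_a" in fits:
        dr_a, _ = fits["drug_a"]
        combo_dr = normalize_plate(plates["combo"])
        comb = analyze_combination(
            dr_a, mono_b_at_fixed=0.5, combo=combo_dr,
            excess_threshold=config.excess_threshold, drug_b="drug_b",
            schedule_note="drug B administered 30 min before drug A",
        )
        state["combination"] = comb
        comb.table.assign(enhancement_flag=comb.enhancement_flag).to_csv(
            out / "combination.tsv", sep="\t", index=False, float_format="%.4f")
    return len(rows)


_STAGES = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "kinases": _stage_kinases,
    "diff": _stage_diff,
    "enrich": _stage_enrich,
    "viability": _stage_viability,
}
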