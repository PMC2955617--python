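import numpy as np
import pandas as pd
import pytest

import kinoscope as ks


@pytest.fixture(scope="session")
def default_chip():
    return ks.default_layout()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced planted cohort shared across tests (small chip for speed)."""
    rng = np.random.default_rng(42)
    layout = _toy_layout(n_substrates=200, n_replicates=3, n_controls=4)
    annotation, kinases, pathways, pw_id = ks.generate_annotation(
        n_substrates=200, n_kinases=20, substrates_per_kinase=6,
        multi_map_rate=0.2, cell_cycle_fraction=0.25, seed=7,
        planted_pathway_kinases=frozenset({"KIN003", "KIN011", "KIN017"}),
    )
    # higher background mean than the full-size chip so the ~600-spot toy
    # still clears the million-hit acquisition threshold
    truth = ks.SyntheticTruth(
        active_kinases=frozenset({"KIN003", "KIN011", "KIN017"}),
        boost=3.0, background_log_mean=7.5, seed=11,
    )
    scans = ks.simulate_arrays(layout, annotation, truth, n_samples=4)
    return {
        "layout": layout, "annotation": annotation, "kinases": kinases,
        "pathways": pathways, "planted_pathway": pw_id, "truth": truth,
        "scans": scans,
    }


def _toy_layout(n_substrates, n_replicates, n_controls):
    spots, controls = [], []
    pos = ((b, r, c) for b in range(40) for r in range(10) for c in range(10))
    i = 0
    for s in range(n_substrates):
        for rep in range(n_replicates):
            b, r, c = next(pos)
            spots.append(ks.SpotDef(f"spot{i:05d}", f"S{s + 1:04d}", rep, b, r, c))
            i += 1
    for ctype, prefix in (("negative", "NEG"), ("positive", "POS")):
        for j in range(n_controls):
            b, r, c = next(pos)
            controls.append(ks.SpotDef(f"{prefix}{j + 1:02d}", None, 0, b, r, c, ctype))
    return ks.ChipLayout(chip_id="toy", spots=spots, controls=controls)


@pytest.fixture
def toy_layout():
    return _toy_layout(n_substrates=6, n_replicates=3, n_controls=2)


@pytest.fixture
def toy_scan(toy_layout):
    """Deterministic scan over the 6-substrate toy chip."""
    rows = []
    for spot in toy_layout.spots:
        base = 100.0 * (1 + int(spot.substrate_id[1:]))
        rows.append((spot.spot_id, spot.substrate_id, spot.replicate_idx, "none",
                     base + spot.replicate_idx))
    for spot in toy_layout.controls:
        val = 10.0 if spot.control_type == "negative" else 5000.0
        rows.append((spot.spot_id, "", spot.replicate_idx, spot.control_type, val))
    df = pd.DataFrame(rows, columns=["spot_id", "substrate_id", "replicate_idx",
                                     "control_type", "intensity"])
    df["flagged"] = False
    return ks.ArrayScan(sample_id="toy01", condition="normal_medium", spots=df,
                        total_hits=float(df["intensity"].sum()))


def make_scan(values_by_substrate, sample_id="s1", negatives=(), positives=()):
    """Build a minimal ArrayScan from {substrate: [replicate intensities]}."""
    rows = []
    i = 0
    for sub, vals in values_by_substrate.items():
        for rep, v in enumerate(vals):
            rows.append((f"sp{i:04d}", sub, rep, "none", float(v)))
            i += 1
    for v in negatives:
        rows.append((f"neg{i:04d}", "", 0, "negative", float(v)))
        i += 1
    for v in positives:
        rows.append((f"pos{i:04d}", "", 0, "positive", float(v)))
        i += 1
    df = pd.DataFrame(rows, columns=["spot_id", "substrate_id", "replicate_idx",
                                     "control_type", "intensity"])
    df["flagged"] = False
    return ks.ArrayScan(sample_id=sample_id, condition="normal_medium", spots=df,
                        total_hits=float(df["intensity"].sum()))
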