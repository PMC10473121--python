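"""Plain-text readers and writers for the pipeline's file formats.

Formats are deliberately simple: beta matrices as (optionally gzipped) TSV
with probe IDs in the first column and one column per sample; sample sheets
and cell-type references as CSV; blacklists as one-column CSV files with a
``probe_id`` header; clock definitions as a weight CSV plus a JSON sidecar;
panels as CSV with ``probe_id, sign, weight``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import BetaMatrix, PanelDefinition
from .clocks import ClockDefinition
from .preprocess import ProbeBlacklists


def write_beta_matrix(m: BetaMatrix, path, detection_path=None) -> None:
    m.values.rename_axis("probe_id").to_csv(path, sep="\t")
    if detection_path is not None and m.detection_p is not None:
        m.detection_p.rename_axis("probe_id").to_csv(detection_path, sep="\t")


def read_beta_matrix(path, detection_path=None, design_path=None) -> BetaMatrix:
    values = pd.read_csv(path, sep="\t", index_col="probe_id")
    detp = (pd.read_csv(detection_path, sep="\t", index_col="probe_id")
            if detection_path else None)
    design = (pd.read_csv(design_path, index_col="probe_id")["design"]
              if design_path else None)
    return BetaMatrix(values=values, detection_p=detp, design=design)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_blacklists(directory) -> ProbeBlacklists:
    """Read per-category blacklist CSVs (``<name>.csv``, header ``probe_id``)."""
    directory = Path(directory)
    kwargs = {}
    for name in ("multimapping", "snp_proximal", "meqtl", "sex_chromosome"):
        f = directory / f"{name}.csv"
        if f.exists():
            kwargs[name] = set(pd.read_csv(f)["probe_id"])
    return ProbeBlacklists(**kwargs)


def write_clock(clock: ClockDefinition, csv_path, json_path) -> None:
    pd.DataFrame({"probe_id": list(clock.weights),
                  "weight": list(clock.weights.values())}).to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump({"name": clock.name, "intercept": clock.intercept,
                   "calibration": clock.calibration, "adult_age": clock.adult_age,
                   "is_age_estimator": clock.is_age_estimator}, fh)


def read_clock(csv_path, json_path) -> ClockDefinition:
    tab = pd.read_csv(csv_path)
    with open(json_path) as fh:
        meta = json.load(fh)
    return ClockDefinition(weights=dict(zip(tab["probe_id"], tab["weight"])), **meta)


def write_panel(panel: PanelDefinition, path) -> None:
    pd.DataFrame({
        "probe_id": panel.probes,
        "sign": [panel.signs[p] for p in panel.probes],
        "weight": [panel.weights.get(p, float("nan")) for p in panel.probes],
    }).to_csv(path, index=False)


def read_panel(path) -> PanelDefinition:
    tab = pd.read_csv(path)
    return PanelDefinition(
        probes=list(tab["probe_id"]),
        signs=dict(zip(tab["probe_id"], tab["sign"].astype(int))),
        weights={p: float(w) for p, w in zip(tab["probe_id"], tab["weight"])
                 if pd.notna(w)},
    )
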