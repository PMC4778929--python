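"""Delimited-text and JSON serialization.

All datasets travel as plain CSV; fitted models and the synthetic ground
truth as JSON; every run writes a manifest recording parameters and seed.
"""

from __future__ import annotations

import json
import os

import pandas as pd

from .config import RunConfig
from .pipeline import FittedModels, SimulatedData
from .qol import PooledQOLModel
from .survival import PiecewiseExponential, SplineSurvival

PROMS_DTYPES = {
    "patient_id": "int64", "brand": "string", "age": "float64",
    "sex": "string", "comorbidity_count": "int64", "asa_grade": "int64",
    "bmi": "float64", "imd_quintile": "int64", "patella_replaced": "int64",
    "disability": "int64", "surgical_position": "int64",
    "preop_eq5d": "float64", "preop_oks": "float64",
    "treatment_centre": "int64", "senior_surgeon": "int64",
    "hospital": "int64", "postop_eq5d": "float64", "postop_oks": "float64",
    "los_days": "float64",
}

DATA_DICTIONARY = {
    "proms_cohort.csv": {
        "patient_id": "synthetic patient identifier",
        "brand": "prosthesis brand (one of five cemented fixed-bearing brands)",
        "age": "age at surgery, years (inclusion window 55-84)",
        "sex": "M or F",
        "comorbidity_count": "number of patient-reported comorbidities",
        "asa_grade": "ASA physical status grade (1-3)",
        "bmi": "body mass index, kg/m^2",
        "imd_quintile": "deprivation quintile, 1 = most deprived",
        "patella_replaced": "1 if the patella was resurfaced",
        "disability": "1 if a limiting disability was reported",
        "surgical_position": "1 for the non-standard surgical approach flag",
        "preop_eq5d": "EQ-5D-3L utility index before surgery (-0.594 to 1)",
        "preop_oks": "Oxford Knee Score before surgery (0-48)",
        "treatment_centre": "1 if operated at an independent-sector treatment centre",
        "senior_surgeon": "1 if operated by a senior (consultant) surgeon",
        "hospital": "synthetic provider identifier",
        "postop_eq5d": "EQ-5D-3L utility index six months after surgery (may be missing)",
        "postop_oks": "Oxford Knee Score six months after surgery (may be missing)",
        "los_days": "length of the primary hospital stay, days",
    },
    "revisions.csv": {
        "patient_id": "synthetic patient identifier",
        "brand": "prosthesis brand",
        "time_to_event": "years from primary surgery to revision or censoring",
        "event": "1 = revision observed, 0 = censored",
        "antibiotic_cement": "1 if antibiotic-loaded cement was used",
    },
    "rerevisions.csv": {
        "patient_id": "synthetic revision-patient identifier",
        "time_to_event": "years from first revision to re-revision or censoring",
        "event": "1 = re-revision observed, 0 = censored",
    },
}


def write_datasets(data: SimulatedData, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    data.proms.to_csv(os.path.join(outdir, "proms_cohort.csv"), index=False)
    data.revisions.to_csv(os.path.join(outdir, "revisions.csv"), index=False)
    data.rerevisions.to_csv(os.path.join(outdir, "rerevisions.csv"), index=False)
    data.revision_proms.to_csv(os.path.join(outdir, "revision_proms.csv"),
                               index=False)
    data.truth.to_json(os.path.join(outdir, "truth.json"))
    with open(os.path.join(outdir, "data_dictionary.json"), "w") as fh:
        json.dump(DATA_DICTIONARY, fh, indent=1)


def read_proms(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c, t in PROMS_DTYPES.items():
        if c in df.columns:
            df[c] = df[c].astype(t)
    df["brand"] = df["brand"].astype(object)
    df["sex"] = df["sex"].astype(object)
    return df


def read_survival(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def _pooled_qol_dict(m: PooledQOLModel | None) -> dict | None:
    if m is None:
        return None
    return {
        "terms": list(m.params_.index),
        "params": m.params_.to_list(),
        "cov": m.cov_.to_numpy().tolist(),
        "m_imputations": m.m,
        "fp_selections": {
            c: {"kind": s.kind, "powers": list(s.powers),
                "shift": s.shift, "scale": s.scale}
            for c, s in m.ref.fp_selections_.items()},
    }


def write_models(models: FittedModels, path: str) -> None:
    payload = {
        "qol": _pooled_qol_dict(models.qol),
        "oks": _pooled_qol_dict(models.oks),
        "state_pre": {"params": models.state_pre.params_.to_list(),
                      "cov": models.state_pre.cov_.to_numpy().tolist()},
        "state_post": {"params": models.state_post.params_.to_list(),
                       "cov": models.state_post.cov_.to_numpy().tolist()},
        "revision": {b: m.to_dict() for b, m in models.revision.items()},
        "rerevision": models.rerevision.to_dict(),
        "los": {f"{b}|{s}": list(v) for (b, s), v in models.los.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_survival_model(d: dict) -> SplineSurvival | PiecewiseExponential:
    if d["model"] == "spline_survival":
        return SplineSurvival.from_dict(d)
    return PiecewiseExponential.from_dict(d)


def write_manifest(run: RunConfig, path: str, **extra) -> None:
    payload = {"seed": run.seed, "config": run.to_manifest(), **extra}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
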