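"""Ingestion of CRF metadata into the trial-master model.

Two source shapes are supported: CDISC ODM 1.3 XML (see :mod:`.odm`) and
delimited tables with a column-mapping *dialect* (CRFs exported from
spreadsheets upstream).  Trial metadata — disease area, planned
enrollment, site count — arrives as a separate CSV and is mandatory:
trials without a planned enrollment are rejected because the inventory
ranking needs the weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .model import DataType, FormDef, ItemRecord, StudySet, TrialMeta
from .odm import parse_odm, write_odm

AREA_ORDER = (
    "cardiovascular",
    "diabetes",
    "infectious",
    "neuroscience",
    "oncology",
    "psychiatric",
    "respiratory",
)


@dataclass
class TableDialect:
    """Column mapping for delimited CRF exports.

    ``columns`` maps model fields to source column names; ``trial_id``,
    ``form_id``, ``form_name`` and ``label`` are mandatory.
    """

    columns: dict[str, str]
    separator: str = ","
    encoding: str = "utf-8"

    MANDATORY = ("trial_id", "form_id", "form_name", "label")
    OPTIONAL = ("item_id", "cdisc_variable_name", "data_type", "units", "repeating")

    def __post_init__(self) -> None:
        missing = [c for c in self.MANDATORY if c not in self.columns]
        if missing:
            raise ValueError(f"dialect missing mandatory column mappings: {missing}")
        unknown = [
            c for c in self.columns if c not in self.MANDATORY + self.OPTIONAL
        ]
        if unknown:
            raise ValueError(f"dialect maps unknown fields: {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TableDialect":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(
            columns=cfg["columns"],
            separator=cfg.get("separator", ","),
            encoding=cfg.get("encoding", "utf-8"),
        )


def parse_table(path: str | Path, dialect: TableDialect) -> StudySet:
    """Parse a delimited CRF export into a StudySet fragment.

    Rows with an empty label are dropped and counted in the provenance
    entry; duplicate (form, item) pairs are an error.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=dialect.separator, encoding=dialect.encoding, dtype=str
    )
    cols = dialect.columns
    missing = [src for src in cols.values() if src not in df.columns]
    if missing:
        raise ValueError(f"{path}: mapped columns absent from file: {missing}")

    def get(row, field_name, default=None):
        src = cols.get(field_name)
        if src is None:
            return default
        val = row[src]
        if pd.isna(val) or str(val).strip() == "":
            return default
        return str(val).strip()

    n_dropped = 0
    forms: dict[str, FormDef] = {}
    items_per_form: dict[str, list[ItemRecord]] = {}
    counters: dict[str, int] = {}
    collisions: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        label_src = row[cols["label"]]
        label = None if pd.isna(label_src) else str(label_src).strip()
        if not label:
            n_dropped += 1
            continue
        form_id = get(row, "form_id")
        if form_id not in forms:
            forms[form_id] = FormDef(
                form_id=form_id,
                trial_id=get(row, "trial_id"),
                form_name=get(row, "form_name") or form_id,
                items=[],
                repeating=(get(row, "repeating", "") or "").lower()
                in ("yes", "true", "1"),
            )
            items_per_form[form_id] = []
        counters[form_id] = counters.get(form_id, 0) + 1
        item_id = get(row, "item_id") or f"{form_id}.IT{counters[form_id]:03d}"
        if any(i.item_id == item_id for i in items_per_form[form_id]):
            collisions.append((form_id, item_id))
            continue
        dt = (get(row, "data_type") or "text").lower()
        items_per_form[form_id].append(
            ItemRecord(
                item_id=item_id,
                form_id=form_id,
                raw_label=label,
                cdisc_variable_name=get(row, "cdisc_variable_name"),
                data_type=DataType(dt) if dt in DataType._value2member_map_ else DataType.text,
                units=get(row, "units"),
            )
        )
    if collisions:
        raise ValueError(f"{path}: duplicate (form, item) pairs: {collisions}")
    out_forms = []
    for fid, f in forms.items():
        f.items = items_per_form[fid]
        out_forms.append(f)
    return StudySet(
        trials=[],
        forms=out_forms,
        provenance=[
            {
                "source": str(path),
                "format": "table",
                "n_forms": len(out_forms),
                "n_items": sum(len(f.items) for f in out_forms),
                "n_dropped_empty_label": n_dropped,
            }
        ],
    )


def load_trial_meta(path: str | Path) -> list[TrialMeta]:
    """Read the trial-metadata CSV (trial_id, disease_area,
    planned_enrollment, n_sites).  Missing enrollment is a hard error."""
    df = pd.read_csv(path)
    required = {"trial_id", "disease_area", "planned_enrollment", "n_sites"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: trial metadata missing columns {sorted(missing)}")
    trials = []
    for _, row in df.iterrows():
        if pd.isna(row["planned_enrollment"]):
            raise ValueError(
                f"{path}: trial {row['trial_id']} lacks planned_enrollment"
            )
        trials.append(
            TrialMeta(
                trial_id=str(row["trial_id"]),
                disease_area=str(row["disease_area"]),
                planned_enrollment=int(row["planned_enrollment"]),
                n_sites=int(row["n_sites"]),
            )
        )
    return trials


def save_trial_meta(trials: Sequence[TrialMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "trial_id": t.trial_id,
                "disease_area": t.disease_area.value,
                "planned_enrollment": t.planned_enrollment,
                "n_sites": t.n_sites,
            }
            for t in trials
        ]
    ).to_csv(path, index=False)


def assemble_study_set(
    fragments: Iterable[StudySet], trials: Sequence[TrialMeta]
) -> StudySet:
    """Combine parsed fragments with trial metadata and validate."""
    combined = StudySet(trials=list(trials))
    for frag in fragments:
        combined = StudySet(
            trials=combined.trials,
            forms=combined.forms + frag.forms,
            provenance=combined.provenance + frag.provenance,
        )
    combined.validate()
    return combined


def tabulate_corpus(study_set: StudySet) -> pd.DataFrame:
    """Per-disease-area corpus table with a Sum row.

    Rows appear for every area present in the study set (in canonical
    area order); ``Sum`` carries the column totals.
    """
    rows = []
    by_area: dict[str, set[str]] = {}
    for t in study_set.trials:
        by_area.setdefault(t.disease_area.value, set()).add(t.trial_id)
    forms_per_trial: dict[str, int] = {}
    for f in study_set.forms:
        forms_per_trial[f.trial_id] = forms_per_trial.get(f.trial_id, 0) + 1
    for area in AREA_ORDER:
        if area not in by_area:
            continue
        trial_ids = by_area[area]
        rows.append(
            {
                "disease_area": area,
                "n_trials": len(trial_ids),
                "n_forms": sum(forms_per_trial.get(t, 0) for t in trial_ids),
            }
        )
    total = {
        "disease_area": "Sum",
        "n_trials": sum(r["n_trials"] for r in rows),
        "n_forms": sum(r["n_forms"] for r in rows),
    }
    rows.append(total)
    return pd.DataFrame(rows, columns=["disease_area", "n_trials", "n_forms"])


def save_study_set(study_set: StudySet, out_dir: str | Path) -> dict[str, Path]:
    """Persist the TMDB as canonical ODM + trial-meta CSV + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    odm_path = out / "studyset.odm.xml"
    meta_path = out / "trials_meta.csv"
    manifest_path = out / "manifest.json"
    write_odm(study_set, odm_path)
    save_trial_meta(study_set.trials, meta_path)
    manifest_path.write_text(
        json.dumps(
            {
                "n_trials": len(study_set.trials),
                "n_forms": len(study_set.forms),
                "n_items": study_set.n_items,
                "provenance": study_set.provenance,
            },
            indent=2,
        )
    )
    return {"odm": odm_path, "meta": meta_path, "manifest": manifest_path}


def load_study_set(in_dir: str | Path) -> StudySet:
    """Load a TMDB previously written by :func:`save_study_set`."""
    in_dir = Path(in_dir)
    frag = parse_odm(in_dir / "studyset.odm.xml")
    trials = load_trial_meta(in_dir / "trials_meta.csv")
    return assemble_study_set([frag], trials)
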