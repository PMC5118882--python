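"""Form-to-domain classification.

Every CRF form gets exactly one topic domain, SDTM-coded where a code
exists (two custom entries: Disease Characteristics "(ZC)" and Surgery,
which has none).  The shipped dictionary carries keyword rules as a
surrogate for expert allocation; an override table is authoritative
where present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .model import FormDef, StudySet
from .normalize import ElementCluster, clean_label

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class DomainDef:
    """One form domain: key, optional 2-letter SDTM code, keyword rules."""

    domain_key: str
    display_name: str
    sdtm_code: str | None = None
    keywords: tuple[str, ...] = ()
    custom: bool = False

    def __post_init__(self) -> None:
        if self.sdtm_code is not None and not (
            len(self.sdtm_code) == 2 and self.sdtm_code.isalpha()
            and self.sdtm_code.isupper()
        ):
            raise ValueError(
                f"domain {self.domain_key}: sdtm_code must be 2 uppercase "
                f"letters, got {self.sdtm_code!r}"
            )


#: The 14 consensus form domains, in rank order, with keyword surrogates
#: for expert allocation.  First matching rule (dictionary order) wins.
DEFAULT_DOMAIN_DICTIONARY: tuple[DomainDef, ...] = (
    DomainDef("MH", "Medical History", "MH",
              ("medical history", "history", "prior condition")),
    DomainDef("AE", "Adverse Event", "AE",
              ("adverse event", "serious adverse", "sae", "adverse experience")),
    DomainDef("LB", "Laboratory test results", "LB",
              ("laboratory", "lab test", "lab results", "chemistry",
               "hematology", "haematology", "coagulation", "urinalysis",
               "panel", "serology", "lipid")),
    DomainDef("DS", "Disposition", "DS",
              ("disposition", "completion", "termination", "withdrawal",
               "end of study", "end of treatment", "discontinuation")),
    DomainDef("VS", "Vital Signs", "VS", ("vital sign", "vitals")),
    DomainDef("CM", "Concomitant Medications", "CM",
              ("concomitant", "medication", "con med", "conmed",
               "prior therapy")),
    DomainDef("QS", "Questionnaire/Patient reported outcome", "QS",
              ("questionnaire", "patient reported", "quality of life",
               "qol", "scale", "score", "survey", "diary")),
    DomainDef("DM", "Demographics", "DM", ("demograph",)),
    DomainDef("EG", "ECG", "EG", ("ecg", "electrocardiogram", "holter")),
    DomainDef("ZC", "Disease Characteristics", "ZC",
              ("disease characteristic", "diagnosis", "staging",
               "disease status", "disease assessment"), custom=True),
    DomainDef("SU", "Substance Use", "SU",
              ("substance", "smoking", "tobacco", "alcohol", "caffeine",
               "drug use")),
    DomainDef("SURGERY", "Surgery", None,
              ("surgery", "surgical", "operation", "procedure")),
    DomainDef("PE", "Physical Examination", "PE",
              ("physical exam",)),
    DomainDef("RS", "Tumor response", "RS",
              ("tumor response", "tumour response", "response assessment",
               "recist", "tumor assessment")),
)


@dataclass(frozen=True)
class FormDomainAssignment:
    form_id: str
    domain_key: str
    method: str  # override | keyword | unassigned

    def __post_init__(self) -> None:
        if self.method not in ("override", "keyword", "unassigned"):
            raise ValueError(f"unknown assignment method {self.method!r}")


def load_domain_dictionary(path: str | Path) -> tuple[DomainDef, ...]:
    """Read a dictionary CSV (domain_key, display_name, sdtm_code,
    keywords semicolon-separated, custom)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    out = []
    for _, r in df.iterrows():
        out.append(
            DomainDef(
                domain_key=r["domain_key"],
                display_name=r["display_name"],
                sdtm_code=r["sdtm_code"] or None,
                keywords=tuple(
                    k.strip() for k in r["keywords"].split(";") if k.strip()
                ),
                custom=str(r.get("custom", "")).lower() in ("true", "1", "yes"),
            )
        )
    return tuple(out)


def load_domain_overrides(path: str | Path) -> dict[str, str]:
    """Read form-level overrides (form_id, domain_key); conflicting rows
    for one form are fatal."""
    df = pd.read_csv(path, dtype=str)
    out: dict[str, str] = {}
    conflicts = []
    for _, r in df.iterrows():
        fid, dk = str(r["form_id"]), str(r["domain_key"])
        if fid in out and out[fid] != dk:
            conflicts.append(fid)
        out[fid] = dk
    if conflicts:
        raise ValueError(f"conflicting domain overrides for forms: {sorted(set(conflicts))}")
    return out


def assign_domain(
    form: FormDef,
    dictionary: Sequence[DomainDef] = DEFAULT_DOMAIN_DICTIONARY,
    overrides: Mapping[str, str] | None = None,
) -> FormDomainAssignment:
    """Override > first keyword rule on the cleaned form name > unassigned."""
    if not dictionary:
        raise ValueError("domain dictionary must be nonempty")
    if overrides and form.form_id in overrides:
        return FormDomainAssignment(form.form_id, overrides[form.form_id], "override")
    name = clean_label(form.form_name).text.casefold()
    for dom in dictionary:
        for kw in dom.keywords:
            if kw.casefold() in name:
                return FormDomainAssignment(form.form_id, dom.domain_key, "keyword")
    return FormDomainAssignment(form.form_id, UNASSIGNED, "unassigned")


def assign_domains(
    study_set: StudySet,
    dictionary: Sequence[DomainDef] = DEFAULT_DOMAIN_DICTIONARY,
    overrides: Mapping[str, str] | None = None,
) -> list[FormDomainAssignment]:
    return [assign_domain(f, dictionary, overrides) for f in study_set.forms]


def domain_table(
    assignments: Sequence[FormDomainAssignment],
    study_set: StudySet,
    clusters: Sequence[ElementCluster] | None = None,
    dictionary: Sequence[DomainDef] = DEFAULT_DOMAIN_DICTIONARY,
) -> pd.DataFrame:
    """Ranked per-domain table: n_trials, n_forms, n_unique_elements.

    Sorted by n_trials desc, n_forms desc, domain_key asc (a total
    order, so output is stable).  Includes an 'unassigned' row when any
    form fell through, so form counts are conserved.
    """
    by_form = {a.form_id: a.domain_key for a in assignments}
    form_trial = study_set.form_trial_map()
    trials_per_domain: dict[str, set[str]] = {}
    forms_per_domain: dict[str, int] = {}
    for f in study_set.forms:
        dk = by_form.get(f.form_id, UNASSIGNED)
        trials_per_domain.setdefault(dk, set()).add(f.trial_id)
        forms_per_domain[dk] = forms_per_domain.get(dk, 0) + 1

    elements_per_domain: dict[str, set[str]] = {}
    if clusters is not None:
        for c in clusters:
            for _tr, fid, _iid in c.members:
                dk = by_form.get(fid, UNASSIGNED)
                elements_per_domain.setdefault(dk, set()).add(c.cluster_id)

    names = {d.domain_key: d.display_name for d in dictionary}
    codes = {d.domain_key: d.sdtm_code or "" for d in dictionary}
    rows = []
    for dk in forms_per_domain:
        rows.append(
            {
                "domain_key": dk,
                "display_name": names.get(dk, dk),
                "sdtm_code": codes.get(dk, ""),
                "n_trials": len(trials_per_domain[dk]),
                "n_forms": forms_per_domain[dk],
                "n_unique_elements": len(elements_per_domain.get(dk, set())),
            }
        )
    rows.sort(key=lambda r: (-r["n_trials"], -r["n_forms"], r["domain_key"]))
    return pd.DataFrame(
        rows,
        columns=[
            "domain_key", "display_name", "sdtm_code",
            "n_trials", "n_forms", "n_unique_elements",
        ],
    )


def assignments_to_frame(
    assignments: Sequence[FormDomainAssignment],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"form_id": a.form_id, "domain_key": a.domain_key, "method": a.method}
            for a in assignments
        ],
        columns=["form_id", "domain_key", "method"],
    )


def assignments_from_frame(df: pd.DataFrame) -> list[FormDomainAssignment]:
    return [
        FormDomainAssignment(str(r.form_id), str(r.domain_key), str(r.method))
        for r in df.itertuples()
    ]
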