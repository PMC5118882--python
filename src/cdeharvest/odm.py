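"""CDISC ODM 1.3 metadata reader and writer (lxml-based).

Only the study-metadata section is handled: Study / MetaDataVersion /
FormDef / ItemGroupDef / ItemDef.  Clinical (subject) data sections are
out of scope.  Item labels are taken from the item Question, preferring
the configured language's TranslatedText, falling back to any question
text, then to the item Name attribute; SDSVarName populates the CDISC
variable name.
"""

from __future__ import annotations

import warnings
from pathlib import Path

from lxml import etree

from .model import DataType, FormDef, ItemRecord, StudySet

ODM_NS = "http://www.cdisc.org/ns/odm/v1.3"
XML_NS = "http://www.w3.org/XML/1998/namespace"
_NSMAP = {"odm": ODM_NS}

SUPPORTED_ODM_VERSIONS = ("1.3", "1.3.1", "1.3.2")

# ODM DataType attribute -> internal enum (identity for most)
_DATATYPE_IN = {
    "text": DataType.text,
    "string": DataType.text,
    "integer": DataType.integer,
    "float": DataType.float,
    "double": DataType.float,
    "date": DataType.date,
    "datetime": DataType.datetime,
    "boolean": DataType.boolean,
    "codelist": DataType.codelist,
}
_DATATYPE_OUT = {
    DataType.text: "text",
    DataType.integer: "integer",
    DataType.float: "float",
    DataType.date: "date",
    DataType.datetime: "datetime",
    DataType.boolean: "boolean",
    DataType.codelist: "text",  # ODM has no 'codelist' DataType; kept as text
}


class OdmParseError(ValueError):
    """Raised for malformed or metadata-free ODM input."""


def _q(tag: str) -> str:
    return f"{{{ODM_NS}}}{tag}"


def _item_label(item_def: etree._Element, language: str) -> str | None:
    """Question TranslatedText (preferred language > first) > Name."""
    texts = item_def.findall(f"{_q('Question')}/{_q('TranslatedText')}")
    chosen = None
    for tt in texts:
        lang = tt.get(f"{{{XML_NS}}}lang")
        text = (tt.text or "").strip()
        if not text:
            continue
        if lang == language:
            return text
        if chosen is None:
            chosen = text
    if chosen is not None:
        return chosen
    name = item_def.get("Name")
    return name.strip() if name else None


def parse_odm(path: str | Path, language: str = "en") -> StudySet:
    """Parse one ODM 1.3 file into a StudySet fragment (no trial meta).

    Every FormDef in the metadata appears exactly once; items with an
    empty resolved label are dropped (and the drop is recorded in the
    fragment's provenance entry).
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise OdmParseError(f"cannot parse ODM file {path}: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "ODM":
        raise OdmParseError(f"{path}: root element is not ODM")
    version = root.get("ODMVersion")
    if version and version not in SUPPORTED_ODM_VERSIONS:
        warnings.warn(
            f"{path}: unknown ODMVersion {version!r}; attempting best-effort parse",
            stacklevel=2,
        )

    forms: list[FormDef] = []
    n_dropped = 0
    studies = root.findall(_q("Study"))
    any_meta = False
    for study in studies:
        trial_id = study.get("OID") or path.stem
        for mdv in study.findall(_q("MetaDataVersion")):
            any_meta = True
            item_defs = {
                idf.get("OID"): idf for idf in mdv.findall(_q("ItemDef"))
            }
            group_defs = {
                g.get("OID"): g for g in mdv.findall(_q("ItemGroupDef"))
            }
            for form_el in mdv.findall(_q("FormDef")):
                form_id = form_el.get("OID")
                items: list[ItemRecord] = []
                for gref in form_el.findall(_q("ItemGroupRef")):
                    group = group_defs.get(gref.get("ItemGroupOID"))
                    if group is None:
                        continue
                    for iref in group.findall(_q("ItemRef")):
                        idef = item_defs.get(iref.get("ItemOID"))
                        if idef is None:
                            continue
                        label = _item_label(idef, language)
                        if not label:
                            n_dropped += 1
                            continue
                        items.append(
                            ItemRecord(
                                item_id=idef.get("OID"),
                                form_id=form_id,
                                raw_label=label,
                                cdisc_variable_name=idef.get("SDSVarName"),
                                data_type=_DATATYPE_IN.get(
                                    (idef.get("DataType") or "text").lower(),
                                    DataType.text,
                                ),
                            )
                        )
                forms.append(
                    FormDef(
                        form_id=form_id,
                        trial_id=trial_id,
                        form_name=form_el.get("Name") or form_id,
                        items=items,
                        repeating=(form_el.get("Repeating") == "Yes"),
                    )
                )
    if not any_meta:
        raise OdmParseError(f"{path}: no study metadata (MetaDataVersion) found")
    return StudySet(
        trials=[],
        forms=forms,
        provenance=[
            {
                "source": str(path),
                "format": "odm",
                "n_forms": len(forms),
                "n_items": sum(len(f.items) for f in forms),
                "n_dropped_empty_label": n_dropped,
            }
        ],
    )


def write_odm(study_set: StudySet, path: str | Path, language: str = "en") -> None:
    """Write the StudySet as canonical ODM 1.3 XML (one Study per trial).

    Re-parsing the output reproduces the same forms and items
    (round-trip identity); trial metadata lives in the companion CSV,
    not in the ODM.
    """
    root = etree.Element(_q("ODM"), nsmap={None: ODM_NS})
    root.set("ODMVersion", "1.3")
    root.set("FileType", "Snapshot")
    root.set("FileOID", "cdeharvest.studyset")

    by_trial: dict[str, list[FormDef]] = {}
    for f in study_set.forms:
        by_trial.setdefault(f.trial_id, []).append(f)

    trial_order = study_set.trial_ids or sorted(by_trial)
    for trial_id in trial_order:
        study = etree.SubElement(root, _q("Study"), OID=trial_id)
        gv = etree.SubElement(study, _q("GlobalVariables"))
        etree.SubElement(gv, _q("StudyName")).text = trial_id
        etree.SubElement(gv, _q("StudyDescription")).text = trial_id
        etree.SubElement(gv, _q("ProtocolName")).text = trial_id
        mdv = etree.SubElement(
            study, _q("MetaDataVersion"), OID=f"{trial_id}.MDV", Name="metadata"
        )
        forms = by_trial.get(trial_id, [])
        for form in forms:
            fel = etree.SubElement(
                mdv,
                _q("FormDef"),
                OID=form.form_id,
                Name=form.form_name,
                Repeating="Yes" if form.repeating else "No",
            )
            etree.SubElement(
                fel, _q("ItemGroupRef"), ItemGroupOID=f"{form.form_id}.IG",
                Mandatory="No",
            )
        for form in forms:
            gel = etree.SubElement(
                mdv,
                _q("ItemGroupDef"),
                OID=f"{form.form_id}.IG",
                Name=form.form_name,
                Repeating="No",
            )
            for order, item in enumerate(form.items, start=1):
                etree.SubElement(
                    gel,
                    _q("ItemRef"),
                    ItemOID=item.item_id,
                    OrderNumber=str(order),
                    Mandatory="No",
                )
        for form in forms:
            for item in form.items:
                attrs = {
                    "OID": item.item_id,
                    "Name": item.raw_label,
                    "DataType": _DATATYPE_OUT[item.data_type],
                }
                if item.cdisc_variable_name:
                    attrs["SDSVarName"] = item.cdisc_variable_name
                iel = etree.SubElement(mdv, _q("ItemDef"), **attrs)
                q = etree.SubElement(iel, _q("Question"))
                tt = etree.SubElement(q, _q("TranslatedText"))
                tt.set(f"{{{XML_NS}}}lang", language)
                tt.text = item.raw_label

    Path(path).write_bytes(
        etree.tostring(
            root, xml_declaration=True, encoding="UTF-8", pretty_print=True
        )
    )
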