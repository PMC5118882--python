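"""Ranked common-data-element inventory.

Domains that occur only once corpus-wide are dropped; elements are
ranked within the surviving domains by an enrollment-weighted score (the
sum of planned enrollments of the distinct trials containing the
element — exposed alternative: per form occurrence), with semantic codes
(UMLS CUI / SNOMED CT) attached from a static mapping table and a
comparison against a prior inventory.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .domains import UNASSIGNED, FormDomainAssignment
from .model import TrialMeta
from .normalize import ElementCluster

logger = logging.getLogger(__name__)

_CUI_RE = re.compile(r"^C\d{7}$")
_SNOMED_RE = re.compile(r"^\d+$")


@dataclass
class CanonicalElement:
    """One deduplicated common data element."""

    cde_id: str
    canonical_label: str
    domain_key: str
    category: str = "clinical"  # clinical | administrative
    umls_cui: str | None = None
    snomed_code: str | None = None
    sdtm_variable: str | None = None
    definition: str | None = None

    def __post_init__(self) -> None:
        if self.category not in ("clinical", "administrative"):
            raise ValueError(f"unknown category {self.category!r}")
        if self.umls_cui is not None and not _CUI_RE.match(self.umls_cui):
            raise ValueError(f"invalid UMLS CUI {self.umls_cui!r}")
        if self.snomed_code is not None and not _SNOMED_RE.match(self.snomed_code):
            raise ValueError(f"invalid SNOMED code {self.snomed_code!r}")


@dataclass
class InventoryRow:
    element: CanonicalElement
    n_trials: int
    n_form_occurrences: int
    weighted_score: int
    rank: int = 0
    uncoded: bool = True


@dataclass(frozen=True)
class InventoryComparison:
    n_identical: int
    n_new: int
    identical_ids: tuple[str, ...]
    new_ids: tuple[str, ...]


def filter_domains(table: pd.DataFrame, min_forms: int = 2) -> pd.DataFrame:
    """Drop domains whose forms appear no more than once corpus-wide.

    The singleton rule is interpreted corpus-wide (a domain with two
    forms in one trial survives); ``min_forms`` exposes the alternative.
    """
    if table.empty:
        return table
    dropped = table.loc[table["n_forms"] < min_forms, "domain_key"].tolist()
    if dropped:
        logger.info("removed singleton domains: %s", dropped)
    return table.loc[table["n_forms"] >= min_forms].reset_index(drop=True)


def rank_elements(
    clusters: Sequence[ElementCluster],
    assignments: Sequence[FormDomainAssignment],
    trials: Sequence[TrialMeta],
    *,
    weight: str = "per_trial",
    domains_keep: set[str] | None = None,
) -> list[InventoryRow]:
    """Rank elements by enrollment-weighted frequency.

    weighted_score = sum of planned enrollments over the distinct trials
    containing the element (``weight='per_form'`` instead sums the
    enrollment of the owning trial once per form occurrence).  Elements
    spanning several domains yield one row per domain with per-domain
    counts (logged).  Sort: score desc, n_trials desc, label asc; ranks
    are dense 1..N.  The result is independent of cluster input order.
    """
    if weight not in ("per_trial", "per_form"):
        raise ValueError("weight must be 'per_trial' or 'per_form'")
    enrollment = {t.trial_id: t.planned_enrollment for t in trials}
    form_domain = {a.form_id: a.domain_key for a in assignments}

    rows: list[InventoryRow] = []
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        per_domain: dict[str, list[tuple[str, str]]] = {}
        for tr, fid, _iid in c.members:
            dk = form_domain.get(fid, UNASSIGNED)
            per_domain.setdefault(dk, []).append((tr, fid))
        if len(per_domain) > 1:
            logger.info(
                "element %s (%s) spans domains %s; one row per domain",
                c.cluster_id, c.canonical_label, sorted(per_domain),
            )
        for dk, occ in sorted(per_domain.items()):
            if domains_keep is not None and dk not in domains_keep:
                continue
            trial_set = sorted({tr for tr, _ in occ})
            form_set = sorted({fid for _, fid in occ})
            missing = [t for t in trial_set if t not in enrollment]
            if missing:
                raise ValueError(
                    f"element {c.cluster_id}: trials without enrollment: {missing}"
                )
            if weight == "per_trial":
                score = sum(enrollment[t] for t in trial_set)
            else:
                per_trial_forms: dict[str, set[str]] = {}
                for tr, fid in occ:
                    per_trial_forms.setdefault(tr, set()).add(fid)
                score = sum(
                    enrollment[tr] * len(fids)
                    for tr, fids in per_trial_forms.items()
                )
            suffix = "" if len(per_domain) == 1 else f"@{dk}"
            rows.append(
                InventoryRow(
                    element=CanonicalElement(
                        cde_id=c.cluster_id + suffix,
                        canonical_label=c.canonical_label,
                        domain_key=dk,
                        category=c.category or "clinical",
                        sdtm_variable=c.cdisc_variable_name,
                    ),
                    n_trials=len(trial_set),
                    n_form_occurrences=len(form_set),
                    weighted_score=score,
                )
            )
    rows.sort(
        key=lambda r: (
            -r.weighted_score,
            -r.n_trials,
            r.element.canonical_label.casefold(),
            r.element.cde_id,
        )
    )
    for i, r in enumerate(rows, start=1):
        r.rank = i
    return rows


def compare_inventories(
    current: Sequence[InventoryRow], prior: pd.DataFrame
) -> InventoryComparison:
    """Partition the current inventory into identical-to-prior and new.

    Match precedence: equal UMLS CUIs; else (when either side lacks a
    CUI) case-folded canonical labels.  Duplicate keys in the prior list
    are fatal.
    """
    prior = prior.fillna("")
    labels = [str(x).casefold() for x in prior.get("canonical_label", [])]
    cuis = [
        str(x) for x in prior.get("umls_cui", pd.Series([""] * len(prior)))
    ]
    nonempty_cuis = [c for c in cuis if c]
    if len(labels) != len(set(labels)) or len(nonempty_cuis) != len(
        set(nonempty_cuis)
    ):
        raise ValueError("duplicate keys in prior inventory")
    prior_cuis = set(nonempty_cuis)
    cui_by_label = dict(zip(labels, cuis))

    identical, new = [], []
    for row in current:
        cui = row.element.umls_cui
        label = row.element.canonical_label.casefold()
        if cui and cui in prior_cuis:
            identical.append(row.element.cde_id)
        elif label in cui_by_label and (not cui or not cui_by_label[label]):
            # fall back to the label key when either side lacks a CUI
            identical.append(row.element.cde_id)
        else:
            new.append(row.element.cde_id)
    return InventoryComparison(
        n_identical=len(identical),
        n_new=len(new),
        identical_ids=tuple(identical),
        new_ids=tuple(new),
    )


def annotate(
    inventory: Sequence[InventoryRow], code_map: pd.DataFrame | None
) -> list[InventoryRow]:
    """Attach UMLS / SNOMED codes from a static mapping table.

    Map rows carry ``key`` (cde_id or case-insensitive canonical label),
    ``umls_cui``, ``snomed_code``, optional ``definition``.  A
    syntactically invalid code is a fatal validation error naming the
    row; unmapped elements keep ``uncoded=True`` (counted in the log).
    """
    if code_map is None or len(code_map) == 0:
        for r in inventory:
            r.uncoded = True
        return list(inventory)
    code_map = code_map.fillna("")
    by_key: dict[str, dict] = {}
    for idx, row in code_map.iterrows():
        cui = str(row.get("umls_cui", "")).strip()
        sno = str(row.get("snomed_code", "")).strip()
        if cui and not _CUI_RE.match(cui):
            raise ValueError(f"code map row {idx}: invalid UMLS CUI {cui!r}")
        if sno and not _SNOMED_RE.match(sno):
            raise ValueError(f"code map row {idx}: invalid SNOMED code {sno!r}")
        by_key[str(row["key"]).casefold()] = {
            "umls_cui": cui or None,
            "snomed_code": sno or None,
            "definition": str(row.get("definition", "")).strip() or None,
        }
    n_uncoded = 0
    for r in inventory:
        hit = by_key.get(r.element.cde_id.casefold()) or by_key.get(
            r.element.canonical_label.casefold()
        )
        if hit:
            r.element.umls_cui = hit["umls_cui"]
            r.element.snomed_code = hit["snomed_code"]
            if hit["definition"]:
                r.element.definition = hit["definition"]
            r.uncoded = hit["umls_cui"] is None and hit["snomed_code"] is None
        else:
            r.uncoded = True
            n_uncoded += 1
    if n_uncoded:
        logger.info("%d inventory elements remain uncoded", n_uncoded)
    return list(inventory)


# ---------------------------------------------------------------------------
# persistence

def inventory_to_frame(inventory: Sequence[InventoryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": r.rank,
                "cde_id": r.element.cde_id,
                "canonical_label": r.element.canonical_label,
                "domain_key": r.element.domain_key,
                "category": r.element.category,
                "n_trials": r.n_trials,
                "n_form_occurrences": r.n_form_occurrences,
                "weighted_score": r.weighted_score,
                "umls_cui": r.element.umls_cui or "",
                "snomed_code": r.element.snomed_code or "",
                "sdtm_variable": r.element.sdtm_variable or "",
                "definition": r.element.definition or "",
                "uncoded": r.uncoded,
            }
            for r in inventory
        ],
        columns=[
            "rank", "cde_id", "canonical_label", "domain_key", "category",
            "n_trials", "n_form_occurrences", "weighted_score",
            "umls_cui", "snomed_code", "sdtm_variable", "definition", "uncoded",
        ],
    )


def inventory_from_frame(df: pd.DataFrame) -> list[InventoryRow]:
    df = df.fillna("")
    out = []
    for r in df.itertuples():
        out.append(
            InventoryRow(
                element=CanonicalElement(
                    cde_id=str(r.cde_id),
                    canonical_label=str(r.canonical_label),
                    domain_key=str(r.domain_key),
                    category=str(r.category) or "clinical",
                    umls_cui=str(r.umls_cui) or None,
                    snomed_code=str(r.snomed_code) or None,
                    sdtm_variable=str(r.sdtm_variable) or None,
                    definition=str(r.definition) or None,
                ),
                n_trials=int(r.n_trials),
                n_form_occurrences=int(r.n_form_occurrences),
                weighted_score=int(r.weighted_score),
                rank=int(r.rank),
                uncoded=bool(r.uncoded),
            )
        )
    return out


def comparison_to_json(cmp: InventoryComparison, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "n_identical": cmp.n_identical,
                "n_new": cmp.n_new,
                "identical_ids": list(cmp.identical_ids),
                "new_ids": list(cmp.new_ids),
            },
            indent=2,
        )
    )
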