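"""Core data model for the trial-master database (TMDB).

The unit of analysis is the *data element* (item) on a case report form
(CRF).  A study set bundles every ingested trial: trial-level metadata
(disease area, planned enrollment, site count), the forms of each CRF and
the raw items on each form.  Downstream stages (normalization, domain
mapping, inventory ranking, EHR coverage) all operate on this model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator


class DiseaseArea(str, Enum):
    """Closed set of therapeutic areas covered by the corpus."""

    cardiovascular = "cardiovascular"
    diabetes = "diabetes"
    infectious = "infectious"
    neuroscience = "neuroscience"
    oncology = "oncology"
    psychiatric = "psychiatric"
    respiratory = "respiratory"


class DataType(str, Enum):
    text = "text"
    integer = "integer"
    float = "float"
    date = "date"
    datetime = "datetime"
    boolean = "boolean"
    codelist = "codelist"


@dataclass(frozen=True)
class TrialMeta:
    """Identity and weighting metadata for one clinical trial.

    ``planned_enrollment`` is the ranking weight used by the inventory
    builder; trials without it are rejected at ingestion rather than
    defaulted.
    """

    trial_id: str
    disease_area: DiseaseArea
    planned_enrollment: int
    n_sites: int

    def __post_init__(self) -> None:
        if not self.trial_id:
            raise ValueError("trial_id must be non-empty")
        object.__setattr__(self, "disease_area", DiseaseArea(self.disease_area))
        if self.planned_enrollment < 1:
            raise ValueError(
                f"trial {self.trial_id}: planned_enrollment must be >= 1, "
                f"got {self.planned_enrollment}"
            )
        if self.n_sites < 1:
            raise ValueError(f"trial {self.trial_id}: n_sites must be >= 1")


@dataclass(frozen=True)
class ItemRecord:
    """One raw CRF data element as ingested (label not yet cleaned)."""

    item_id: str
    form_id: str
    raw_label: str
    cdisc_variable_name: str | None = None
    data_type: DataType = DataType.text
    units: str | None = None

    def __post_init__(self) -> None:
        if self.raw_label is None:
            raise ValueError(f"item {self.item_id}: raw_label must not be null")
        object.__setattr__(self, "data_type", DataType(self.data_type))

    @property
    def key(self) -> tuple[str, str]:
        return (self.form_id, self.item_id)


@dataclass
class FormDef:
    """One CRF form.  Repeating/unscheduled forms are ingested once with
    ``repeating=True``; repetition never multiplies element counts."""

    form_id: str
    trial_id: str
    form_name: str
    items: list[ItemRecord] = field(default_factory=list)
    repeating: bool = False

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for it in self.items:
            if it.item_id in seen:
                raise ValueError(
                    f"form {self.form_id}: duplicate item_id {it.item_id!r}"
                )
            seen.add(it.item_id)


@dataclass
class StudySet:
    """The trial-master database: all trials, forms and items plus a
    provenance manifest of the source files they came from."""

    trials: list[TrialMeta] = field(default_factory=list)
    forms: list[FormDef] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)

    def trial(self, trial_id: str) -> TrialMeta:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t
        raise KeyError(trial_id)

    @property
    def trial_ids(self) -> list[str]:
        return [t.trial_id for t in self.trials]

    def form_trial_map(self) -> dict[str, str]:
        """form_id -> trial_id for every form."""
        return {f.form_id: f.trial_id for f in self.forms}

    def iter_items(self) -> Iterator[ItemRecord]:
        for f in self.forms:
            yield from f.items

    @property
    def n_items(self) -> int:
        return sum(len(f.items) for f in self.forms)

    def validate(self) -> None:
        """Check referential integrity and uniqueness invariants."""
        ids = [t.trial_id for t in self.trials]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate trial_ids: {dupes}")
        known = set(ids)
        form_ids: set[str] = set()
        for f in self.forms:
            if f.trial_id not in known:
                raise ValueError(
                    f"form {f.form_id} references unknown trial {f.trial_id}"
                )
            if f.form_id in form_ids:
                raise ValueError(f"duplicate form_id: {f.form_id}")
            form_ids.add(f.form_id)

    def merge(self, other: "StudySet") -> "StudySet":
        """Concatenate two fragments (validation deferred to caller)."""
        return StudySet(
            trials=self.trials + other.trials,
            forms=self.forms + other.forms,
            provenance=self.provenance + other.provenance,
        )


def as_dict(obj) -> dict:
    d = dataclasses.asdict(obj)
    for k, v in d.items():
        if isinstance(v, Enum):
            d[k] = v.value
    return d


def forms_by_trial(forms: Iterable[FormDef]) -> dict[str, list[FormDef]]:
    out: dict[str, list[FormDef]] = {}
    for f in forms:
        out.setdefault(f.trial_id, []).append(f)
    return out
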