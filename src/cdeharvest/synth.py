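"""Synthetic CRF corpus and EHR site-export generator with ground truth.

The confidential study corpus cannot ship, so this module emulates its
shape: by default 23 trials across 7 disease areas with the per-area
trial and form counts of the real corpus (1086 forms in total),
four-digit planned enrollments, item labels drawn from a fixed
per-domain vocabulary and perturbed by a parameterized noise model
(markup wrapping, unit suffixes, case changes, typos), plus per-site
EHR export tables with known value/patient counts.  Every perturbation
and the true element partition are recorded, so each pipeline stage can
be scored against ground truth.

All randomness flows through one ``random.Random(seed)`` stream with a
fixed draw order (typo, case, unit, markup per label); runs are
byte-identical for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .coverage import AVAILABLE, NOT_AVAILABLE, SiteExport
from .ingest import save_trial_meta
from .inventory import InventoryRow
from .model import DataType, FormDef, ItemRecord, StudySet, TrialMeta
from .odm import write_odm
from .textmetrics import levenshtein
from .vocab import SAE_ELEMENTS, VOCABULARY, element_catalog

#: Default corpus shape: trials and form totals per disease area.
DEFAULT_TRIALS_PER_AREA: dict[str, int] = {
    "cardiovascular": 3, "diabetes": 3, "infectious": 2, "neuroscience": 1,
    "oncology": 3, "psychiatric": 1, "respiratory": 10,
}
DEFAULT_FORMS_PER_AREA: dict[str, int] = {
    "cardiovascular": 158, "diabetes": 172, "infectious": 60,
    "neuroscience": 64, "oncology": 192, "psychiatric": 69,
    "respiratory": 371,
}

#: Relative chance of a form belonging to each domain (beyond the core
#: set every trial carries); proportional to observed per-domain form
#: totals.
DOMAIN_FORM_WEIGHTS: dict[str, int] = {
    "MH": 85, "AE": 78, "LB": 75, "DS": 74, "VS": 56, "CM": 52, "QS": 35,
    "DM": 34, "EG": 30, "ZC": 25, "SU": 22, "SURGERY": 20, "PE": 10, "RS": 7,
}
CORE_DOMAINS = ("DM", "MH", "AE", "VS")

_FORM_QUALIFIERS = (
    "Baseline", "Visit 2", "Visit 3", "Week 12", "Follow-up", "Unscheduled",
    "Cycle 1", "Cycle 2", "Screening", "Week 24", "Month 6", "Final Visit",
)
_NOISE_UNITS = ("kg", "cm", "mmHg", "bpm", "%", "mg/dL", "mmol/L", "IU/L",
                "ms", "min")
_ITEM_DATATYPES = (DataType.text, DataType.integer, DataType.float,
                   DataType.date, DataType.boolean)


@dataclass
class NoiseModel:
    """Label-perturbation probabilities (per item occurrence)."""

    p_case_change: float = 0.10
    p_html_wrap: float = 0.10
    p_unit_suffix: float = 0.15
    p_typo: float = 0.05
    typo_edits: tuple[int, int] = (1, 2)
    p_cdisc_name_present: float = 0.30

    def __post_init__(self) -> None:
        for name in ("p_case_change", "p_html_wrap", "p_unit_suffix",
                     "p_typo", "p_cdisc_name_present"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        self.typo_edits = tuple(self.typo_edits)
        if self.typo_edits[0] < 1 or self.typo_edits[0] > self.typo_edits[1]:
            raise ValueError("typo_edits must be a range with lower bound >= 1")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, (1, 1), 0.0)


@dataclass
class GeneratorConfig:
    """Corpus-shape and noise parameters of the synthetic study set."""

    n_trials_per_area: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TRIALS_PER_AREA))
    forms_per_area: dict[str, int] | None = field(
        default_factory=lambda: dict(DEFAULT_FORMS_PER_AREA))
    forms_per_trial: tuple[int, int] = (22, 164)
    elements_per_form: tuple[int, int] = (4, 20)
    enrollment_range: tuple[int, int] = (1000, 9999)
    n_sites_range: tuple[int, int] = (201, 900)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    sae_block: bool = True

    def __post_init__(self) -> None:
        for name in ("forms_per_trial", "elements_per_form",
                     "enrollment_range", "n_sites_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} range ({lo}, {hi}) is degenerate")
        smallest = min(len(v) for v in VOCABULARY.values())
        if self.elements_per_form[1] > smallest:
            raise ValueError(
                f"elements_per_form upper bound {self.elements_per_form[1]} "
                f"exceeds the smallest domain vocabulary ({smallest})"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None
                  ) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "noise" in raw:
            raw["noise"] = NoiseModel(**raw["noise"])
        for key in ("forms_per_trial", "elements_per_form",
                    "enrollment_range", "n_sites_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        if seed is not None:
            cfg.seed = seed
        return cfg


@dataclass
class GroundTruth:
    """What the generator actually did, for scoring the pipeline."""

    true_partition: dict[str, str] = field(default_factory=dict)
    true_domains: dict[str, str] = field(default_factory=dict)
    true_occurrence: dict[str, list[str]] = field(default_factory=dict)
    element_labels: dict[str, str] = field(default_factory=dict)
    typo_log: list[dict] = field(default_factory=list)
    perturbation_counts: dict[str, int] = field(default_factory=dict)
    forms_per_area: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    @staticmethod
    def item_key(trial_id: str, form_id: str, item_id: str) -> str:
        return f"{trial_id}|{form_id}|{item_id}"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def perturb_label(label: str, noise: NoiseModel, rng: random.Random
                  ) -> tuple[str, dict]:
    """Apply the noise model to one label occurrence.

    Draw order is fixed (typo, case, unit, markup) so that the stream
    stays aligned across runs.  The typo's *actual* edit distance to the
    original is recomputed and returned in the log (random edits can
    cancel).
    """
    if not label:
        raise ValueError("label must be nonempty")
    log: dict = {"applied": []}
    text = label

    if rng.random() < noise.p_typo:
        n_edits = rng.randint(*noise.typo_edits)
        mutated = text
        for _ in range(n_edits):
            ops = ["substitute", "insert"]
            if len(mutated) > 2:
                ops.append("delete")
            op = rng.choice(ops)
            pos = rng.randrange(len(mutated))
            ch = rng.choice("abcdefghijklmnopqrstuvwxyz")
            if op == "substitute":
                mutated = mutated[:pos] + ch + mutated[pos + 1:]
            elif op == "insert":
                mutated = mutated[:pos] + ch + mutated[pos:]
            else:
                mutated = mutated[:pos] + mutated[pos + 1:]
        log["applied"].append("typo")
        log["typo_edit_distance"] = levenshtein(label, mutated)
        log["typo_result"] = mutated
        text = mutated

    if rng.random() < noise.p_case_change:
        style = rng.choice(("upper", "lower", "title"))
        text = getattr(text, style)()
        log["applied"].append(f"case_{style}")

    if rng.random() < noise.p_unit_suffix:
        unit = rng.choice(_NOISE_UNITS)
        text = f"{text} ({unit})"
        log["applied"].append("unit_suffix")

    if rng.random() < noise.p_html_wrap:
        wrap = rng.choice((
            ("<b>", "</b>"), ("<i>", "</i>"), ("<em>", "</em>"),
            ("<span style='font-weight:bold'>", "</span>"),
        ))
        text = f"{wrap[0]}{text}{wrap[1]}"
        log["applied"].append("html_wrap")
    return text, log


def _cdisc_names(catalog: Sequence[tuple[str, str, str]]) -> dict[str, str]:
    """Deterministic per-element CDISC-style variable names."""
    names: dict[str, str] = {}
    used: set[str] = set()
    for eid, dom, label in catalog:
        stem = re.sub(r"[^A-Z]", "", label.upper())[:8] or "X"
        name = f"{dom}_{stem}"
        k = 1
        while name in used:
            k += 1
            name = f"{dom}_{stem}{k}"
        used.add(name)
        names[eid] = name
    return names


def generate_studyset(
    cfg: GeneratorConfig | None = None, out_dir: str | Path | None = None
) -> tuple[StudySet, GroundTruth]:
    """Generate the synthetic multi-trial study set plus ground truth.

    When ``out_dir`` is given, writes one ODM 1.3 file per trial, a
    trials-meta CSV and the ground-truth JSON manifest.
    """
    cfg = cfg or GeneratorConfig()
    rng = random.Random(cfg.seed)
    catalog = element_catalog()
    by_domain: dict[str, list[tuple[str, str]]] = {}
    label_to_eid: dict[tuple[str, str], str] = {}
    for eid, dom, label in catalog:
        by_domain.setdefault(dom, []).append((eid, label))
        label_to_eid[(dom, label)] = eid
    cdisc = _cdisc_names(catalog)
    # element-level fixed attributes
    dtypes = {eid: rng.choice(_ITEM_DATATYPES) for eid, _d, _l in catalog}

    truth = GroundTruth(seed=cfg.seed)
    truth.element_labels = {eid: label for eid, _d, label in catalog}
    occurrence: dict[str, set[str]] = {}
    perturb_counts: dict[str, int] = {}

    trials: list[TrialMeta] = []
    forms: list[FormDef] = []

    area_codes = {
        "cardiovascular": "CARD", "diabetes": "DIAB", "infectious": "INFX",
        "neuroscience": "NEUR", "oncology": "ONCO", "psychiatric": "PSYC",
        "respiratory": "RESP",
    }
    for area in sorted(cfg.n_trials_per_area):
        n_trials = cfg.n_trials_per_area[area]
        if cfg.forms_per_area is not None:
            total = cfg.forms_per_area[area]
            base, rem = divmod(total, n_trials)
            form_counts = [base + (1 if i < rem else 0) for i in range(n_trials)]
        else:
            form_counts = [
                rng.randint(*cfg.forms_per_trial) for _ in range(n_trials)
            ]
        for t_idx in range(n_trials):
            trial_id = f"T-{area_codes[area]}-{t_idx + 1:02d}"
            trials.append(
                TrialMeta(
                    trial_id=trial_id,
                    disease_area=area,
                    planned_enrollment=rng.randint(*cfg.enrollment_range),
                    n_sites=rng.randint(*cfg.n_sites_range),
                )
            )
            n_forms = form_counts[t_idx]
            # core domains first, remainder drawn by weight
            eligible = [
                d for d in DOMAIN_FORM_WEIGHTS
                if d != "RS" or area == "oncology"
            ]
            weights = [DOMAIN_FORM_WEIGHTS[d] for d in eligible]
            domains = list(CORE_DOMAINS[:n_forms])
            while len(domains) < n_forms:
                domains.append(rng.choices(eligible, weights=weights)[0])
            domain_serial: dict[str, int] = {}
            for f_idx, dom in enumerate(domains):
                form_id = f"{trial_id}.F{f_idx + 1:03d}"
                domain_serial[dom] = domain_serial.get(dom, 0) + 1
                display = _display_name(dom)
                if domain_serial[dom] == 1:
                    form_name = display
                else:
                    qual = _FORM_QUALIFIERS[
                        (domain_serial[dom] - 2) % len(_FORM_QUALIFIERS)
                    ]
                    form_name = f"{display} - {qual}"
                truth.true_domains[form_id] = dom
                n_items = rng.randint(*cfg.elements_per_form)
                pool = by_domain[dom]
                if cfg.sae_block and dom == "AE":
                    sae = [
                        (label_to_eid[("AE", s)], s) for s in SAE_ELEMENTS
                    ]
                    rest = [p for p in pool if p[1] not in SAE_ELEMENTS]
                    extra = max(0, n_items - len(sae))
                    chosen = sae + rng.sample(rest, min(extra, len(rest)))
                else:
                    chosen = rng.sample(pool, n_items)
                items: list[ItemRecord] = []
                for i_idx, (eid, label) in enumerate(chosen):
                    item_id = f"{form_id}.IT{i_idx + 1:03d}"
                    noisy, plog = perturb_label(label, cfg.noise, rng)
                    has_name = rng.random() < cfg.noise.p_cdisc_name_present
                    for rule in plog["applied"]:
                        perturb_counts[rule] = perturb_counts.get(rule, 0) + 1
                    if "typo" in plog["applied"]:
                        truth.typo_log.append(
                            {
                                "item_key": GroundTruth.item_key(
                                    trial_id, form_id, item_id),
                                "original": label,
                                "perturbed": plog["typo_result"],
                                "edit_distance": plog["typo_edit_distance"],
                            }
                        )
                    items.append(
                        ItemRecord(
                            item_id=item_id,
                            form_id=form_id,
                            raw_label=noisy,
                            cdisc_variable_name=cdisc[eid] if has_name else None,
                            data_type=dtypes[eid],
                        )
                    )
                    truth.true_partition[
                        GroundTruth.item_key(trial_id, form_id, item_id)
                    ] = eid
                    occurrence.setdefault(eid, set()).add(trial_id)
                forms.append(
                    FormDef(
                        form_id=form_id,
                        trial_id=trial_id,
                        form_name=form_name,
                        items=items,
                        repeating=rng.random() < 0.2,
                    )
                )
    truth.true_occurrence = {e: sorted(ts) for e, ts in sorted(occurrence.items())}
    truth.perturbation_counts = dict(sorted(perturb_counts.items()))
    area_forms: dict[str, int] = {}
    for t in trials:
        area_forms.setdefault(t.disease_area.value, 0)
    for f in forms:
        area = next(t.disease_area.value for t in trials if t.trial_id == f.trial_id)
        area_forms[area] += 1
    truth.forms_per_area = area_forms

    study_set = StudySet(
        trials=trials,
        forms=forms,
        provenance=[{"source": "synthetic", "seed": cfg.seed,
                     "n_trials": len(trials), "n_forms": len(forms)}],
    )
    study_set.validate()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for trial in trials:
            sub = StudySet(
                trials=[trial],
                forms=[f for f in forms if f.trial_id == trial.trial_id],
            )
            write_odm(sub, out / f"{trial.trial_id}.odm.xml")
        save_trial_meta(trials, out / "trials_meta.csv")
        truth.to_json(out / "ground_truth.json")
    return study_set, truth


def _display_name(domain_key: str) -> str:
    from .domains import DEFAULT_DOMAIN_DICTIONARY

    for d in DEFAULT_DOMAIN_DICTIONARY:
        if d.domain_key == domain_key:
            return d.display_name
    return domain_key


#: Per-domain probability that an element is available in a site's EHR;
#: demographics and laboratory lead, SAE-bearing AE elements trail.
DOMAIN_AVAILABILITY: dict[str, float] = {
    "DM": 0.97, "LB": 0.85, "VS": 0.80, "CM": 0.60, "MH": 0.55, "EG": 0.50,
    "SURGERY": 0.60, "ZC": 0.45, "QS": 0.20, "SU": 0.50, "DS": 0.35,
    "PE": 0.40, "RS": 0.25, "AE": 0.45,
}
#: Reference frequency/patient-count example forced into site_1's export.
WORKED_EXAMPLE = {"element": "Bilirubin, total", "n_values": 9574,
                  "n_patients": 31493}


def generate_exports(
    inventory: Sequence[InventoryRow],
    n_sites: int = 7,
    *,
    seed: int = 0,
    sae_sparse: bool = True,
    n_availability_only: int = 2,
    year: int = 2013,
    out_dir: str | Path | None = None,
) -> tuple[list[SiteExport], dict]:
    """Generate per-site EHR export rows with known counts.

    The last ``n_availability_only`` sites report availability flags
    only (no counts).  When ``sae_sparse`` is set, elements of the AE
    domain are forced not-available at more than half of the sites
    except 'Date of Death'.  Site 1 carries the pinned worked-example
    counts for 'Bilirubin, total' when the inventory contains it.
    """
    if not inventory:
        raise ValueError("inventory must be nonempty")
    rng = random.Random(seed)
    rows: list[SiteExport] = []
    truth: dict = {"sites": {}, "cells": {}}
    count_sites = n_sites - n_availability_only
    sae_blocked_sites: set[int] = set()
    if sae_sparse and n_sites > 1:
        n_blocked = n_sites // 2 + 1
        sae_blocked_sites = set(
            rng.sample(range(1, n_sites + 1), n_blocked))
    for s in range(1, n_sites + 1):
        site_id = f"site_{s}"
        n_patients = rng.randint(8000, 60000)
        if s == 1:
            n_patients = WORKED_EXAMPLE["n_patients"]
        counts_allowed = s <= count_sites
        truth["sites"][site_id] = {
            "n_patients": n_patients, "counts_allowed": counts_allowed,
        }
        for r in inventory:
            el = r.element
            p_avail = DOMAIN_AVAILABILITY.get(el.domain_key, 0.5)
            available = rng.random() < p_avail
            if s == 1 and el.canonical_label == WORKED_EXAMPLE["element"]:
                available = True  # the reference example is always exported
            if (
                sae_sparse and el.domain_key == "AE"
                and s in sae_blocked_sites
                and el.canonical_label.casefold() != "date of death"
            ):
                available = False
            key = el.umls_cui or el.cde_id
            if not available:
                row = SiteExport(site_id, key, None, None, NOT_AVAILABLE, year)
            elif not counts_allowed:
                row = SiteExport(site_id, key, None, None, AVAILABLE, year)
            else:
                frac = rng.random() ** 2 * 1.5
                n_values = int(n_patients * frac)
                if (
                    s == 1
                    and el.canonical_label == WORKED_EXAMPLE["element"]
                ):
                    n_values = WORKED_EXAMPLE["n_values"]
                row = SiteExport(site_id, key, n_values, n_patients,
                                 AVAILABLE, year)
            rows.append(row)
            truth["cells"][f"{site_id}|{el.cde_id}"] = {
                "n_values": row.n_values, "n_patients": row.n_patients,
                "availability": row.availability,
            }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(
            [
                {
                    "site_id": r.site_id, "element_key": r.element_key,
                    "n_values": r.n_values, "n_patients": r.n_patients,
                    "availability": r.availability, "year": r.year,
                }
                for r in rows
            ]
        )
        for site_id, grp in df.groupby("site_id", sort=True):
            grp.to_csv(out / f"export_{site_id}.csv", index=False)
        Path(out / "export_truth.json").write_text(json.dumps(truth, indent=2))
    return rows, truth
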