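"""Label cleaning and fuzzy deduplication of CRF data elements.

Raw item labels arrive polluted with markup, style fragments, unit
suffixes, case changes and typos.  This module (1) cleans each label
with regular-expression rules and a unit lexicon, and (2) merges label
variants into canonical element clusters by single-linkage agglomeration
over a three-part matching rule:

hard key   — equal CDISC variable names merge, unequal ones veto;
exact      — case-folded cleaned texts equal;
fuzzy      — Jaro-Winkler above threshold AND Levenshtein within a
             length-scaled budget AND (optionally) Metaphone agreement.

Blocking on the first Metaphone character keeps the pairwise stage
tractable; a separate pass unions items sharing a CDISC variable name
across blocks.  An override table (merge / split / rename / remove /
recategorize) stands in for expert review of the automatic clustering.
"""

from __future__ import annotations

import html
import logging
import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import ItemRecord
from .textmetrics import jaro_winkler, levenshtein, metaphone

logger = logging.getLogger(__name__)

#: Unit tokens stripped from trailing "(...)" / "[...]" groups.  UCUM-style
#: print forms plus common CRF spellings; extensible via config.
DEFAULT_UNIT_LEXICON: tuple[str, ...] = (
    "kg", "g", "mg", "ug", "µg", "ng", "lb", "lbs",
    "m", "cm", "mm", "in",
    "l", "ml", "dl", "ul", "µl",
    "%", "percent",
    "mmhg", "bpm", "beats/min", "breaths/min",
    "mg/dl", "g/dl", "mmol/l", "µmol/l", "umol/l", "mEq/l", "meq/l",
    "iu/l", "u/l", "ng/ml", "pg/ml", "miu/ml",
    "g/l", "mg/l", "cells/µl", "cells/ul", "10^9/l", "10^12/l",
    "kg/m2", "kg/m^2",
    "°c", "°f", "c", "f",
    "s", "sec", "ms", "msec", "min", "h", "hr", "hours", "days", "weeks",
    "years", "yrs",
)

_TAG_RE = re.compile(r"<[^>]*>")
_STYLE_RE = re.compile(
    r"\b[\w-]+\s*:\s*[^;{}]+;|\{[^{}]*\}"  # inline css declarations / blocks
)
_WS_RE = re.compile(r"\s+")
_UNIT_GROUP_RE = re.compile(r"[\(\[]\s*([^\(\)\[\]]+?)\s*[\)\]]\s*$")


@dataclass(frozen=True)
class CleanLabel:
    """A cleaned item label: markup-free text plus what was removed."""

    text: str
    removed_units: str | None = None
    removal_log: tuple[str, ...] = ()

    @property
    def empty(self) -> bool:
        return self.text == ""


def clean_label(
    raw: str, unit_lexicon: Sequence[str] = DEFAULT_UNIT_LEXICON
) -> CleanLabel:
    """Strip markup, style fragments and a trailing unit token.

    Case is preserved here — case-folding happens inside matching.  A
    label that cleans to the empty string is flagged by ``empty`` and
    excluded from clustering by the caller.
    """
    if raw is None:
        raise ValueError("raw label must not be null")
    text = raw
    log: list[str] = []
    if "&" in text:
        unescaped = html.unescape(text)
        if unescaped != text:
            text, log = unescaped, log + ["entities"]
    if _TAG_RE.search(text):
        text = _TAG_RE.sub(" ", text)
        log.append("html_tags")
    if _STYLE_RE.search(text):
        text = _STYLE_RE.sub(" ", text)
        log.append("style")
    text = _WS_RE.sub(" ", text).strip()
    removed_units = None
    m = _UNIT_GROUP_RE.search(text)
    if m:
        candidate = m.group(1).strip()
        lex = {u.casefold() for u in unit_lexicon}
        if candidate.casefold() in lex:
            removed_units = candidate
            text = text[: m.start()].rstrip()
            log.append("unit_suffix")
    text = _WS_RE.sub(" ", text).strip()
    return CleanLabel(text=text, removed_units=removed_units, removal_log=tuple(log))


@dataclass
class SimilarityConfig:
    """Thresholds of the fuzzy-matching rule; logged with every run.

    ``lev_max`` caps absolute edits; ``lev_len_ratio`` scales the budget
    down for short strings so that e.g. a 4-letter label tolerates only
    one edit.
    """

    jw_threshold: float = 0.90
    lev_max: int = 3
    lev_len_ratio: float = 0.25
    require_phonetic_agreement: bool = False
    winkler_prefix_weight: float = 0.1
    max_cluster_fraction: float = 0.25  # blow-up warning threshold

    def __post_init__(self) -> None:
        if not 0.0 <= self.jw_threshold <= 1.0:
            raise ValueError("jw_threshold must lie in [0, 1]")
        if self.lev_max < 0:
            raise ValueError("lev_max must be >= 0")
        if not 0.0 < self.lev_len_ratio <= 1.0:
            raise ValueError("lev_len_ratio must lie in (0, 1]")
        if not 0.0 <= self.winkler_prefix_weight <= 0.25:
            raise ValueError("winkler_prefix_weight must lie in [0, 0.25]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimilarityConfig":
        return cls(**dict(d))


def is_match(
    a: CleanLabel | str,
    b: CleanLabel | str,
    va: str | None = None,
    vb: str | None = None,
    cfg: SimilarityConfig | None = None,
) -> tuple[bool, str | None]:
    """Decide whether two cleaned labels denote the same element.

    Returns (decision, reason) with reason in {"cdisc", "exact",
    "fuzzy", None}.  Non-null unequal variable names veto any text
    similarity.
    """
    cfg = cfg or SimilarityConfig()
    ta = a.text if isinstance(a, CleanLabel) else a
    tb = b.text if isinstance(b, CleanLabel) else b
    if va is not None and vb is not None:
        if va.casefold() == vb.casefold():
            return True, "cdisc"
        return False, None
    if ta.casefold() == tb.casefold():
        return True, "exact"
    jw = jaro_winkler(ta.casefold(), tb.casefold(), cfg.winkler_prefix_weight)
    if jw < cfg.jw_threshold:
        return False, None
    budget = min(
        cfg.lev_max, int(cfg.lev_len_ratio * max(len(ta), len(tb)))
    )
    if levenshtein(ta.casefold(), tb.casefold()) > budget:
        return False, None
    if cfg.require_phonetic_agreement and metaphone(ta) != metaphone(tb):
        return False, None
    return True, "fuzzy"


@dataclass
class ElementCluster:
    """One candidate common data element: a set of label variants.

    ``variants`` holds (raw_label, trial_id, form_id) provenance;
    ``members`` the exact (trial, form, item) keys, so partitions can be
    checked for conservation.  ``locked`` marks clusters fixed by an
    override.
    """

    cluster_id: str
    canonical_label: str
    variants: set[tuple[str, str, str]] = field(default_factory=set)
    members: list[tuple[str, str, str]] = field(default_factory=list)
    cdisc_variable_name: str | None = None
    locked: bool = False
    category: str | None = None  # set by recategorize overrides


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # smaller index wins the root for determinism
            if ra < rb:
                self.parent[rb] = ra
            else:
                self.parent[ra] = rb


def cluster_labels(
    items: Iterable[ItemRecord],
    cfg: SimilarityConfig | None = None,
    *,
    form_trial: Mapping[str, str] | None = None,
    unit_lexicon: Sequence[str] = DEFAULT_UNIT_LEXICON,
) -> list[ElementCluster]:
    """Single-linkage clustering of items into candidate elements.

    The result is independent of input order: items are sorted on
    (case-folded cleaned text, trial, form, item) before any pairwise
    work, and cluster ids are assigned from the sorted canonical labels.
    Items cleaning to the empty string are excluded (logged).

    Blocking: candidate pairs are generated only within groups sharing
    the first character of the Metaphone code; a second pass unions
    representatives sharing a CDISC variable name.  A union that would
    put two distinct non-null variable names into one cluster is skipped
    (the hard-key veto holds transitively).
    """
    cfg = cfg or SimilarityConfig()
    form_trial = form_trial or {}

    cleaned: list[tuple[ItemRecord, CleanLabel, str]] = []
    n_empty = 0
    for it in items:
        cl = clean_label(it.raw_label, unit_lexicon)
        if cl.empty:
            n_empty += 1
            continue
        trial = form_trial.get(it.form_id, "")
        cleaned.append((it, cl, trial))
    if n_empty:
        logger.info("excluded %d items with empty-after-clean labels", n_empty)
    cleaned.sort(key=lambda t: (t[1].text.casefold(), t[2], t[0].form_id, t[0].item_id))

    # deduplicate to representatives: identical (case-folded text, hard key)
    rep_index: dict[tuple[str, str | None], int] = {}
    reps: list[tuple[str, str | None]] = []  # (display text of first seen, key)
    rep_items: list[list[tuple[ItemRecord, CleanLabel, str]]] = []
    for rec in cleaned:
        it, cl, trial = rec
        key = (
            cl.text.casefold(),
            it.cdisc_variable_name.casefold() if it.cdisc_variable_name else None,
        )
        idx = rep_index.get(key)
        if idx is None:
            idx = len(reps)
            rep_index[key] = idx
            reps.append((cl.text, key[1]))
            rep_items.append([])
        rep_items[idx].append(rec)

    n = len(reps)
    uf = _UnionFind(n)
    root_varname: dict[int, str] = {}
    for i, (_, vn) in enumerate(reps):
        if vn is not None:
            root_varname[i] = vn

    def try_union(i: int, j: int) -> None:
        ri, rj = uf.find(i), uf.find(j)
        if ri == rj:
            return
        vi, vj = root_varname.get(ri), root_varname.get(rj)
        if vi is not None and vj is not None and vi != vj:
            logger.debug(
                "union vetoed: %r vs %r carry distinct variable names %s / %s",
                reps[i][0], reps[j][0], vi, vj,
            )
            return
        uf.union(i, j)
        r = uf.find(ri)
        vn = vi if vi is not None else vj
        if vn is not None:
            root_varname[r] = vn

    # pass 1: shared hard keys
    by_varname: dict[str, list[int]] = {}
    for i, (_, vn) in enumerate(reps):
        if vn is not None:
            by_varname.setdefault(vn, []).append(i)
    for idxs in by_varname.values():
        for j in idxs[1:]:
            try_union(idxs[0], j)

    # pass 2: fuzzy matching within metaphone-initial blocks
    blocks: dict[str, list[int]] = {}
    for i, (text, _) in enumerate(reps):
        code = metaphone(text)
        blocks.setdefault(code[:1], []).append(i)
    for key in sorted(blocks):
        idxs = blocks[key]
        for ai in range(len(idxs)):
            i = idxs[ai]
            ti, vi = reps[i]
            for bi in range(ai + 1, len(idxs)):
                j = idxs[bi]
                tj, vj = reps[j]
                ok, _reason = is_match(ti, tj, vi, vj, cfg)
                if ok:
                    try_union(i, j)

    # materialize clusters
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    clusters: list[ElementCluster] = []
    for root in groups:
        idxs = groups[root]
        recs = [rec for i in idxs for rec in rep_items[i]]
        # canonical label: modal cleaned text (original case), ties by
        # shortest then lexicographically smallest
        counts: dict[str, int] = {}
        for _it, cl, _tr in recs:
            counts[cl.text] = counts.get(cl.text, 0) + 1
        canonical = min(counts, key=lambda t: (-counts[t], len(t), t))
        varnames = sorted(
            {
                it.cdisc_variable_name
                for it, _cl, _tr in recs
                if it.cdisc_variable_name
            }
        )
        clusters.append(
            ElementCluster(
                cluster_id="",  # assigned below, from sorted order
                canonical_label=canonical,
                variants={(it.raw_label, tr, it.form_id) for it, _cl, tr in recs},
                members=sorted((tr, it.form_id, it.item_id) for it, _cl, tr in recs),
                cdisc_variable_name=varnames[0] if varnames else None,
            )
        )
    clusters.sort(key=lambda c: (c.canonical_label.casefold(), c.canonical_label,
                                 c.members[0] if c.members else ("", "", "")))
    width = max(4, len(str(len(clusters))))
    for k, c in enumerate(clusters, start=1):
        c.cluster_id = f"CDE{k:0{width}d}"

    total = sum(len(c.members) for c in clusters)
    if total >= 20:  # the fraction heuristic is meaningless on tiny inputs
        biggest = max((len(c.members) for c in clusters), default=0)
        if biggest > cfg.max_cluster_fraction * total and len(clusters) > 1:
            warnings.warn(
                f"largest cluster holds {biggest}/{total} items "
                f"(> {cfg.max_cluster_fraction:.0%}); review similarity thresholds",
                stacklevel=2,
            )
    return clusters


# ---------------------------------------------------------------------------
# override table

OVERRIDE_ACTIONS = ("merge", "split", "rename", "remove", "recategorize")


def load_overrides(path: str | Path) -> pd.DataFrame:
    """Read an override CSV with columns action, target, argument."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"action", "target", "argument"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: override table missing columns {sorted(missing)}")
    bad = df.loc[~df["action"].isin(OVERRIDE_ACTIONS)]
    if len(bad):
        raise ValueError(f"{path}: unknown override actions: {bad['action'].tolist()}")
    return df


def apply_overrides(
    clusters: Sequence[ElementCluster], overrides: pd.DataFrame | None
) -> list[ElementCluster]:
    """Apply expert overrides in file order; affected clusters are locked.

    Actions: merge(target <- argument), split(variant raw label out of
    target into a new cluster), rename(target, new label),
    remove(target, reason), recategorize(target, clinical|administrative).
    Unknown targets are a fatal error listing every unresolved row.
    """
    out = {c.cluster_id: _copy_cluster(c) for c in clusters}
    if overrides is None or len(overrides) == 0:
        return [out[c.cluster_id] for c in clusters]
    unresolved: list[int] = []
    removed: list[str] = []
    split_serial = 0
    order: list[str] = [c.cluster_id for c in clusters]

    for idx, row in overrides.iterrows():
        action, target, arg = row["action"], row["target"], row["argument"]
        c = out.get(target)
        if action == "merge":
            other = out.get(arg)
            if c is None or other is None:
                unresolved.append(idx)
                continue
            c.variants |= other.variants
            c.members = sorted(c.members + other.members)
            if c.cdisc_variable_name is None:
                c.cdisc_variable_name = other.cdisc_variable_name
            c.locked = True
            del out[other.cluster_id]
            order.remove(other.cluster_id)
        elif action == "split":
            if c is None:
                unresolved.append(idx)
                continue
            moving = {v for v in c.variants if v[0] == arg}
            if not moving:
                unresolved.append(idx)
                continue
            moved_keys = {(tr, fid) for _raw, tr, fid in moving}
            moving_members = [
                m for m in c.members if (m[0], m[1]) in moved_keys
            ]
            c.variants -= moving
            c.members = [m for m in c.members if (m[0], m[1]) not in moved_keys]
            c.locked = True
            split_serial += 1
            new_id = f"{c.cluster_id}.S{split_serial}"
            out[new_id] = ElementCluster(
                cluster_id=new_id,
                canonical_label=clean_label(arg).text or arg,
                variants=moving,
                members=sorted(moving_members),
                cdisc_variable_name=None,
                locked=True,
            )
            order.insert(order.index(c.cluster_id) + 1, new_id)
        elif action == "rename":
            if c is None:
                unresolved.append(idx)
                continue
            c.canonical_label = arg
            c.locked = True
        elif action == "remove":
            if c is None:
                unresolved.append(idx)
                continue
            removed.append(target)
            logger.info("override removed cluster %s (%s)", target, arg or "no reason")
            del out[target]
            order.remove(target)
        elif action == "recategorize":
            if c is None:
                unresolved.append(idx)
                continue
            if arg not in ("clinical", "administrative"):
                raise ValueError(
                    f"override row {idx}: recategorize argument must be "
                    f"'clinical' or 'administrative', got {arg!r}"
                )
            c.category = arg
            c.locked = True
    if unresolved:
        raise ValueError(
            "override rows referencing unknown clusters/variants: "
            f"{overrides.loc[unresolved].to_dict('records')}"
        )
    return [out[cid] for cid in order]


def _copy_cluster(c: ElementCluster) -> ElementCluster:
    return ElementCluster(
        cluster_id=c.cluster_id,
        canonical_label=c.canonical_label,
        variants=set(c.variants),
        members=list(c.members),
        cdisc_variable_name=c.cdisc_variable_name,
        locked=c.locked,
        category=c.category,
    )


# ---------------------------------------------------------------------------
# persistence

def clusters_to_frame(clusters: Sequence[ElementCluster]) -> pd.DataFrame:
    """Long-format cluster table, one row per member item."""
    rows = []
    for c in clusters:
        raw_by_key = {}
        for raw, tr, fid in sorted(c.variants):
            raw_by_key.setdefault((tr, fid), raw)
        for tr, fid, iid in c.members:
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "canonical_label": c.canonical_label,
                    "raw_label": raw_by_key.get((tr, fid), c.canonical_label),
                    "trial_id": tr,
                    "form_id": fid,
                    "item_id": iid,
                    "cdisc_variable_name": c.cdisc_variable_name or "",
                    "locked": c.locked,
                    "category": c.category or "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "canonical_label", "raw_label", "trial_id",
            "form_id", "item_id", "cdisc_variable_name", "locked", "category",
        ],
    )


def clusters_from_frame(df: pd.DataFrame) -> list[ElementCluster]:
    df = df.fillna("")
    out: list[ElementCluster] = []
    for cid, grp in df.groupby("cluster_id", sort=True):
        first = grp.iloc[0]
        vn = str(first.get("cdisc_variable_name", "") or "") or None
        cat = str(first.get("category", "") or "") or None
        out.append(
            ElementCluster(
                cluster_id=str(cid),
                canonical_label=str(first["canonical_label"]),
                variants={
                    (str(r.raw_label), str(r.trial_id), str(r.form_id))
                    for r in grp.itertuples()
                },
                members=sorted(
                    (str(r.trial_id), str(r.form_id), str(r.item_id))
                    for r in grp.itertuples()
                ),
                cdisc_variable_name=vn,
                locked=bool(first.get("locked", False)),
                category=cat,
            )
        )
    return out
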