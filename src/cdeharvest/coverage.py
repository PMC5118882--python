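"""Availability and frequency-of-documentation of inventory elements in
EHR site exports, plus the coverage heat-map matrices.

Frequency of documentation is the number of values entered for an
element in the reference year divided by the number of patients seen
that year, as a percent (it may exceed 100 when an element is recorded
several times per patient).  Sites that may not export counts report an
availability flag instead; a complete (element x site) grid is built
with 'not available' as the default for unreported cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .inventory import InventoryRow

AVAILABLE = "available"
NOT_AVAILABLE = "not_available"
UNKNOWN = "unknown"
FREQUENCY = "frequency"


class ExportRowError(ValueError):
    """A site-export row violating the model invariants."""


@dataclass(frozen=True)
class SiteExport:
    """One site's report for one element in the reference year."""

    site_id: str
    element_key: str
    n_values: int | None
    n_patients: int | None
    availability: str = UNKNOWN
    year: int = 2013

    def __post_init__(self) -> None:
        if self.availability not in (AVAILABLE, NOT_AVAILABLE, UNKNOWN):
            raise ExportRowError(
                f"{self.site_id}/{self.element_key}: bad availability "
                f"{self.availability!r}"
            )
        if self.n_values is not None and self.n_values < 0:
            raise ExportRowError(
                f"{self.site_id}/{self.element_key}: n_values must be >= 0"
            )
        if (
            self.availability == NOT_AVAILABLE
            and self.n_values is not None
            and self.n_values > 0
        ):
            raise ExportRowError(
                f"{self.site_id}/{self.element_key}: not_available row "
                f"carries n_values > 0"
            )

    @property
    def has_counts(self) -> bool:
        return self.n_values is not None and self.n_patients is not None


@dataclass(frozen=True)
class CoverageCell:
    site_id: str
    cde_id: str
    status: str  # frequency | available | not_available
    frequency_pct: float | None = None

    def __post_init__(self) -> None:
        if (self.status == FREQUENCY) != (self.frequency_pct is not None):
            raise ValueError("frequency_pct present iff status == 'frequency'")

    def render(self) -> str:
        if self.status == FREQUENCY:
            return f"{self.frequency_pct:.1f}"
        return "A" if self.status == AVAILABLE else "N/A"


def compute_frequency(n_values: int, n_patients: int) -> float:
    """Documentation frequency in percent, rounded half-up to 1 decimal.

    May exceed 100 (several values per patient).  ``n_patients`` below 1
    is an error: the cell must degrade to availability-only.
    """
    if n_patients < 1:
        raise ExportRowError("frequency undefined: n_patients < 1")
    if n_values < 0:
        raise ExportRowError("n_values must be >= 0")
    pct = Decimal(100 * n_values) / Decimal(n_patients)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def classify_cell(row: SiteExport, cde_id: str | None = None) -> CoverageCell:
    """Turn one validated export row into a coverage cell.

    Counts win: when both counts are present the cell carries a
    frequency.  Otherwise the availability flag passes through; a bare
    'unknown' degrades to not_available.
    """
    cde = cde_id or row.element_key
    if row.availability == NOT_AVAILABLE:
        # a 0-count row for a not-available element stays not_available;
        # frequency 0.0 is reserved for available-but-never-collected
        return CoverageCell(site_id=row.site_id, cde_id=cde, status=NOT_AVAILABLE)
    if row.has_counts and row.n_patients >= 1:
        return CoverageCell(
            site_id=row.site_id,
            cde_id=cde,
            status=FREQUENCY,
            frequency_pct=compute_frequency(row.n_values, row.n_patients),
        )
    if row.availability == AVAILABLE:
        return CoverageCell(site_id=row.site_id, cde_id=cde, status=AVAILABLE)
    return CoverageCell(site_id=row.site_id, cde_id=cde, status=NOT_AVAILABLE)


def read_site_export(path: str | Path) -> list[SiteExport]:
    """Read one per-site CSV (site_id, element_key, n_values, n_patients,
    availability, year); invalid rows raise, listing the offender."""
    df = pd.read_csv(path)
    rows = []
    for _, r in df.iterrows():
        def _int(v):
            return None if pd.isna(v) or str(v).strip() == "" else int(v)

        rows.append(
            SiteExport(
                site_id=str(r["site_id"]),
                element_key=str(r["element_key"]),
                n_values=_int(r.get("n_values")),
                n_patients=_int(r.get("n_patients")),
                availability=str(r.get("availability", UNKNOWN)) or UNKNOWN,
                year=int(r.get("year", 2013)),
            )
        )
    return rows


def match_element(
    key: str, inventory: Sequence[InventoryRow]
) -> str | None:
    """Resolve an export element key to a cde_id.

    Precedence: cde_id, semantic code (UMLS CUI then SNOMED), case-folded
    canonical label.  Ambiguity (one key resolving to several elements)
    is an error.
    """
    key_cf = key.casefold()
    hits = {r.element.cde_id for r in inventory if r.element.cde_id.casefold() == key_cf}
    if not hits:
        hits = {
            r.element.cde_id
            for r in inventory
            if key == (r.element.umls_cui or "") or key == (r.element.snomed_code or "")
        }
    if not hits:
        hits = {
            r.element.cde_id
            for r in inventory
            if r.element.canonical_label.casefold() == key_cf
        }
    if len(hits) > 1:
        raise ExportRowError(f"element key {key!r} matches several elements: {sorted(hits)}")
    return hits.pop() if hits else None


@dataclass
class HeatmapMatrix:
    """Complete (element x site) coverage grid with a recorded row order."""

    rows: list[str]  # cde_ids, ordered
    cols: list[str]  # site_ids, ordered
    cells: dict[tuple[str, str], CoverageCell]
    ordering_rule: str

    def to_frame(self) -> pd.DataFrame:
        data = {
            site: [self.cells[(cde, site)].render() for cde in self.rows]
            for site in self.cols
        }
        return pd.DataFrame(data, index=pd.Index(self.rows, name="cde_id"))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def build_heatmap(
    cells: Iterable[CoverageCell],
    inventory: Sequence[InventoryRow],
    *,
    sites: Sequence[str] | None = None,
) -> HeatmapMatrix:
    """Assemble the coverage heat map.

    Rows (elements) are sorted by number of sites with any coverage
    (desc), then mean frequency over frequency cells (desc), then label;
    columns are site ids sorted; missing cells default to not_available
    so the grid is complete.  Duplicate (site, element) cells are fatal.
    """
    cell_map: dict[tuple[str, str], CoverageCell] = {}
    for c in cells:
        k = (c.cde_id, c.site_id)
        if k in cell_map:
            raise ExportRowError(f"duplicate cell for {k}")
        cell_map[k] = c

    col_set = set(sites or []) | {c.site_id for c in cell_map.values()}
    cols = sorted(col_set)
    label = {r.element.cde_id: r.element.canonical_label for r in inventory}
    cde_ids = [r.element.cde_id for r in inventory]

    for cde in cde_ids:
        for site in cols:
            cell_map.setdefault(
                (cde, site),
                CoverageCell(site_id=site, cde_id=cde, status=NOT_AVAILABLE),
            )

    def row_key(cde: str):
        row_cells = [cell_map[(cde, s)] for s in cols]
        n_covered = sum(c.status != NOT_AVAILABLE for c in row_cells)
        freqs = [c.frequency_pct for c in row_cells if c.status == FREQUENCY]
        mean_freq = sum(freqs) / len(freqs) if freqs else 0.0
        return (-n_covered, -mean_freq, label.get(cde, cde).casefold(), cde)

    ordered = sorted(cde_ids, key=row_key)
    return HeatmapMatrix(
        rows=ordered,
        cols=cols,
        cells={k: v for k, v in cell_map.items() if k[0] in set(cde_ids)},
        ordering_rule="n_sites_covered desc, mean_frequency desc, label asc",
    )


def coverage_pipeline(
    inventory: Sequence[InventoryRow],
    exports: Iterable[SiteExport],
    *,
    sae_domain: str | None = "AE",
) -> tuple[HeatmapMatrix, HeatmapMatrix | None, dict]:
    """Match exports to the inventory, classify cells and build the full
    heat map plus (optionally) the SAE-domain submatrix and a summary."""
    cells: list[CoverageCell] = []
    sites: set[str] = set()
    n_unmatched = 0
    n_rejected = 0
    seen: set[tuple[str, str]] = set()
    for row in exports:
        sites.add(row.site_id)
        cde = match_element(row.element_key, inventory)
        if cde is None:
            n_unmatched += 1
            continue
        if (cde, row.site_id) in seen:
            raise ExportRowError(
                f"duplicate export for element {cde} at site {row.site_id}"
            )
        seen.add((cde, row.site_id))
        try:
            cells.append(classify_cell(row, cde))
        except ExportRowError:
            n_rejected += 1
    full = build_heatmap(cells, inventory, sites=sorted(sites))

    sae = None
    if sae_domain is not None:
        sae_inv = [r for r in inventory if r.element.domain_key == sae_domain]
        if sae_inv:
            sae_ids = {r.element.cde_id for r in sae_inv}
            sae = build_heatmap(
                [c for c in cells if c.cde_id in sae_ids],
                sae_inv,
                sites=sorted(sites),
            )

    n_cells = len(full.rows) * len(full.cols)
    n_covered = sum(
        1 for c in full.cells.values() if c.status != NOT_AVAILABLE
    )
    summary = {
        "n_elements": len(full.rows),
        "n_sites": len(full.cols),
        "n_cells": n_cells,
        "n_covered_cells": n_covered,
        "coverage_fraction": round(n_covered / n_cells, 4) if n_cells else 0.0,
        "n_unmatched_export_rows": n_unmatched,
        "n_rejected_export_rows": n_rejected,
    }
    return full, sae, summary


def render_heatmap(matrix: HeatmapMatrix, path: str | Path,
                   inventory: Sequence[InventoryRow] | None = None) -> None:
    """Optional graphical rendering (PNG/SVG via matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    label = {}
    if inventory:
        label = {r.element.cde_id: r.element.canonical_label for r in inventory}
    vals = np.zeros((len(matrix.rows), len(matrix.cols)))
    for i, cde in enumerate(matrix.rows):
        for j, site in enumerate(matrix.cols):
            c = matrix.cells[(cde, site)]
            if c.status == FREQUENCY:
                vals[i, j] = min(c.frequency_pct, 100.0)
            elif c.status == AVAILABLE:
                vals[i, j] = np.nan
            else:
                vals[i, j] = -10.0
    fig, ax = plt.subplots(
        figsize=(max(4, len(matrix.cols) * 0.8), max(4, len(matrix.rows) * 0.25))
    )
    im = ax.imshow(vals, aspect="auto", cmap="YlGn", vmin=-10, vmax=100)
    ax.set_xticks(range(len(matrix.cols)), matrix.cols, rotation=45, ha="right")
    ax.set_yticks(
        range(len(matrix.rows)),
        [label.get(c, c) for c in matrix.rows],
        fontsize=6,
    )
    fig.colorbar(im, ax=ax, label="frequency of documentation (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def summary_to_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2))
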