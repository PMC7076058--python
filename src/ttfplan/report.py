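"""Cross-configuration comparison reports and overlay images.

Aggregates plan-quality records over montage configurations: percent
changes of every metric versus a baseline configuration, arithmetic means
over the alternative configurations, a ranking by GTV field coverage
(E_AUC), and calibrated field-over-anatomy overlay images. All reported
numbers are rounded half-up to one decimal, matching the precision such
tables are conventionally printed at.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .metrics import PQMRecord, records_to_frame  # noqa: E402
from .phantom import LabelVolume  # noqa: E402

__all__ = [
    "ReportError",
    "round1",
    "percent_change",
    "rounding_consistent",
    "aggregate_alternatives",
    "ComparisonReport",
    "build_report",
    "export_overlay",
]


class ReportError(ValueError):
    """Raised for invalid report inputs."""


def round1(x: float) -> float:
    """Round half-up to one decimal (printed-table convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def percent_change(value: float, baseline: float) -> float:
    """100 * (value - baseline) / baseline, rounded to one decimal."""
    if baseline <= 0:
        raise ReportError("baseline value must be > 0 for a percent change")
    return round1(100.0 * (value - baseline) / baseline)


def rounding_consistent(reported: float, computed: float, tol: float = 0.3) -> bool:
    """Whether a printed percent change agrees with one recomputed from
    rounded table entries, allowing the drift that rounding introduces."""
    return abs(reported - computed) <= tol


def aggregate_alternatives(
    records: list[PQMRecord],
    metric: str,
    *,
    baseline: str = "SUPRATENTORIAL",
    roi: str | None = None,
) -> float:
    """Arithmetic mean of one metric over the non-baseline configurations,
    rounded to one decimal.

    ``metric`` may be an attribute name (``"e_auc"``) or a report column
    name (``"E_AUC"``).
    """
    attr = metric if metric in PQMRecord.COLUMNS else None
    if attr is None:
        by_col = {col: a for a, col in PQMRecord.COLUMNS.items()}
        attr = by_col.get(metric)
    if attr is None:
        raise ReportError(
            f"unknown metric {metric!r}; choose from {sorted(PQMRecord.COLUMNS.values())}"
        )
    pool = [
        r for r in records
        if r.configuration != baseline and (roi is None or r.roi == roi)
    ]
    if not pool:
        raise ReportError("no alternative-configuration records to aggregate")
    return round1(float(np.mean([getattr(r, attr) for r in pool])))


@dataclass
class ComparisonReport:
    """Assembled comparison across montage configurations."""

    baseline: str
    table: pd.DataFrame           # (roi, configuration) x metric
    percent_vs_baseline: pd.DataFrame
    aggregate: pd.DataFrame       # per-roi mean over alternative configurations
    ranking: dict[str, list[str]]  # roi -> configurations by descending E_AUC
    best: dict[str, str]          # roi -> top-ranked configuration
    ties: dict[str, bool] = field(default_factory=dict)

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(directory / "pqm_table.csv")
        self.percent_vs_baseline.to_csv(directory / "percent_vs_baseline.csv")
        self.aggregate.to_csv(directory / "aggregate_alternatives.csv")

    def to_json(self) -> dict:
        return {
            "baseline": self.baseline,
            "best": self.best,
            "ties": self.ties,
            "ranking": self.ranking,
            "aggregate": {
                "|".join(k) if isinstance(k, tuple) else k: v
                for k, v in self.aggregate.round(6).to_dict("index").items()
            },
        }


def build_report(records: list[PQMRecord], baseline: str = "SUPRATENTORIAL") -> ComparisonReport:
    """Percent-change and aggregate tables plus an E_AUC ranking.

    Deterministic and pure: identical records give identical tables.
    Ranking ties are broken by configuration name and flagged.
    """
    table = records_to_frame(records)
    rois = table.index.get_level_values("roi").unique()
    if not all(baseline in table.loc[roi].index for roi in rois):
        raise ReportError(f"baseline configuration {baseline!r} missing from records")

    pct_rows = {}
    agg_rows = {}
    ranking: dict[str, list[str]] = {}
    best: dict[str, str] = {}
    ties: dict[str, bool] = {}
    for roi in rois:
        sub = table.loc[roi]
        base = sub.loc[baseline]
        if (base <= 0).any():
            nonpos = list(base.index[base <= 0])
            pct = pd.DataFrame(index=sub.index, columns=sub.columns, dtype=float)
            for col in sub.columns:
                if col in nonpos:
                    pct[col] = np.nan
                else:
                    pct[col] = (100.0 * (sub[col] - base[col]) / base[col]).map(round1)
        else:
            pct = (100.0 * (sub - base) / base).map(round1)
        for config in sub.index:
            pct_rows[(roi, config)] = pct.loc[config]
        alts = sub.drop(index=baseline)
        if len(alts):
            agg_rows[roi] = alts.mean(axis=0).map(round1)
        order = sorted(
            sub.index, key=lambda c: (-sub.loc[c, "E_AUC"], c)
        )
        ranking[roi] = order
        best[roi] = order[0]
        top = sub.loc[order[0], "E_AUC"]
        ties[roi] = bool((sub["E_AUC"] == top).sum() > 1)

    percent_vs_baseline = pd.DataFrame(pct_rows).T
    percent_vs_baseline.index.names = ["roi", "configuration"]
    aggregate = (
        pd.DataFrame(agg_rows).T if agg_rows
        else pd.DataFrame(columns=table.columns)
    )
    aggregate.index.name = "roi"
    return ComparisonReport(
        baseline=baseline, table=table, percent_vs_baseline=percent_vs_baseline,
        aggregate=aggregate, ranking=ranking, best=best, ties=ties,
    )


_PLANES = {"axial": 2, "coronal": 1, "sagittal": 0}


def export_overlay(
    volume: LabelVolume,
    field: np.ndarray,
    plane: str,
    index: int,
    path: str | Path,
    *,
    vmax: float = 100.0,
    quantity_label: str = "|E| (V/m)",
    cmap: str = "inferno",
) -> Path:
    """Write a grayscale anatomy slice with a calibrated field overlay.

    The color scale is fixed at [0, ``vmax``] regardless of the data, so
    overlays of different configurations are directly comparable; output
    is deterministic (fixed colormap, no timestamps).
    """
    if plane not in _PLANES:
        raise ReportError(f"plane must be one of {sorted(_PLANES)}")
    axis = _PLANES[plane]
    if not 0 <= index < volume.grid.shape[axis]:
        raise ReportError(
            f"slice {index} out of range for axis {axis} of size {volume.grid.shape[axis]}"
        )
    if field.shape != volume.labels.shape:
        raise ReportError("field and anatomy grids differ")

    sl = [slice(None)] * 3
    sl[axis] = index
    anat = volume.labels[tuple(sl)].astype(float).T
    fld = np.asarray(field, dtype=float)[tuple(sl)].T

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(anat, cmap="gray", origin="lower", interpolation="nearest")
    overlay = np.ma.masked_where(fld <= 0, fld)
    im = ax.imshow(
        overlay, cmap=cmap, origin="lower", interpolation="nearest",
        vmin=0.0, vmax=vmax, alpha=0.6,
    )
    cbar = fig.colorbar(im, ax=ax, fraction=0.046)
    cbar.set_label(quantity_label)
    ax.set_title(f"{plane} slice {index}")
    ax.set_xticks([])
    ax.set_yticks([])
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight", metadata={"Software": "ttfplan"})
    plt.close(fig)
    return path
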