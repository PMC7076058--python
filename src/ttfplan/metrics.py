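"""Field-volume histograms and plan-quality metrics (PQM).

Directly analogous to radiotherapy dose-volume histograms: for a scalar
field f over an ROI, the electric-field-volume histogram (EVH) gives the
fraction of ROI volume at or above each threshold t,

    fraction(t) = #{voxels in ROI : f >= t} / #{voxels in ROI},

and likewise the current-density-volume histogram (CDVH) for |J|. The
closed ">= t" convention is used everywhere. Scalar summaries:

* ``E_AUC`` — area under fraction-vs-threshold; by the layer-cake
  identity this equals the ROI mean magnitude as the threshold grid
  refines (and exactly, with per-unique-value thresholds).
* ``E_x%`` — the intensity received by the hottest x% of the ROI volume
  (largest t with at least x% of the volume >= t); E_50% is the median,
  E_5% the hotspot intensity.
* ``V_Et`` — percent of ROI volume at or above a fixed threshold t.

Voxels are weighted equally (uniform voxel volume).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import ROIMask

__all__ = [
    "EVHCurve",
    "PQMRecord",
    "MetricsError",
    "E_VOLUME_THRESHOLDS",
    "CD_VOLUME_THRESHOLDS",
    "compute_evh",
    "evh_auc",
    "intensity_percentile",
    "volume_at_threshold",
    "pqm",
    "records_to_frame",
]

#: Fixed thresholds for the volume-coverage metrics, V/m and A/m^2.
E_VOLUME_THRESHOLDS = (75.0, 50.0, 25.0)
CD_VOLUME_THRESHOLDS = (15.0, 10.0, 5.0)

DEFAULT_N_THRESHOLDS = 2048


class MetricsError(ValueError):
    """Raised for invalid metric inputs (empty ROI, bad thresholds)."""


def _roi_values(field: np.ndarray, mask) -> np.ndarray:
    member = mask.member if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    field = np.asarray(field, dtype=float)
    if field.shape != member.shape:
        raise MetricsError("field and mask shapes differ")
    values = field[member]
    if values.size == 0:
        raise MetricsError("ROI mask is empty")
    return values


@dataclass
class EVHCurve:
    """Volume-fraction curve of one scalar quantity over one ROI."""

    thresholds: np.ndarray  # ascending, starting at 0
    fraction: np.ndarray    # non-increasing, fraction[0] == 1
    roi: str = ""
    quantity: str = "E"     # "E" or "CD"
    exact: bool = False     # thresholds at every unique ROI value

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.thresholds.ndim != 1 or self.thresholds.shape != self.fraction.shape:
            raise MetricsError("thresholds and fraction must be matching 1-D arrays")
        if self.thresholds[0] != 0.0:
            raise MetricsError("threshold grid must start at 0")
        if np.any(np.diff(self.thresholds) < 0):
            raise MetricsError("thresholds must be ascending")
        if np.any(np.diff(self.fraction) > 1e-12):
            raise MetricsError("fraction must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fraction": self.fraction})


def compute_evh(
    field: np.ndarray,
    mask,
    thresholds: np.ndarray | None = None,
    *,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
    exact: bool = False,
    roi: str = "",
    quantity: str = "E",
) -> EVHCurve:
    """Exact-counting volume histogram of ``field`` over ``mask``.

    With ``exact=True`` the threshold grid is {0} plus every unique ROI
    value, which makes the AUC reproduce the ROI mean to machine
    precision; otherwise a uniform grid of ``n_thresholds`` points from 0
    to the ROI maximum is used (or an explicit ascending grid).
    """
    values = _roi_values(field, mask)
    if isinstance(mask, ROIMask) and not roi:
        roi = mask.name
    if thresholds is None:
        if exact:
            thresholds = np.unique(np.concatenate([[0.0], np.unique(values)]))
        else:
            top = float(values.max())
            thresholds = np.linspace(0.0, top if top > 0 else 1.0, n_thresholds)
    else:
        thresholds = np.asarray(thresholds, dtype=float)
        if thresholds.ndim != 1 or thresholds.size == 0:
            raise MetricsError("thresholds must be a non-empty 1-D array")
        if np.any(np.diff(thresholds) < 0):
            raise MetricsError("thresholds must be ascending")
        if thresholds[0] != 0.0:
            raise MetricsError("threshold grid must start at 0")
    # fraction(t) = P(value >= t), exact counting via a sorted search
    sorted_vals = np.sort(values)
    n = values.size
    fraction = (n - np.searchsorted(sorted_vals, thresholds, side="left")) / n
    return EVHCurve(thresholds=thresholds, fraction=fraction, roi=roi,
                    quantity=quantity, exact=exact)


def evh_auc(curve: EVHCurve) -> float:
    """Area under the volume-fraction curve, in field units.

    Exact curves use the right-Riemann rule, which by the layer-cake
    identity returns exactly the ROI mean; sampled curves use the
    trapezoidal rule.
    """
    t, f = curve.thresholds, curve.fraction
    if curve.exact:
        return float(np.sum(np.diff(t) * f[1:]))
    return float(np.trapezoid(f, t))


def intensity_percentile(field: np.ndarray, mask, x_percent: float) -> float:
    """Intensity received by the hottest ``x_percent`` of the ROI volume.

    The largest threshold t such that at least x% of the ROI has value
    >= t; ties resolve toward the larger threshold. E_50% is the median
    ("at least half the volume at or above"), E_5% the hotspot intensity.
    """
    if not 0 < x_percent < 100:
        raise MetricsError("x_percent must be in (0, 100)")
    values = _roi_values(field, mask)
    n = values.size
    k = int(np.ceil(x_percent / 100.0 * n))  # voxels required at/above t
    return float(np.sort(values)[::-1][k - 1])


def volume_at_threshold(field: np.ndarray, mask, t: float) -> float:
    """Percent of ROI volume with value >= ``t``."""
    if t < 0:
        raise MetricsError("threshold must be >= 0")
    values = _roi_values(field, mask)
    return 100.0 * float(np.mean(values >= t))


@dataclass
class PQMRecord:
    """One full plan-quality row for a (configuration, ROI) pair."""

    configuration: str
    roi: str
    e_auc: float
    v_e75: float
    v_e50: float
    v_e25: float
    e_75: float
    e_50: float
    e_5: float
    cd_auc: float
    v_cd15: float
    v_cd10: float
    v_cd5: float
    cd_75: float
    cd_50: float
    cd_5: float

    #: report/CSV column names (V/m for E columns, % for V columns, A/m^2 for CD)
    COLUMNS = {
        "e_auc": "E_AUC", "v_e75": "V_E75", "v_e50": "V_E50", "v_e25": "V_E25",
        "e_75": "E_75%", "e_50": "E_50%", "e_5": "E_5%",
        "cd_auc": "CD_AUC", "v_cd15": "V_CD15", "v_cd10": "V_CD10", "v_cd5": "V_CD5",
        "cd_75": "CD_75%", "cd_50": "CD_50%", "cd_5": "CD_5%",
    }

    def __post_init__(self) -> None:
        eps = 1e-9
        if not (self.e_75 <= self.e_50 + eps and self.e_50 <= self.e_5 + eps):
            raise MetricsError("percentile ordering violated: need E_75% <= E_50% <= E_5%")
        if not (self.cd_75 <= self.cd_50 + eps and self.cd_50 <= self.cd_5 + eps):
            raise MetricsError("percentile ordering violated: need CD_75% <= CD_50% <= CD_5%")
        if not (self.v_e75 <= self.v_e50 + eps and self.v_e50 <= self.v_e25 + eps):
            raise MetricsError("volume ordering violated: need V_E75 <= V_E50 <= V_E25")
        for name in self.COLUMNS:
            if getattr(self, name) < 0:
                raise MetricsError(f"metric {name} must be >= 0")

    def as_series(self) -> pd.Series:
        return pd.Series({col: getattr(self, attr) for attr, col in self.COLUMNS.items()},
                         name=(self.roi, self.configuration))


def pqm(
    e_field: np.ndarray,
    cd_field: np.ndarray,
    mask,
    configuration: str,
    roi: str | None = None,
) -> PQMRecord:
    """All plan-quality metrics for |E| and |J| over one ROI.

    AUCs use exact per-unique-value histograms (so they equal the ROI
    means); volume metrics use the fixed thresholds 75/50/25 V/m and
    15/10/5 A/m^2.
    """
    if roi is None:
        roi = mask.name if isinstance(mask, ROIMask) else "ROI"
    e_curve = compute_evh(e_field, mask, exact=True, roi=roi, quantity="E")
    cd_curve = compute_evh(cd_field, mask, exact=True, roi=roi, quantity="CD")
    te75, te50, te25 = E_VOLUME_THRESHOLDS
    tc15, tc10, tc5 = CD_VOLUME_THRESHOLDS
    return PQMRecord(
        configuration=configuration,
        roi=roi,
        e_auc=evh_auc(e_curve),
        v_e75=volume_at_threshold(e_field, mask, te75),
        v_e50=volume_at_threshold(e_field, mask, te50),
        v_e25=volume_at_threshold(e_field, mask, te25),
        e_75=intensity_percentile(e_field, mask, 75),
        e_50=intensity_percentile(e_field, mask, 50),
        e_5=intensity_percentile(e_field, mask, 5),
        cd_auc=evh_auc(cd_curve),
        v_cd15=volume_at_threshold(cd_field, mask, tc15),
        v_cd10=volume_at_threshold(cd_field, mask, tc10),
        v_cd5=volume_at_threshold(cd_field, mask, tc5),
        cd_75=intensity_percentile(cd_field, mask, 75),
        cd_50=intensity_percentile(cd_field, mask, 50),
        cd_5=intensity_percentile(cd_field, mask, 5),
    )


def records_to_frame(records: list[PQMRecord]) -> pd.DataFrame:
    """Stack PQM records into a (roi, configuration)-indexed DataFrame."""
    if not records:
        raise MetricsError("no records")
    df = pd.DataFrame([r.as_series() for r in records])
    df.index = pd.MultiIndex.from_tuples(
        [(r.roi, r.configuration) for r in records], names=["roi", "configuration"]
    )
    return df
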