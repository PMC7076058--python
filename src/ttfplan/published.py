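"""Published plan-quality metrics for the seven montage configurations.

These are the reported PQM values from a single-patient finite-element
modelling study of a posterior-fossa (cerebellar) glioblastoma, for the
conventional supratentorial montage and six posterior-fossa alternatives,
evaluated over the GTV and the cerebellum. They serve as worked-example
inputs for the report module's aggregation arithmetic (averages over the
alternative configurations, percent increases versus the supratentorial
baseline); they are *not* outputs of this package's solver, whose phantom
and drive settings are not calibrated to that patient.

Column order per row: E_AUC (V/m), V_E75, V_E50, V_E25 (%), E_75%, E_50%,
E_5% (V/m), CD_AUC (A/m^2), V_CD15, V_CD10, V_CD5 (%), CD_75%, CD_50%,
CD_5% (A/m^2).
"""

from __future__ import annotations

from .metrics import PQMRecord

__all__ = ["BASELINE", "ALTERNATIVES", "published_records"]

BASELINE = "SUPRATENTORIAL"

ALTERNATIVES = (
    "PA_HORIZONTAL",
    "PA_HORIZONTAL_RIGHT",
    "PA_HORIZONTAL_LEFT",
    "PA_VERTICAL_SUPERIOR",
    "PA_VERTICAL_CENTER",
    "AP_PA_HORIZONTAL",
)

_ROWS: dict[tuple[str, str], tuple[float, ...]] = {
    # roi, configuration: (E_AUC, V_E75, V_E50, V_E25, E_75%, E_50%, E_5%,
    #                      CD_AUC, V_CD15, V_CD10, V_CD5, CD_75%, CD_50%, CD_5%)
    ("GTV", "SUPRATENTORIAL"):       (26.4, 0.1, 1.9, 64.6, 22.6, 28.0, 44.1,
                                      7.7, 4.8, 20.4, 70.5, 3.4, 8.3, 14.9),
    ("GTV", "PA_HORIZONTAL"):        (41.0, 10.4, 28.2, 71.6, 22.8, 38.1, 99.1,
                                      11.6, 25.5, 49.8, 82.5, 6.3, 10.0, 26.5),
    ("GTV", "PA_HORIZONTAL_RIGHT"):  (39.2, 9.9, 24.0, 69.5, 21.7, 36.4, 95.6,
                                      11.3, 24.3, 47.9, 81.9, 6.2, 9.6, 25.7),
    ("GTV", "PA_HORIZONTAL_LEFT"):   (39.9, 9.9, 25.5, 71.0, 22.5, 37.0, 95.7,
                                      11.4, 24.5, 48.8, 82.4, 6.2, 9.8, 25.6),
    ("GTV", "PA_VERTICAL_SUPERIOR"): (34.4, 1.2, 18.9, 72.6, 23.7, 36.9, 60.8,
                                      9.3, 17.2, 47.1, 70.1, 3.3, 9.6, 17.8),
    ("GTV", "PA_VERTICAL_CENTER"):   (39.3, 2.7, 34.9, 78.0, 27.3, 42.3, 67.3,
                                      10.5, 23.1, 55.7, 79.3, 5.5, 11.0, 18.7),
    ("GTV", "AP_PA_HORIZONTAL"):     (40.9, 10.3, 27.8, 71.2, 22.6, 37.9, 98.7,
                                      11.7, 25.3, 49.8, 82.7, 6.5, 9.9, 26.3),
    ("CEREBELLUM", "SUPRATENTORIAL"):       (20.5, 0.0, 0.3, 35.1, 14.7, 21.5, 36.5,
                                             3.4, 0.0, 0.1, 16.4, 2.0, 3.5, 5.9),
    ("CEREBELLUM", "PA_HORIZONTAL"):        (69.8, 40.1, 62.9, 82.2, 35.9, 62.9, 159.4,
                                             11.4, 28.1, 48.9, 73.5, 4.7, 9.8, 26.0),
    ("CEREBELLUM", "PA_HORIZONTAL_RIGHT"):  (68.1, 38.7, 61.8, 82.0, 35.0, 61.4, 155.8,
                                             11.1, 26.6, 47.5, 73.2, 4.6, 9.5, 25.6),
    ("CEREBELLUM", "PA_HORIZONTAL_LEFT"):   (68.1, 38.4, 62.3, 82.3, 35.5, 61.9, 155.4,
                                             11.1, 26.4, 48.2, 73.3, 4.7, 9.7, 25.5),
    ("CEREBELLUM", "PA_VERTICAL_SUPERIOR"): (38.2, 8.0, 34.9, 65.9, 18.3, 36.7, 79.5,
                                             6.5, 5.5, 20.2, 54.0, 2.5, 5.7, 15.3),
    ("CEREBELLUM", "PA_VERTICAL_CENTER"):   (51.3, 25.2, 48.2, 75.9, 26.0, 48.1, 114.4,
                                             8.4, 14.0, 36.4, 64.6, 3.6, 7.5, 17.8),
    ("CEREBELLUM", "AP_PA_HORIZONTAL"):     (69.1, 39.5, 62.6, 82.3, 35.7, 62.4, 158.0,
                                             11.3, 27.5, 48.5, 73.4, 4.7, 9.7, 25.7),
}


def published_records() -> list[PQMRecord]:
    """The published PQM table as a list of records (GTV rows first)."""
    fields = list(PQMRecord.COLUMNS)
    out = []
    for (roi, config), values in _ROWS.items():
        out.append(PQMRecord(configuration=config, roi=roi,
                             **dict(zip(fields, values))))
    return out
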