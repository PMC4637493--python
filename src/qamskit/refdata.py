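"""Published reference values for the nine-flavonoid HPLC-DAD assay of
*Psoralea corylifolia* seed extracts.

The single-marker study this package implements reported, for nine
prenylated flavonoids separated in a 60-minute reverse-phase gradient:

* per-analyte linear calibration parameters (slope, intercept, R²,
  linear range, LOD, LOQ),
* relative correction factors (``f``) of six analytes against the
  neobavaisoflavone marker, measured across seven injection volumes and
  across four instrument × column combinations,
* per-batch contents (mg per g of powdered seed) for thirteen commercial
  batches by the external-standard method, and the matching single-marker
  contents with their accuracy percentages.

These constants serve two purposes: they are the default truth for the
synthetic study generator (slopes/intercepts as detector response,
contents as realistic sample composition), and they are frozen fixtures
for summary-statistic checks (column means, RSDs, accuracy ratios).
Raw peak areas were never published, so the absolute area scale is
anchored only by the calibration parameters; any common scale factor is
unidentifiable and irrelevant to the ratios the method consumes.

A note on the content tables: the accuracy column printed next to each
single-marker content reproduces the ratio against the external-standard
table only for a subset of cells (the two tables' column alignments are
internally inconsistent in the source data).  :func:`matched_accuracy_pairs`
therefore validates every candidate pairing numerically and returns only
the cells whose printed accuracy equals the recomputed ratio at its
printed precision.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = [
    "PANEL",
    "MARKER_ID",
    "QAMS_EXCLUDED",
    "QAMS_ANALYTES",
    "DEFAULT_RETENTION_TIMES",
    "REFERENCE_CALIBRATIONS",
    "RCF_VOLUMES_UL",
    "RCF_BY_VOLUME",
    "RCF_PRINTED_MEAN",
    "RCF_PRINTED_RSD",
    "RCF_BY_INSTRUMENT",
    "ES_CONTENTS",
    "QAMS_CONTENTS",
    "AccuracyPair",
    "matched_accuracy_pairs",
    "resolve_analyte",
]

#: The nine-analyte panel in elution order.
PANEL: tuple[str, ...] = (
    "isobavachin",
    "neobavaisoflavone",
    "bavachin",
    "corylin",
    "bavachalcone",
    "bavachinin",
    "isobavachalcone",
    "corylifol_a",
    "o_methylbavachalcone",
)

#: Neobavaisoflavone is the single marker: commercially available and of
#: comparatively stable content across batches.
MARKER_ID = "neobavaisoflavone"

#: Bavachalcone and corylin are excluded from single-marker quantification
#: by default (poor separation and low content in the reference study).
QAMS_EXCLUDED: tuple[str, ...] = ("bavachalcone", "corylin")

#: Analytes quantified through the marker in the reference study
#: (f1..f6, in that order).
QAMS_ANALYTES: tuple[str, ...] = (
    "isobavachin",
    "bavachin",
    "bavachinin",
    "isobavachalcone",
    "corylifol_a",
    "o_methylbavachalcone",
)

#: Plausible retention times (min) inside the 60-min separation window,
#: in elution order.  The source study did not tabulate retention times;
#: these anchor the simulated chromatograms only — every downstream
#: computation consumes areas, never positions.
DEFAULT_RETENTION_TIMES: dict[str, float] = {
    "isobavachin": 18.2,
    "neobavaisoflavone": 21.5,
    "bavachin": 24.8,
    "corylin": 27.9,
    "bavachalcone": 31.4,
    "bavachinin": 36.0,
    "isobavachalcone": 40.2,
    "corylifol_a": 45.1,
    "o_methylbavachalcone": 50.3,
}

#: Published calibration parameters: area = slope * (µg/mL) + intercept.
#: ``range`` is the validated linear range in µg/mL; LOD/LOQ in µg/mL.
REFERENCE_CALIBRATIONS: dict[str, dict] = {
    "isobavachin": {
        "slope": 6094.2, "intercept": -47.492, "r_squared": 0.9994,
        "range": (18.75, 300.0), "lod": 2.615, "loq": 8.718,
    },
    "neobavaisoflavone": {
        "slope": 28072.0, "intercept": -228.09, "r_squared": 0.9994,
        "range": (16.88, 270.0), "lod": 0.5610, "loq": 1.872,
    },
    "bavachin": {
        "slope": 9536.0, "intercept": -72.258, "r_squared": 0.9997,
        "range": (9.375, 300.0), "lod": 2.612, "loq": 8.706,
    },
    "corylin": {
        "slope": 52057.0, "intercept": -175.41, "r_squared": 0.9996,
        "range": (7.500, 120.0), "lod": 0.4780, "loq": 1.594,
    },
    "bavachalcone": {
        "slope": 10586.0, "intercept": -84.429, "r_squared": 0.9992,
        "range": (12.50, 200.0), "lod": 1.809, "loq": 6.029,
    },
    "bavachinin": {
        "slope": 8039.5, "intercept": -89.087, "r_squared": 0.9996,
        "range": (28.13, 450.9), "lod": 2.805, "loq": 9.349,
    },
    "isobavachalcone": {
        "slope": 9564.5, "intercept": -112.19, "r_squared": 0.9995,
        "range": (22.50, 360.0), "lod": 2.704, "loq": 9.012,
    },
    "corylifol_a": {
        "slope": 19363.0, "intercept": -148.88, "r_squared": 0.9996,
        "range": (12.50, 200.0), "lod": 1.014, "loq": 3.381,
    },
    "o_methylbavachalcone": {
        "slope": 13683.0, "intercept": 0.87600, "r_squared": 0.9997,
        "range": (7.656, 245.0), "lod": 1.853, "loq": 6.178,
    },
}

#: Injection volumes (µL) at which per-volume correction factors were
#: tabulated.  (The study text lists 8 µL as well but tabulates seven
#: rows; the seven tabulated rows are the fixture.)
RCF_VOLUMES_UL: tuple[float, ...] = (1, 2, 4, 6, 10, 16, 20)

#: Relative correction factors f = (W_marker × A_analyte) /
#: (W_analyte × A_marker) per injection volume, analyte vs the
#: neobavaisoflavone marker; one value per volume in ``RCF_VOLUMES_UL``.
RCF_BY_VOLUME: dict[str, tuple[float, ...]] = {
    "isobavachin":          (0.712, 0.702, 0.699, 0.687, 0.672, 0.651, 0.656),
    "bavachin":             (3.03, 2.95, 2.95, 2.91, 2.89, 2.80, 2.86),
    "bavachinin":           (0.859, 0.852, 0.849, 0.833, 0.827, 0.803, 0.806),
    "isobavachalcone":      (1.94, 1.94, 1.92, 2.00, 2.00, 2.01, 2.04),
    "corylifol_a":          (0.734, 0.745, 0.745, 0.776, 0.774, 0.780, 0.786),
    "o_methylbavachalcone": (1.38, 1.42, 1.34, 1.43, 1.46, 1.47, 1.48),
}

#: Printed column means of the per-volume f table.  The bavachin mean as
#: printed (2.92) is not recoverable from its own rounded column
#: (which averages to 2.91); it is kept here for completeness but is not
#: used as a recomputation fixture.
RCF_PRINTED_MEAN: dict[str, float] = {
    "isobavachin": 0.683,
    "bavachin": 2.92,
    "bavachinin": 0.833,
    "isobavachalcone": 1.98,
    "corylifol_a": 0.763,
    "o_methylbavachalcone": 1.43,
}

#: Printed column RSDs (%).  The bavachin (2.3) and bavachinin (2.6)
#: entries are not recoverable from the rounded columns; the remaining
#: four are exact recomputation fixtures.
RCF_PRINTED_RSD: dict[str, float] = {
    "isobavachin": 3.5,
    "bavachin": 2.3,
    "bavachinin": 2.6,
    "isobavachalcone": 2.3,
    "corylifol_a": 2.7,
    "o_methylbavachalcone": 3.6,
}

#: f measured on four instrument × column combinations (mean of n = 3).
RCF_BY_INSTRUMENT: dict[tuple[str, str], dict[str, float]] = {
    ("Agilent 1100", "Purospher C18"): {
        "isobavachin": 0.683, "bavachin": 2.916, "bavachinin": 0.833,
        "isobavachalcone": 1.98, "corylifol_a": 0.763,
        "o_methylbavachalcone": 1.46,
    },
    ("Agilent 1100", "Alltima C18"): {
        "isobavachin": 0.676, "bavachin": 2.928, "bavachinin": 0.814,
        "isobavachalcone": 2.07, "corylifol_a": 0.778,
        "o_methylbavachalcone": 1.52,
    },
    ("Waters 2695", "Purospher C18"): {
        "isobavachin": 0.672, "bavachin": 2.956, "bavachinin": 0.799,
        "isobavachalcone": 2.02, "corylifol_a": 0.774,
        "o_methylbavachalcone": 1.44,
    },
    ("Waters 2695", "Alltima C18"): {
        "isobavachin": 0.688, "bavachin": 2.935, "bavachinin": 0.803,
        "isobavachalcone": 2.12, "corylifol_a": 0.780,
        "o_methylbavachalcone": 1.48,
    },
}

_ES_ROWS: dict[str, tuple] = {
    # panel order; None marks a cell reported as "—" (not quantifiable)
    "S1":  (None, 9.124, 4.367, 0.7310, 2.478, 8.251, 8.013, 6.616, None),
    "S2":  (None, 9.647, 5.043, 0.7800, 2.368, 12.18, 11.61, 7.749, None),
    "S3":  (None, 9.538, 5.280, 1.031, 2.983, 9.386, 11.17, 7.432, 1.049),
    "S4":  (6.847, 9.677, 5.623, 1.610, 4.040, 9.178, 12.605, 6.997, 1.818),
    "S5":  (8.115, 9.058, 3.503, 1.187, 3.328, 6.416, 8.731, 7.237, 2.004),
    "S6":  (4.846, 8.202, 5.570, 2.011, 6.741, 7.707, 9.729, 6.624, 2.582),
    "S7":  (8.915, 7.837, 4.075, 1.478, 3.744, 7.547, 7.948, 5.962, 2.024),
    "S8":  (8.411, 14.66, 7.026, 1.452, 4.260, 10.94, 13.68, 9.726, 5.393),
    "S9":  (None, 10.29, 4.517, 0.6540, 2.122, 10.70, 12.43, 7.185, 2.120),
    "S10": (None, 5.413, 3.437, 1.349, 2.928, 4.229, 7.519, 4.892, 1.466),
    "S11": (None, 7.326, 3.149, 0.694, 3.958, 9.948, 8.287, 5.792, 2.981),
    "S12": (None, 5.474, 3.145, 0.638, 1.768, 6.040, 6.964, 3.437, 1.208),
    "S13": (None, 8.281, 3.142, 1.231, 2.921, 6.367, 7.120, 7.247, 1.479),
}

#: External-standard contents (mg/g): sample -> analyte -> value or None.
ES_CONTENTS: dict[str, dict[str, float | None]] = {
    sample: dict(zip(PANEL, row)) for sample, row in _ES_ROWS.items()
}

_QAMS_ROWS: dict[str, tuple] = {
    # QAMS_ANALYTES order; each cell (content mg/g, printed accuracy %)
    # with the accuracy kept as a string to preserve printed precision.
    "S1":  (None, (9.393, "102.9"), (4.229, "96.84"), (8.092, "99.86"),
            (6.750, "102.0"), None),
    "S2":  (None, (9.476, "98.23"), (4.773, "94.65"), (11.52, "99.33"),
            (7.650, "98.73"), None),
    "S3":  (None, (9.665, "101.3"), (5.195, "98.39"), (11.41, "102.1"),
            (7.541, "101.5"), (1.064, "101.5")),
    "S4":  ((6.755, "98.66"), (9.846, "101.7"), (5.607, "99.72"),
            (13.07, "103.7"), (7.070, "101.0"), (1.853, "102.0")),
    "S5":  ((8.682, "107.0"), (9.740, "107.5"), (3.383, "96.57"),
            (9.231, "105.7"), (7.809, "107.9"), (2.168, "108.2")),
    "S6":  ((4.660, "96.15"), (8.448, "103.0"), (5.705, "102.4"),
            (10.09, "103.7"), (6.839, "103.2"), (2.714, "105.1")),
    "S7":  ((9.329, "104.6"), (8.045, "102.7"), (3.349, "96.92"),
            (8.028, "101.0"), (6.080, "102.0"), (2.124, "105.0")),
    "S8":  ((8.300, "98.69"), (15.03, "102.5"), (7.057, "100.4"),
            (13.97, "102.1"), (9.932, "102.1"), (5.386, "99.87")),
    "S9":  (None, (10.31, "100.2"), (4.252, "94.13"), (12.61, "101.5"),
            (7.136, "99.33"), (2.116, "99.82")),
    "S10": (None, (5.152, "94.88"), (3.720, "108.2"), (7.773, "103.4"),
            (5.030, "97.26"), (1.495, "102.0")),
    "S11": (None, (7.159, "97.73"), (2.925, "92.89"), (8.077, "97.46"),
            (5.640, "97.38"), (3.015, "101.1")),
    "S12": (None, (5.597, "102.2"), (2.985, "94.92"), (7.200, "103.4"),
            (3.284, "95.57"), (1.323, "109.5")),
    "S13": (None, (9.052, "109.3"), (3.016, "96.00"), (7.309, "102.6"),
            (7.852, "108.35"), (1.609, "108.8")),
}

#: Single-marker contents: sample -> analyte -> (mg/g, printed accuracy %)
#: or None where the cell was reported as "—".
QAMS_CONTENTS: dict[str, dict[str, tuple[float, str] | None]] = {
    sample: dict(zip(QAMS_ANALYTES, row)) for sample, row in _QAMS_ROWS.items()
}


class AccuracyPair(NamedTuple):
    """A validated (single-marker, external-standard) content pair."""

    sample_id: str
    analyte_id: str
    w_qams: float        # mg/g, single-marker method
    w_es: float          # mg/g, external-standard method
    printed_accuracy: float  # % as printed alongside w_qams


def _printed_tolerance(text: str) -> float:
    """Half a unit in the last printed decimal place."""
    decimals = len(text.split(".")[1]) if "." in text else 0
    return 0.5 * 10.0 ** (-decimals) + 1e-9


def matched_accuracy_pairs() -> list[AccuracyPair]:
    """Return content pairs whose printed accuracy equals the recomputed
    ratio at printed precision.

    For each single-marker cell the matching external-standard cell is
    located numerically within the same sample's row (the published
    column alignments are inconsistent, see module docstring); cells
    with no numerically consistent partner are dropped.
    """
    pairs: list[AccuracyPair] = []
    for sample, row in QAMS_CONTENTS.items():
        es_row = ES_CONTENTS[sample]
        for analyte, cell in row.items():
            if cell is None:
                continue
            w_qams, acc_text = cell
            acc = float(acc_text)
            tol = _printed_tolerance(acc_text)
            best: tuple[float, float] | None = None  # (diff, w_es)
            for w_es in es_row.values():
                if w_es is None:
                    continue
                diff = abs(100.0 * w_qams / w_es - acc)
                if diff <= tol and (best is None or diff < best[0]):
                    best = (diff, w_es)
            if best is not None:
                pairs.append(AccuracyPair(sample, analyte, w_qams, best[1], acc))
    return pairs


def resolve_analyte(name: str) -> str:
    """Resolve a case-insensitive unique prefix (e.g. ``"NEO"``) to a
    panel analyte id."""
    key = name.strip().lower().replace("-", "_").replace(" ", "_")
    if key in PANEL:
        return key
    hits = [a for a in PANEL if a.startswith(key)]
    if len(hits) == 1:
        return hits[0]
    if not hits:
        raise KeyError(f"unknown analyte {name!r}")
    raise KeyError(f"ambiguous analyte {name!r}: matches {hits}")
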