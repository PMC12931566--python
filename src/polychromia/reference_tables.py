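"""Vendored worked-example values from the framework's published tables.

These are the printed numbers of the reference case study — one
histopathologically confirmed superficial melanoma and one benign junctional
nevus, each with a lesional and a perilesional ROI — vendored verbatim so
the table-verification harness never depends on the source document.

Layout:

* ``TABLE1``: global (grayscale vs composite-RGB) histogram stats per
  lesional ROI.
* ``TABLE2``: channel means, SDs and entropies per ROI column.
* ``TABLE3``: derived metrics (deltas, red asymmetry, polychromia index)
  per ROI column, as printed.
* ``TABLE4``: normalized metrics (lesional − perilesional) for both
  lesions, plus the printed residual-difference and residual-% columns.
* ``TABLE5``: normalized polychromia index per lesion.

Values are as printed (2 decimals unless the source printed more).  Known
print quirks, excluded from verification: the red-asymmetry row of TABLE3
does not follow from TABLE2's rounded entropies (computed upstream from
unrounded values), and TABLE4's Δ(R−B) percentage (+243%) does not follow
from its own printed inputs.
"""

ROI_COLUMNS = (
    "nevus_lesional",
    "nevus_perilesional",
    "melanoma_lesional",
    "melanoma_perilesional",
)

# Global histogram metrics of the lesional ROIs (grayscale vs composite RGB).
TABLE1 = {
    "nevus": {
        "grayscale": {"mean": 94.63, "sd": 53.27, "entropy": 7.45,
                      "skewness": 0.90, "kurtosis": 2.13},
        "rgb_composite": {"mean": 94.12, "sd": 52.84, "entropy": 7.42,
                          "skewness": 0.88, "kurtosis": 2.11},
    },
    "melanoma": {
        "grayscale": {"mean": 101.92, "sd": 70.02, "entropy": 7.67,
                      "skewness": 0.26, "kurtosis": 2.03},
        "rgb_composite": {"mean": 102.35, "sd": 69.44, "entropy": 7.63,
                          "skewness": 0.21, "kurtosis": 1.98},
    },
}

#: Printed % difference of melanoma entropy, RGB composite vs grayscale
#: (the only % cell of TABLE1 whose printed sign matches its own inputs).
TABLE1_MELANOMA_ENTROPY_PCT = -0.52

# Channel-specific means, SDs and entropies per ROI column.
TABLE2 = {
    "mean_red": dict(zip(ROI_COLUMNS, (109.44, 112.80, 120.58, 108.34))),
    "mean_green": dict(zip(ROI_COLUMNS, (111.32, 114.92, 131.44, 109.73))),
    "mean_blue": dict(zip(ROI_COLUMNS, (108.87, 110.41, 118.26, 106.80))),
    "sd_red": dict(zip(ROI_COLUMNS, (52.21, 50.14, 71.88, 60.33))),
    "sd_green": dict(zip(ROI_COLUMNS, (53.77, 51.60, 74.21, 59.44))),
    "sd_blue": dict(zip(ROI_COLUMNS, (51.94, 50.98, 69.30, 58.15))),
    "entropy_red": dict(zip(ROI_COLUMNS, (6.89, 6.91, 7.22, 6.88))),
    "entropy_green": dict(zip(ROI_COLUMNS, (6.92, 6.95, 7.31, 6.90))),
    "entropy_blue": dict(zip(ROI_COLUMNS, (6.88, 6.89, 7.19, 6.87))),
}

# Derived per-ROI metrics, as printed.
TABLE3 = {
    "delta_rg": dict(zip(ROI_COLUMNS, (0.03, 0.04, 0.09, 0.02))),
    "delta_rb": dict(zip(ROI_COLUMNS, (0.01, 0.02, 0.03, 0.01))),
    "delta_gb": dict(zip(ROI_COLUMNS, (0.04, 0.06, 0.12, 0.03))),
    "a_r": dict(zip(ROI_COLUMNS, (-0.03, -0.06, 0.036, 0.04))),  # excluded from checks
    "i_p": dict(zip(ROI_COLUMNS, (0.026, 0.04, 0.08, 0.02))),
}

# Normalized metrics (lesional − perilesional) with the residual columns,
# row -> (melanoma_norm, nevus_norm, residual, residual_pct).
TABLE4 = {
    "mean_red": (12.24, -3.36, 15.60, 464),
    "mean_green": (21.71, -3.60, 25.31, 703),
    "mean_blue": (11.46, -1.54, 13.00, 844),
    "sd_red": (11.55, 2.07, 9.48, 458),
    "sd_green": (14.77, 2.17, 12.60, 580),
    "sd_blue": (11.15, 0.96, 10.19, 1061),
    "entropy_red": (0.34, -0.02, 0.36, 1800),
    "entropy_green": (0.41, -0.03, 0.44, 1467),
    "entropy_blue": (0.32, -0.01, 0.33, 3300),
    "delta_rg": (9.47, -0.24, 9.71, 4045),
    "delta_rb": (0.78, -1.82, 2.60, 243),  # % cell irreproducible, excluded
    "delta_gb": (10.25, -2.06, 12.31, 597),
    "a_r": (7.53, 1.16, 6.37, 549),
}

#: Rows of TABLE4 that are direct lesional − perilesional differences of
#: TABLE2 rows (the delta/a_r rows of TABLE4 are on a different, unstated
#: scale than TABLE3 and are verified only internally to TABLE4).
TABLE4_ROWS_FROM_TABLE2 = (
    "mean_red", "mean_green", "mean_blue",
    "sd_red", "sd_green", "sd_blue",
    "entropy_red", "entropy_green", "entropy_blue",
)

#: The % cell excluded from verification (does not follow from its inputs).
TABLE4_EXCLUDED_PCT_ROWS = ("delta_rb",)

# Normalized polychromia index per lesion.
TABLE5 = {"melanoma": 6.84, "nevus": -1.38}

#: Separation between the two normalized polychromia indices.
TABLE5_IP_GAP = 8.22
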