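"""Published reference values for the 16-compound P. multiflorum panel.

These small tables hold the reported study-level results for the
MRM-quantified compound panel (X1-X16): the differential-screen
statistics of the 13 metabolomics-derived compounds, the gray
relational degrees and standardized OPLS coefficients ("R values")
against 1/IC50 and IC50 of L02 and HepG2 hepatocytes, and the
network sensitivity results (Garson percentage and mean impact
value). They serve as fixed inputs for exercising the selection and
consensus rules and as plausibility anchors for the synthetic cohort.
"""

from __future__ import annotations

import pandas as pd

PANEL_COMPOUNDS = [
    "X1", "X2", "X3", "X4", "X5", "X6", "X7", "X8",
    "X9", "X10", "X11", "X12", "X13", "X14", "X15", "X16",
]

COMPOUND_NAMES = {
    "X1": "Catechin",
    "X2": "Epicatechin",
    "X3": "Torachrysone-8-O-b-D-glucopyranoside",
    "X4": "7-acetyl-3,8-dihydroxy-6-methyl-1-naphthyl-b-D-glucopyranoside",
    "X5": "Epicatechin-3-O-gallate",
    "X6": "Emodin-8-O-b-D-glucopyranoside",
    "X7": "Emodin bianthrones",
    "X8": "Emodin-physcion bianthrones",
    "X9": "Physcion bianthrones",
    "X10": "2,3,5,4'-tetrahydroxystilbene-2-O-b-D-(2-O-monogalloylesters)-glucopyranoside",
    "X11": "Polygonibene E",
    "X12": "Polygonumnolides C1-C4",
    "X13": "Polygonumnolides A1-A4",
    "X14": "PM 14-17",
    "X15": "PM 22-25",
    "X16": "PM 5",
}

# Differential-screen statistics of the 13 compounds identified from the
# untargeted raw-vs-processed comparison (VIP from OPLS-DA, Welch p,
# processed/raw fold change). The three dianthrone nuclear parents
# (X7-X9) entered the panel from prior toxicity work, not this screen.
_SCREEN_ROWS = [
    ("X1", "4.88_289.0716", 11.03, 1.50e-6, 0.286),
    ("X2", "7.89_290.0786n", 4.08, 4.60e-4, 0.397),
    ("X3", "23.71_408.1413n", 9.99, 1.00e-9, 0.225),
    ("X4", "17.97_393.1173", 3.48, 2.42e-10, 0.137),
    ("X5", "11.59_442.0917n", 7.44, 9.32e-5, 0.328),
    ("X6", "25.61_431.2031", 2.47, 1.75e-8, 0.441),
    ("X10", "14.58_558.1371n", 13.36, 5.97e-5, 0.359),
    ("X11", "22.91_582.1726n", 5.56, 2.50e-7, 0.366),
    ("X12", "32.40_671.1733", 1.83, 5.55e-3, 0.380),
    ("X13", "34.95_685.1887", 2.06, 3.15e-3, 0.366),
    ("X14", "30.37_758.1799n", 1.59, 2.04e-3, 0.157),
    ("X15", "27.64_933.2410", 1.86, 7.60e-5, 0.186),
    ("X16", "27.10_920.2342n", 1.77, 1.23e-4, 0.180),
]

# Gray relational degree of each compound's peak-area series against
# the 1/IC50 reference series, per cell line.
_GRA_DEGREES = {
    "X1": (0.763, 0.754), "X2": (0.818, 0.778), "X3": (0.806, 0.813),
    "X4": (0.804, 0.816), "X5": (0.825, 0.814), "X6": (0.826, 0.776),
    "X7": (0.755, 0.718), "X8": (0.750, 0.707), "X9": (0.718, 0.681),
    "X10": (0.800, 0.776), "X11": (0.786, 0.769), "X12": (0.733, 0.715),
    "X13": (0.744, 0.755), "X14": (0.772, 0.779), "X15": (0.750, 0.774),
    "X16": (0.755, 0.775),
}

# Standardized OPLS regression coefficients ("R values") of peak area
# against IC50, per cell line; negative = abundance up, IC50 down.
_OPLS_R = {
    "X1": (0.873, 0.478), "X2": (-0.285, 0.061), "X3": (0.193, -0.055),
    "X4": (-0.062, -0.150), "X5": (-0.515, -0.510), "X6": (-0.387, -0.210),
    "X7": (-0.443, -0.222), "X8": (0.160, 0.070), "X9": (-0.101, -0.190),
    "X10": (-0.266, -0.318), "X11": (-0.191, -0.062), "X12": (0.504, 0.506),
    "X13": (0.239, 0.198), "X14": (-0.597, -0.440), "X15": (0.048, -0.121),
    "X16": (-0.272, -0.252),
}

# Network sensitivity: Garson contribution percentage and mean impact
# value of each input on the IC50 output, per cell line.
_ANN_SENSITIVITY = {
    "X1": (4.07, 7.57, 0.009, 0.015), "X2": (5.01, 9.43, -0.029, 0.004),
    "X3": (7.29, 5.69, 0.105, 0.029), "X4": (7.03, 6.51, -0.046, -0.131),
    "X5": (6.60, 4.08, 0.002, 0.062), "X6": (7.35, 6.05, -0.089, -0.023),
    "X7": (6.40, 7.40, -0.161, -0.247), "X8": (8.50, 6.19, 0.086, 0.145),
    "X9": (4.99, 6.21, -0.038, 0.020), "X10": (7.61, 6.63, -0.055, 0.033),
    "X11": (5.77, 6.19, 0.022, -0.103), "X12": (8.12, 5.91, 0.072, 0.178),
    "X13": (5.47, 6.07, 0.002, -0.102), "X14": (4.88, 5.32, -0.015, -0.006),
    "X15": (5.70, 4.95, -0.040, 0.004), "X16": (5.22, 5.79, -0.013, 0.032),
}

# Reported cohort-level group means of the replicate-mean IC50 (ug/ml):
# 30 raw and 20 processed batches on each hepatocyte line.
REPORTED_MEAN_IC50 = {
    ("raw", "L02"): 250.0,
    ("raw", "HepG2"): 281.0,
    ("processed", "L02"): 735.0,
    ("processed", "HepG2"): 1185.0,
}

#: the three consensus hepatotoxicity markers of the panel
REPORTED_CONSENSUS_MARKERS = ("X6", "X7", "X14")


def panel_screen_stats() -> pd.DataFrame:
    """VIP / p / FC of the 13 differential compounds (feature-ID indexed)."""
    frame = pd.DataFrame(
        _SCREEN_ROWS, columns=["compound", "feature", "VIP", "p", "FC"]
    )
    return frame.set_index("compound")


def panel_gra_degrees() -> pd.DataFrame:
    """Gray relational degrees, compounds x cell lines."""
    return pd.DataFrame.from_dict(
        _GRA_DEGREES, orient="index", columns=["L02", "HepG2"]
    ).reindex(PANEL_COMPOUNDS)


def panel_opls_coefficients() -> pd.DataFrame:
    """Standardized OPLS coefficients vs IC50, compounds x cell lines."""
    return pd.DataFrame.from_dict(
        _OPLS_R, orient="index", columns=["L02", "HepG2"]
    ).reindex(PANEL_COMPOUNDS)


def panel_ann_sensitivity() -> pd.DataFrame:
    """Garson percentages and MIVs, compounds x (metric, cell line)."""
    frame = pd.DataFrame.from_dict(
        _ANN_SENSITIVITY,
        orient="index",
        columns=["garson_L02", "garson_HepG2", "miv_L02", "miv_HepG2"],
    ).reindex(PANEL_COMPOUNDS)
    return frame
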