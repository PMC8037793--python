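"""Published reference values from the clinical/CFD study this package models.

These constants are *inputs*, not results: the printed mesh-independence
velocity triplets feed the grid-convergence verification, the two-group
summary statistics parameterize the synthetic cohort generator and the
closed-form AUC surrogate, and the stationary packing-density sweep table
(obtained on the unshared patient-specific geometry) serves as a
qualitative curve-shape reference.  None of them is ever used as a fitted
or asserted output of this package's own solvers.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

from .gci import GridTriplet

# Mesh-independence study: velocity probes on fine/middle/coarse grids
# (14.04M / 6.24M / 2.44M elements), refinement ratios r21=1.310, r32=1.368.
R21, R32 = 1.310, 1.368

GRID_TRIPLETS: dict[str, GridTriplet] = {
    "right_pca_velocity": GridTriplet(0.1334, 0.1328, 0.1340, R21, R32),
    "left_sca_velocity": GridTriplet(0.1391, 0.1388, 0.1375, R21, R32),
    "median_cross_section_velocity": GridTriplet(0.182, 0.179, 0.169, R21, R32),
    "frontal_cross_section_velocity": GridTriplet(0.221, 0.218, 0.19, R21, R32),
    "aneurysm_wall_wss": GridTriplet(3.82, 3.83, 3.74, R21, R32),
}

# Group summaries (mean, sd) for the first-coil volume packing density,
# recanalization vs no-recanalization, with the late-recanalization group
# sizes 11 / 55 (alternative 6-month split: 18 / 48).
FIRST_VPD_RECAN = (10.51, 2.83)
FIRST_VPD_NO_RECAN = (18.28, 4.16)
N_RECAN_LATE, N_NO_RECAN_LATE = 11, 55
N_RECAN_6MO, N_NO_RECAN_6MO = 18, 48

# Published predictor statistics (documentation values, not fit targets).
PUBLISHED_AUC = 0.94
PUBLISHED_AUC_CI = (0.86, 1.00)
PUBLISHED_CUTOFF_PCT = 10.56
PUBLISHED_SENSITIVITY = 0.722
PUBLISHED_SPECIFICITY = 0.979

# Stationary packing-density sweep on the patient-specific geometry:
# columns are 1st VPD (%), neck velocity (m/s), artery-wall WSS (Pa),
# dome-wall WSS (Pa), dome-wall pressure (Pa), RFV/AV (%).
_SWEEP_CSV = """vpd_pct,neck_velocity,wss_artery,wss_aneurysm,pressure_aneurysm,rfv_av_pct
0,0.243,4.99,5.36,11344.0,98.9
1,0.214,4.98,3.83,11341.8,98.7
2,0.203,4.98,3.01,11341.5,98.4
3,0.199,4.98,2.44,11343.1,97.8
4,0.199,4.98,2.07,11345.5,96.8
5,0.200,4.99,1.84,11348.3,95.3
6,0.202,4.99,1.67,11351.0,93.6
7,0.204,5.00,1.53,11353.1,91.6
8,0.206,5.00,1.41,11354.7,89.2
9,0.207,5.01,1.31,11355.7,86.5
10,0.207,5.01,1.21,11356.1,83.3
11,0.206,5.02,1.13,11356.0,79.6
12,0.203,5.02,1.04,11355.7,75.2
13,0.200,5.02,0.96,11355.0,69.9
14,0.195,5.03,0.89,11354.2,64.0
15,0.188,5.03,0.82,11353.2,57.8
16,0.181,5.03,0.75,11352.0,51.8
17,0.173,5.04,0.69,11351.0,46.3
18,0.164,5.04,0.63,11350.0,41.7
19,0.155,5.05,0.58,11349.0,37.7
20,0.147,5.05,0.54,11348.0,34.2
21,0.138,5.06,0.50,11347.5,31.1
22,0.131,5.06,0.46,11346.8,28.3
23,0.123,5.06,0.43,11346.3,25.8
24,0.116,5.07,0.41,11345.8,23.6
25,0.109,5.07,0.38,11345.5,21.5
26,0.103,5.07,0.36,11345.2,19.7
27,0.097,5.08,0.34,11344.9,17.9
28,0.092,5.08,0.32,11344.9,16.3
29,0.087,5.08,0.31,11344.9,14.8
30,0.082,5.08,0.29,11344.9,13.4
"""


def reference_sweep() -> pd.DataFrame:
    """The published stationary sweep table as a DataFrame."""
    return pd.read_csv(StringIO(_SWEEP_CSV))
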