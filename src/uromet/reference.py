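"""Published summary statistics of the motivating acute-alcohol
crossover study.

The study profiled 120 urinary organic acids (umol/mmol creatinine) in
12 healthy young men at hours 0-4 after a controlled alcohol dose, and
reported 13 metabolites passing the triple selection criterion
(VIP >= 1.0, Wilcoxon p <= 0.05, |FC| >= 1.5) at the 0 h vs 1 h
contrast.  This module carries those printed per-metabolite statistics
— VIP, Wilcoxon p-values and signed fold changes at the 0-1 h and
0-4 h contrasts, and per-hour mean [SD] concentrations — as package
data.  They anchor the synthetic generator's preset (baselines and
planted response magnitudes) and serve as fixed inputs for
fold-change-arithmetic checks.

Note two printed rounding artifacts: the 0-1 h fold changes of
3-hydroxybutyric (printed +5.9) and malic acid (printed +4.9) do not
follow from the printed means (2.39/0.40 -> 6.0; 1.30/0.27 -> 4.8),
because the source rounded the means and the fold changes
independently.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = ["metabolite", "vip", "p_0_1", "fc_0_1",
            "mean_0", "sd_0", "mean_1", "sd_1", "mean_2", "sd_2",
            "mean_3", "sd_3", "mean_4", "sd_4", "p_0_4", "fc_0_4"]

_ROWS = [
    ("hippuric acid",          19.6, 0.002,  3.2, 948, 737, 3037, 1357, 2775, 2051, 1157, 1111, 726, 764, 0.239, -1.3),
    ("lactic acid",            14.4, 0.015, 27.4, 8.73, 3.65, 239, 412, 28.1, 19.7, 15.5, 14.7, 12.1, 8.51, 0.209, 1.4),
    ("fumaric acid",           7.24, 0.003,  6.4, 0.78, 0.47, 4.96, 4.53, 5.88, 6.08, 2.62, 1.94, 2.8, 2.15, 0.006, 3.6),
    ("vanillylmandelic acid",  5.03, 0.034, -1.6, 15.4, 3.61, 9.87, 7.39, 2.96, 2.32, 1.87, 1.11, 1.75, 0.99, 0.002, -8.8),
    ("2-hydroxybutyric acid",  4.06, 0.034,  4.3, 2.68, 1.54, 11.4, 16.0, 3.85, 2.68, 2.26, 1.16, 2.52, 2.15, 0.695, -1.1),
    ("succinic acid",          3.88, 0.010,  2.6, 3.81, 3.81, 9.83, 7.90, 20.2, 24.6, 12.8, 12.8, 12.7, 12.3, 0.004, 3.3),
    ("3-hydroxybutyric acid",  2.76, 0.041,  5.9, 0.40, 0.54, 2.39, 2.96, 0.59, 0.55, 0.47, 0.40, 0.77, 0.68, 0.182, 1.9),
    ("2-ethylhydracrylic acid", 1.66, 0.010, 2.1, 1.09, 1.00, 2.30, 1.73, 2.53, 2.78, 1.76, 1.61, 1.86, 1.47, 0.015, 1.7),
    ("3-hydroxyisobutyric acid", 1.56, 0.034, 1.9, 3.01, 1.27, 5.76, 3.86, 3.31, 2.05, 2.74, 1.25, 3.44, 1.95, 0.239, 1.1),
    ("2-hydroxyisobutyric acid", 1.39, 0.034, 1.8, 11.1, 4.03, 20.5, 14.2, 20.5, 13.4, 12.8, 6.93, 16.3, 13.1, 0.209, 1.5),
    ("malic acid",             1.32, 0.023,  4.9, 0.27, 0.16, 1.30, 1.60, 1.81, 1.59, 0.86, 0.67, 1.19, 1.37, 0.006, 4.5),
    ("N-tiglylglycine",        1.22, 0.034,  1.7, 1.55, 1.15, 2.65, 1.39, 10.9, 9.15, 10.9, 9.35, 10.8, 8.64, 0.002, 7.0),
    ("2-hydroxyglutaric acid", 1.06, 0.023,  1.7, 2.88, 0.99, 4.91, 3.39, 10.0, 5.90, 7.22, 3.62, 8.50, 5.73, 0.003, 3.0),
]

#: Printed per-metabolite statistics of the 13 reported alcohol-responsive
#: urinary organic acids (concentrations in umol/mmol Cr).
REFERENCE_PROFILE = pd.DataFrame(_ROWS, columns=_COLUMNS).set_index(
    "metabolite", drop=False)

#: Fold changes at the 0-1 h contrast that are *not* reproducible from the
#: printed means at one-decimal rounding (mean-rounding artifacts).
MEAN_ROUNDING_ARTIFACTS = ("3-hydroxybutyric acid", "malic acid")
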