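"""Published reference values used in worked examples and validation.

``FREE_RUNNING_RHYTHM_COUNTS`` reproduces the published free-running
summary table for *Pdf*-driven clock-gene manipulations: per genotype and
rearing-temperature block, the number of flies assayed (n), the number
called rhythmic (nR), and the printed percent rhythmicity, period (h) ± SEM
and rhythmic power ± SEM.  The counts are inputs; the percentages are
recomputable as 100·nR/n and serve as an arithmetic cross-check of the
summary layer.

``RHYTHMICITY_CONTRAST_2X2`` is the headline contingency contrast between
the driver control (39/40 rhythmic) and the constitutive knockdown
(4/40 rhythmic) under free-running conditions.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = ["RhythmTableRow", "FREE_RUNNING_RHYTHM_COUNTS",
           "RHYTHMICITY_CONTRAST_2X2"]


class RhythmTableRow(NamedTuple):
    block: str  # rearing/assay temperature protocol
    genotype: str
    n: int
    n_rhythmic: int
    percent_rhythmic: float  # as printed, 2 dp
    period_h: float
    period_sem: float
    power: float
    power_sem: float


FREE_RUNNING_RHYTHM_COUNTS: tuple[RhythmTableRow, ...] = (
    RhythmTableRow("28C/28C", "driver control", 40, 39, 97.50, 24.44, 0.06, 109.80, 6.39),
    RhythmTableRow("28C/28C", "cyc-RNAi control", 48, 41, 85.42, 24.02, 0.08, 85.74, 7.91),
    RhythmTableRow("28C/28C", "Pdf>cyc-RNAi", 40, 4, 10.00, 25.88, 3.03, 24.32, 3.71),
    RhythmTableRow("28C/28C", "Clk-RNAi control", 26, 24, 92.31, 23.73, 0.10, 97.66, 8.90),
    RhythmTableRow("28C/28C", "Pdf>Clk-RNAi", 21, 11, 52.38, 25.36, 0.22, 36.74, 6.76),
    RhythmTableRow("28C/28C", "driver control (vri)", 24, 24, 100.00, 24.50, 0.07, 101.40, 8.97),
    RhythmTableRow("28C/28C", "cas9+vri-g control", 16, 14, 87.50, 23.86, 0.11, 124.60, 10.39),
    RhythmTableRow("28C/28C", "Pdf>cas9+vri-g", 18, 7, 38.89, 23.50, 0.15, 29.02, 3.68),
    RhythmTableRow("28C/28C", "driver control (dn)", 31, 26, 83.87, 24.98, 0.07, 56.76, 6.73),
    RhythmTableRow("28C/28C", "dn-cyc control", 24, 23, 95.83, 23.54, 0.08, 72.79, 9.29),
    RhythmTableRow("28C/28C", "Pdf>dn-cyc", 32, 1, 3.13, 25.50, 0.00, 13.66, 0.00),
    RhythmTableRow("28C/28C", "dn-Clk control", 27, 27, 100.00, 23.52, 0.06, 93.52, 8.71),
    RhythmTableRow("28C/28C", "Pdf>dn-Clk", 28, 1, 3.57, 23.50, 0.00, 17.18, 0.00),
    RhythmTableRow("28C/18C", "driver control", 68, 60, 88.24, 24.40, 0.17, 87.80, 7.33),
    RhythmTableRow("28C/18C", "cyc-RNAi control", 94, 88, 93.62, 24.18, 0.04, 81.06, 4.38),
    RhythmTableRow("28C/18C", "Pdf>cyc-RNAi", 70, 19, 27.14, 23.82, 0.81, 21.42, 1.78),
    RhythmTableRow("18C/28C", "driver control", 30, 30, 100.00, 24.93, 0.04, 127.80, 6.76),
    RhythmTableRow("18C/28C", "cyc-RNAi control", 25, 24, 96.00, 24.04, 0.07, 150.10, 12.44),
    RhythmTableRow("18C/28C", "Pdf>cyc-RNAi", 31, 12, 38.71, 23.67, 0.61, 24.27, 3.68),
    RhythmTableRow("25C/25C", "driver control", 29, 26, 89.66, 24.52, 0.08, 152.20, 11.53),
    RhythmTableRow("25C/25C", "cyc-RNAi control", 31, 26, 83.87, 24.06, 0.08, 95.44, 9.61),
    RhythmTableRow("25C/25C", "Pdf>cyc-RNAi", 31, 4, 12.90, 23.13, 0.24, 21.55, 6.93),
)

# driver control vs constitutive knockdown, rhythmic/arrhythmic under DD
RHYTHMICITY_CONTRAST_2X2 = (39, 1, 4, 36)
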