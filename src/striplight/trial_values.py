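"""Row-level summary values reported by the two-year strip-width field trial.

These small in-text tables are the worked-example inputs for the
heterogeneity statistics: per-treatment means for the eastern and western
border rows (and middle rows where reported).  Units follow the trial's
bookkeeping: accumulated PAR in 1e5 umol m-2 s-1 (sum of 15-min readings),
RUE in g MJ-1, leaf area in cm2 plant-1, dry matter and yield in g plant-1.
Treatment order is M2S3 .. M2S8 throughout.
"""

from __future__ import annotations

TREATMENT_ORDER = ("M2S3", "M2S4", "M2S5", "M2S6", "M2S7", "M2S8")

#: whole-period accumulated canopy PAR, 1e5 umol m-2 s-1
ACC_PAR_WHOLE_PERIOD = {
    "west": (17.8, 19.5, 22.4, 24.0, 26.7, 27.1),
    "east": (16.5, 18.2, 21.1, 22.8, 23.5, 26.9),
}

#: grain-filling-stage (R5) radiation use efficiency, g MJ-1
RUE_R5 = {
    "east": (1.59, 1.22, 1.42, 1.35, 1.33, 1.30),
    "west": (1.58, 1.49, 1.46, 1.39, 1.40, 1.34),
}

#: R5 leaf area, cm2 plant-1
LEAF_AREA_R5 = {
    "east": (1086.2, 982.5, 1194.7, 1356.9, 1488.8, 1511.1),
    "west": (1076.4, 1109.4, 1291.3, 1540.7, 1615.4, 1731.6),
    "middle": (1357.6, 1308.6, 1590.8, 1701.2, 1906.6, 2063.5),
}

#: R5 dry matter, g plant-1
DRY_MATTER_R5 = {
    "east": (10.7, 10.6, 16.8, 19.6, 22.6, 24.1),
    "west": (10.6, 13.3, 17.6, 20.5, 24.1, 26.3),
    "middle": (14.6, 17.8, 23.0, 26.2, 29.2, 33.0),
}

#: grain yield, g plant-1
YIELD_PER_PLANT = {
    "east": (8.0, 7.9, 12.1, 12.5, 14.3, 15.1),
    "west": (10.1, 9.1, 13.2, 14.6, 14.5, 16.7),
    "middle": (11.0, 12.3, 15.8, 18.7, 20.7, 20.5),
}
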