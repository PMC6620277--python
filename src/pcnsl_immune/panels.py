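"""Built-in score-panel fixtures.

``pcnsl2019`` holds the four published PCNSL prognosis formulas: weighted sums
of transcript-variant FPKM values scoring Th-1 status, Th-2 status, and
stimulatory / inhibitory immune-checkpoint activity.  Coefficients are
transcribed exactly as printed; ordering follows the printed formulas.

Note CD4-001 appears in both the Th1 and Th2 panels, and IL2RB-001 in both
the Th2 and Stimulatory panels, so the union of all panel variants (48) is
smaller than the sum of panel sizes (50).
"""

PCNSL2019: dict[str, dict[str, float]] = {
    "Th1": {
        "CD4-001": 0.007,
        "IFNG-001": 0.012,
        "STAT1-001": 0.017,
        "STAT1-002": 0.012,
        "STAT1-003": 0.006,
        "STAT1-010": 0.003,
        "STAT1-011": 0.001,
        "TNFRSF1A-001": 0.007,
        "TNFRSF1A-004": 0.006,
        "TNFRSF1B-001": 0.004,
    },
    "Th2": {
        "CD28-001": 0.018,
        "CD28-201": 0.002,
        "CD28-202": 0.012,
        "CD4-001": 0.011,
        "IL18R1-001": 0.015,
        "IL18R1-003": 0.001,
        "IL18R1-201": 0.004,
        "IL18R1-202": 0.001,
        "IL2RB-001": 0.003,
        "IL10-003": 0.01,
        "IL6-001": 0.025,
        "IL6-003": 0.002,
        "IL6-004": 0.029,
        "IL6-005": 0.015,
        "IL6-006": 0.005,
        "IL6-201": 0.017,
        "STAT6-001": 0.047,
        "TGFB3-001": 0.029,
    },
    "Stimulatory": {
        "IL2RB-001": 0.003,
        "TNFRSF18-001": 0.013,
        "TNFRSF18-002": 0.015,
        "TNFRSF18-003": 0.005,
        "CD27-001": 0.003,
        "CD40-001": 0.013,
        "CD40-002": 0.011,
        "TNFRSF4-001": 0.015,
        "CD70-001": 0.022,
    },
    "Inhibitory": {
        "ADORA2A-001": 0.004,
        "BTLA-001": 0.004,
        "BTLA-002": 0.002,
        "PDCD1LG2-001": 0.007,
        "PDCD1LG2-201": 0.01,
        "CD274-001": 0.025,
        "CD274-201": 0.023,
        "HAVCR2-001": 0.003,
        "IDO1-002": 0.009,
        "LAG3-001": 0.012,
        "PDCD1-001": 0.042,
        "PDCD1-002": 0.034,
        "PDCD1-003": 0.039,
    },
}

BUILTIN_PANELS: dict[str, dict[str, dict[str, float]]] = {"pcnsl2019": PCNSL2019}
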