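"""Small bundled example data.

The gallbladder tRF profile is a classic cautionary example for
tissue-of-origin work: a tRNA-derived fragment whose normalized
expression in gallbladder is nearly ten-fold that of the next most
abundant tissue (ileum) — so it classifies as gallbladder-enriched — yet
it is highly expressed across most solid tissues and low only in blood
cells, making it a poor marker of tissue specificity in blood-derived
fluids.
"""

from __future__ import annotations

import pandas as pd

#: Normalized counts of the gallbladder-enriched tRF
#: TCCCTGGTGGTCTAGTGGTTAGGATTCGGCGC across 33 sources
#: (30 tissues + monocytes, PBMCs and red blood cells).
GALLBLADDER_TRF_SEQUENCE = "TCCCTGGTGGTCTAGTGGTTAGGATTCGGCGC"

_GALLBLADDER_TRF_COUNTS = {
    "ADRENAL_GLAND": 120_004,
    "BLADDER": 127_655,
    "BREAST": 44_534,
    "CEREBELLUM": 124_302,
    "CEREBRAL_CORTEX": 137_064,
    "CEREBRAL_WHITE_MATTER": 424_818,
    "COLON_TRANSVERSE": 75_749,
    "DIAPHRAGM": 381_206,
    "DUODENUM": 619_992,
    "GALLBLADDER": 15_953_357,
    "ILEUM": 1_615_212,
    "JEJUNUM": 284_800,
    "KIDNEY": 139_955,
    "LARYNX": 958_023,
    "LEFT_HEART": 22_264,
    "LIVER": 530_800,
    "LOWER_ESOPHAGUS": 58_251,
    "LUNG": 66_785,
    "MONO": 11_612,
    "PANCREAS": 187_907,
    "PBMC": 6_166,
    "PROSTATE": 64_484,
    "RBC": 490,
    "RIGHT_HEART": 22_535,
    "SCIATIC": 393_225,
    "SIGMOID_COLON": 114_936,
    "SKELETAL_MUSCLE": 34_388,
    "SKIN": 136_642,
    "SPINAL_CORD": 164_628,
    "STOMACH": 164_674,
    "SUBMANDIBULAR_GLAND": 37_790,
    "THYROID": 146_499,
    "UPPER_ESOPHAGUS": 121_985,
}


def gallbladder_trf_profile() -> pd.Series:
    """Per-source normalized counts of the gallbladder-enriched tRF."""
    return pd.Series(_GALLBLADDER_TRF_COUNTS, name=GALLBLADDER_TRF_SEQUENCE, dtype=float)
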