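"""Shared categorical dimensions of the model.

Four behavioural risk factors and four directly affected cancer sites are
modelled.  Ages run over single years 0..100; age-dependent tables that do
not need single-year resolution (risk-factor distributions, relative risks,
5-year case fatality) use the coarser bands defined here.
"""
from __future__ import annotations

import numpy as np

FACTORS = ("bmi", "physical_activity", "sedentary_time", "alcohol")
F_BMI, F_ACTIVITY, F_SEDENTARY, F_ALCOHOL = range(4)
N_FACTORS = 4

CANCERS = ("breast", "colorectal", "oesophageal", "liver")
C_BREAST, C_COLORECTAL, C_OESOPHAGEAL, C_LIVER = range(4)
N_CANCERS = 4

SEXES = ("male", "female")
MALE, FEMALE = 0, 1

MAX_AGE = 100
N_AGES = MAX_AGE + 1

# Age-band edges: band i covers [edge_i, edge_{i+1})
AGE_BAND_EDGES = np.array([0, 20, 35, 50, 65, 80, N_AGES])
N_BANDS = len(AGE_BAND_EDGES) - 1
AGE_BAND_LABELS = tuple(
    f"{AGE_BAND_EDGES[i]}-{AGE_BAND_EDGES[i + 1] - 1}" for i in range(N_BANDS)
)


def age_band(ages) -> np.ndarray:
    """Map single-year ages to age-band indices (vectorized)."""
    ages = np.asarray(ages)
    return np.clip(
        np.searchsorted(AGE_BAND_EDGES, ages, side="right") - 1, 0, N_BANDS - 1
    )
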