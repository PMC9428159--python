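"""Built-in study conditions: per-treatment soil-property means/SDs and genus pools.

The soil table reproduces the published per-treatment means and standard
deviations of the field trial the synthetic generator emulates (pH, total
nitrogen TN, soil organic carbon SOC, nitrate NO3_N, ammonium NH4_N,
available phosphorus AP, dissolved organic nitrogen DON, soil water content
SWC). PDA (potential denitrification activity) and cumulative N2O were
published only as percent changes relative to the unfertilized control, so
their rows carry synthetic CK baselines scaled by the published ratios.
"""

from __future__ import annotations

import pandas as pd

from .design import DEFAULT_TREATMENTS

#: Trait names in fixed unit convention: pH (-), TN/SOC (g kg-1),
#: NO3_N/NH4_N/AP/DON (mg kg-1), SWC (%).
TRAITS = ("pH", "TN", "SOC", "NO3_N", "NH4_N", "AP", "DON", "SWC")

# mean, sd per treatment in CK, MF, MOF, OFP, MSP order
_SOIL = {
    "pH":    [(8.66, 0.03), (8.32, 0.07), (8.44, 0.08), (8.45, 0.05), (8.54, 0.06)],
    "TN":    [(0.85, 0.01), (0.93, 0.03), (0.94, 0.02), (0.98, 0.03), (0.99, 0.02)],
    "SOC":   [(7.48, 0.18), (7.93, 0.07), (8.81, 0.33), (8.84, 0.20), (9.81, 0.19)],
    "NO3_N": [(17.84, 1.04), (30.81, 2.78), (28.40, 3.57), (25.40, 1.41), (21.93, 1.81)],
    "NH4_N": [(15.33, 1.63), (16.07, 1.48), (14.87, 2.22), (15.81, 1.36), (16.53, 2.80)],
    "AP":    [(9.73, 1.41), (16.70, 1.57), (18.32, 1.69), (19.81, 0.72), (15.14, 0.97)],
    "DON":   [(10.89, 0.62), (12.42, 0.78), (11.89, 1.04), (17.78, 1.25), (18.48, 1.57)],
    "SWC":   [(23.11, 1.13), (28.21, 2.10), (32.42, 2.46), (31.93, 1.24), (28.63, 1.91)],
}

# Synthetic baselines for responses reported only as change vs CK.
_PDA_CK = 50.0          # ng N2O-N g-1 h-1
_PDA_RATIO = {"CK": 1.0, "MF": 1.346, "MOF": 1.464, "OFP": 1.941, "MSP": 1.608}
_N2O_CK = 0.85          # kg ha-1 cumulative over the season
_N2O_RATIO = {"CK": 1.0, "MF": 1.761, "MOF": 1.634, "OFP": 1.399, "MSP": 1.334}
_RESPONSE_CV = 0.10     # synthetic relative SD for PDA / N2O

#: Dominant genera per functional gene, used as the default genus pools of
#: the OTU-table generator. nirK/nirS encode the two nitrite reductases,
#: nosZ the N2O reductase.
GENUS_POOLS = {
    "nirK": ("Nitrosospira", "Rhodobacter", "Alcaligenes", "Mesorhizobium",
             "Rubellimicrobium", "Ochrobactrum"),
    "nirS": ("Cupriavidus", "Bradyrhizobium", "Rhodanobacter", "Azospira",
             "Herbaspirillum", "Zoogloea"),
    "nosZ": ("Azospirillum", "Mesorhizobium", "Burkholderia", "Herbaspirillum",
             "Shinella", "Ensifer", "Pseudomonas"),
}


def soil_property_table(include_responses: bool = True) -> pd.DataFrame:
    """Per-treatment trait means and SDs as a long table.

    Returns a DataFrame with columns ``trait, treatment, mean, sd``; this is
    the default ``trait_means_sds`` configuration of
    :func:`denitnet.simulate.generate_soil_covariates`.
    """
    rows = []
    for trait, cells in _SOIL.items():
        for treatment, (mean, sd) in zip(DEFAULT_TREATMENTS, cells):
            rows.append((trait, treatment, mean, sd))
    if include_responses:
        for treatment in DEFAULT_TREATMENTS:
            pda = _PDA_CK * _PDA_RATIO[treatment]
            n2o = _N2O_CK * _N2O_RATIO[treatment]
            rows.append(("PDA", treatment, pda, _RESPONSE_CV * pda))
            rows.append(("N2O", treatment, n2o, _RESPONSE_CV * n2o))
    return pd.DataFrame(rows, columns=["trait", "treatment", "mean", "sd"])


def treatment_means(trait: str) -> pd.Series:
    """Published treatment means for one soil trait, indexed by treatment."""
    table = soil_property_table(include_responses=True)
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise KeyError(f"unknown trait {trait!r}; known: {sorted(table['trait'].unique())}")
    return sub.set_index("treatment")["mean"]
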