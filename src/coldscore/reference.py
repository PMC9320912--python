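"""Published cohort summary for the 39-genotype maize cold-stress panel.

This module is the single calibration source for the default trait registry
and the synthetic-cohort generator.  For each of the 29 traits measured on
seedlings grown for 7 days at 22 °C (control, CK) and 10 °C (low temperature,
LT) it records:

``rc_percent``
    The cohort-mean rate change of the trait under cold stress, in percent
    (negative = decrease at 10 °C).  The generator turns this into a
    cold-effect multiplier ``m = 1 + rc/100``.
``cvg_ck`` / ``cvg_lt``
    The genetic coefficient of variation (SD of genotype means over their
    mean, x100) under each treatment.  ``cvg_ck`` is the default
    between-genotype dispersion of the generator.
``baseline_ck``
    A control-condition cohort mean in the trait's units.  Where a cold-
    treatment cohort mean is published, the baseline is that value
    back-transformed through the multiplier; otherwise a round value on a
    realistic scale for maize seedlings.
``direction``
    +1 if a larger value indicates stronger cold resistance, -1 if a larger
    value indicates damage.  Only malondialdehyde, the two reactive-oxygen
    readouts and intercellular CO2 rise with injury; everything else supports
    resistance.

The five retained principal-component variance shares of the published
trait-structure analysis are kept here as well; they are used for arithmetic
consistency checks, not as model inputs.
"""

from __future__ import annotations

# name, long_name, category, units, direction, rc_percent, cvg_ck, cvg_lt, baseline_ck
TRAIT_TABLE: tuple[tuple[str, str, str, str, int, float, float, float, float], ...] = (
    ("SL",       "seedling length",                 "growth",         "cm",                        +1,  -48.6, 20.58, 27.56,  25.0),
    ("RL",       "root length",                     "growth",         "cm",                        +1,  -39.0, 22.55, 24.66,  20.0),
    ("RN",       "root number",                     "growth",         "count",                     +1,  -10.2, 16.96, 23.99,   5.0),
    ("SFW",      "seedling fresh weight",           "growth",         "g",                         +1,  -28.1, 27.29, 28.38,   5.0),
    ("RFW",      "root fresh weight",               "growth",         "g",                         +1,  -21.1, 21.08, 34.54,   1.5),
    ("PB",       "plant biomass",                   "growth",         "g",                         +1,  -24.2, 26.54, 27.92,   6.5),
    ("RSR",      "root-shoot ratio",                "growth",         "ratio",                     +1,    9.9, 24.15, 31.21,   0.30),
    ("Chl_a",    "chlorophyll a content",           "photosynthetic", "mg g-1 FW",                 +1,  -18.6, 10.88, 16.75,   0.442),
    ("Chl_b",    "chlorophyll b content",           "photosynthetic", "mg g-1 FW",                 +1,  -21.7, 15.46, 17.90,   0.511),
    ("Chl_ab",   "chlorophyll a+b content",         "photosynthetic", "mg g-1 FW",                 +1,  -20.3, 11.49, 16.07,   0.954),
    ("Chl_ratio","chlorophyll a:b ratio",           "photosynthetic", "ratio",                     +1,    3.3, 13.45, 12.02,   0.866),
    ("Pn",       "net photosynthetic rate",         "photosynthetic", "uM m-2 s-1",                +1,  -19.7, 21.44, 18.63,   6.874),
    ("Ci",       "intercellular CO2 concentration", "photosynthetic", "uM M-1",                    -1,    7.2,  8.67,  9.21, 240.0),
    ("Gs",       "stomatal conductance",            "photosynthetic", "mol m-2 s-1",               +1,  -12.0,  6.52, 11.82,   0.15),
    ("Tr",       "transpiration rate",              "photosynthetic", "mM m-2 s-1",                +1,   -2.8,  9.19, 10.87,   2.47),
    ("WUE",      "water use efficiency",            "photosynthetic", "uM mM-1",                   +1,  -17.1, 13.16,  8.43,   2.774),
    ("Rubisco",  "Rubisco carboxylation activity",  "photosynthetic", "M m-2 s-1",                 +1,  -25.1, 32.15, 29.16,   8.772),
    ("MDA",      "malondialdehyde content",         "membrane",       "uM g-1 FW",                 -1,  221.9, 18.72, 27.18,   5.0),
    ("MSI",      "membrane stability index",        "membrane",       "%",                         +1,  -19.5,  5.76, 14.07,  82.07),
    ("O2",       "superoxide production rate",      "ROS",            "uM min-1 g-1 FW",           -1,  163.4, 11.82, 16.49,   2.0),
    ("H2O2",     "hydrogen peroxide content",       "ROS",            "uM g-1 FW",                 -1,  159.2, 15.20, 19.74,  10.0),
    ("SOD",      "superoxide dismutase activity",   "antioxidant",    "Unit g-1 protein",          +1,   42.7,  7.43, 34.85,   1.710),
    ("POD",      "peroxidase activity",             "antioxidant",    "Unit g-1 protein",          +1,  144.4, 14.56, 24.27,   0.675),
    ("CAT",      "catalase activity",               "antioxidant",    "uM min-1 g-1 protein",      +1,  101.1, 37.59, 40.13,   0.323),
    ("APX",      "ascorbate peroxidase activity",   "antioxidant",    "uM min-1 g-1 protein",      +1,   65.8, 15.35, 27.81,   3.287),
    ("Pro",      "proline content",                 "osmotic",        "ug g-1 FW",                 +1,  311.8,  9.69, 22.48,  20.0),
    ("Put",      "putrescine concentration",        "polyamine",      "nM g-1 FW",                 +1,  183.7,  8.87, 12.72,  96.89),
    ("Spd",      "spermidine concentration",        "polyamine",      "nM g-1 FW",                 +1,   69.2,  8.32, 20.02,  31.14),
    ("Spm",      "spermine concentration",          "polyamine",      "nM g-1 FW",                 +1,   56.6,  4.59, 15.62,  29.25),
)

TRAIT_NAMES: tuple[str, ...] = tuple(row[0] for row in TRAIT_TABLE)

#: Percent of total variance carried by the five principal components with
#: eigenvalue > 1 in the published trait-structure analysis, plus the printed
#: cumulative total.
PUBLISHED_PC_VARIANCE_SHARES: tuple[float, ...] = (49.683, 24.528, 8.749, 4.325, 3.867)
PUBLISHED_PC_CUMULATIVE: float = 91.152

#: Published range and dispersion of the comprehensive resistance score
#: across the 39-genotype panel (context, not a simulation input).
PUBLISHED_UJ_RANGE: tuple[float, float] = (0.152, 0.743)
PUBLISHED_UJ_CV: float = 34.2


def rc_percent(name: str) -> float:
    """Published cohort-mean rate change (%) for a trait."""
    for row in TRAIT_TABLE:
        if row[0] == name:
            return row[5]
    raise KeyError(name)


def cold_multiplier(name: str) -> float:
    """Cold-effect multiplier m = 1 + RC/100 for a trait."""
    return 1.0 + rc_percent(name) / 100.0
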