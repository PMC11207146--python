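"""Published study-level constants used as fixed inputs.

These are program facts and printed survey margins for China's Conversion of
Cropland to Forest Program (CCFP) study sites: payment rates, currency and
area conversions, and the survey tallies that downstream arithmetic
(shares, matched-pair counts, national scaling) consumes as inputs.
"""

# CCFP payment rates, Yuan / year / m^2 of enrolled cropland
PAYMENT_RATE = {"JC": 0.135, "TTZ": 0.1875}

# Currency and land-unit conversions (2014-2015 survey period)
YUAN_PER_USD = 6.22
M2_PER_MU = 666.7

# Unit price used to value collected fuelwood, Yuan / kg
FUELWOOD_PRICE_YUAN_PER_KG = 0.4

# log10(km) distance-bin edges for migration flows: short / medium / long
DISTANCE_BIN_EDGES = (1.7, 2.2, 2.7, 3.2)
DISTANCE_BIN_LABELS = ("short", "medium", "long")

# Survey tallies (printed margins of the two-site household survey)
SURVEY = {
    "individuals_total": 2905,
    "households_total": 731,
    "individuals_15_59": 1994,
    "migrants": 767,
    "migrant_households": 458,
    "migrants_sending": 277,
    "households_receiving": 233,
    "households_not_receiving": 225,
    "destination_cities": 87,
    "destination_cities_with_remittance": 55,
    "destination_provinces": 36,
    "destination_provinces_with_remittance": 24,
    "groups_jc": 22,
    "groups_ttz": 41,
}

# Program-level totals (1999-2019) used for national scaling
NATIONAL = {
    "total_investment_usd": 64e9,
    "enrolled_area_ha": 29.8e6,
}
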