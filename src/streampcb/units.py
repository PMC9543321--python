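"""Unit conversion constants.

Internally everything is SI (m, s, kg) with two domain conveniences:
concentrations in water are ng/L (= ug/m3) and in solids mg/kg dry weight.
Configuration files may use the field units common at small stream sites
(feet, miles, gallons per minute, cubic feet per second).
"""

M_PER_FT = 0.3048
M_PER_MILE = 1609.344
FT_PER_MILE = 5280.0

M3S_PER_CFS = 0.0283168466
M3S_PER_GPM = 6.30901964e-5  # US gallon = 3.785411784 L
M3_PER_GAL = 3.785411784e-3

SECONDS_PER_DAY = 86400.0
DAYS_PER_YEAR = 365.0

# 1 ng/L * 1 m3/s = 86.4 mg/day
MG_PER_DAY_PER_NGL_M3S = 86.4


def ft_to_m(x: float) -> float:
    return x * M_PER_FT


def miles_to_m(x: float) -> float:
    return x * M_PER_MILE


def gpm_to_m3s(x: float) -> float:
    return x * M3S_PER_GPM


def cfs_to_m3s(x: float) -> float:
    return x * M3S_PER_CFS


def gallons_to_m3(x: float) -> float:
    return x * M3_PER_GAL
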