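"""Unit conversions used throughout the package.

The mechanics simulator works in a single self-consistent clinical unit
system (pressure in cmH2O, volume in L, time in s, flow in L/s), which is
the native system of lung compliance/resistance and ventilator settings.
The gas/Reynolds module works in SI.  Every cross-system constant lives
here and nowhere else.
"""

#: 1 cmH2O expressed in pascal (conventional water column at 4 degC, g = 9.80665).
CMH2O_TO_PA: float = 98.0665

#: Work conversion: 1 cmH2O * 1 L = 98.0665 mJ.  (Identical digits to the
#: pressure constant because 1 L = 1e-3 m^3 and 1 mJ = 1e-3 J.)
CMH2O_L_TO_MJ: float = 98.0665

#: 1 L/min in m^3/s.
LPM_TO_M3S: float = 1.0 / 60_000.0

#: 1 L/min in L/s.
LPM_TO_LPS: float = 1.0 / 60.0

#: 1 mL in L.
ML_TO_L: float = 1.0e-3


def lpm_to_m3s(flow_lpm: float) -> float:
    return flow_lpm * LPM_TO_M3S


def lps_to_m3s(flow_lps: float) -> float:
    return flow_lps * 1.0e-3


def cmh2o_l_to_mj(work: float) -> float:
    """Convert mechanical work from cmH2O*L to millijoule."""
    return work * CMH2O_L_TO_MJ
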