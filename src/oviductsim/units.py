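"""Unit conversions. Internal convention: lengths mm, time s, pressure kPa,
stress kPa, viscosity Pa·s, cell dimensions µm where noted."""

MMHG_TO_KPA = 0.133322

UM_TO_MM = 1e-3
MM_TO_UM = 1e3

HOUR_TO_S = 3600.0
S_TO_HOUR = 1.0 / 3600.0


def mmhg_to_kpa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_KPA
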