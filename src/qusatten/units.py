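"""Unit conventions and conversions.

The package works in cm / microseconds / MHz throughout, so attenuation
slopes are Np/(cm.MHz) and exponents ``alpha0 * f * z`` are dimensionless.
"""

NEPER_TO_DB = 8.685889638065035  # 20 / ln(10)


def np_to_db(value_np: float) -> float:
    """Convert nepers to decibels (1 Np = 8.686 dB)."""
    return value_np * NEPER_TO_DB


def db_to_np(value_db: float) -> float:
    """Convert decibels to nepers."""
    return value_db / NEPER_TO_DB


def sound_speed_cm_per_us(sound_speed_m_s: float) -> float:
    """Convert a sound speed in m/s to cm/us (1540 m/s -> 0.154 cm/us)."""
    return sound_speed_m_s * 1e-4
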