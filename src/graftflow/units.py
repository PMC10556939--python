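"""Unit conversions.

Geometry is specified in millimetres (the scale surgeons and the design
drawings use); the flow solver works in SI metres.  All conversions go
through these helpers so the factor appears in exactly one place.
"""

MM_PER_M = 1000.0
PA_PER_MMHG = 133.322
ML_PER_M3 = 1.0e6
MM2_PER_M2 = 1.0e6


def mm_to_m(x):
    """Millimetres -> metres (works on scalars and arrays)."""
    return x / MM_PER_M


def m_to_mm(x):
    """Metres -> millimetres."""
    return x * MM_PER_M


def mmhg_to_pa(p):
    """mmHg -> Pascal."""
    return p * PA_PER_MMHG


def m3_to_ml(v):
    """Cubic metres -> millilitres."""
    return v * ML_PER_M3


def m2_to_mm2(a):
    """Square metres -> square millimetres."""
    return a * MM2_PER_M2
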