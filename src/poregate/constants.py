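"""Physical constants and shared defaults (nm / ns / kcal/mol unit system)."""

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_MOL_K = 0.0019872

#: Wetting criterion: a pore region counts as wet when the largest axial gap
#: between consecutive water oxygens (with region-end anchors) is at most this
#: value, the size of a water-water hydrogen-bond contact (nm).
WET_THRESHOLD_NM = 0.38

#: Default simulation temperature (K) for free-energy conversions.
DEFAULT_TEMPERATURE_K = 310.0

#: Effective diameter of hexahydrated Mg2+ (nm), the permeant species.
HEXAHYDRATED_MG_DIAMETER_NM = 0.68

NS_PER_S = 1.0e9


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at a decimal precision.

    Works on the decimal representation, so 0.705 -> 0.71 at 2 digits even
    though the nearest binary float is 0.70499999...  Values are first
    snapped to 10 decimals to absorb accumulated floating-point fuzz well
    below any printed precision.
    """
    from decimal import Decimal, ROUND_HALF_UP

    snapped = Decimal(repr(x)).quantize(Decimal(1).scaleb(-10),
                                        rounding=ROUND_HALF_UP)
    q = Decimal(1).scaleb(-ndigits)
    return float(snapped.quantize(q, rounding=ROUND_HALF_UP))
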