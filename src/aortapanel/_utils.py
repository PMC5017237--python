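"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (clinical-table convention), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def parse_optional_float(token: str | float | None) -> float | None:
    """Read a numeric annotation cell where '.' / 'NA' / '' mean absent."""
    if token is None:
        return None
    if isinstance(token, float):
        return None if token != token else token  # NaN -> absent
    token = str(token).strip()
    if token in {"", ".", "NA", "na", "nan", "None"}:
        return None
    return float(token)
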