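"""Concentration unit handling.

All slowex internals work in molar. I/O layers accept explicit unit tags
(``"uM"``, ``"nM"``, ...) so that the nanomolar orthosteric and micromolar
allosteric dissociation constants can never be silently mixed up by a
factor of 1000.
"""

from __future__ import annotations

import math
import re

from .errors import DomainError

#: Multiplier from tagged unit to molar.
UNIT_TO_MOLAR: dict[str, float] = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,  # greek mu, distinct codepoint from micro sign
    "nM": 1e-9,
    "pM": 1e-12,
}

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([A-Za-zµμ]+)\s*$")


def to_molar(value: float, unit: str) -> float:
    """Convert ``value`` expressed in ``unit`` to molar."""
    try:
        scale = UNIT_TO_MOLAR[unit]
    except KeyError:
        raise DomainError(
            f"unknown concentration unit {unit!r}; expected one of "
            + ", ".join(sorted(set(UNIT_TO_MOLAR) - {"μM"}))
        ) from None
    result = float(value) * scale
    if not math.isfinite(result):
        raise DomainError(f"non-finite concentration: {value!r} {unit}")
    return result


def parse_concentration(text: str) -> float:
    """Parse a quantity string such as ``"79 uM"`` or ``"10nM"`` to molar."""
    m = _QUANTITY_RE.match(text)
    if m is None:
        raise DomainError(f"cannot parse concentration {text!r} (expected e.g. '79 uM')")
    try:
        value = float(m.group(1))
    except ValueError:
        raise DomainError(f"cannot parse numeric part of {text!r}") from None
    return to_molar(value, m.group(2))


def format_molar(molar: float) -> str:
    """Render a molar value with a human-friendly unit (for logs and reports)."""
    for unit, scale in (("M", 1.0), ("mM", 1e-3), ("uM", 1e-6), ("nM", 1e-9)):
        if abs(molar) >= scale:
            return f"{molar / scale:.4g} {unit}"
    return f"{molar / 1e-12:.4g} pM"
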