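"""Monoisotopic atomic masses and common modification mass deltas.

The delta table maps elemental-composition labels (``CH2``, ``H2``, ``O`` ...)
to monoisotopic mass differences in Da, recomputed here from atomic masses so
that no hand-typed delta can drift out of sync with its formula.
"""

from __future__ import annotations

import re

import pandas as pd

# CODATA/IUPAC monoisotopic masses of the light elements that occur in
# plant-metabolite modifications, in Da.
MONOISOTOPIC: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

#: Compositions of the deltas shipped by default; labels are plain formulas.
DEFAULT_DELTA_FORMULAS: tuple[str, ...] = (
    "H2",
    "CH2",
    "O",
    "CH2O",
    "C2H4",
    "CO",
    "CO2",
    "H2O",
    "NH",
    "C2H2O",
)


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of a simple elemental formula such as ``C2H4O``.

    Raises ``ValueError`` on unknown element symbols or empty input.
    """
    if not formula or not formula.strip():
        raise ValueError("empty formula")
    pos = 0
    total = 0.0
    for match in _FORMULA_TOKEN.finditer(formula):
        if not match.group(0):
            continue
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at offset {pos}")
        pos = match.end()
        symbol, count = match.group(1), int(match.group(2) or 1)
        if symbol not in MONOISOTOPIC:
            raise ValueError(f"unknown element {symbol!r} in formula {formula!r}")
        total += MONOISOTOPIC[symbol] * count
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at offset {pos}")
    return total


def default_mass_deltas() -> pd.DataFrame:
    """Delta table with columns ``label`` and ``delta_da`` (monoisotopic Da)."""
    rows = [(f, formula_mass(f)) for f in DEFAULT_DELTA_FORMULAS]
    return pd.DataFrame(rows, columns=["label", "delta_da"])


def write_mass_deltas(path) -> None:
    """Write the default delta table as CSV (label, delta_da)."""
    default_mass_deltas().to_csv(path, index=False)
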