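"""Feature engineering from atom counts.

The base representation is the ten atom counts (C, H, N, O, S, P, F, Cl, Br,
I).  The extended representation appends eleven deterministic transformations
of those counts: the nine heteroatom-to-carbon ratios, the molar weight, and
the double-bond equivalents (DBE), for a total of M = 21 columns in a frozen
order.  No structural descriptors are ever computed -- the whole point of the
model is that molecular formula is the only input.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formula import ELEMENTS, HALOGENS, AtomCounts, validate_counts

#: IUPAC conventional atomic weights, g/mol.  The table is version-stamped so
#: serialized models record which weights produced their MW column.
ATOMIC_WEIGHTS: Mapping[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "Cl": 35.45,
    "Br": 79.904,
    "I": 126.904,
}

WEIGHT_TABLE_VERSION = "iupac-conventional-2021"

BASE_COLUMNS = list(ELEMENTS)
RATIO_COLUMNS = [f"{sym}/C" for sym in ELEMENTS if sym != "C"]
EXTENDED_COLUMNS = BASE_COLUMNS + RATIO_COLUMNS + ["MW", "DBE"]


class InconsistentFormulaWarning(UserWarning):
    """A formula whose DBE is negative or non-integer (radical/salt-like)."""


def molar_weight(counts: Mapping[str, int], table: Mapping[str, float] = ATOMIC_WEIGHTS) -> float:
    """Molar weight in g/mol: sum of atom counts times atomic weights."""
    counts = validate_counts(counts)
    return float(sum(n * table[sym] for sym, n in counts.items()))


def dbe(counts: Mapping[str, int], warn: bool = True) -> float:
    """Double-bond equivalents: rings plus degrees of unsaturation.

    DBE = C - (H + halogens)/2 + N/2 + 1.  Benzene (C6H6) gives 4,
    cyclohexyne (C6H8) gives 3, any alkane CnH2n+2 gives 0.  Chemically
    inconsistent formulas can yield negative or half-integer values; these
    are returned with an :class:`InconsistentFormulaWarning` rather than
    rejected, since mined datasets contain radicals and salts and the model
    treats DBE as a plain numeric feature.
    """
    counts = validate_counts(counts)
    halogens = sum(counts.get(sym, 0) for sym in HALOGENS)
    value = (
        counts.get("C", 0)
        - (counts.get("H", 0) + halogens) / 2.0
        + counts.get("N", 0) / 2.0
        + 1.0
    )
    if warn and (value < 0 or value != int(value)):
        warnings.warn(
            f"chemically inconsistent formula: DBE = {value}",
            InconsistentFormulaWarning,
            stacklevel=2,
        )
    return value


def elemental_ratios(counts: Mapping[str, int]) -> dict[str, float]:
    """The nine atom-to-carbon ratios (H/C, N/C, ..., I/C).

    Raises ``ValueError`` for carbon-free compounds; those must be filtered
    out upstream (they are outside the organic model space).
    """
    counts = validate_counts(counts)
    n_c = counts.get("C", 0)
    if n_c < 1:
        raise ValueError("carbon-free compound: elemental ratios are undefined")
    return {f"{sym}/C": counts.get(sym, 0) / n_c for sym in ELEMENTS if sym != "C"}


def feature_vector(counts: Mapping[str, int], extended: bool = False) -> np.ndarray:
    """Single-compound feature vector, length 10 (base) or 21 (extended)."""
    counts = validate_counts(counts)
    base = np.array([counts.get(sym, 0) for sym in ELEMENTS], dtype=float)
    if not extended:
        return base
    ratios = elemental_ratios(counts)
    extra = np.array(
        [ratios[col] for col in RATIO_COLUMNS]
        + [molar_weight(counts), dbe(counts, warn=False)],
        dtype=float,
    )
    return np.concatenate([base, extra])


def featurize(records: Sequence[Mapping[str, int]], extended: bool = False) -> pd.DataFrame:
    """Build the N x M feature matrix for a list of atom-count mappings.

    Row order parallels the input list.  Column order is frozen
    (:data:`BASE_COLUMNS` / :data:`EXTENDED_COLUMNS`) so serialized models
    are portable across runs.
    """
    if len(records) == 0:
        raise ValueError("cannot featurize an empty record list")
    rows = []
    for i, counts in enumerate(records):
        counts = validate_counts(counts)
        if counts.get("C", 0) < 1:
            raise ValueError(f"carbon-free compound at row {i}: not featurizable")
        rows.append(feature_vector(counts, extended=extended))
    columns = EXTENDED_COLUMNS if extended else BASE_COLUMNS
    return pd.DataFrame(np.vstack(rows), columns=columns)
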