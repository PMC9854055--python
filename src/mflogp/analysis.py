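"""Post-hoc error analysis: functional-group stratification, error ranking,
and feature-response correlation screening.

SMILES strings are used here and only here: the predictive path never sees
structure, so stratifying errors by functional group is a diagnostic of the
formula-only model, not an input to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy import stats

#: SMARTS substructure patterns per functional-group flag.  A molecule may
#: match several groups; each flag is 1 when any listed pattern matches.
#: The taxonomy (aromatic / carbonyl / alcohol / amine-nitrile / unsaturated
#: aliphatic / ether-ester / halogenated / other heteroatom) is an explicit,
#: documented stand-in covering the groups commonly discussed for LogP error
#: stratification.
GROUP_PATTERNS: Mapping[str, tuple[str, ...]] = {
    "aromatic": ("a",),
    "carbonyl": ("[CX3]=[OX1]",),
    "alcohol": ("[OX2H]",),
    "amine_nitrile": ("[NX3;!$([NX3]=O)]", "[CX2]#[NX1]"),
    "unsaturated_aliphatic": ("C=C", "C#C"),
    "ether_ester": ("[OD2]([#6])[#6]",),
    "halogenated": ("[F,Cl,Br,I]",),
    "heteroatom_other": ("[#16]", "[#15]"),
}

_COMPILED = {
    group: tuple(Chem.MolFromSmarts(p) for p in patterns)
    for group, patterns in GROUP_PATTERNS.items()
}

GROUPS = tuple(GROUP_PATTERNS)


@dataclass
class ErrorRecord:
    """One compound's absolute prediction error with its group flags."""

    identity: str
    abs_error: float
    flags: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.abs_error < 0:
            raise ValueError("absolute error must be non-negative")


@dataclass
class CorrelationReport:
    """Pearson matrix over [features + response] plus per-feature F-tests."""

    pearson: pd.DataFrame
    f_tests: pd.DataFrame  # columns: f_statistic, p_value (index = feature)


def detect_groups(smiles: str) -> dict[str, int]:
    """One-hot functional-group flags from a SMILES string.

    Raises ``ValueError`` on unparseable SMILES (batch callers should catch
    and log-skip such records).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return {
        group: int(any(mol.HasSubstructMatch(p) for p in patterns))
        for group, patterns in _COMPILED.items()
    }


def build_error_records(
    identities: Sequence[str],
    y: Sequence[float],
    yhat: Sequence[float],
    smiles: Sequence[str | None] | None = None,
) -> tuple[list[ErrorRecord], list[dict]]:
    """Absolute errors |yhat - y| with group flags; skipped SMILES are logged.

    Returns (records, skipped) where each skipped entry records the index and
    reason.  Records without SMILES get empty flags (they appear in no group).
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) != len(yhat):
        raise ValueError("y and yhat must have equal length")
    records, skipped = [], []
    for i, ident in enumerate(identities):
        flags: dict[str, int] = {}
        if smiles is not None and smiles[i]:
            try:
                flags = detect_groups(smiles[i])
            except ValueError as exc:
                skipped.append({"index": i, "identity": ident, "reason": str(exc)})
                continue
        records.append(ErrorRecord(identity=str(ident), abs_error=float(abs(yhat[i] - y[i])), flags=flags))
    return records, skipped


def group_error_summary(errors: Sequence[ErrorRecord]) -> pd.DataFrame:
    """Per-group distribution of absolute errors.

    A molecule contributes to every group it matches, so group counts can
    sum past N.  Percentiles use linear interpolation between order
    statistics.  Empty groups are reported with n = 0 and NaN statistics.
    """
    if not errors:
        raise ValueError("no error records to summarize")
    rows = []
    for group in GROUPS:
        values = np.array([e.abs_error for e in errors if e.flags.get(group, 0)])
        if len(values):
            rows.append(
                {
                    "group": group,
                    "n": len(values),
                    "mean": float(values.mean()),
                    "median": float(np.median(values)),
                    "p5": float(np.percentile(values, 5)),
                    "p95": float(np.percentile(values, 95)),
                }
            )
        else:
            rows.append(
                {"group": group, "n": 0, "mean": np.nan, "median": np.nan, "p5": np.nan, "p95": np.nan}
            )
    return pd.DataFrame(rows).set_index("group")


def rank_errors(errors: Sequence[ErrorRecord], k: int) -> tuple[list[ErrorRecord], list[ErrorRecord]]:
    """The k best- and worst-predicted records (ties keep input order)."""
    if k > len(errors):
        raise ValueError(f"k = {k} exceeds the {len(errors)} available records")
    best = sorted(errors, key=lambda e: e.abs_error)  # stable: ties keep input order
    worst = sorted(errors, key=lambda e: -e.abs_error)
    return best[:k], worst[:k]


def correlation_screen(X, y, feature_names: Sequence[str] | None = None) -> CorrelationReport:
    """Pearson correlations among features and with the response, plus F-tests.

    The F statistic per feature is the univariate-regression test
    F = r^2 (N - 2) / (1 - r^2) with p-value from F(1, N-2).  Constant
    columns have undefined correlation and are reported as NaN rather than
    raising.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns) if feature_names is None else list(feature_names)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least three rows for a correlation screen")
    if len(y) != n:
        raise ValueError("response length does not match feature rows")
    data = np.column_stack([X, y])
    labels = list(feature_names) + ["logp"]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    pearson = pd.DataFrame(corr, index=labels, columns=labels)
    f_rows = []
    for j, name in enumerate(feature_names):
        r = corr[j, -1]
        if not np.isfinite(r):
            f_rows.append({"feature": name, "f_statistic": np.nan, "p_value": np.nan})
            continue
        r2 = min(r * r, 1.0 - 1e-15)
        f_stat = r2 * (n - 2) / (1.0 - r2)
        p = float(stats.f.sf(f_stat, 1, n - 2))
        f_rows.append({"feature": name, "f_statistic": float(f_stat), "p_value": p})
    return CorrelationReport(pearson=pearson, f_tests=pd.DataFrame(f_rows).set_index("feature"))
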