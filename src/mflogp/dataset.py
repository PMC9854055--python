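"""Reading, curating, summarizing and splitting LogP compound datasets."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formula import AtomCounts, FormulaError, hill_formula, is_organic, parse_formula

#: Default CSV column names; override via ``column_map`` in :func:`read_records`.
DEFAULT_COLUMNS = {
    "formula": "formula",
    "logp": "logp",
    "name": "name",
    "smiles": "smiles",
    "source": "source",
}


@dataclass
class CompoundRecord:
    """One experimental LogP observation.

    ``logp`` is the base-10 log of the octanol-water partition coefficient.
    ``counts`` is derived from ``formula`` at construction; ``smiles`` is
    optional and only ever used for post-hoc error analysis, never for
    prediction.
    """

    formula: str
    logp: float
    name: str | None = None
    smiles: str | None = None
    source: str = ""
    counts: AtomCounts = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.counts is None:
            self.counts = parse_formula(self.formula)
        if not math.isfinite(float(self.logp)):
            raise ValueError(f"non-finite logp for {self.formula!r}")
        self.logp = float(self.logp)

    @property
    def hill(self) -> str:
        """Canonical Hill-notation formula (duplicate / isomer key)."""
        return hill_formula(self.counts)

    @property
    def identity(self):
        """Canonical compound identity: SMILES if present, else (name, Hill)."""
        if self.smiles:
            return self.smiles
        return (self.name or "", self.hill)


@dataclass
class ReadResult:
    records: list[CompoundRecord]
    rejects: pd.DataFrame  # columns: row, formula, reason


@dataclass
class CuratedDataset:
    """Filtered, deduplicated compound collection with filter provenance."""

    records: list[CompoundRecord]
    provenance: dict[str, int]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def counts(self) -> list[AtomCounts]:
        return [r.counts for r in self.records]

    @property
    def logp(self) -> np.ndarray:
        return np.array([r.logp for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self.records],
                "formula": [r.hill for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "logp": [r.logp for r in self.records],
                "source": [r.source for r in self.records],
            }
        )


@dataclass
class SplitIndices:
    """A disjoint train / held-out index partition of range(N)."""

    train: np.ndarray
    held_out: np.ndarray
    seed: int


@dataclass
class IsomerStats:
    """Per-formula LogP spread: how far formula-only prediction can go.

    ``per_formula`` is indexed by Hill formula with columns ``n``, ``mean``,
    ``std`` (sample std, n-1 denominator; NaN for singletons).  ``summary``
    aggregates min/mean/max of the stds over formulas with n >= 2.
    """

    per_formula: pd.DataFrame
    summary: dict[str, float]


def read_records(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> ReadResult:
    """Read compound records from a CSV file.

    Rows whose formula fails to parse (unsupported element, malformed syntax)
    are collected into the ``rejects`` report rather than silently dropped.
    A missing required column (formula, logp) raises ``KeyError``.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path)
    for required in ("formula", "logp"):
        if cols[required] not in df.columns:
            raise KeyError(
                f"required column {cols[required]!r} (mapped from {required!r}) "
                f"not found in {path}"
            )

    def _get(row, key):
        col = cols[key]
        if col not in df.columns:
            return None
        value = row[col]
        return None if pd.isna(value) else value

    records: list[CompoundRecord] = []
    rejects: list[dict] = []
    for i, row in df.iterrows():
        formula = row[cols["formula"]]
        try:
            rec = CompoundRecord(
                formula=str(formula),
                logp=float(row[cols["logp"]]),
                name=_get(row, "name"),
                smiles=_get(row, "smiles"),
                source=str(_get(row, "source") or ""),
            )
        except (FormulaError, ValueError, TypeError) as exc:
            rejects.append({"row": i, "formula": formula, "reason": str(exc)})
            continue
        records.append(rec)
    return ReadResult(records, pd.DataFrame(rejects, columns=["row", "formula", "reason"]))


def curate(records: Sequence[CompoundRecord]) -> CuratedDataset:
    """Filter a record list into a modeling-ready dataset.

    Removes carbon-free ("inorganic") records and exact duplicates of
    (canonical identity, logp), keeping the first occurrence.  Repeated
    measurements of one compound with *different* LogP values are retained
    (they carry experimental variance), as are isomers sharing a formula.
    """
    kept: list[CompoundRecord] = []
    seen: set = set()
    provenance = {"inorganic": 0, "duplicates": 0}
    for rec in records:
        if not is_organic(rec.counts):
            provenance["inorganic"] += 1
            continue
        key = (rec.identity, rec.logp)
        if key in seen:
            provenance["duplicates"] += 1
            continue
        seen.add(key)
        kept.append(rec)
    if not kept:
        raise ValueError("empty dataset after curation")
    return CuratedDataset(kept, provenance)


def isomer_deviation(ds: CuratedDataset) -> IsomerStats:
    """Per-formula LogP spread statistics.

    Groups records by Hill formula and reports n / mean / sample std per
    formula; the summary aggregates stds over formulas with at least two
    observations (singletons have undefined std and are excluded).
    """
    df = pd.DataFrame({"hill": [r.hill for r in ds.records], "logp": [r.logp for r in ds.records]})
    grouped = df.groupby("hill")["logp"].agg(n="size", mean="mean", std="std")
    multi = grouped.loc[grouped["n"] >= 2, "std"]
    summary = {
        "n_formulas": int(len(grouped)),
        "n_formulas_multi": int((grouped["n"] >= 2).sum()),
        "min_std": float(multi.min()) if len(multi) else float("nan"),
        "mean_std": float(multi.mean()) if len(multi) else float("nan"),
        "max_std": float(multi.max()) if len(multi) else float("nan"),
    }
    return IsomerStats(grouped, summary)


def split_dataset(n: int, train_fraction: float, seed: int) -> SplitIndices:
    """Random train / held-out partition of ``range(n)``.

    ``|train| = floor(train_fraction * n)`` -- the convention uniquely
    consistent with the published split sizes (85% of 18,091 -> 15,377 and
    80% of 15,377 -> 12,301).  Deterministic for fixed (n, fraction, seed).
    """
    if n < 2:
        raise ValueError("need at least two records to split")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(math.floor(train_fraction * n))
    return SplitIndices(train=perm[:n_train], held_out=perm[n_train:], seed=seed)
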