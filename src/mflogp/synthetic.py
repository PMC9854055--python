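"""Synthetic organic-formula datasets with a known LogP-generating function.

The generator emulates the statistical shape of mined LogP collections:
carbon numbers concentrated in the 1-25 range with a tail up to 62, sparse
heteroatom occurrence, repeated formulas whose LogP values spread like real
isomer families (~0.46 log units), plus optional exact-duplicate and
carbon-free contamination so curation has something to remove.  The response
is linear in the engineered features plus Gaussian noise, so linear-model
parameter recovery is exact at zero noise and every downstream stage has a
known noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset import CompoundRecord, CuratedDataset, curate
from .features import EXTENDED_COLUMNS, feature_vector
from .formula import hill_formula

#: Probability that each heteroatom occurs in a molecule, and the Poisson
#: mean of (count - 1) given occurrence.  Oxygen and nitrogen are common,
#: phosphorus and iodine rare -- sparse occupancy like real datasets.
DEFAULT_ELEMENT_PROBS: Mapping[str, tuple[float, float]] = {
    "N": (0.30, 0.8),
    "O": (0.45, 1.2),
    "S": (0.06, 0.3),
    "P": (0.02, 0.2),
    "F": (0.06, 1.0),
    "Cl": (0.10, 1.0),
    "Br": (0.04, 0.4),
    "I": (0.02, 0.3),
}

#: Generating coefficients over the extended feature columns.  Signs follow
#: lipophilicity chemistry (halogens raise LogP, N/O lower it); magnitudes
#: are scaled so single-feature correlations with the response stay moderate
#: (~0.4-0.6), as observed in mined LogP data.
DEFAULT_COEFFICIENTS: Mapping[str, float] = {
    "C": 0.085,
    "H": 0.004,
    "N": -0.45,
    "O": -0.40,
    "S": 0.20,
    "P": -0.35,
    "F": 0.15,
    "Cl": 0.45,
    "Br": 0.55,
    "I": 0.70,
    "H/C": 0.15,
    "O/C": -0.10,
    "DBE": -0.10,
}


@dataclass
class GeneratorSpec:
    """Knobs of the synthetic dataset generator.

    ``noise_sigma`` is per-measurement Gaussian noise (log units);
    ``isomer_sigma`` is a per-record structural offset that makes records
    sharing a formula disagree the way real isomers do.  ``duplicate_rate``
    and ``inorganic_rate`` inject contamination for curation tests.
    """

    n: int = 2000
    seed: int = 0
    max_carbon: int = 62
    carbon_log_mean: float = 2.1
    carbon_log_sigma: float = 0.7
    element_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENT_PROBS)
    )
    coefficients: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    intercept: float = 0.25
    noise_sigma: float = 0.5
    isomer_sigma: float = 0.46
    duplicate_rate: float = 0.0
    inorganic_rate: float = 0.0

    def __post_init__(self):
        for name in ("duplicate_rate", "inorganic_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        if self.noise_sigma < 0 or self.isomer_sigma < 0:
            raise ValueError("noise scales must be non-negative")

    def beta_vector(self) -> np.ndarray:
        """Coefficients as a dense vector over the 21 extended columns."""
        return np.array([self.coefficients.get(col, 0.0) for col in EXTENDED_COLUMNS])


_INORGANIC_POOL = ("H2O", "H3N", "H2S", "O2S", "H3P", "ClH", "BrH", "HI")


def _draw_formula(rng: np.random.Generator, spec: GeneratorSpec) -> dict[str, int]:
    n_c = int(np.clip(round(float(rng.lognormal(spec.carbon_log_mean, spec.carbon_log_sigma))), 1, spec.max_carbon))
    counts = {"C": n_c}
    for sym, (p_occur, extra_mean) in spec.element_probs.items():
        if rng.random() < p_occur:
            counts[sym] = 1 + int(rng.poisson(extra_mean))
    halogens = sum(counts.get(s, 0) for s in ("F", "Cl", "Br", "I"))
    n_n = counts.get("N", 0)
    # choose an unsaturation level, then back out H so DBE is a non-negative integer
    h_max = 2 * n_c + 2 + n_n - halogens
    max_dbe = max(h_max // 2, 0)
    n_dbe = int(min(rng.poisson(1.0 + n_c / 6.0), max_dbe))
    n_h = h_max - 2 * n_dbe
    if n_h > 0:
        counts["H"] = n_h
    return counts


def generate_formulas(spec: GeneratorSpec) -> list[str]:
    """Draw ``spec.n`` formula strings (Hill notation), deterministic under seed.

    With ``inorganic_rate > 0`` a matching fraction of carbon-free species is
    mixed in for curation tests; otherwise every formula has C >= 1.
    """
    rng = np.random.default_rng(spec.seed)
    formulas = []
    for _ in range(spec.n):
        if spec.inorganic_rate > 0 and rng.random() < spec.inorganic_rate:
            formulas.append(str(rng.choice(_INORGANIC_POOL)))
        else:
            formulas.append(hill_formula(_draw_formula(rng, spec)))
    return formulas


def generate_responses(
    formulas: list[str], spec: GeneratorSpec
) -> tuple[list[CompoundRecord], dict]:
    """Attach LogP responses to formulas via the known generating function.

    LogP = beta . extended_features + intercept + N(0, isomer_sigma)
    + N(0, noise_sigma).  The isomer term is drawn per record, so records
    sharing a formula disagree with std sqrt(isomer^2 + noise^2).  Exact
    duplicates are appended at ``duplicate_rate``.  Returns the records and
    a ground-truth dict for parameter-recovery tests.
    """
    from .formula import parse_formula  # deferred to keep import graph flat

    rng = np.random.default_rng(spec.seed + 1)
    beta = spec.beta_vector()
    records: list[CompoundRecord] = []
    for i, f in enumerate(formulas):
        counts = parse_formula(f)
        if counts.get("C", 0) >= 1:
            x = feature_vector(counts, extended=True)
            mu = float(x @ beta) + spec.intercept
        else:  # contaminant; response is irrelevant, curation removes it
            mu = 0.0
        logp = mu + float(rng.normal(0.0, spec.isomer_sigma)) + float(rng.normal(0.0, spec.noise_sigma))
        records.append(
            CompoundRecord(formula=f, logp=logp, name=f"syn-{i}", source="synthetic")
        )
    if spec.duplicate_rate > 0 and records:
        n_dup = int(rng.binomial(len(records), spec.duplicate_rate))
        for idx in rng.integers(0, len(records), size=n_dup):
            src = records[int(idx)]
            records.append(
                CompoundRecord(
                    formula=src.formula, logp=src.logp, name=src.name, source="synthetic-dup"
                )
            )
    truth = {
        "coefficients": dict(spec.coefficients),
        "beta": spec.beta_vector().tolist(),
        "intercept": spec.intercept,
        "noise_sigma": spec.noise_sigma,
        "isomer_sigma": spec.isomer_sigma,
    }
    return records, truth


def generate_dataset(spec: GeneratorSpec) -> tuple[list[CompoundRecord], dict]:
    """Formulas plus responses in one call."""
    return generate_responses(generate_formulas(spec), spec)


# fixed hand-verifiable fixture -------------------------------------------------

#: (name, formula, logp, smiles) rows: classic small molecules, an isomer
#: pair sharing C2H6O, one exact duplicate (last benzene row) and one
#: carbon-free record, so curation removes exactly two rows.
GOLD_ROWS = (
    ("benzene", "C6H6", 2.13, "c1ccccc1"),
    ("cyclohexyne", "C6H8", 2.20, None),
    ("methane", "CH4", 1.09, "C"),
    ("ethanol", "C2H6O", -0.31, "CCO"),
    ("dimethyl ether", "C2H6O", 0.10, "COC"),
    ("carbon tetrachloride", "CCl4", 2.83, "ClC(Cl)(Cl)Cl"),
    ("toluene", "C7H8", 2.73, "Cc1ccccc1"),
    ("phenol", "C6H6O", 1.46, "Oc1ccccc1"),
    ("aniline", "C6H7N", 0.90, "Nc1ccccc1"),
    ("acetone", "C3H6O", -0.24, "CC(=O)C"),
    ("acetic acid", "C2H4O2", -0.17, "CC(=O)O"),
    ("butane", "C4H10", 2.89, "CCCC"),
    ("isobutane", "C4H10", 2.76, "CC(C)C"),
    ("pyridine", "C5H5N", 0.65, "c1ccncc1"),
    ("naphthalene", "C10H8", 3.30, "c1ccc2ccccc2c1"),
    ("chloroform", "CHCl3", 1.97, "ClC(Cl)Cl"),
    ("ethylamine", "C2H7N", -0.13, "CCN"),
    ("benzene", "C6H6", 2.13, "c1ccccc1"),  # exact duplicate
    ("water", "H2O", -1.38, "O"),  # inorganic
)


def make_gold_records() -> list[CompoundRecord]:
    """The raw ~20-record fixture, pre-curation (1 duplicate, 1 inorganic)."""
    return [
        CompoundRecord(formula=f, logp=lp, name=name, smiles=smi, source="gold")
        for name, f, lp, smi in GOLD_ROWS
    ]


def make_gold_fixture() -> CuratedDataset:
    """The curated gold fixture: hand-verifiable features, isomer pair intact."""
    return curate(make_gold_records())
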