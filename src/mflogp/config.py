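"""Default configuration: tuning grids, split fractions, repeats.

All values can be overridden from a YAML or JSON file via :func:`load_config`;
the file's top-level keys shadow the defaults key by key.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

#: Hyperparameter search grids per model kind, expanded exhaustively in the
#: listed order (ties in CV score break toward earlier grid points).  Penalty
#: values are on the un-normalized RSS + lambda scale.  The tree grids are
#: kept deliberately small so that the full eight-cell factorial experiment
#: remains tractable on a single CPU; widen them from a config file for
#: full-scale runs.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "mlr": {},
    "ridge": {"penalty": [1e-4, 1e-2, 1.0, 1e2, 1e4]},
    "lasso": {"penalty": [1e-4, 1e-2, 1.0, 1e2, 1e4]},
    "rfr": {"n_estimators": [100], "max_depth": [10, None]},
    "gbr": {"n_estimators": [100], "max_depth": [3, 5]},
    "knnr": {"n_neighbors": [1, 2, 5, 10, 25]},
}

DEFAULTS: dict = {
    "grids": DEFAULT_GRIDS,
    "outer_fraction": 0.85,
    "inner_fraction": 0.8,
    "folds": 8,
    "repeats": 100,
    "seed": 0,
}


def load_config(path: str | Path | None = None) -> dict:
    """Merge a YAML/JSON config file over the package defaults."""
    config = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    if path is None:
        return config
    text = Path(path).read_text()
    loaded = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if loaded:
        for key, value in loaded.items():
            config[key] = value
    return config
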