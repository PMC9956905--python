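"""Pipeline configuration: defaults, TOML/YAML loading, validation.

Every study constant lives here rather than in code: the design (8 heifers,
7 cows, days 0/7/14/21/28, 4 runs), the two bucket schemes (250 buckets
over 0.50-4.67 ppm; 200 buckets over 1.1-9.0 ppm with the 4.7-5.2 water
window and 6.8-8.0 ppm excluded), cross-validation folds, screening alpha
and the pathway library.
"""

from __future__ import annotations

import copy
import hashlib
import json
import tomllib
from pathlib import Path

from .preprocess import BucketScheme

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config", "scheme_from_config", "config_hash"]

DEFAULT_CONFIG: dict = {
    "generator": {
        "n_heifers": 8,
        "n_cows": 7,
        "days": [0, 7, 14, 21, 28],
        "n_runs": 4,
        "n_replicates": 1,
        "seed": 42,
        "cattle_effect_scale": 1.0,
        "agingtype_effect_scale": 1.0,
        "animal_re_scale": 1.0,
        "run_re_scale": 1.0,
        "noise_sd": 0.02,
        "n_points": 32768,
        "linewidth": 0.0015,
        "sample_mass_mg": 200.0,
        "extract_fraction": 1.0,
    },
    "preprocess": {
        "aging_time": {"ppm_lo": 0.50, "ppm_hi": 4.67, "n_buckets": 250, "exclusions": []},
        "aging_type": {
            "ppm_lo": 1.1,
            "ppm_hi": 9.0,
            "n_buckets": 200,
            "exclusions": [[4.7, 5.2], [6.8, 8.0]],
        },
        "standard_region": [6.15, 6.40],
        "standard_target_integral": 1.0,
    },
    "models": {
        "pls_max_components": 10,
        "pls_folds": 10,
        "oplsda_folds": 25,
        "oplsda_orthogonal": 1,
        "lda_folds": 10,
        "lda_variance_kept": 0.95,
        "lda_days": [21, 28],
        "pca_components": 5,
        "seed": 42,
    },
    "screening": {"alpha": 0.05, "model": "model1"},
    "ora": {"library": ""},  # empty → bundled snapshot
}


def merge_config(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a TOML (or YAML) config and merge it over the defaults."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        user = yaml.safe_load(path.read_text()) or {}
    else:
        user = tomllib.loads(path.read_text())
    cfg = merge_config(DEFAULT_CONFIG, user)
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    alpha = cfg["screening"]["alpha"]
    if not 0 < alpha < 1:
        raise ValueError("screening.alpha must be in (0, 1)")
    for name in ("aging_time", "aging_type"):
        scheme_from_config(cfg, name)  # raises on invalid schemes


def scheme_from_config(cfg: dict, name: str) -> BucketScheme:
    block = cfg["preprocess"][name]
    return BucketScheme(
        ppm_lo=float(block["ppm_lo"]),
        ppm_hi=float(block["ppm_hi"]),
        n_buckets=int(block["n_buckets"]),
        exclusions=tuple((float(a), float(b)) for a, b in block.get("exclusions", [])),
        name=name,
    )


def config_hash(cfg: dict) -> str:
    """Stable short hash identifying a configuration."""
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]
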