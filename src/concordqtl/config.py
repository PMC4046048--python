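"""Pipeline configuration: nested YAML with per-stage sections.

Defaults are the full-scale run constants (pi = 0.99, nu = 4.2, 40-marker
windows, top 20 regions, 10-marker status intervals, GQ >= 20, 90%
concordance, >= 5 hom and >= 5 het comparisons); a config file overrides
any subset of them.
"""

from __future__ import annotations

import copy
import hashlib

import yaml

DEFAULTS: dict = {
    "seed": 1,
    "outdir": "concordqtl_out",
    "inputs": {  # real-data path; ignored when a simulate section is present
        "panel_vcf": None,
        "ebv_tsv": None,
        "sequence_vcf": None,
        "pedigree_tsv": None,
        "annotation_tsv": None,
    },
    "deregression": {"h2": 0.3, "weight_form": "literal"},
    "bayesc": {
        "pi": 0.99,
        "nu": 4.2,
        "n_iter": 180_000,
        "burn_in": 20_000,
        "thin": 50,
        "sigma2_a_prior": None,
        "sigma2_e_prior": None,
        "sigma2_u_prior": None,
        "polygenic_enabled": False,
        "use_weights": False,
    },
    "regions": {"L": 40, "K": 20, "maf_min": 0.05, "mode": "sliding"},
    "status": {"interval": 10, "restarts": 10},
    "concordance": {
        "gq_min": 20,
        "fraction_min": 0.90,
        "min_het": 5,
        "min_hom": 5,
        "sweep": True,
    },
    "ld": {"enabled": True, "max_lag": 20},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Merge DEFAULTS <- YAML file <- programmatic overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived by name hashing."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
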