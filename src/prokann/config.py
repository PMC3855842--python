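"""YAML run configuration: defaults, loading and parameter-block parsing."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .consensus import ConsensusParams
from .products import (
    DEFAULT_HYPOTHETICAL_PATTERNS,
    DEFAULT_NAME_CLEANUP_RULES,
    ProductParams,
)

__all__ = ["DEFAULT_CONFIG", "load_config", "consensus_params", "product_params"]

DEFAULT_CONFIG: dict = {
    "consensus": {
        "min_cds_len": 90,
        "start_vote": "majority",
        "orphan_policy": "keep",
        "max_rna_overlap": 0,
        "predictor_priority": [],
    },
    "products": {
        "db_precedence": ["uniprot", "nr", "kegg", "cdd"],
        "max_evalue": 1e-5,
        "min_identity": 30.0,
        "min_query_cov": 0.5,
        "hypothetical_patterns": list(DEFAULT_HYPOTHETICAL_PATTERNS),
        "include_rna_as_functional": False,
    },
    "gbt": {
        "db": "nr",
        "binomial": False,
        "scope": "per_contig",
    },
    "summaries": {
        # core-COG lists are placeholders: swap in a curated list for real use
        "core_cogs_bacteria": ["COG0012", "COG0016", "COG0048", "COG0049", "COG0052"],
        "core_cogs_archaea": ["COG0012", "COG0030", "COG0048", "COG0080", "COG0090"],
        "ko_to_pathways": {},
        "lineage_map": {},
    },
    "enrichment": {
        "method": "bh",
    },
    "benchmark": {
        "offset": 50,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged (deeply) with an optional YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return _merge(DEFAULT_CONFIG, user)


def consensus_params(config: dict) -> ConsensusParams:
    block = config.get("consensus", {})
    return ConsensusParams(
        min_cds_len=block.get("min_cds_len", 90),
        start_vote=block.get("start_vote", "majority"),
        orphan_policy=block.get("orphan_policy", "keep"),
        max_rna_overlap=block.get("max_rna_overlap", 0),
        predictor_priority=tuple(block.get("predictor_priority", [])),
    )


def product_params(config: dict) -> ProductParams:
    block = config.get("products", {})
    return ProductParams(
        db_precedence=tuple(block.get("db_precedence", ["uniprot", "nr", "kegg", "cdd"])),
        max_evalue=block.get("max_evalue", 1e-5),
        min_identity=block.get("min_identity", 30.0),
        min_query_cov=block.get("min_query_cov", 0.5),
        hypothetical_patterns=tuple(
            block.get("hypothetical_patterns", DEFAULT_HYPOTHETICAL_PATTERNS)
        ),
        name_cleanup_rules=DEFAULT_NAME_CLEANUP_RULES,
    )
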