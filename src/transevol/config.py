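"""Central declarative configuration.

``DEFAULTS`` holds every analysis threshold used across the pipeline, set to
the study's published operating points.  A YAML file with the same keys can
override any subset (``load_config``); unknown keys are rejected to catch
typos.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    # assembly / integrity
    "min_contig_length": 250,        # nt, minimum assembled contig length
    "blast_e_max": 1e-5,             # similarity-search significance cutoff
    "integrity_identity_min": 90.0,  # %, strict '>' filter on ortholog pairs
    "full_length_min": 0.8,          # ortholog-hit-ratio cutoff for "full length"
    # differential expression
    "de_fold_change_min": 2.0,       # minimum |weighted-proportion fold change|
    "de_alpha": 0.01,                # Bonferroni-corrected p cutoff
    "de_min_total_count": 10,        # reliability filter defining the tested set
    # enrichment
    "enrich_p_max": 1e-5,
    "enrich_min_observed": 5,        # strict '>' on observed matches
    # clustering
    "n_bootstrap": 1000,
    # mobilome
    "repeat_min_length": 100,        # nt, strict '>' for repeat-library entries
    "te_domain_whitelist": [
        "IPR000477",  # reverse transcriptase
        "IPR023109",  # integrase/recombinase N-terminal
        "IPR001584",  # integrase catalytic core
        "IPR004244",  # transposase
        "IPR002156",  # ribonuclease H domain (retroelement)
        "IPR025724",  # GIY-YIG / TE endonuclease
        "IPR005135",  # endonuclease/exonuclease/phosphatase (non-LTR EN)
    ],
    # gene-family expansion
    "cluster_identity_min": 0.75,    # amino-acid identity for redundancy removal
    "expansion_min_focal_count": 20,
    "expansion_alpha": 0.05,
    # molecular evolution
    "ortholog_e_max": 1e-50,
    "rrt_alpha": 0.05,
    "max_gap_fraction": 0.0,         # column filter: remove any gapped column
    "actinodin_motif": "C[ND]PxxDPxC",
}


def load_config(path: str | Path | None = None) -> dict:
    """Return the default configuration, optionally overridden from YAML."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is None:
        return cfg
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    unknown = set(overrides) - set(cfg)
    if unknown:
        raise KeyError(f"unknown configuration keys: {sorted(unknown)}")
    cfg.update(overrides)
    return cfg
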