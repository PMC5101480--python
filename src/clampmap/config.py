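"""YAML/JSON analysis configuration.

A config file holds everything the readers must never guess: sample
concentrations and molar ratios per titration point, numbering offsets
between constructs and structure files, and analysis thresholds.  Example:

.. code-block:: yaml

    labelled_conc: 10.0          # uM
    dialect: tsv
    points:
      - {ratio: 0.0, path: free.tsv}
      - {ratio: 1.0, path: r1.tsv}
    offsets:
      structure: 0               # structure = peaklist + offset
    thresholds:
      csp: 0.10                  # ppm
      sasa: 45.0                 # %
      jump: 0.15                 # ppm
    weight_N: 0.2
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

DEFAULTS = {
    "dialect": "tsv",
    "weight_N": 0.2,
    "offsets": {"structure": 0},
    "thresholds": {"csp": 0.10, "sasa": 45.0, "jump": 0.15, "pre": 0.7},
}


def load_config(path) -> dict:
    """Load a YAML or JSON config and fill defaulted sections."""
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    merged = {**DEFAULTS, **cfg}
    for key in ("offsets", "thresholds"):
        merged[key] = {**DEFAULTS[key], **(cfg.get(key) or {})}
    return merged
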