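"""Named study-level defaults and YAML config loading.

Every threshold that enters a reported metric is a named key here so a
study run can record exactly which values it used.
"""

from __future__ import annotations

import copy
from typing import Any

import yaml

#: Defaults for every tunable threshold in the analysis chain.
DEFAULTS: dict[str, Any] = {
    # DCE-MRI
    "rsi_threshold": 1.5,          # enhancing iff RSI_1min >= this ratio
    "auc_window_s": 60.0,          # initial-AUC integration window (s)
    # micro-CT morphometry
    "vesselness_scales_um": [9.0, 18.0, 36.0, 72.0],
    "min_component_voxels": 27,    # remove smaller segmented components
    "vc_large_um": 150.0,          # "large vessel" caliber cut (strict >)
    "dnv_far_um": 200.0,           # avascular-distance cut (strict >)
    # histology
    "sma_min_dist_um": 5.0,        # immature iff vessel >= this from α-SMA
    "nucleus_diameter_um": 8.0,    # watershed marker separation basis
    "pec_rule": "centroid",        # or "overlap" (>= 50% pixels in vessel)
    # HSV bands: (hue_lo, hue_hi, sat_lo, sat_hi), hue normalized to [0, 1]
    "stain_bands": {
        "lectin": (0.52, 0.72, 0.25, 1.0),
        "ki67": (0.03, 0.13, 0.30, 1.0),
        "sma": (0.86, 0.98, 0.30, 1.0),
    },
    # spectroscopy
    "line_broadening_hz": 0.3,
    "spectrometer_mhz": 600.0,
    "plsda_region_ppm": (3.0, 3.5),
    "plsda_components": 2,
    "n_permutations": 1000,
    # statistics
    "alpha": 0.05,
    "exact_test_max_n": 12,        # exact Mann-Whitney up to this n_a+n_b
}


def load_config(path: str | None = None,
                overrides: dict[str, Any] | None = None) -> dict[str, Any]:
    """Return the full config: defaults, then YAML file, then overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        unknown = set(loaded) - set(cfg)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(loaded)
    if overrides:
        unknown = set(overrides) - set(cfg)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(overrides)
    return cfg
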