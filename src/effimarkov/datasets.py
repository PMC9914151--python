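"""Packaged study data.

The package ships the published results of the source study as plain-text
fixtures so every downstream stage (state classification, Markov estimation,
trend prediction) can be reproduced without the raw yearbook indicator data,
which are not redistributable:

* the 20-province x 10-year (2010-2019) super-efficiency SBM score panel;
* a first-order land-border contiguity edge list among the 20 in-sample
  provinces (reconstructed; out-of-sample neighbors such as eastern
  provinces are deliberately absent);
* the study's published 4-state transition matrix, spatial-lag-conditioned
  transition matrices, initial distribution, and limiting distributions.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .panels import AdjacencyMap, EfficiencyPanel

#: Frozen checksum of the packaged efficiency panel: sum of all 200 scores.
EFFICIENCY_PANEL_CHECKSUM = 174.504


def _data(name: str):
    return resources.files("effimarkov.data").joinpath(name)


def load_efficiency_panel() -> EfficiencyPanel:
    """The published efficiency score panel: 20 provinces x 2010-2019."""
    with _data("efficiency_panel_2010_2019.csv").open() as fh:
        panel = EfficiencyPanel(pd.read_csv(fh))
    total = float(panel.data["rho"].sum())
    if abs(total - EFFICIENCY_PANEL_CHECKSUM) > 1e-9:
        raise RuntimeError(
            f"packaged efficiency panel corrupted: checksum {total}"
        )
    return panel


def load_contiguity() -> AdjacencyMap:
    """First-order contiguity among the 20 in-sample provinces."""
    with _data("contiguity_20_provinces.csv").open() as fh:
        amap = AdjacencyMap.from_csv(fh)
    return amap


def _reference() -> dict:
    with _data("reference_markov_tables.json").open() as fh:
        return json.load(fh)


def reference_transition_matrix() -> np.ndarray:
    """Published 4x4 one-step transition probability matrix (4 dp)."""
    return np.asarray(_reference()["transition_matrix"], float)


def reference_spatial_matrices() -> dict[int, np.ndarray]:
    """Published lag-conditioned transition matrices, keyed by lag state 1-4."""
    raw = _reference()["spatial_transition_matrices"]
    return {int(k): np.asarray(v, float) for k, v in raw.items()}


def reference_initial_distribution() -> np.ndarray:
    """Published initial 4-state occupancy distribution (2 dp)."""
    return np.asarray(_reference()["initial_distribution"], float)


def reference_limiting_distributions() -> dict[str, np.ndarray]:
    """Published limiting distributions keyed by 'no_lag' and lag state.

    The 'no_lag' and '4' rows do not sum to 1 as published (0.9895 and
    1.0156); they are kept verbatim for comparison but are known to be
    finite-iteration/rounding artifacts (see docs/methods.md).
    """
    raw = _reference()["limiting_distributions"]
    return {k: np.asarray(v, float) for k, v in raw.items()}
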