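"""Channel montage: 64 scalp electrodes (10-10 names) plus 4 EOG channels.

The scalp layout is the 64-channel extended 10-20 arrangement (Biosemi64
naming), which contains the parietal electrodes the analyses reference (Pz,
CP1). Positions come from mne's standard montage and drive the spatial
weighting of simulated components and the region-of-interest (ROI)
definitions: hemisphere by the sign of the x coordinate, anterior/posterior
by the sign of the y coordinate, midline electrodes excluded from ROIs.
"""

from __future__ import annotations

from functools import lru_cache

import mne
import numpy as np

EOG_CHANNELS = ["LHEOG", "RHEOG", "LVEOG", "RVEOG"]

#: Synthetic stand-in map from HydroCel-64 sensor labels to approximate
#: 10-10 names, as a template for real-data ingestion. The true
#: correspondence depends on the net revision and fit; verify against the
#: vendor's position file before relying on it.
EGI64_TO_1010 = {
    "E2": "Fp2", "E9": "Fp1", "E34": "Pz", "E17": "Cz", "E11": "Fz",
    "E24": "C3", "E52": "C4", "E28": "P3", "E47": "P4",
    "E35": "O1", "E39": "O2", "E23": "T7", "E53": "T8",
}


@lru_cache(maxsize=4)
def scalp_montage(name: str = "biosemi64"):
    return mne.channels.make_standard_montage(name)


def scalp_channels(name: str = "biosemi64") -> list[str]:
    return list(scalp_montage(name).ch_names)


def all_channels(name: str = "biosemi64") -> list[str]:
    return scalp_channels(name) + EOG_CHANNELS


def channel_positions(name: str = "biosemi64") -> dict[str, np.ndarray]:
    """Scalp electrode -> 3D head-frame position in meters."""
    pos = scalp_montage(name).get_positions()["ch_pos"]
    return {ch: np.asarray(p, float) for ch, p in pos.items()}


def spatial_weights(center: str, sigma_m: float = 0.06,
                    name: str = "biosemi64") -> np.ndarray:
    """Gaussian spatial falloff from ``center``, 1.0 at the center electrode."""
    pos = channel_positions(name)
    c = pos[center]
    d = np.array([np.linalg.norm(pos[ch] - c) for ch in scalp_channels(name)])
    return np.exp(-(d ** 2) / (2 * sigma_m ** 2))


def roi_membership(name: str = "biosemi64", midline_tol_m: float = 1e-3
                   ) -> dict[str, str]:
    """Electrode -> ROI label among LA/RA/LP/RP; midline electrodes omitted."""
    pos = channel_positions(name)
    rois = {}
    for ch, p in pos.items():
        if abs(p[0]) < midline_tol_m:
            continue
        hemi = "L" if p[0] < 0 else "R"
        ap = "A" if p[1] > 0 else "P"
        rois[ch] = hemi + ap
    return rois


def posterior_channels(name: str = "biosemi64") -> list[str]:
    pos = channel_positions(name)
    return [ch for ch in scalp_channels(name) if pos[ch][1] <= 0]
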