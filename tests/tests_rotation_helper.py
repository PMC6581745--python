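"""Shared helper: a scheme/tensor pair and its jointly rotated copy."""

import numpy as np

from mapboot import synthetic_data as sd
from mapboot.scheme_io import AcquisitionScheme


def _rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


def rotated_pair(D, preset="sparc30", axis=(1, 2, 3), angle=0.9):
    """(scheme, rotated scheme, D, R D R^T) for invariance checks."""
    scheme = sd.preset_scheme(preset, seed=1)
    R = _rotation(axis, angle)
    rscheme = AcquisitionScheme(
        scheme.bvals,
        scheme.bvecs @ R.T,
        scheme.delta_small,
        scheme.delta_big,
        scheme.t_d,
    )
    return scheme, rscheme, np.asarray(D, float), R @ D @ R.T
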