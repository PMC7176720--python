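"""Acquisition and training protocol constants.

These encode the imaging protocols the networks are built around:

- Full SIM acquisition: 3 angles x 5 phases = 15 raw frames; the fast
  variant keeps only the first phase of each angle (3 frames).
- Normal-light protocol: 10 % laser intensity, 200 ms exposure; low-light
  protocol: 1 % intensity, 20 ms exposure.  The expected photon dose scales
  with intensity x exposure.
- SRRF-style restoration: 5 TIRF input frames versus a 200-frame
  radial-fluctuation reference reconstruction.
- Full training from scratch: ~2000 epochs; transfer-learning retraining:
  ~200 epochs on ~200 samples.
"""

from __future__ import annotations

SIM_ANGLES = 3
SIM_PHASES = 5
SIM_FRAMES = SIM_ANGLES * SIM_PHASES       # 15
SIM3_FRAMES = SIM_ANGLES                   # first phase of each angle

NORMAL_LIGHT = {"intensity_fraction": 0.10, "exposure_ms": 200.0}
LOW_LIGHT = {"intensity_fraction": 0.01, "exposure_ms": 20.0}

SRRF_INPUT_FRAMES = 5
SRRF_REFERENCE_FRAMES = 200

FULL_TRAINING_EPOCHS = 2000
TRANSFER_EPOCHS = 200
TRANSFER_SAMPLES = 200


def dose(intensity_fraction: float, exposure_ms: float) -> float:
    """Relative photon dose of a protocol (intensity x exposure)."""
    return intensity_fraction * exposure_ms


def frame_reduction_factor() -> float:
    """How many fewer raw frames the 3-frame variant consumes."""
    return SIM_FRAMES / SIM3_FRAMES


def photon_dose_ratio() -> float:
    """Dose ratio between the normal- and low-light protocols."""
    return dose(**NORMAL_LIGHT) / dose(**LOW_LIGHT)


def srrf_frame_reduction_factor() -> float:
    """Input-frame reduction relative to the radial-fluctuation reference."""
    return SRRF_REFERENCE_FRAMES / SRRF_INPUT_FRAMES


def transfer_effort_ratio() -> float:
    """Retraining epochs as a fraction of full training epochs."""
    return TRANSFER_EPOCHS / FULL_TRAINING_EPOCHS
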