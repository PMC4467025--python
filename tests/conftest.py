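"""Shared fixtures: synthetic localization tables and the session-scoped
simulation runs reused across test modules (they are the expensive inputs)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ssxcorr as sx


def make_uniform_table(
    rng: np.random.Generator,
    box: float,
    n_per_channel: int,
    n_frames: int,
    frame_interval: float = 1.0,
) -> sx.LocalizationTable:
    """Two independent homogeneous-Poisson channels, frames assigned uniformly."""
    parts = []
    for ch in (1, 2):
        parts.append(
            pd.DataFrame(
                {
                    "x": rng.uniform(0, box, n_per_channel),
                    "y": rng.uniform(0, box, n_per_channel),
                    "frame": rng.integers(0, n_frames, n_per_channel),
                    "channel": ch,
                }
            )
        )
    return sx.LocalizationTable(
        pd.concat(parts, ignore_index=True), frame_interval=frame_interval
    )


def square_roi(box: float, pixel_size: float = 100.0) -> sx.ROIMask:
    return sx.make_roi_mask(
        {"type": "rectangle", "bounds": [0, 0, box, box]}, pixel_size=pixel_size
    )


@pytest.fixture(scope="session")
def lj_run() -> sx.LJResult:
    """Full-length Lennard-Jones run (paper configuration, ~1 min)."""
    return sx.lj_simulate(sx.LJConfig(seed=0))


@pytest.fixture(scope="session")
def lj_table(lj_run) -> sx.LocalizationTable:
    """The LJ run observed losslessly (every atom localized every snapshot)."""
    return sx.observe_smlm(lj_run.channel_positions(), sx.BlinkModel(seed=1))


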