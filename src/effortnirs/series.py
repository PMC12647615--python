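"""In-memory containers shared by the forward simulator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ODSeries:
    """Optical-density change, time x channel x wavelength, dimensionless.

    OD is referenced to each channel's mean intensity, so the OD of the
    reference level is 0 by construction.
    """

    od: np.ndarray
    fs: float
    stages: list = field(default_factory=list)  # provenance of applied steps

    def copy(self) -> "ODSeries":
        return ODSeries(self.od.copy(), self.fs, list(self.stages))


@dataclass
class HbSeries:
    """HbO/HbR concentration change in µM, time x channel.

    ``channel_mask`` is True for channels that survived quality control;
    rejected channels keep their data but are flagged, never silently dropped.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    channel_mask: np.ndarray | None = None
    stages: list = field(default_factory=list)

    def __post_init__(self):
        if self.channel_mask is None:
            self.channel_mask = np.ones(self.hbo.shape[1], dtype=bool)

    @property
    def hbdiff(self) -> np.ndarray:
        return self.hbo - self.hbr

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]

    def copy(self) -> "HbSeries":
        return HbSeries(
            self.hbo.copy(), self.hbr.copy(), self.fs, self.channel_mask.copy(), list(self.stages)
        )
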