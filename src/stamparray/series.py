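"""Multi-channel time-lapse container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageSeries:
    """A (time, channel, y, x) intensity stack with channel roles, pixel
    size and acquisition-day stamps."""

    data: np.ndarray
    channel_roles: dict[str, int]
    pixel_size_um: float
    days: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must be (time, channel, y, x)")
        if len(self.days) != self.data.shape[0]:
            raise ValueError("len(days) must equal the time extent")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        idx = list(self.channel_roles.values())
        if len(set(idx)) != len(idx) or any(not 0 <= i < self.data.shape[1] for i in idx):
            raise ValueError("channel role indices must be unique and in range")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel(self, role: str) -> np.ndarray:
        """The (time, y, x) stack for one channel role."""
        if role not in self.channel_roles:
            raise KeyError(f"no channel with role {role!r}; have {sorted(self.channel_roles)}")
        return self.data[:, self.channel_roles[role]]

    def frame(self, role: str, index: int) -> np.ndarray:
        return self.channel(role)[index]
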