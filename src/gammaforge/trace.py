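"""Uniformly sampled signal container.

A :class:`Trace` is the universal input of the pipeline: one channel of an
extracellular field recording (µV) or an intracellular current recording
(pA), sampled at a fixed rate (typically 10 kHz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Trace"]


@dataclass
class Trace:
    """One uniformly sampled channel.

    Parameters
    ----------
    samples
        1-D array of sample values, converted to float64.
    sampling_rate
        Samples per second (Hz); must be positive.
    unit
        Physical unit label of the samples (``"µV"``, ``"pA"``, ``"mV"``).
    name
        Channel name; must be unique within a container.
    metadata
        Free-form annotations (genotype label, condition, epoch notes,
        filter provenance).
    """

    samples: np.ndarray
    sampling_rate: float
    unit: str = "µV"
    name: str = "ch0"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Trace samples must be one-dimensional")
        self.sampling_rate = float(self.sampling_rate)
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not self.unit:
            raise ValueError("unit label is mandatory")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate

    def copy_with(self, samples: np.ndarray, **meta: Any) -> "Trace":
        """Return a new Trace with replaced samples and merged metadata."""
        md = dict(self.metadata)
        md.update(meta)
        return Trace(
            samples=np.asarray(samples, dtype=np.float64),
            sampling_rate=self.sampling_rate,
            unit=self.unit,
            name=self.name,
            metadata=md,
        )
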