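"""Container for one reduced 1-D scattering curve with contrast metadata."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .resolution import ResolutionKernel

__all__ = ["SASDataset"]


@dataclass
class SASDataset:
    """A reduced I(Q) curve.

    q in Å^-1 (strictly increasing), i and sigma_i in cm^-1 (absolute
    scale), plus the resolution description and the contrast metadata the
    simultaneous fit needs: which core (h/d) and solvent the sample had,
    and the fixed computed SLDs for both.
    """

    q: np.ndarray
    i: np.ndarray
    sigma_i: np.ndarray
    resolution: ResolutionKernel = field(default_factory=ResolutionKernel)
    contrast_label: str = ""
    sld_solvent: float = 0.0
    sld_core: float = 0.0
    temperature_c: float = 25.0
    concentration_mg_ml: float = 0.0

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        self.sigma_i = np.asarray(self.sigma_i, dtype=float)
        if not (self.q.shape == self.i.shape == self.sigma_i.shape):
            raise ValueError("q, i, sigma_i must have equal length")
        if self.q.ndim != 1 or len(self.q) == 0:
            raise ValueError("arrays must be non-empty and 1-D")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.sigma_i <= 0):
            raise ValueError("sigma_i must be > 0")

    def __len__(self) -> int:
        return len(self.q)

    def replace(self, **kwargs) -> "SASDataset":
        return replace(self, **kwargs)
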