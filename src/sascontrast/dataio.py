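"""Readers/writers for reduced 1-D scattering curves.

The on-disk format is whitespace-delimited ASCII with 3 or 4 numeric
columns (Q, I, sigma_I[, sigma_Q]) and ``# key: value`` header lines for
metadata.  The canonical Q unit is Å^-1; nm^-1 files are accepted with an
explicit unit flag or header and converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np

from .dataset import SASDataset
from .resolution import ResolutionKernel

__all__ = ["DataFileDialect", "read_dat", "write_dat"]

logger = logging.getLogger(__name__)

_META_FIELDS = {
    "contrast_label": str,
    "sld_solvent": float,
    "sld_core": float,
    "temperature_c": float,
    "concentration_mg_ml": float,
}


@dataclass(frozen=True)
class DataFileDialect:
    """Column and unit conventions of a data file."""

    q_unit: Literal["inverse_angstrom", "inverse_nanometer"] = "inverse_angstrom"
    comment_prefix: str = "#"

    @property
    def q_scale(self) -> float:
        # 1 nm^-1 = 0.1 A^-1
        return 0.1 if self.q_unit == "inverse_nanometer" else 1.0


def read_dat(path: Union[str, Path],
             dialect: Optional[DataFileDialect] = None) -> SASDataset:
    """Read a 3/4-column ASCII curve into a :class:`SASDataset`.

    Header metadata lines of the form ``# key: value`` populate the dataset
    fields (contrast_label, sld_core, ...); a ``# q_unit: ...`` header
    overrides the dialect.  A missing sigma column is imputed as 2% of I
    with a logged warning; a 4th column is read as pointwise sigma_Q.
    """
    path = Path(path)
    dialect = dialect or DataFileDialect()
    meta: dict = {}
    q_unit = None
    rows = []
    with path.open() as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(dialect.comment_prefix):
                body = line.lstrip(dialect.comment_prefix).strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key = key.strip()
                    value = value.strip()
                    if key in _META_FIELDS:
                        meta[key] = _META_FIELDS[key](value)
                    elif key == "q_unit":
                        q_unit = value
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: non-numeric data") from exc
    if len(rows) < 10:
        raise ValueError(f"{path}: need >= 10 data rows, found {len(rows)}")
    ncol = len(rows[0])
    if ncol not in (2, 3, 4) or any(len(r) != ncol for r in rows):
        raise ValueError(f"{path}: expected 3 or 4 numeric columns")
    data = np.asarray(rows, dtype=float)

    if q_unit is not None:
        dialect = DataFileDialect(q_unit=q_unit)  # type: ignore[arg-type]
    q = data[:, 0] * dialect.q_scale
    i = data[:, 1]
    if ncol == 2:
        logger.warning("%s: no sigma column; imputing sigma = 2%% of I", path)
        sigma = 0.02 * np.abs(i)
        sigma[sigma == 0] = 0.02 * np.abs(i[i != 0]).min() if np.any(i != 0) else 1.0
    else:
        sigma = data[:, 2]
    bad = np.flatnonzero(np.diff(q) <= 0)
    if bad.size:
        raise ValueError(f"{path}: q not strictly increasing at row {bad[0] + 2}")
    if ncol == 4:
        resolution = ResolutionKernel(
            "gaussian_pointwise", data[:, 3] * dialect.q_scale
        )
    else:
        resolution = ResolutionKernel("none")
    return SASDataset(q=q, i=i, sigma_i=sigma, resolution=resolution, **meta)


def write_dat(dataset: SASDataset, path: Union[str, Path],
              dialect: Optional[DataFileDialect] = None,
              extra_header: Optional[dict] = None) -> Path:
    """Write a dataset as deterministic fixed-precision ASCII; returns path."""
    from . import __version__

    path = Path(path)
    dialect = dialect or DataFileDialect()
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    scale = 1.0 / dialect.q_scale
    lines = [f"# sascontrast: {__version__}", f"# q_unit: {dialect.q_unit}"]
    for key in _META_FIELDS:
        value = getattr(dataset, key)
        lines.append(f"# {key}: {value}")
    for key, value in (extra_header or {}).items():
        lines.append(f"# {key}: {value}")
    sigma_q = dataset.resolution.sigma_q(dataset.q)
    has_dq = np.any(sigma_q > 0)
    cols = "q i sigma_i" + (" sigma_q" if has_dq else "")
    lines.append(f"# columns: {cols}")
    for j in range(len(dataset)):
        row = f"{dataset.q[j] * scale:.6e} {dataset.i[j]:.6e} {dataset.sigma_i[j]:.6e}"
        if has_dq:
            row += f" {sigma_q[j] * scale:.6e}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")
    return path
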