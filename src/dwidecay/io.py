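"""File-format helpers: NIfTI volumes, b-value tables, YAML configs.

Volumes go through nibabel (NIfTI-1).  The b-value table is a two-column
whitespace-separated text sidecar (b, nsa); an FSL-style ``.bval`` single
row is also accepted, with every NSA defaulting to 1.
"""

from __future__ import annotations

import os
from typing import Optional, Tuple

import nibabel as nib
import numpy as np
import yaml

from .exceptions import InvalidParameterError
from .signal_models import BValueScheme

__all__ = [
    "load_volume",
    "save_volume",
    "read_btable",
    "write_btable",
    "load_yaml",
    "save_yaml",
]


def load_volume(path: str) -> Tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data array, affine)."""
    img = nib.load(path)
    return np.asarray(img.get_fdata()), img.affine


def save_volume(path: str, data: np.ndarray,
                affine: Optional[np.ndarray] = None) -> None:
    """Write an array as NIfTI-1 (identity affine by default)."""
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), path)


def read_btable(path: str, n_directions: int = 3) -> BValueScheme:
    """Read a b-value scheme from a text sidecar.

    Two whitespace-separated columns (b, nsa), one row per b-value; or an
    FSL-style ``.bval`` file (all b-values on one row), in which case every
    NSA defaults to 1.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if line:
                rows.append([float(tok) for tok in line.split()])
    if not rows:
        raise InvalidParameterError(f"empty b-table: {path}")
    if len(rows) == 1 and len(rows[0]) > 2:
        b_values = rows[0]
        nsa = [1] * len(b_values)
    else:
        if any(len(r) not in (1, 2) for r in rows):
            raise InvalidParameterError("b-table rows must be 'b [nsa]'")
        b_values = [r[0] for r in rows]
        nsa = [int(r[1]) if len(r) == 2 else 1 for r in rows]
    return BValueScheme(tuple(b_values), tuple(nsa), n_directions)


def write_btable(path: str, scheme: BValueScheme) -> None:
    """Write the two-column (b, nsa) sidecar."""
    with open(path, "w") as fh:
        fh.write("# b[s/mm2]  nsa\n")
        for b, nsa in zip(scheme.b_values, scheme.nsa):
            fh.write(f"{b:g} {nsa}\n")


def load_yaml(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_yaml(path: str, obj: dict) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
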