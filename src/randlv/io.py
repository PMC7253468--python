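"""Plain-text import/export of interaction matrices.

A matrix is stored as whitespace-delimited dense rows (full float64
precision) with a JSON sidecar ``<file>.json`` carrying the generation
parameters, so a saved draw can be reproduced or re-analysed exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .matrix_gen import GenParams, InteractionMatrix, classify_pairs

__all__ = ["save_matrix", "load_matrix", "sidecar_path"]


def sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def save_matrix(im: InteractionMatrix, path) -> Path:
    """Write the matrix (text) and its parameter sidecar; returns the path."""
    path = Path(path)
    np.savetxt(path, im.A, fmt="%.17g")
    meta = {"n": im.n}
    if im.params is not None:
        meta["params"] = dataclasses.asdict(im.params)
    sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path


def load_matrix(path) -> InteractionMatrix:
    """Read a matrix saved by :func:`save_matrix` (sidecar optional)."""
    path = Path(path)
    A = np.atleast_2d(np.loadtxt(path))
    params = None
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        if "params" in meta:
            params = GenParams(**meta["params"])
    return InteractionMatrix(A=A, params=params, pair_types=classify_pairs(A))
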