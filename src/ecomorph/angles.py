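"""Angular comparison of covariation/allometry vectors in shape space.

Because singular-vector signs are arbitrary, angles are folded to [0°, 90°]
via the absolute cosine.  Under the null that one direction is uniform on
the unit sphere in p dimensions, cos²θ follows Beta(1/2, (p−1)/2); the
reported p-value is the probability that a random pair of directions is at
least this collinear (significantly < 90° means shared directionality).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as sps


@dataclass
class AngleResult:
    angle_degrees: float
    p: float
    dimension: int


def vector_angle(u: np.ndarray, v: np.ndarray) -> AngleResult:
    """Folded angle between two shape-space directions with its Beta-null p."""
    u = np.asarray(u, float).ravel()
    v = np.asarray(v, float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero vector has no direction")
    cos = abs(float(u @ v) / (nu * nv))
    cos = min(cos, 1.0)
    angle = float(np.degrees(np.arccos(cos)))
    p_dim = len(u)
    if p_dim < 2:
        raise ValueError("need at least 2 dimensions")
    pval = float(sps.beta.sf(cos**2, 0.5, (p_dim - 1) / 2.0))
    return AngleResult(angle_degrees=angle, p=max(pval, np.finfo(float).tiny), dimension=p_dim)


def pairwise_angle_table(vectors: dict[str, np.ndarray]) -> pd.DataFrame:
    """All-pairs angle matrix: angles below the diagonal, p-values above."""
    if len(vectors) < 2:
        raise ValueError("need at least 2 vectors")
    labels = list(vectors)
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        res = vector_angle(vectors[a], vectors[b])
        out.loc[b, a] = res.angle_degrees
        out.loc[a, b] = res.p
    return out
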