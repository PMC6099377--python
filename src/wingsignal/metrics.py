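"""Per-patch colour metrics in avian tetrahedral colour space.

Luminance is the double-cone catch. Chromatic position is the proportion of
total single-cone catch per channel, plotted in a regular tetrahedron whose
vertices are the four cone classes; saturation is the Euclidean distance
from the achromatic centre. Hue is an opponent-style ratio channel,
LW / ((UV + SW + MW)/3), which grows with redness; a PCA of the relative
catches across patches is provided to verify that one long-vs-short axis
dominates the ensemble variance.
"""

from __future__ import annotations

import numpy as np

# Regular tetrahedron with centroid at the origin and unit centre-to-vertex
# distance; rows are the UV, SW, MW, LW vertices. Any regular-tetrahedron
# convention differs only by a global scale/rotation, which cannot affect
# correlations or regressions downstream.
TETRA_VERTICES = np.array(
    [
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ]
) / np.sqrt(3.0)


def standardize_catches(q: np.ndarray) -> np.ndarray:
    """Relative catches: each single-cone catch over the sum of the four."""
    q = np.asarray(q, float)
    if q.shape != (4,) or np.any(q < 0):
        raise ValueError("need 4 non-negative single-cone catches")
    total = q.sum()
    if total <= 0:
        raise ValueError("all-zero catch cannot be standardized")
    return q / total


def _check_rel(rel: np.ndarray) -> np.ndarray:
    rel = np.asarray(rel, float)
    if rel.shape != (4,) or np.any(rel < 0) or abs(rel.sum() - 1.0) > 1e-9:
        raise ValueError("relative catches must be 4 non-negative values summing to 1")
    return rel


def tetra_saturation(rel: np.ndarray) -> float:
    """Distance from the achromatic centre of the tetrahedral colour space.

    0 at the centre (equal relative catches), 1 at a vertex (all catch in
    one cone class).
    """
    rel = _check_rel(rel)
    return float(np.linalg.norm(rel @ TETRA_VERTICES))


def hue_channel(rel: np.ndarray) -> float:
    """Opponent-style hue: LW / ((UV + SW + MW)/3) on relative catches.

    1 for achromatic stimuli; larger values mean relatively more
    long-wavelength catch, i.e. redder colours.
    """
    rel = _check_rel(rel)
    u, s, m, l = rel
    denom = (u + s + m) / 3.0
    if denom <= 0:
        raise ValueError("pure-LW stimulus: hue ratio undefined")
    return float(l / denom)


def pca_first_component(rel_table: np.ndarray) -> tuple[np.ndarray, float]:
    """Dominant axis of chromatic variation across an ensemble of patches.

    Eigen-decomposition of the 4x4 covariance matrix of relative catches;
    returns the first eigenvector (sign fixed so the LW loading is >= 0) and
    its share of total variance.
    """
    X = np.asarray(rel_table, float)
    if X.ndim != 2 or X.shape[1] != 4 or X.shape[0] < 3:
        raise ValueError("need an (n >= 3) x 4 table of relative catches")
    cov = np.cov(X, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 1e-14:
        raise ValueError("constant ensemble: zero covariance")
    pc1 = evecs[:, -1]
    if pc1[3] < 0:
        pc1 = -pc1
    return pc1, float(evals[-1] / evals.sum())


def relative_spot_area(spot_areas_mm2, wing_area_mm2: float) -> float:
    """Summed spot area as a proportion of total wing area."""
    if wing_area_mm2 <= 0:
        raise ValueError("wing area must be positive")
    spots = np.asarray(list(spot_areas_mm2), float)
    if spots.size and np.any(spots < 0):
        raise ValueError("spot areas must be non-negative")
    total = float(spots.sum()) if spots.size else 0.0
    if total > wing_area_mm2 * (1 + 1e-12):
        raise ValueError("spots exceed the wing area")
    return total / wing_area_mm2
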