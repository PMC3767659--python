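"""Nest spatial statistics and isolation-by-distance testing."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree


@dataclass
class NearestNeighborResult:
    n: int
    area: float
    boundary_length: float | None
    mean_obs_distance: float
    expected_distance: float
    R: float
    z: float
    p: float
    correction: str  # "none" | "donnelly"


@dataclass
class MantelResult:
    statistic: float
    p: float
    n_perms: int
    method: str = "spearman"


def nearest_neighbor_distances(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(coords)
    d, _ = tree.query(coords, k=2)
    return d[:, 1]


def clark_evans(
    coords: np.ndarray,
    area: float,
    boundary_length: float | None = None,
    correction: str = "donnelly",
) -> NearestNeighborResult:
    """Nearest-neighbour aggregation index R with optional edge correction.

    R = mean observed nearest-neighbour distance / expectation under complete
    spatial randomness.  Uncorrected expectation is 1/(2 sqrt(rho)); the
    Donnelly boundary correction (the refinement recommended for rectangular
    plots) adjusts both the expectation and the variance using the boundary
    length B:

        E(r) = 0.5 sqrt(A/n) + (0.0514 + 0.041/sqrt(n)) B / n
        Var(rbar) = 0.0703 A / n^2 + 0.037 B sqrt(A) / n^(5/2)

    The z statistic compares the observed mean against E(r); p is two-sided
    normal.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 points")
    if area <= 0:
        raise ValueError("area must be positive")
    if correction not in ("none", "donnelly"):
        raise ValueError(f"unknown correction {correction!r}")
    if correction == "donnelly" and boundary_length is None:
        raise ValueError("donnelly correction requires boundary_length")

    nn = nearest_neighbor_distances(coords)
    if (nn == 0).any():
        import warnings

        warnings.warn("coincident points: zero nearest-neighbour distances present")
    mean_obs = float(nn.mean())
    rho = n / area
    if correction == "none":
        expected = 1.0 / (2.0 * math.sqrt(rho))
        se = 0.26136 / math.sqrt(n * rho)
    else:
        B = float(boundary_length)
        expected = 0.5 * math.sqrt(area / n) + (0.0514 + 0.041 / math.sqrt(n)) * B / n
        se = math.sqrt(0.0703 * area / n ** 2 + 0.037 * B * math.sqrt(area) / n ** 2.5)
    z = (mean_obs - expected) / se
    p = float(2 * stats.norm.sf(abs(z)))
    return NearestNeighborResult(
        n=n, area=area, boundary_length=boundary_length, mean_obs_distance=mean_obs,
        expected_distance=expected, R=mean_obs / expected, z=float(z), p=p,
        correction=correction,
    )


# ---------------------------------------------------------------------------
# Isolation by distance
# ---------------------------------------------------------------------------


def ibd_table(
    fst: pd.DataFrame, coords: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Pairs of (F_ST/(1-F_ST), ln distance) for colonies in both inputs.

    Pairs with F_ST = 1 (infinite linearisation) or zero geographic distance
    are excluded and counted in the report dict.
    """
    ids = [c for c in fst.index if c in set(coords["colony"])]
    if len(ids) < 2:
        raise ValueError("fewer than 2 colonies shared between matrices")
    xy = coords.set_index("colony").loc[ids, ["x", "y"]].to_numpy(dtype=float)
    rows = []
    excluded_fst1 = excluded_zero_d = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            f = float(fst.loc[ids[i], ids[j]])
            d = float(np.hypot(*(xy[i] - xy[j])))
            if not np.isfinite(f):
                continue
            if f >= 1.0:
                excluded_fst1 += 1
                continue
            if d <= 0:
                excluded_zero_d += 1
                continue
            rows.append({
                "colony_a": ids[i], "colony_b": ids[j],
                "linearized_fst": f / (1.0 - f), "ln_distance": math.log(d),
                "distance": d, "fst": f,
            })
    report = {"excluded_fst_one": excluded_fst1, "excluded_zero_distance": excluded_zero_d}
    return pd.DataFrame(rows), report


def _lower_triangle(mat: np.ndarray) -> np.ndarray:
    idx = np.tril_indices(mat.shape[0], k=-1)
    return mat[idx]


def mantel_test(
    matrix_a: np.ndarray,
    matrix_b: np.ndarray,
    n_perms: int = 10_000,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test with a Spearman rank statistic over off-diagonal pairs.

    The null distribution comes from simultaneous row/column permutations of
    the second matrix; p is two-tailed with the (hits+1)/(N+1) convention.
    Because the statistic is rank-based it is invariant to monotone
    transforms of either matrix.
    """
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = a.shape[0]
    if n < 4:
        raise ValueError("need at least 4x4 matrices")
    if not (np.allclose(a, a.T, equal_nan=True) and np.allclose(b, b.T, equal_nan=True)):
        raise ValueError("matrices must be symmetric")

    tri_a = _lower_triangle(a)
    tri_b = _lower_triangle(b)
    if np.ptp(tri_a) == 0 or np.ptp(tri_b) == 0:
        raise ValueError("constant matrix: statistic undefined")

    # rank matrices: a simultaneous permutation of rows/cols permutes the
    # multiset of off-diagonal entries, so triangle ranks stay valid
    def rank_matrix(m, tri):
        ranks = stats.rankdata(tri)
        rm = np.zeros_like(m)
        idx = np.tril_indices(n, k=-1)
        rm[idx] = ranks
        rm = rm + rm.T
        return rm

    ra = rank_matrix(a, tri_a)
    rb = rank_matrix(b, tri_b)
    va = _lower_triangle(ra)
    vb = _lower_triangle(rb)

    def pearson(x, y):
        xc = x - x.mean()
        yc = y - y.mean()
        return float((xc * yc).sum() / math.sqrt((xc ** 2).sum() * (yc ** 2).sum()))

    obs = pearson(va, vb)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perms):
        perm = rng.permutation(n)
        vp = _lower_triangle(rb[np.ix_(perm, perm)])
        if abs(pearson(va, vp)) >= abs(obs) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perms + 1)
    return MantelResult(statistic=obs, p=p, n_perms=n_perms)
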