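"""Inter-individual genetic distances (Rousset's â) and geography.

Rousset's â treats each diploid individual as a deme of two genes and, for
every pair, partitions allelic variance between and within those two-gene
demes; the multilocus ratio of sums of the between- and within-components
gives a quantity on the F/(1−F) scale whose regression slope on
ln(distance) estimates 1/(4πDσ²) under two-dimensional isolation by
distance.
"""

from __future__ import annotations

import numpy as np

from .data_io import MISSING, GenotypeTable, SymmetricMatrix

__all__ = ["rousset_ar", "population_centroids", "euclidean_matrix", "log_distance"]


def rousset_ar(table: GenotypeTable) -> SymmetricMatrix:
    """Pairwise â over individuals, multilocus by ratio of sums.

    For one locus and one allele, with the two individuals as 2-gene demes:
    MSB = (p_i − p_j)² (1 df between demes), MSW = (SSW_i + SSW_j)/2
    (2 df within).  â = Σ (MSB − MSW) / Σ (2·MSW), the sums running over
    alleles and loci.  Values may be negative; pairs whose denominator is
    empty (no heterozygosity at any shared locus) are flagged NaN.
    """
    n, L = table.n_samples, table.n_loci
    if n < 2:
        raise ValueError("need at least 2 individuals")
    calls = table.calls

    # Per locus the allele sums collapse: Σ_al (p_i − p_j)² = 2 − h_i/2 −
    # h_j/2 − 2 Σ_al p_i p_j and Σ_al MSW = (h_i + h_j)/2 with h the
    # heterozygosity indicator, so
    #   num_l(i,j) = 2 − h_i − h_j − 2 Σ_al p_i p_j,   den_l(i,j) = h_i + h_j.
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    shared = np.zeros((n, n))
    for l in range(L):
        g = calls[:, :, :][:, l, :]
        valid = g[:, 0] != MISSING
        alleles = np.unique(g[valid])
        k = len(alleles)
        if k == 0:
            continue
        amap = {int(a): i for i, a in enumerate(alleles)}
        X = np.zeros((n, k))
        for i in np.flatnonzero(valid):
            X[i, amap[int(g[i, 0])]] += 0.5
            X[i, amap[int(g[i, 1])]] += 0.5
        h = (valid & (g[:, 0] != g[:, 1])).astype(float)
        v = valid.astype(float)
        A = np.outer(v, v)
        S = X @ X.T
        num += A * 2.0 - A * h[:, None] - A * h[None, :] - 2.0 * S * A
        den += A * (h[:, None] + h[None, :])
        shared += A
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    out[shared == 0] = np.nan
    np.fill_diagonal(out, 0.0)
    out = 0.5 * (out + out.T)
    return SymmetricMatrix(list(table.sample_id), out, "a_r")


def population_centroids(table: GenotypeTable) -> dict[str, tuple[float, float]]:
    """Arithmetic mean coordinate of each population's members (weight 1 each)."""
    if table.coords is None:
        raise ValueError("table has no coordinates")
    out = {}
    for pop in table.populations:
        xy = table.coords[table.pop_indices(pop)]
        xy = xy[~np.isnan(xy).any(axis=1)]
        if len(xy) == 0:
            raise ValueError(f"population {pop} has no coordinates")
        out[pop] = (float(xy[:, 0].mean()), float(xy[:, 1].mean()))
    return out


def euclidean_matrix(points: dict[str, tuple[float, float]]) -> SymmetricMatrix:
    """Straight-line distances (meters) between labelled planar points."""
    labels = list(points)
    xy = np.array([points[l] for l in labels], dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    return SymmetricMatrix(labels, d, "meters")


def log_distance(dist: SymmetricMatrix) -> SymmetricMatrix:
    """Natural log of a distance matrix; zero-distance pairs flagged NaN.

    Coincident points (same trap) are excluded from log-space regressions
    because ln 0 is undefined.
    """
    vals = dist.values.copy()
    off = ~np.eye(len(dist.labels), dtype=bool)
    with np.errstate(divide="ignore"):
        vals[off] = np.where(vals[off] > 0, np.log(vals[off]), np.nan)
    return SymmetricMatrix(dist.labels, vals, f"ln({dist.units})")
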