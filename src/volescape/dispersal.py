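"""Sex-biased dispersal tests and dispersal distance from IBD slopes.

Two complementary approaches:

* randomization tests comparing per-sex differentiation (F_ST) and
  corrected assignment indices (mAIC, vAIC) — the dispersing sex is
  expected to show lower F_ST, negative mean corrected assignment index and
  inflated assignment-index variance;
* Rousset's demographic relation for two-dimensional isolation by distance,
  b = 1/(4πDσ²), inverting the slope b of the â-versus-ln(distance)
  regression into the axial parent–offspring dispersal distance σ given an
  effective density D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_io import MISSING, GenotypeTable
from ._wc import theta_from_components, wc_components

__all__ = ["sexbias_tests", "sigma_from_slope", "assignment_indices",
           "SexBiasReport", "DispersalSigma"]


def assignment_indices(table: GenotypeTable) -> np.ndarray:
    """Corrected assignment index AIc per individual.

    AIc is the log-likelihood (natural log) of an individual's multilocus
    genotype under its own population's allele frequencies, computed
    leave-one-out (the individual's own alleles are removed from the
    counts), with a 1/(2n) floor for alleles unobserved after removal, and
    centred to mean zero within each population.  Loci missing for an
    individual are skipped.
    """
    n = table.n_samples
    ai = np.zeros(n)
    for pop in table.populations:
        idx = table.pop_indices(pop)
        for l in range(table.n_loci):
            g = table.calls[idx, l, :]
            genotyped = g[:, 0] != MISSING
            genes = g[genotyped].ravel()
            vals, cnt = np.unique(genes, return_counts=True)
            counts = dict(zip(vals.tolist(), cnt.tolist()))
            total = int(genes.size)
            for local_i, i in enumerate(idx):
                if not genotyped[local_i]:
                    continue
                a, b = table.calls[i, l]
                n_genes = total - 2
                if n_genes <= 0:
                    continue
                floor = 1.0 / (2 * max(n_genes, 1))
                # leave-one-out counts
                ca = counts.get(int(a), 0) - (2 if a == b else 1)
                cb = counts.get(int(b), 0) - (2 if a == b else 1)
                pa = max(ca / n_genes, floor)
                pb = max(cb / n_genes, floor)
                if a == b:
                    ai[i] += math.log(pa * pa)
                else:
                    ai[i] += math.log(2 * pa * pb)
        # centre within population
        ai[idx] -= ai[idx].mean()
    return ai


@dataclass
class SexBiasReport:
    stats: dict               # {"FST": {"male":…,"female":…,"p":…}, "mAIC": …, "vAIC": …}
    n_perm: int


def _sex_statistics(
    table: GenotypeTable, sex_labels: np.ndarray, which: tuple[str, ...]
) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    ai = assignment_indices(table) if ("mAIC" in which or "vAIC" in which) else None
    for stat in which:
        vals = {}
        for sex in ("male", "female"):
            sel = np.flatnonzero(sex_labels == sex)
            if stat == "FST":
                sub = table.subset(sel)
                vals[sex] = theta_from_components(wc_components(sub))
            elif stat == "mAIC":
                vals[sex] = float(ai[sel].mean())
            elif stat == "vAIC":
                vals[sex] = float(ai[sel].var(ddof=1))
        out[stat] = vals
    return out


def sexbias_tests(
    table: GenotypeTable,
    statistics: tuple[str, ...] = ("FST", "mAIC", "vAIC"),
    n_perm: int = 1000,
    seed: int | None = None,
) -> SexBiasReport:
    """Randomization tests for sex-biased dispersal.

    Observed per-sex statistics are compared with their distribution under
    random reassignment of sex labels within populations (per-population sex
    counts preserved).  p-values are two-sided on the female − male
    difference, with the (x+1)/(n+1) estimator.  Populations containing a
    single sex are excluded with a warning.
    """
    keep = []
    import warnings

    for pop in table.populations:
        idx = table.pop_indices(pop)
        sexes = set(table.sex[idx]) - {"unknown"}
        if len(sexes) < 2:
            warnings.warn(f"population {pop} has one sex only; excluded")
            continue
        keep.extend(int(i) for i in idx if table.sex[i] in ("male", "female"))
    sub = table.subset(np.array(keep))
    if len(set(sub.population)) < 2:
        raise ValueError("need two populations with both sexes")

    obs = _sex_statistics(sub, sub.sex, statistics)
    diffs_obs = {s: obs[s]["female"] - obs[s]["male"] for s in statistics}
    rng = np.random.default_rng(seed)
    hits = {s: 0 for s in statistics}
    sex_labels = np.array(sub.sex, dtype=object)
    for _ in range(n_perm):
        perm_sex = sex_labels.copy()
        for pop in sub.populations:
            idx = sub.pop_indices(pop)
            perm_sex[idx] = rng.permutation(sex_labels[idx])
        stats_p = _sex_statistics(sub, perm_sex, statistics)
        for s in statistics:
            d = stats_p[s]["female"] - stats_p[s]["male"]
            if abs(d) >= abs(diffs_obs[s]) - 1e-12:
                hits[s] += 1
    report = {}
    for s in statistics:
        report[s] = {
            "female": obs[s]["female"],
            "male": obs[s]["male"],
            "difference": diffs_obs[s],
            "p": (hits[s] + 1) / (n_perm + 1),
        }
    return SexBiasReport(stats=report, n_perm=n_perm)


@dataclass
class DispersalSigma:
    slope: float
    density: float                   # individuals per m²
    sigma_m: float                   # meters
    sigma_sq_m2: float
    interval: tuple[float, float] | None = None  # over a density range


def sigma_from_slope(
    b: float,
    D: float,
    density_range: tuple[float, float] | None = None,
) -> DispersalSigma:
    """Axial dispersal distance σ from an IBD slope and effective density.

    Under two-dimensional isolation by distance the slope of â (or
    linearized F_ST) on ln(distance) is b = 1/(4πDσ²), so
    σ = (4πDb)^(−1/2).  ``D`` and ``density_range`` are in individuals per
    m²; σ is returned in meters.  If a density range is given, the
    bracketing σ interval over that range is reported as well.
    """
    if b <= 0:
        raise ValueError("no IBD signal: slope must be positive")
    if D <= 0:
        raise ValueError("density must be positive")
    sigma2 = 1.0 / (4.0 * math.pi * D * b)
    interval = None
    if density_range is not None:
        lo, hi = sorted(density_range)
        s_hi = math.sqrt(1.0 / (4.0 * math.pi * lo * b))
        s_lo = math.sqrt(1.0 / (4.0 * math.pi * hi * b))
        interval = (s_lo, s_hi)
    return DispersalSigma(
        slope=b,
        density=D,
        sigma_m=math.sqrt(sigma2),
        sigma_sq_m2=sigma2,
        interval=interval,
    )
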