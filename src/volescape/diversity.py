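"""Per-population diversity statistics and Hardy–Weinberg testing.

Implements observed heterozygosity, Nei's unbiased expected heterozygosity,
allelic richness by rarefaction, the exact (probability) Hardy–Weinberg test
with complete enumeration or Monte-Carlo evaluation, Fisher's combination of
per-locus HWE p-values, and the Weir–Cockerham inbreeding coefficient f
(F_IS) with a bootstrap-over-loci confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .data_io import MISSING, GenotypeTable
from ._wc import wc_components

__all__ = [
    "observed_heterozygosity",
    "unbiased_expected_heterozygosity",
    "allelic_richness",
    "hwe_exact_test",
    "global_hwe",
    "fis_with_ci",
    "diversity_table",
]


def _per_pop_locus(table: GenotypeTable, fn) -> pd.DataFrame:
    """Apply fn(genotypes ndarray (k,2) without missing) per (pop, locus)."""
    rows = {}
    for pop in table.populations:
        idx = table.pop_indices(pop)
        vals = []
        for l in range(table.n_loci):
            g = table.calls[idx, l, :]
            g = g[g[:, 0] != MISSING]
            vals.append(fn(g) if len(g) else np.nan)
        rows[pop] = vals
    return pd.DataFrame(rows, index=table.locus_names).T


def observed_heterozygosity(table: GenotypeTable) -> pd.DataFrame:
    """H_O per (population, locus): fraction of non-missing calls heterozygous."""
    return _per_pop_locus(table, lambda g: float(np.mean(g[:, 0] != g[:, 1])))


def unbiased_expected_heterozygosity(table: GenotypeTable) -> pd.DataFrame:
    """Nei's unbiased H_E per (population, locus).

    H_E = (2n / (2n − 1)) · (1 − Σ_a p̂_a²) with n genotyped individuals.
    """

    def he(g: np.ndarray) -> float:
        n = len(g)
        genes = g.ravel()
        _, cnt = np.unique(genes, return_counts=True)
        p = cnt / (2 * n)
        return (2 * n) / (2 * n - 1) * (1 - float(np.sum(p**2))) if n > 1 else np.nan

    return _per_pop_locus(table, he)


def allelic_richness(table: GenotypeTable, g: int | None = None) -> pd.DataFrame:
    """Allelic richness rarefied to ``g`` genes per (population, locus).

    AR = Σ_a [1 − C(N−N_a, g) / C(N, g)] where N is the number of genes
    genotyped and N_a the copies of allele a — the expected number of
    distinct alleles in a random subsample of g genes.  The default g is
    twice the smallest per-(population, locus) sample of individuals.
    """
    counts_n = []
    for pop in table.populations:
        idx = table.pop_indices(pop)
        for l in range(table.n_loci):
            gg = table.calls[idx, l, :]
            counts_n.append(int(2 * np.sum(gg[:, 0] != MISSING)))
    n_min = min(counts_n)
    if g is None:
        g = n_min
    if g > n_min:
        # identify the limiting cell for the error message
        for pop in table.populations:
            idx = table.pop_indices(pop)
            for l in range(table.n_loci):
                gg = table.calls[idx, l, :]
                ng = int(2 * np.sum(gg[:, 0] != MISSING))
                if ng < g:
                    raise ValueError(
                        f"g={g} exceeds {ng} genes at ({pop}, {table.locus_names[l]})"
                    )

    def _lchoose(n: np.ndarray, k: int) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        out = np.full(n.shape, -np.inf)
        ok = n >= k
        out[ok] = gammaln(n[ok] + 1) - gammaln(k + 1) - gammaln(n[ok] - k + 1)
        return out

    def ar(geno: np.ndarray) -> float:
        genes = geno.ravel()
        _, cnt = np.unique(genes, return_counts=True)
        N = cnt.sum()
        with np.errstate(over="ignore"):
            frac = np.exp(_lchoose(N - cnt, g) - _lchoose(np.array([N]), g))
        return float(np.sum(1.0 - frac))

    return _per_pop_locus(table, ar)


# ---------------------------------------------------------------------------
# HWE exact (probability) test
# ---------------------------------------------------------------------------

def _log_levene(counts: dict[tuple[int, int], int], allele_counts: np.ndarray) -> float:
    """Log conditional probability of a genotype array given allele counts."""
    n = sum(counts.values())
    n_genes = int(allele_counts.sum())
    h = sum(c for (a, b), c in counts.items() if a != b)
    lp = (
        gammaln(n + 1)
        - sum(gammaln(c + 1) for c in counts.values())
        + h * math.log(2.0)
        + float(np.sum(gammaln(allele_counts + 1)))
        - gammaln(n_genes + 1)
    )
    return lp


def _enumerate_arrays(allele_counts: np.ndarray, max_nodes: int = 2_000_000):
    """All genotype-count arrays consistent with the allele counts.

    Depth-first over unordered genotype categories (a ≤ b), assigning
    genotype counts that exactly consume the remaining gene counts.
    Returns None when the search exceeds ``max_nodes`` visits (the caller
    then falls back to Monte Carlo).
    """
    k = len(allele_counts)
    cats = [(a, b) for a in range(k) for b in range(a, k)]
    # alleles still touchable by categories at index >= ci
    later: list[set[int]] = [set() for _ in range(len(cats) + 1)]
    for ci in range(len(cats) - 1, -1, -1):
        later[ci] = later[ci + 1] | set(cats[ci])
    out: list[dict] = []
    nodes = 0

    def rec(ci: int, remaining: np.ndarray, current: dict) -> bool:
        nonlocal nodes
        nodes += 1
        if nodes > max_nodes:
            return False
        if ci == len(cats):
            if not remaining.any():
                out.append(dict(current))
            return True
        stranded = [x for x in range(k) if remaining[x] > 0 and x not in later[ci]]
        if stranded:
            return True
        a, b = cats[ci]
        max_c = remaining[a] // 2 if a == b else min(remaining[a], remaining[b])
        for c in range(int(max_c), -1, -1):
            rem = remaining.copy()
            if a == b:
                rem[a] -= 2 * c
            else:
                rem[a] -= c
                rem[b] -= c
            if c:
                current[(a, b)] = c
            ok = rec(ci + 1, rem, current)
            current.pop((a, b), None)
            if not ok:
                return False
        return True

    complete = rec(0, allele_counts.astype(int).copy(), {})
    return out if complete else None


def hwe_exact_test(
    table: GenotypeTable,
    pop: str,
    locus: int | str,
    n_steps: int = 100_000,
    seed: int | None = None,
    enumeration_cap: int = 50_000,
) -> float:
    """Exact probability test for Hardy–Weinberg at one (population, locus).

    p = Σ of Levene conditional probabilities of all genotype arrays (with
    the observed allele counts) that are no more probable than the observed
    array.  Complete enumeration when the number of genotype arrays is below
    ``enumeration_cap``; otherwise Monte Carlo by repeatedly shuffling the
    gene vector into random diploid pairings (which samples arrays exactly
    from the Levene distribution).
    """
    if isinstance(locus, str):
        locus = table.locus_names.index(locus)
    idx = table.pop_indices(pop)
    g = table.calls[idx, locus, :]
    g = g[g[:, 0] != MISSING]
    if len(g) < 2:
        return 1.0
    alleles, inv = np.unique(g.ravel(), return_inverse=True)
    if len(alleles) < 2:
        return 1.0
    geno = np.sort(inv.reshape(-1, 2), axis=1)
    obs: dict[tuple[int, int], int] = {}
    for a, b in geno:
        obs[(int(a), int(b))] = obs.get((int(a), int(b)), 0) + 1
    allele_counts = np.bincount(inv, minlength=len(alleles))
    lp_obs = _log_levene(obs, allele_counts)
    tol = 1e-9

    # complete enumeration if feasible
    arrays = _enumerate_arrays(allele_counts, max_nodes=enumeration_cap)
    if arrays is not None and len(arrays) <= enumeration_cap:
        logs = np.array([_log_levene(a, allele_counts) for a in arrays])
        probs = np.exp(logs - logs.max())
        probs /= probs.sum()
        return float(np.sum(probs[logs <= lp_obs + tol]))

    # Monte Carlo: random re-pairings of the gene vector sample genotype
    # arrays exactly from the Levene conditional distribution.  Only the
    # array-dependent part of the log probability is needed for comparison.
    rng = np.random.default_rng(seed)
    k = len(alleles)
    ln2 = math.log(2.0)

    def rel_lp(a: np.ndarray, b: np.ndarray) -> float:
        code = np.minimum(a, b) * k + np.maximum(a, b)
        cnt = np.bincount(code, minlength=k * k)
        h = int(np.sum(a != b))
        return h * ln2 - float(gammaln(cnt + 1).sum())

    lp_obs_rel = rel_lp(geno[:, 0], geno[:, 1])
    genes = inv.copy()
    hits = 0
    for _ in range(n_steps):
        rng.shuffle(genes)
        pairs = genes.reshape(-1, 2)
        if rel_lp(pairs[:, 0], pairs[:, 1]) <= lp_obs_rel + tol:
            hits += 1
    return (hits + 1) / (n_steps + 1)


def global_hwe(
    per_locus_p: dict[str, float],
    excluded_loci: set[str] | None = None,
    chain_length: int = 100_000,
) -> float:
    """Fisher's combination of per-locus HWE p-values for one population.

    χ² = −2 Σ ln p over included loci, df = 2L.  Zero p-values are floored
    at 1/(chain_length + 1).
    """
    excluded_loci = excluded_loci or set()
    ps = [p for l, p in per_locus_p.items() if l not in excluded_loci]
    if not ps:
        raise ValueError("no loci left after exclusion")
    floor = 1.0 / (chain_length + 1)
    ps = [max(p, floor) for p in ps]
    chi2 = -2.0 * sum(math.log(p) for p in ps)
    return float(stats.chi2.sf(chi2, df=2 * len(ps)))


@dataclass
class FisResult:
    f: float
    ci: tuple[float, float] | None
    per_locus: dict[str, float]


def fis_with_ci(
    table: GenotypeTable, n_boot: int = 1000, seed: int | None = None
) -> FisResult:
    """Weir–Cockerham multilocus f (F_IS) with percentile bootstrap over loci."""
    comps = wc_components(table)
    b, c = comps["b"], comps["c"]
    per_locus = {}
    for l, name in enumerate(table.locus_names):
        denom = b[l] + c[l]
        per_locus[name] = float(1.0 - c[l] / denom) if denom > 0 else np.nan
    denom_all = b.sum() + c.sum()
    f = float(1.0 - c.sum() / denom_all) if denom_all > 0 else np.nan
    if table.n_loci < 2 or n_boot < 1:
        return FisResult(f, None, per_locus)
    rng = np.random.default_rng(seed)
    boots = []
    L = table.n_loci
    for _ in range(n_boot):
        pick = rng.integers(0, L, size=L)
        denom = b[pick].sum() + c[pick].sum()
        if denom > 0:
            boots.append(1.0 - c[pick].sum() / denom)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return FisResult(f, (float(lo), float(hi)), per_locus)


def diversity_table(
    table: GenotypeTable,
    rarefaction_g: int | None = None,
    hwe_steps: int = 20_000,
    seed: int | None = None,
    excluded_loci: set[str] | None = None,
) -> pd.DataFrame:
    """Summary per population: N, AR, global HWE p, H_E (unbiased), H_O.

    Mirrors the usual per-population diversity summary; values averaged
    over loci.
    """
    ho = observed_heterozygosity(table)
    he = unbiased_expected_heterozygosity(table)
    ar = allelic_richness(table, rarefaction_g)
    rows = []
    for pop in table.populations:
        per_locus_p = {
            name: hwe_exact_test(table, pop, l, n_steps=hwe_steps, seed=seed)
            for l, name in enumerate(table.locus_names)
        }
        rows.append(
            {
                "population": pop,
                "N": int(len(table.pop_indices(pop))),
                "AR": float(ar.loc[pop].mean()),
                "HWE": global_hwe(per_locus_p, excluded_loci),
                "HE_nb": float(he.loc[pop].mean()),
                "HO": float(ho.loc[pop].mean()),
            }
        )
    return pd.DataFrame(rows).set_index("population")
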