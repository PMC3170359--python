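"""Differentiation statistics: nuclear θ, mitochondrial F_ST, AMOVA/SAMOVA.

Nuclear differentiation uses the Weir–Cockerham variance-components
estimator θ with a bootstrap-over-loci confidence interval and pairwise
values tested by permuting individuals between the two populations.
Mitochondrial differentiation uses the Hudson–Slatkin–Maddison
1 − π_within/π_between estimator on sequence data, plus the standard
calibration F_n = F_mt / (4 − 3·F_mt) that puts a maternally inherited,
quarter-effective-size marker on the nuclear F_ST scale.  AMOVA partitions
molecular variance over a three-level hierarchy, and the SAMOVA search
finds the geographically contiguous grouping of populations that maximizes
the among-group fraction Φ_CT by simulated annealing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .data_io import MISSING, GenotypeTable, HaplotypeAlignment, SymmetricMatrix
from ._wc import f_from_components, theta_from_components, wc_components

__all__ = [
    "wc_fstats",
    "pairwise_fst",
    "linearize_fst",
    "hudson_fst",
    "mito_nuclear_calibrate",
    "sequence_diversity",
    "amova_phi",
    "samova_search",
    "gabriel_graph",
]


# ---------------------------------------------------------------------------
# nuclear F-statistics
# ---------------------------------------------------------------------------

@dataclass
class WcResult:
    theta: float
    f: float
    theta_ci: tuple[float, float] | None
    per_locus_theta: dict[str, float]


def wc_fstats(
    table: GenotypeTable, n_boot: int = 1000, seed: int | None = None
) -> WcResult:
    """Multilocus Weir–Cockerham θ and f, with a bootstrap-over-loci 95% CI for θ."""
    if len(table.populations) < 2:
        raise ValueError("need at least 2 populations")
    comps = wc_components(table)
    a, b, c = comps["a"], comps["b"], comps["c"]
    per_locus = {}
    for l, name in enumerate(table.locus_names):
        denom = a[l] + b[l] + c[l]
        per_locus[name] = float(a[l] / denom) if denom != 0 else np.nan
    theta = theta_from_components(comps)
    f = f_from_components(comps)
    ci = None
    if table.n_loci >= 2 and n_boot > 0:
        rng = np.random.default_rng(seed)
        L = table.n_loci
        boots = []
        for _ in range(n_boot):
            pick = rng.integers(0, L, size=L)
            denom = a[pick].sum() + b[pick].sum() + c[pick].sum()
            if denom != 0:
                boots.append(a[pick].sum() / denom)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (float(lo), float(hi))
    return WcResult(theta, f, ci, per_locus)


def pairwise_fst(
    table: GenotypeTable, n_perm: int = 1000, seed: int | None = None
) -> tuple[SymmetricMatrix, SymmetricMatrix, SymmetricMatrix]:
    """Pairwise θ with one-tailed permutation p and the linearized companion.

    Returns (θ matrix, linearized θ/(1−θ) matrix, p matrix).  Significance
    permutes individuals between the two populations of each pair; the
    p-value uses the (x+1)/(n+1) estimator.  Degenerate pairs (<2
    individuals on a side) are flagged NaN.
    """
    pops = table.populations
    k = len(pops)
    theta_m = np.zeros((k, k))
    lin_m = np.zeros((k, k))
    p_m = np.zeros((k, k))
    rng = np.random.default_rng(seed)
    for i, j in itertools.combinations(range(k), 2):
        idx = np.concatenate([table.pop_indices(pops[i]), table.pop_indices(pops[j])])
        sub = table.subset(idx)
        ni = len(table.pop_indices(pops[i]))
        if ni < 2 or len(idx) - ni < 2:
            theta_m[i, j] = theta_m[j, i] = np.nan
            lin_m[i, j] = lin_m[j, i] = np.nan
            p_m[i, j] = p_m[j, i] = np.nan
            continue
        obs = theta_from_components(wc_components(sub))
        hits = 0
        labels = np.array(sub.population, dtype=object)
        for _ in range(n_perm):
            perm = rng.permutation(len(labels))
            sub.population = labels[perm]
            if theta_from_components(wc_components(sub)) >= obs:
                hits += 1
        sub.population = labels
        p = (hits + 1) / (n_perm + 1)
        theta_m[i, j] = theta_m[j, i] = obs
        lin = linearize_fst(obs) if obs < 1 else np.inf
        lin_m[i, j] = lin_m[j, i] = lin
        p_m[i, j] = p_m[j, i] = p
    return (
        SymmetricMatrix(pops, theta_m, "theta"),
        SymmetricMatrix(pops, lin_m, "theta/(1-theta)"),
        SymmetricMatrix(pops, p_m, "p"),
    )


def linearize_fst(F: float) -> float:
    """F/(1−F) — the linearized differentiation used in IBD regressions."""
    if F >= 1:
        raise ValueError("F must be < 1 to linearize")
    return F / (1.0 - F)


def mito_nuclear_calibrate(F_mt: float) -> float:
    """Put a mitochondrial F_ST on the nuclear scale: F_mt / (4 − 3·F_mt).

    Corrects for the fourfold smaller effective size of a haploid,
    uniparentally inherited marker.  Monotone on [0, 1] with fixed points
    at 0 and 1.
    """
    if not 0 <= F_mt <= 1:
        raise ValueError("F_mt must be in [0, 1]")
    return F_mt / (4.0 - 3.0 * F_mt)


# ---------------------------------------------------------------------------
# sequence statistics
# ---------------------------------------------------------------------------

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_VALID = np.array(list("ACGT"))


def _pairwise_diff_matrix(seqs: np.ndarray) -> np.ndarray:
    """Pairwise nucleotide differences, gaps/N excluded pairwise-complete."""
    n = seqs.shape[0]
    valid = np.isin(seqs, _VALID)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            d[i, j] = d[j, i] = np.sum(seqs[i, ok] != seqs[j, ok])
    return d


@dataclass
class SeqDiversity:
    S: int
    pi: float
    H: float
    h: int
    k: float
    ts_proportion: float
    tv_proportion: float
    n: int


def sequence_diversity(
    alignment: HaplotypeAlignment, by_population: bool = False
):
    """S, π, haplotype diversity H, haplotype count h, mean differences k.

    Haplotype diversity uses the n/(n−1) small-sample correction.  Sites
    containing gaps or N are excluded pairwise-complete for k and π;
    segregating sites are counted on columns restricted to A/C/G/T.
    Transition/transversion proportions classify every non-major allele at
    each segregating site against the site's major allele.
    """
    if by_population:
        return {
            pop: sequence_diversity(
                HaplotypeAlignment(
                    [alignment.ids[i] for i in alignment.pop_indices(pop)],
                    alignment.seqs[alignment.pop_indices(pop)],
                    alignment.population[alignment.pop_indices(pop)],
                )
            )
            for pop in alignment.populations
            if len(alignment.pop_indices(pop)) >= 2
        }

    seqs = alignment.seqs
    n, L = seqs.shape
    if n < 2:
        raise ValueError("need at least 2 sequences")
    valid = np.isin(seqs, _VALID)
    usable_cols = np.flatnonzero(valid.any(axis=0))
    if len(usable_cols) == 0:
        raise ValueError("no usable sites (all gaps/N)")

    S = 0
    ts = tv = 0
    for col in usable_cols:
        states = seqs[valid[:, col], col]
        vals, cnt = np.unique(states, return_counts=True)
        if len(vals) > 1:
            S += 1
            major = vals[np.argmax(cnt)]
            for v, c in zip(vals, cnt):
                if v == major:
                    continue
                same_class = (major in _PURINES and v in _PURINES) or (
                    major in _PYRIMIDINES and v in _PYRIMIDINES
                )
                if same_class:
                    ts += int(c)
                else:
                    tv += int(c)

    d = _pairwise_diff_matrix(seqs)
    iu = np.triu_indices(n, 1)
    k = float(d[iu].mean())
    # per-site π over pairwise-complete sites
    comp = np.zeros(len(iu[0]))
    for m, (i, j) in enumerate(zip(*iu)):
        comp[m] = np.sum(valid[i] & valid[j])
    with np.errstate(invalid="ignore"):
        pi = float(np.nanmean(np.where(comp > 0, d[iu] / comp, np.nan)))

    # haplotypes on the full sequence strings
    haps, inv = np.unique(["".join(s) for s in seqs], return_inverse=True)
    h = len(haps)
    freqs = np.bincount(inv) / n
    H = (n / (n - 1)) * (1 - float(np.sum(freqs**2)))
    tot = ts + tv
    return SeqDiversity(
        S=S,
        pi=pi,
        H=H,
        h=h,
        k=k,
        ts_proportion=ts / tot if tot else np.nan,
        tv_proportion=tv / tot if tot else np.nan,
        n=n,
    )


def hudson_fst(alignment: HaplotypeAlignment) -> tuple[float, SymmetricMatrix]:
    """Hudson–Slatkin–Maddison F_ST = 1 − π_within / π_between on sequences.

    Pairwise: π_within is the unweighted mean of the two within-population
    mean pairwise differences.  Overall: mean within over populations with
    ≥ 2 sequences against the mean over all between-population sequence
    pairs.  Within-population means are taken over all ordered sequence
    pairs including self (the plug-in estimator), so the statistic is
    exactly zero for identical population samples and invariant to
    duplicating every sequence within populations.  Estimates may be
    slightly negative and are reported as computed.
    """
    pops = alignment.populations
    d = _pairwise_diff_matrix(alignment.seqs)
    idx = {p: alignment.pop_indices(p) for p in pops}

    def within(p):
        ii = idx[p]
        if len(ii) < 2:
            return np.nan
        sub = d[np.ix_(ii, ii)]
        return float(sub.mean())  # over all ordered pairs incl. self

    def between(p, q):
        return float(d[np.ix_(idx[p], idx[q])].mean())

    k = len(pops)
    mat = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        wi, wj = within(pops[i]), within(pops[j])
        if math.isnan(wi) or math.isnan(wj):
            mat[i, j] = mat[j, i] = np.nan
            continue
        pw = 0.5 * (wi + wj)
        pb = between(pops[i], pops[j])
        mat[i, j] = mat[j, i] = 1.0 - pw / pb if pb > 0 else np.nan

    wvals = [w for p in pops if not math.isnan(w := within(p))]
    bvals = [between(p, q) for p, q in itertools.combinations(pops, 2)]
    overall = 1.0 - np.mean(wvals) / np.mean(bvals) if np.mean(bvals) > 0 else np.nan
    return float(overall), SymmetricMatrix(pops, mat, "hudson_fst")


# ---------------------------------------------------------------------------
# AMOVA / SAMOVA
# ---------------------------------------------------------------------------

def _genotype_distance_sq(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Squared inter-individual distance = number of allele differences.

    For each locus the contribution is 0 (same unordered genotype), 1 (one
    shared allele) or 2 (no shared allele); missing-locus pairs are skipped.
    """
    n, L = table.n_samples, table.n_loci
    d2 = np.zeros((n, n))
    calls = table.calls
    for i in range(n):
        for j in range(i + 1, n):
            tot = 0
            for l in range(L):
                a = calls[i, l]
                b = calls[j, l]
                if a[0] == MISSING or b[0] == MISSING:
                    continue
                shared = 0
                bb = list(b)
                for x in a:
                    if x in bb:
                        bb.remove(x)
                        shared += 1
                tot += 2 - shared
            d2[i, j] = d2[j, i] = tot
    return d2, np.asarray(table.population, dtype=object)


def _amova_from_d2(
    d2: np.ndarray, pop_of: np.ndarray, grouping: dict[str, int]
) -> tuple[float, float, float]:
    """Three-level AMOVA Φ statistics from a squared-distance matrix."""
    pops = list(dict.fromkeys(pop_of))
    groups = sorted(set(grouping[p] for p in pops))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for Phi_CT")
    N = len(pop_of)
    pop_idx = {p: np.flatnonzero(pop_of == p) for p in pops}
    grp_idx = {
        g: np.concatenate([pop_idx[p] for p in pops if grouping[p] == g])
        for g in groups
    }

    def ss(idx: np.ndarray) -> float:
        if len(idx) < 2:
            return 0.0
        sub = d2[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), 1)
        return float(sub[iu].sum() / len(idx))

    ss_total = ss(np.arange(N))
    ss_wp = sum(ss(pop_idx[p]) for p in pops)
    ss_wg = sum(ss(grp_idx[g]) for g in groups)
    ssd_ag = ss_total - ss_wg
    ssd_ap = ss_wg - ss_wp
    ssd_wp = ss_wp

    P, G = len(pops), len(groups)
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    if df_wp <= 0 or df_ap < 0:
        raise ValueError("degenerate design for AMOVA")
    n_p = np.array([len(pop_idx[p]) for p in pops], dtype=float)
    Ng = {g: sum(len(pop_idx[p]) for p in pops if grouping[p] == g) for g in groups}
    sum_np2_by_g = {
        g: sum(len(pop_idx[p]) ** 2 for p in pops if grouping[p] == g) for g in groups
    }
    n_coef = (n_p.sum() - sum(sum_np2_by_g[g] / Ng[g] for g in groups)) / max(df_ap, 1)
    nprime = (
        sum(sum_np2_by_g[g] / Ng[g] for g in groups) - (n_p**2).sum() / N
    ) / df_ag
    nprime2 = (N - sum(Ng[g] ** 2 for g in groups) / N) / df_ag

    ms_wp = ssd_wp / df_wp
    sigma_c = ms_wp
    if df_ap > 0 and n_coef > 0:
        sigma_b = (ssd_ap / df_ap - sigma_c) / n_coef
    else:
        sigma_b = 0.0
    sigma_a = (ssd_ag / df_ag - sigma_c - nprime * sigma_b) / nprime2
    tot = sigma_a + sigma_b + sigma_c
    phi_ct = sigma_a / tot if tot != 0 else np.nan
    phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else np.nan
    phi_st = (sigma_a + sigma_b) / tot if tot != 0 else np.nan
    return float(phi_ct), float(phi_sc), float(phi_st)


def amova_phi(
    data: GenotypeTable | HaplotypeAlignment, grouping: dict[str, int]
) -> tuple[float, float, float]:
    """Φ_CT, Φ_SC, Φ_ST for a grouping of populations.

    Microsatellite tables use allele-identity squared distances; sequence
    alignments use pairwise nucleotide differences.
    """
    if isinstance(data, GenotypeTable):
        d2, pop_of = _genotype_distance_sq(data)
    else:
        d2 = _pairwise_diff_matrix(data.seqs)
        pop_of = np.asarray(data.population, dtype=object)
    return _amova_from_d2(d2, pop_of, grouping)


def gabriel_graph(coords: dict[str, tuple[float, float]]) -> dict[str, set[str]]:
    """Gabriel neighbour graph: (i,j) adjacent iff no k lies inside the
    circle having segment ij as diameter (d_ij² < d_ik² + d_jk² ∀k)."""
    labels = list(coords)
    xy = np.array([coords[l] for l in labels], dtype=float)
    n = len(labels)
    adj: dict[str, set[str]] = {l: set() for l in labels}
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    for i in range(n):
        for j in range(i + 1, n):
            ok = all(
                d2[i, j] < d2[i, k] + d2[j, k]
                for k in range(n)
                if k != i and k != j
            )
            if ok:
                adj[labels[i]].add(labels[j])
                adj[labels[j]].add(labels[i])
    return adj


def _contiguous(group_pops: list[str], adj: dict[str, set[str]]) -> bool:
    if not group_pops:
        return False
    seen = {group_pops[0]}
    stack = [group_pops[0]]
    gp = set(group_pops)
    while stack:
        u = stack.pop()
        for v in adj[u] & gp:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen == gp


@dataclass
class GroupingResult:
    grouping: dict[str, int]
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_value: float
    restarts: int


def samova_search(
    data: GenotypeTable | HaplotypeAlignment,
    coords: dict[str, tuple[float, float]],
    K: int,
    n_restarts: int = 100,
    n_steps: int = 10_000,
    n_perm: int = 200,
    seed: int | None = None,
    t0: float = 1.0,
    alpha: float = 0.97,
) -> GroupingResult:
    """Simulated-annealing search for the contiguous K-grouping maximizing Φ_CT.

    Contiguity is enforced on the Gabriel graph of population coordinates.
    Moves reassign one population to a neighbouring group, rejected when the
    donor group would empty or disconnect.  The Φ_CT p-value permutes whole
    populations among groups (group sizes fixed).
    """
    pops = (
        data.populations
        if isinstance(data, (GenotypeTable, HaplotypeAlignment))
        else list(coords)
    )
    P = len(pops)
    if not 2 <= K <= P:
        raise ValueError(f"K must be in [2, {P}]")
    if isinstance(data, GenotypeTable):
        d2, pop_of = _genotype_distance_sq(data)
    else:
        d2 = _pairwise_diff_matrix(data.seqs)
        pop_of = np.asarray(data.population, dtype=object)
    adj = gabriel_graph({p: coords[p] for p in pops})
    rng = np.random.default_rng(seed)

    def phi(grouping):
        try:
            return _amova_from_d2(d2, pop_of, grouping)[0]
        except ValueError:
            return -np.inf

    if K == P:
        grouping = {p: i for i, p in enumerate(pops)}
        ct, sc, st = _amova_from_d2(d2, pop_of, grouping)
        return GroupingResult(grouping, ct, sc, st, np.nan, 0)

    def random_contiguous_partition():
        # grow K contiguous groups from K random seeds
        seeds = rng.choice(P, size=K, replace=False)
        grouping = {pops[s]: g for g, s in enumerate(seeds)}
        frontier = list(grouping)
        unassigned = set(pops) - set(grouping)
        while unassigned:
            progressed = False
            for p in list(unassigned):
                nbr_groups = {grouping[q] for q in adj[p] if q in grouping}
                if nbr_groups:
                    grouping[p] = rng.choice(sorted(nbr_groups))
                    unassigned.discard(p)
                    progressed = True
            if not progressed:  # disconnected graph; dump into nearest group
                p = unassigned.pop()
                grouping[p] = int(rng.integers(K))
        return grouping

    best_grouping, best_phi = None, -np.inf
    for _ in range(n_restarts):
        grouping = random_contiguous_partition()
        cur_phi = phi(grouping)
        T = t0
        for _step in range(n_steps):
            p = pops[int(rng.integers(P))]
            g_old = grouping[p]
            donors = [q for q in pops if grouping[q] == g_old]
            if len(donors) == 1:
                T *= alpha
                continue
            nbr_groups = {grouping[q] for q in adj[p]} - {g_old}
            if not nbr_groups:
                T *= alpha
                continue
            g_new = rng.choice(sorted(nbr_groups))
            remaining = [q for q in donors if q != p]
            if not _contiguous(remaining, adj):
                T *= alpha
                continue
            grouping[p] = g_new
            new_phi = phi(grouping)
            dphi = new_phi - cur_phi
            if dphi >= 0 or rng.random() < math.exp(dphi / max(T, 1e-12)):
                cur_phi = new_phi
            else:
                grouping[p] = g_old
            T *= alpha
        if cur_phi > best_phi:
            best_phi, best_grouping = cur_phi, dict(grouping)

    ct, sc, st = _amova_from_d2(d2, pop_of, best_grouping)
    # permutation p for Phi_CT: shuffle populations among groups, sizes fixed
    sizes = [sum(1 for p in pops if best_grouping[p] == g)
             for g in sorted(set(best_grouping.values()))]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pops)
        g_assign = {}
        pos = 0
        for g, s in enumerate(sizes):
            for p in perm[pos:pos + s]:
                g_assign[p] = g
            pos += s
        if phi(g_assign) >= ct:
            hits += 1
    p_val = (hits + 1) / (n_perm + 1)
    return GroupingResult(best_grouping, ct, sc, st, p_val, n_restarts)
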