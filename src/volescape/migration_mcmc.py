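"""Bayesian estimation of contemporary migration rates.

A migrant-ancestry MCMC in the style of multilocus genotype assignment:
each sampled individual of population r is either a non-migrant (t = 0), a
first-generation immigrant from source s (t = 1), or has exactly one
immigrant parent from s (t = 2).  Because at most the last two generations
are modelled, the method assumes neither migration–drift equilibrium nor
Hardy–Weinberg equilibrium; departures from HWE within populations are
absorbed by a per-population inbreeding coefficient F.

Model
-----
* m[r][s] — fraction of population r derived from source s per generation;
  rows are stochastic and the non-migration diagonal is constrained
  m[r][r] ≥ 2/3 (each row's total immigration is at most 1/3).
* Prior: per row the total immigration T = Σ_{s≠r} m[r][s] is uniform on
  [0, 1/3] and is split among sources by a symmetric flat Dirichlet, so the
  diagonal is marginally uniform on [2/3, 1].
* Ancestry prior given m (residence r): P(t=1, s) = m[r][s];
  P(t=2, s) = m[r][r]·m[r][s]·(1 + m[r][r]); P(t=0) = m[r][r]³.  This is the
  exactly normalized two-generation generative model in which a non-migrant
  draws two parents from the row distribution and, when both parents are
  immigrants, one of them is attributed at random.
* Genotype likelihood: for t ∈ {0, 1} the genotype comes from the source
  population's inbreeding-adjusted frequencies, P(aa) = p²(1−F) + pF and
  P(ab) = 2 p q (1−F); for t = 2 one allele comes from the source and one
  from the residence population, with no F term (mixed-ancestry genotypes
  are treated as outbred).
* F_r ~ U[0, 1]; allele frequencies ~ flat Dirichlet per (population, locus).

Sampling is Metropolis-within-Gibbs: ancestries are Gibbs-resampled from
their conditionals; each m row is updated by a reflected random walk on its
total immigration plus a mass transfer between two sources (both uniform in
the (total, composition) parameterization of the prior); F and the allele
frequencies use bounded random walks.  ``prior_only`` disables the
likelihood, so the sampler draws from the prior — the no-information
reference against which posterior intervals are judged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import MISSING, GenotypeTable

__all__ = [
    "run_migration_mcmc",
    "migration_prior_summary",
    "replicate_agreement",
    "MigrationPosterior",
]

MAX_IMMIGRATION = 1.0 / 3.0  # row total immigration bound (diagonal >= 2/3)


@dataclass
class MigrationPosterior:
    populations: list[str]
    mean: np.ndarray              # (P, P) posterior means, rows = into population
    ci_low: np.ndarray            # 2.5% quantiles
    ci_high: np.ndarray           # 97.5% quantiles
    traces: np.ndarray            # (n_samples, P, P), float32
    n_sampled: int
    acceptance: dict = field(default_factory=dict)

    def diagonal_samples(self) -> np.ndarray:
        """Pooled samples of the non-migration (diagonal) rates."""
        P = len(self.populations)
        return self.traces[:, np.arange(P), np.arange(P)].ravel()

    def offdiagonal_samples(self) -> np.ndarray:
        P = len(self.populations)
        off = ~np.eye(P, dtype=bool)
        return self.traces[:, off].ravel()


def _reflect(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    if span <= 0:
        return lo
    y = (x - lo) % (2 * span)
    if y < 0:
        y += 2 * span
    return lo + (span - abs(y - span))


def _ancestry_log_prior_row(m_row: np.ndarray, r: int, counts: dict) -> float:
    """Log ancestry prior of all individuals resident in r, from count sums."""
    mrr = m_row[r]
    if mrr <= 0:
        return -np.inf
    lp = counts["n0"] * 3.0 * math.log(mrr)
    n1, n2 = counts["n1"], counts["n2"]
    for s, c in enumerate(n1):
        if s == r or c == 0:
            continue
        if m_row[s] <= 0:
            return -np.inf
        lp += c * math.log(m_row[s])
    for s, c in enumerate(n2):
        if s == r or c == 0:
            continue
        if m_row[s] <= 0:
            return -np.inf
        lp += c * (math.log(mrr) + math.log(m_row[s]) + math.log1p(mrr))
    return lp


def run_migration_mcmc(
    table: GenotypeTable | None,
    iters: int = 200_000,
    burnin: int = 50_000,
    thin: int = 50,
    seed: int | None = None,
    prior_only: bool = False,
    n_pops: int | None = None,
    step_m: float = 0.05,
    step_f: float = 0.1,
    step_p: float = 0.05,
) -> MigrationPosterior:
    """Run the migrant-ancestry MCMC and return the migration posterior.

    ``iters`` counts total sweeps; states after ``burnin`` are recorded
    every ``thin`` sweeps.  In ``prior_only`` mode the genotype likelihood
    is disabled (``table`` may then be None if ``n_pops`` is given) and the
    sampler draws from the prior.  Matrix orientation: ``mean[r, s]`` is the
    fraction of population r deriving from source s per generation.
    """
    rng = np.random.default_rng(seed)
    if table is not None:
        pops = table.populations
    elif n_pops is not None:
        pops = [f"pop{i + 1}" for i in range(n_pops)]
    else:
        raise ValueError("need a genotype table or n_pops")
    P = len(pops)
    if P < 2:
        raise ValueError("need at least 2 populations")
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")

    # --- initial migration matrix: small immigration, uniform split
    m = np.zeros((P, P))
    T0 = 0.05
    for r in range(P):
        off = [s for s in range(P) if s != r]
        m[r, off] = T0 / (P - 1)
        m[r, r] = 1.0 - T0

    use_lik = not prior_only and table is not None
    if use_lik:
        if any(len(table.pop_indices(p)) < 1 for p in pops):
            raise ValueError("every population needs at least one individual")
        N, L = table.n_samples, table.n_loci
        res_of = np.array([pops.index(p) for p in table.population])
        # allele codes per locus mapped to 0..k-1
        allele_maps = []
        geno_idx = np.zeros((N, L, 2), dtype=np.int64)
        geno_missing = table.missing_mask()
        for l in range(L):
            codes = np.unique(table.calls[:, l, :][~geno_missing[:, l]])
            codes = codes[codes != MISSING]
            amap = {int(c): k for k, c in enumerate(codes)}
            allele_maps.append(amap)
            for i in range(N):
                if not geno_missing[i, l]:
                    geno_idx[i, l, 0] = amap[int(table.calls[i, l, 0])]
                    geno_idx[i, l, 1] = amap[int(table.calls[i, l, 1])]
        n_alleles = [len(a) for a in allele_maps]

        # frequencies initialized from counts + 1 pseudo-count
        freqs = []
        for l in range(L):
            k = n_alleles[l]
            fr = np.ones((P, k))
            for q in range(P):
                idx = table.pop_indices(pops[q])
                genes = geno_idx[idx, l, :][~geno_missing[idx, l]]
                if genes.size:
                    fr[q] += np.bincount(genes.ravel(), minlength=k)
            fr /= fr.sum(axis=1, keepdims=True)
            freqs.append(fr)

        F = np.full(P, 0.1)
        het = geno_idx[:, :, 0] != geno_idx[:, :, 1]

        def locus_c12(l: int) -> tuple[np.ndarray, np.ndarray]:
            """c1, c2 with P(genotype|q,F) = c1 + F_q*c2; shape (N, P)."""
            fr = freqs[l]                      # (P, k)
            pa = fr[:, geno_idx[:, l, 0]].T    # (N, P)
            pb = fr[:, geno_idx[:, l, 1]].T
            hom = ~het[:, l]
            c1 = np.where(hom[:, None], pa * pa, 2 * pa * pb)
            c2 = np.where(hom[:, None], pa * (1 - pa), -2 * pa * pb)
            c1[geno_missing[:, l]] = 1.0
            c2[geno_missing[:, l]] = 0.0
            return c1, c2

        def locus_m2(l: int) -> np.ndarray:
            """P(genotype | source s, residence r_i, t=2); shape (N, P)."""
            fr = freqs[l]
            pa_s = fr[:, geno_idx[:, l, 0]].T      # (N, P) source freq of allele a
            pb_s = fr[:, geno_idx[:, l, 1]].T
            pa_r = fr[res_of, geno_idx[:, l, 0]]   # (N,) residence freq
            pb_r = fr[res_of, geno_idx[:, l, 1]]
            hom = ~het[:, l]
            out = np.where(
                hom[:, None],
                pa_s * pa_r[:, None],
                pa_s * pb_r[:, None] + pb_s * pa_r[:, None],
            )
            out[geno_missing[:, l]] = 1.0
            return out

        C1 = np.stack([locus_c12(l)[0] for l in range(L)], axis=2)  # (N,P,L)
        C2 = np.stack([locus_c12(l)[1] for l in range(L)], axis=2)
        M2 = np.stack([locus_m2(l) for l in range(L)], axis=2)

        # ancestry state: t in {0,1,2}, source
        anc_t = np.zeros(N, dtype=np.int64)
        anc_s = res_of.copy()
        pop_members = [np.flatnonzero(res_of == r) for r in range(P)]
        a_of = geno_idx[:, :, 0]
        b_of = geno_idx[:, :, 1]

    # --- bookkeeping
    n_keep = (iters - burnin) // thin
    traces = np.empty((n_keep, P, P), dtype=np.float32)
    kept = 0
    acc = {"T": [0, 0], "comp": [0, 0], "F": [0, 0], "freq": [0, 0]}

    def ancestry_counts() -> list[dict]:
        out = []
        for r in range(P):
            mem = pop_members[r]
            t = anc_t[mem]
            s = anc_s[mem]
            n1 = np.bincount(s[t == 1], minlength=P)
            n2 = np.bincount(s[t == 2], minlength=P)
            out.append({"n0": int(np.sum(t == 0)), "n1": n1, "n2": n2})
        return out

    for sweep in range(iters):
        # ---- ancestry Gibbs (likelihood mode only)
        if use_lik:
            L0 = (C1 + F[None, :, None] * C2).prod(axis=2)   # (N, P)
            L2 = M2.prod(axis=2)                              # (N, P)
            for r in range(P):
                mem = pop_members[r]
                if mem.size == 0:
                    continue
                mrr = m[r, r]
                w0 = (mrr**3) * L0[mem, r]                    # (n,)
                w1 = m[r][None, :] * L0[mem]                  # (n, P)
                w2 = (mrr * (1 + mrr)) * m[r][None, :] * L2[mem]
                w1[:, r] = 0.0
                w2[:, r] = 0.0
                W = np.concatenate([w0[:, None], w1, w2], axis=1)
                tot = W.sum(axis=1, keepdims=True)
                bad = ~np.isfinite(tot[:, 0]) | (tot[:, 0] <= 0)
                if np.any(bad):
                    raise FloatingPointError("non-finite ancestry weights")
                W /= tot
                u = rng.random(mem.size)
                choice = (W.cumsum(axis=1) < u[:, None]).sum(axis=1)
                t_new = np.zeros(mem.size, dtype=np.int64)
                s_new = np.full(mem.size, r, dtype=np.int64)
                first_gen = (choice >= 1) & (choice <= P)
                second_gen = choice > P
                t_new[first_gen] = 1
                s_new[first_gen] = choice[first_gen] - 1
                t_new[second_gen] = 2
                s_new[second_gen] = choice[second_gen] - 1 - P
                anc_t[mem] = t_new
                anc_s[mem] = s_new
            counts = ancestry_counts()
        else:
            counts = None

        # ---- migration matrix rows
        for r in range(P):
            off = [s for s in range(P) if s != r]
            T = m[r, off].sum()
            # (a) total-immigration update (uniform prior in T)
            T_new = _reflect(T + rng.uniform(-step_m, step_m), 0.0, MAX_IMMIGRATION)
            row_new = m[r].copy()
            if T > 0:
                row_new[off] = m[r, off] * (T_new / T)
            else:
                row_new[off] = T_new / (P - 1)
            row_new[r] = 1.0 - T_new
            acc["T"][1] += 1
            if counts is None:
                m[r] = row_new
                acc["T"][0] += 1
            else:
                d = _ancestry_log_prior_row(row_new, r, counts[r]) - \
                    _ancestry_log_prior_row(m[r], r, counts[r])
                if d >= 0 or rng.random() < math.exp(d):
                    m[r] = row_new
                    acc["T"][0] += 1
            # (b) composition update: transfer mass between two sources
            if P > 2:
                s1, s2 = rng.choice(off, size=2, replace=False)
                tot12 = m[r, s1] + m[r, s2]
                if tot12 > 0:
                    x_new = _reflect(
                        m[r, s1] + rng.uniform(-step_m, step_m) * tot12, 0.0, tot12
                    )
                    row_new = m[r].copy()
                    row_new[s1] = x_new
                    row_new[s2] = tot12 - x_new
                    acc["comp"][1] += 1
                    if counts is None:
                        m[r] = row_new
                        acc["comp"][0] += 1
                    else:
                        d = _ancestry_log_prior_row(row_new, r, counts[r]) - \
                            _ancestry_log_prior_row(m[r], r, counts[r])
                        if d >= 0 or rng.random() < math.exp(d):
                            m[r] = row_new
                            acc["comp"][0] += 1

        # ---- F and allele frequencies (likelihood mode only)
        if use_lik:
            # F: affects t in {0,1} individuals with source q
            src01 = anc_s.copy()
            is01 = anc_t <= 1
            for q in range(P):
                sel = np.flatnonzero(is01 & (src01 == q))
                f_new = _reflect(F[q] + rng.uniform(-step_f, step_f), 0.0, 1.0)
                acc["F"][1] += 1
                if sel.size == 0:
                    F[q] = f_new
                    acc["F"][0] += 1
                    continue
                old = (C1[sel, q, :] + F[q] * C2[sel, q, :]).prod(axis=1)
                new = (C1[sel, q, :] + f_new * C2[sel, q, :]).prod(axis=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    lr = np.log(new).sum() - np.log(old).sum()
                if np.isfinite(lr) and (lr >= 0 or rng.random() < math.exp(lr)):
                    F[q] = f_new
                    acc["F"][0] += 1

            # allele frequencies: one two-allele mass transfer per (q, locus)
            for l in range(L):
                k = n_alleles[l]
                if k < 2:
                    continue
                a_l, b_l = a_of[:, l], b_of[:, l]
                miss_l = geno_missing[:, l]
                hom_l = ~het[:, l]
                fr = freqs[l]
                for q in range(P):
                    a1, a2 = rng.choice(k, size=2, replace=False)
                    tot12 = fr[q, a1] + fr[q, a2]
                    if tot12 <= 0:
                        continue
                    x_new = _reflect(
                        fr[q, a1] + rng.uniform(-step_p, step_p) * tot12, 0.0, tot12
                    )
                    # affected: t<=1 with source q, or t=2 touching q's frequencies
                    sel01 = np.flatnonzero(is01 & (src01 == q) & ~miss_l)
                    sel2 = np.flatnonzero(
                        (anc_t == 2) & ((anc_s == q) | (res_of == q)) & ~miss_l
                    )
                    old_lik = np.concatenate([
                        C1[sel01, q, l] + F[q] * C2[sel01, q, l],
                        M2[sel2, anc_s[sel2], l],
                    ])
                    old_a1, old_a2 = fr[q, a1], fr[q, a2]
                    fr[q, a1], fr[q, a2] = x_new, tot12 - x_new
                    pa01 = fr[q, a_l[sel01]]
                    pb01 = fr[q, b_l[sel01]]
                    lik01 = np.where(
                        hom_l[sel01],
                        pa01 * pa01 + F[q] * (pa01 - pa01 * pa01),
                        2 * pa01 * pb01 * (1 - F[q]),
                    )
                    pa_s = fr[anc_s[sel2], a_l[sel2]]
                    pb_s = fr[anc_s[sel2], b_l[sel2]]
                    pa_r = fr[res_of[sel2], a_l[sel2]]
                    pb_r = fr[res_of[sel2], b_l[sel2]]
                    lik2 = np.where(
                        hom_l[sel2], pa_s * pa_r, pa_s * pb_r + pb_s * pa_r
                    )
                    new_lik = np.concatenate([lik01, lik2])
                    acc["freq"][1] += 1
                    with np.errstate(divide="ignore", invalid="ignore"):
                        lr = np.log(new_lik).sum() - np.log(old_lik).sum()
                    if np.isfinite(lr) and (lr >= 0 or rng.random() < math.exp(lr)):
                        acc["freq"][0] += 1
                        # refresh caches touching population q at this locus
                        pa, pb = fr[q, a_l], fr[q, b_l]
                        C1[:, q, l] = np.where(hom_l, pa * pa, 2 * pa * pb)
                        C2[:, q, l] = np.where(hom_l, pa * (1 - pa), -2 * pa * pb)
                        C1[miss_l, q, l] = 1.0
                        C2[miss_l, q, l] = 0.0
                        par = fr[res_of, a_l]
                        pbr = fr[res_of, b_l]
                        M2[:, q, l] = np.where(
                            hom_l, pa * par, pa * pbr + pb * par
                        )
                        M2[miss_l, q, l] = 1.0
                        rq = pop_members[q]
                        pa_sq = fr[:, a_l[rq]].T
                        pb_sq = fr[:, b_l[rq]].T
                        parq = fr[q, a_l[rq]][:, None]
                        pbrq = fr[q, b_l[rq]][:, None]
                        M2[rq, :, l] = np.where(
                            hom_l[rq][:, None],
                            pa_sq * parq,
                            pa_sq * pbrq + pb_sq * parq,
                        )
                        M2[rq[miss_l[rq]], :, l] = 1.0
                    else:
                        fr[q, a1], fr[q, a2] = old_a1, old_a2

        # ---- record
        assert abs(m.sum(axis=1) - 1.0).max() < 1e-9
        assert m.diagonal().min() >= 2.0 / 3.0 - 1e-9
        if sweep >= burnin and (sweep - burnin) % thin == 0 and kept < n_keep:
            traces[kept] = m
            kept += 1

    traces = traces[:kept]
    mean = traces.mean(axis=0).astype(float)
    lo = np.quantile(traces, 0.025, axis=0).astype(float)
    hi = np.quantile(traces, 0.975, axis=0).astype(float)
    acc_rate = {k: (v[0] / v[1] if v[1] else np.nan) for k, v in acc.items()}
    return MigrationPosterior(pops, mean, lo, hi, traces, kept, acc_rate)


def migration_prior_summary(n_pops: int) -> dict:
    """Analytic no-information summaries of the migration prior.

    Diagonal (non-migration) rate ~ U[2/3, 1]: mean 5/6, quantile q at
    2/3 + q/3.  Per-source migration rate mean (1/6)/(n_pops − 1).
    """
    if n_pops < 2:
        raise ValueError("need at least 2 populations")
    return {
        "diagonal_mean": 5.0 / 6.0,
        "offdiagonal_mean": (1.0 / 6.0) / (n_pops - 1),
        "diagonal_q025": 2.0 / 3.0 + 0.025 / 3.0,
        "diagonal_q975": 2.0 / 3.0 + 0.975 / 3.0,
    }


def replicate_agreement(posteriors: list[MigrationPosterior], flag_at: float = 0.05) -> dict:
    """Between-replicate agreement of posterior mean migration matrices."""
    if len(posteriors) < 2:
        raise ValueError("need at least 2 replicates")
    labels = posteriors[0].populations
    for p in posteriors[1:]:
        if p.populations != labels:
            raise ValueError("replicates have mismatched populations")
    means = np.stack([p.mean for p in posteriors])
    diff = means.max(axis=0) - means.min(axis=0)
    return {
        "max_abs_difference": float(diff.max()),
        "per_cell_difference": diff,
        "flagged": bool(diff.max() > flag_at),
    }
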