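"""Weir–Cockerham (1984) variance components for diploid genotype tables.

Shared backend for θ (F_ST), f (F_IS) and the per-sex differentiation
statistics.  Components are returned per locus, already summed over alleles,
so multilocus estimators are simple ratios of sums.
"""

from __future__ import annotations

import numpy as np

from .data_io import MISSING, GenotypeTable

__all__ = ["wc_components", "theta_from_components", "f_from_components"]


def wc_components(table: GenotypeTable, pops: list[str] | None = None) -> dict:
    """Per-locus a, b, c components summed over alleles.

    a — among populations, b — among individuals within populations,
    c — within individuals.  Populations with fewer than one genotyped
    individual at a locus are dropped for that locus; a locus needs at least
    two contributing populations (otherwise its components are zero).
    """
    pops = pops if pops is not None else table.populations
    L = table.n_loci
    a_out = np.zeros(L)
    b_out = np.zeros(L)
    c_out = np.zeros(L)

    pop_idx = [table.pop_indices(p) for p in pops]
    for l in range(L):
        genos = []
        for idx in pop_idx:
            g = table.calls[idx, l, :]
            g = g[g[:, 0] != MISSING]
            if len(g) >= 1:
                genos.append(g)
        r = len(genos)
        if r < 1:
            continue
        n_i = np.array([len(g) for g in genos], dtype=float)
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        if r >= 2:
            nc = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (r - 1)
            if nc <= 0:
                continue
        alleles = np.unique(np.concatenate([g.ravel() for g in genos]))
        for al in alleles:
            p_i = np.array([np.mean(g == al) for g in genos])
            # frequency of heterozygotes carrying allele al
            h_i = np.array(
                [np.mean((g[:, 0] != g[:, 1]) & np.any(g == al, axis=1)) for g in genos]
            )
            pbar = float(np.sum(n_i * p_i) / n_i.sum())
            hbar = float(np.sum(n_i * h_i) / n_i.sum())
            if r >= 2:
                s2 = float(np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar))
                a = (nbar / nc) * (
                    s2
                    - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
                    / (nbar - 1)
                )
            else:
                # single population: no among-population component; the
                # within-population b and c still define f = F_IS
                s2 = 0.0
                a = 0.0
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2.0
            a_out[l] += a
            b_out[l] += b
            c_out[l] += c
    return {"a": a_out, "b": b_out, "c": c_out}


def theta_from_components(comps: dict) -> float:
    """Multilocus θ = Σa / Σ(a+b+c) (ratio of sums)."""
    a, b, c = comps["a"].sum(), comps["b"].sum(), comps["c"].sum()
    denom = a + b + c
    return float(a / denom) if denom != 0 else np.nan


def f_from_components(comps: dict) -> float:
    """Multilocus f (F_IS) = 1 − Σc / Σ(b+c)."""
    b, c = comps["b"].sum(), comps["c"].sum()
    denom = b + c
    return float(1.0 - c / denom) if denom != 0 else np.nan
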