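"""Diversity and differentiation statistics for diploid SSR data.

Heterozygosities, inbreeding coefficient, hypergeometric rarefied allelic
richness, Nei FST and Jost's D with the Nei & Chesser sample-size
corrections, and principal coordinates analysis of a distance matrix.
Missing genotypes are excluded per locus and per population throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from oakintro.genotype_io import GenotypeMatrix

__all__ = [
    "allele_counts",
    "heterozygosity",
    "fis",
    "allelic_richness",
    "pairwise_fst_nei",
    "overall_fst",
    "jost_dest",
    "pcoa",
    "diversity_report",
]


def allele_counts(G: GenotypeMatrix, locus: int) -> dict[str, np.ndarray]:
    """Per-population allele count vectors (shared allele order) at a locus."""
    sizes, idx = G.allele_index(locus)
    out = {}
    for pop, rows in G.by_population().items():
        sub = idx[rows].reshape(-1)
        sub = sub[sub >= 0]
        out[pop] = np.bincount(sub, minlength=sizes.size)
    return out


def _pop_locus_stats(G: GenotypeMatrix):
    """Yield (pop, locus, n_typed, Ho, sum_p_sq) for every pop x locus cell."""
    pops = G.by_population()
    for l in range(G.n_loci):
        sizes, idx = G.allele_index(l)
        for pop, rows in pops.items():
            sub = idx[rows]
            typed = (sub >= 0).all(axis=1)
            n = int(typed.sum())
            if n == 0:
                yield pop, l, 0, np.nan, np.nan
                continue
            het = (sub[typed, 0] != sub[typed, 1]).mean()
            counts = np.bincount(sub[typed].reshape(-1), minlength=sizes.size)
            p = counts / counts.sum()
            yield pop, l, n, float(het), float((p**2).sum())


def heterozygosity(G: GenotypeMatrix) -> pd.DataFrame:
    """Observed, expected and unbiased expected heterozygosity.

    One row per population x locus with n typed individuals:
    Ho = heterozygote fraction, He = 1 - sum p^2,
    uHe = 2n/(2n-1) * He.
    """
    rows = []
    for pop, l, n, ho, sum_p2 in _pop_locus_stats(G):
        if n == 0:
            rows.append({"pop_id": pop, "locus": G.loci[l], "n": 0, "Ho": np.nan,
                         "He": np.nan, "uHe": np.nan})
            continue
        he = 1.0 - sum_p2
        uhe = he * (2 * n) / (2 * n - 1) if n > 0 else np.nan
        rows.append({"pop_id": pop, "locus": G.loci[l], "n": n, "Ho": ho,
                     "He": he, "uHe": uhe})
    return pd.DataFrame(rows)


def _nei_hs(n: int, ho: float, sum_p2: float) -> float:
    """Unbiased within-population gene diversity (Nei 1987)."""
    if n < 2:
        return np.nan
    return n / (n - 1) * (1.0 - sum_p2 - ho / (2 * n))


def fis(G: GenotypeMatrix) -> pd.Series:
    """Per-population inbreeding coefficient 1 - mean(Ho)/mean(Hs).

    Ho and the unbiased gene diversity Hs are averaged over loci before the
    ratio (basic-stats convention).
    """
    acc: dict[str, list[tuple[float, float]]] = {}
    for pop, _l, n, ho, sum_p2 in _pop_locus_stats(G):
        if n == 0 or np.isnan(ho):
            continue
        hs = _nei_hs(n, ho, sum_p2)
        if not np.isnan(hs):
            acc.setdefault(pop, []).append((ho, hs))
    out = {}
    for pop, vals in acc.items():
        ho_bar = np.mean([v[0] for v in vals])
        hs_bar = np.mean([v[1] for v in vals])
        out[pop] = 1.0 - ho_bar / hs_bar if hs_bar > 0 else np.nan
    return pd.Series(out, name="FIS")


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected allele count in a random subsample of g gene copies.

    AR = sum_i [1 - C(N - N_i, g) / C(N, g)] with N total copies and N_i
    copies of allele i (hypergeometric expectation).
    """
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    N = counts.sum()
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds N={N}")
    with np.errstate(invalid="ignore"):
        log_ratio = _log_comb(N - counts, g) - _log_comb(N, g)
    term = np.where(N - counts >= g, np.exp(log_ratio), 0.0)
    return float((1.0 - term).sum())


def allelic_richness(G: GenotypeMatrix, g: int) -> pd.DataFrame:
    """Rarefied allelic richness per population x locus at g gene copies.

    Cells with fewer than g typed gene copies are NA with a warning.
    """
    rows = []
    for l in range(G.n_loci):
        for pop, counts in allele_counts(G, l).items():
            N = counts.sum()
            if N < g:
                warnings.warn(
                    f"locus {G.loci[l]} pop {pop}: only {N} gene copies < g={g}; AR set to NA",
                    stacklevel=2,
                )
                ar = np.nan
            else:
                ar = rarefied_richness(counts, g)
            rows.append({"pop_id": pop, "locus": G.loci[l], "N_copies": int(N), "AR": ar})
    return pd.DataFrame(rows)


def _fst_components(G: GenotypeMatrix):
    """Per-locus (Hs_hat, Ht_hat) with Nei & Chesser corrections."""
    pops = G.by_population()
    k = len(pops)
    hs_list, ht_list = [], []
    for l in range(G.n_loci):
        sizes, idx = G.allele_index(l)
        if sizes.size == 0:
            raise ValueError(f"locus {G.loci[l]} has no typed alleles")
        ns, hos, pmat = [], [], []
        for rows in pops.values():
            sub = idx[rows]
            typed = (sub >= 0).all(axis=1)
            n = int(typed.sum())
            if n == 0:
                continue
            ns.append(n)
            hos.append((sub[typed, 0] != sub[typed, 1]).mean())
            counts = np.bincount(sub[typed].reshape(-1), minlength=sizes.size)
            pmat.append(counts / counts.sum())
        if len(ns) < k:
            # a population untyped at this locus: skip the locus entirely
            continue
        ns = np.asarray(ns, float)
        pmat = np.asarray(pmat)
        n_harm = len(ns) / (1.0 / ns).sum()
        ho_bar = float(np.mean(hos))
        hs_raw = 1.0 - float(np.mean((pmat**2).sum(axis=1)))
        hs = n_harm / (n_harm - 1) * (hs_raw - ho_bar / (2 * n_harm))
        p_bar = pmat.mean(axis=0)
        ht = 1.0 - float((p_bar**2).sum()) + hs / (n_harm * k) - ho_bar / (2 * n_harm * k)
        hs_list.append(hs)
        ht_list.append(ht)
    if not hs_list:
        raise ValueError("no locus typed in every population")
    return np.asarray(hs_list), np.asarray(ht_list)


def overall_fst(G: GenotypeMatrix) -> float:
    """Multilocus Nei FST = 1 - sum(Hs)/sum(Ht) (ratio of per-locus sums)."""
    hs, ht = _fst_components(G)
    return float(1.0 - hs.sum() / ht.sum())


def pairwise_fst_nei(G: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric matrix of pairwise multilocus Nei FST between populations."""
    pops = list(G.by_population())
    index = G.by_population()
    mat = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            sub = G.subset(np.concatenate([index[pops[i]], index[pops[j]]]))
            mat[i, j] = mat[j, i] = overall_fst(sub)
    return pd.DataFrame(mat, index=pops, columns=pops)


def jost_dest(G: GenotypeMatrix, with_se: bool = False):
    """Jost's D averaged over loci: per locus
    D = (Ht - Hs)/(1 - Hs) * k/(k - 1) with unbiased Hs/Ht."""
    hs, ht = _fst_components(G)
    k = len(G.by_population())
    if k < 2:
        raise ValueError("Jost's D needs at least two populations")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (ht - hs) / (1.0 - hs) * k / (k - 1)
    d = d[np.isfinite(d)]
    mean = float(d.mean())
    if with_se:
        se = float(d.std(ddof=1) / np.sqrt(d.size)) if d.size > 1 else np.nan
        return mean, se
    return mean


def pairwise_jost_dest(G: GenotypeMatrix) -> pd.DataFrame:
    pops = list(G.by_population())
    index = G.by_population()
    mat = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            sub = G.subset(np.concatenate([index[pops[i]], index[pops[j]]]))
            mat[i, j] = mat[j, i] = jost_dest(sub)
    return pd.DataFrame(mat, index=pops, columns=pops)


@dataclass
class PCoAResult:
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    explained: np.ndarray
    n_negative: int


def pcoa(D: np.ndarray) -> PCoAResult:
    """Principal coordinates analysis of a symmetric distance matrix.

    Gower double-centering of -D^2/2 followed by eigendecomposition; axes
    with non-positive eigenvalues are dropped and counted.
    """
    D = np.asarray(D, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    explained = vals[pos] / vals[pos].sum() if pos.any() else np.empty(0)
    return PCoAResult(coords, vals[pos], explained, int((vals < -1e-10).sum()))


def diversity_report(
    G: GenotypeMatrix, groups: dict[str, list[str]], rarefaction_copies: int = 16
) -> pd.DataFrame:
    """Group-level summary table: N, AR_g, Ho, He, FIS, FST, D_EST with
    standard errors over loci (Ho/He/AR) or populations (FIS)."""
    rows = []
    pop_index = G.by_population()
    for group, pop_list in groups.items():
        idx = np.concatenate([pop_index[p] for p in pop_list])
        sub = G.subset(idx)
        het = heterozygosity(sub)
        by_locus = het.groupby("locus", sort=False)[["Ho", "He"]].mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ar = allelic_richness(sub, rarefaction_copies)
        ar_locus = ar.groupby("locus", sort=False)["AR"].mean()
        f = fis(sub)
        nloc = len(by_locus)
        multi_pop = len(pop_list) > 1
        d_mean, d_se = jost_dest(sub, with_se=True) if multi_pop else (np.nan, np.nan)
        rows.append(
            {
                "group": group,
                "N_pop": len(pop_list),
                "N_ind": sub.n_individuals,
                "AR": ar_locus.mean(),
                "AR_se": ar_locus.std(ddof=1) / np.sqrt(nloc),
                "Ho": by_locus["Ho"].mean(),
                "Ho_se": by_locus["Ho"].std(ddof=1) / np.sqrt(nloc),
                "He": by_locus["He"].mean(),
                "He_se": by_locus["He"].std(ddof=1) / np.sqrt(nloc),
                "FIS": f.mean(),
                "FIS_se": f.std(ddof=1) / np.sqrt(len(f)) if len(f) > 1 else np.nan,
                "FST": overall_fst(sub) if multi_pop else np.nan,
                "D_EST": d_mean,
                "D_EST_se": d_se,
            }
        )
    return pd.DataFrame(rows)
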