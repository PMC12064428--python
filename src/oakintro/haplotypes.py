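"""Chloroplast haplotype calling, minimum spanning network and
Pons-Petit diversity/differentiation statistics."""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import mannwhitneyu

logger = logging.getLogger(__name__)

__all__ = [
    "call_haplotypes",
    "stepwise_distance",
    "msn",
    "pons_petit",
    "compare_groups",
]


def call_haplotypes(cp_genotypes: pd.DataFrame, n_loci: int | None = None) -> pd.DataFrame:
    """Label multilocus chloroplast haplotypes.

    Input rows carry ``individual_id``, ``pop_id`` and either a ``haplotype``
    string ("a-b-c-...") or per-locus columns ``cp1..cpN``. Individuals with
    any missing cp locus (sentinel <= 0 or NaN) are excluded and logged.
    Identical allele vectors share a label; labels H1, H2, ... follow
    descending frequency then first appearance.
    """
    frame = cp_genotypes.copy()
    if "haplotype" not in frame.columns:
        cp_cols = [c for c in frame.columns if c.startswith("cp")]
        if n_loci is not None:
            cp_cols = cp_cols[:n_loci]
        if not cp_cols:
            raise ValueError("no haplotype column and no cp* locus columns")
        frame["haplotype"] = frame[cp_cols].apply(
            lambda r: "-".join(str(int(v)) for v in r), axis=1
        )

    def _vector(h):
        try:
            return tuple(int(t) for t in str(h).split("-"))
        except ValueError:
            return None

    frame["_vec"] = frame["haplotype"].map(_vector)
    ok = frame["_vec"].map(lambda v: v is not None and all(a > 0 for a in v))
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("call_haplotypes: excluded %d individuals with missing cp loci", n_excluded)
    frame = frame[ok].copy()
    if frame.empty:
        raise ValueError("no individuals with complete chloroplast genotypes")
    lengths = frame["_vec"].map(len).unique()
    if len(lengths) != 1:
        raise ValueError(f"inconsistent haplotype lengths: {sorted(lengths)}")

    counts = frame["_vec"].value_counts()
    order = sorted(counts.index, key=lambda v: (-counts[v], list(frame["_vec"]).index(v)))
    labels = {vec: f"H{i + 1}" for i, vec in enumerate(order)}
    frame["haplotype_label"] = frame["_vec"].map(labels)
    frame.attrs["n_excluded"] = n_excluded
    return frame.drop(columns="_vec")


def stepwise_distance(a, b, motif_lengths=None) -> float:
    """Sum over loci of |size difference| / motif length (repeat steps)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("haplotype vectors differ in length")
    if motif_lengths is None:
        motif_lengths = np.ones_like(a)
    return float(np.sum(np.abs(a - b) / np.asarray(motif_lengths, float)))


def msn(haplotypes: pd.DataFrame, motif_lengths=None) -> nx.Graph:
    """Minimum spanning network over distinct haplotypes.

    Kruskal MST in which *all* co-minimal ties are retained: an edge of
    weight w joins the network whenever its endpoints are still in different
    components considering only edges of strictly smaller weight. Node
    attributes carry count and frequency.
    """
    vecs: dict[str, tuple] = {}
    counts: dict[str, int] = {}
    for _, row in haplotypes.iterrows():
        lab = row["haplotype_label"]
        vecs[lab] = tuple(int(t) for t in str(row["haplotype"]).split("-"))
        counts[lab] = counts.get(lab, 0) + 1

    labels = sorted(vecs, key=lambda s: int(s[1:]) if s[1:].isdigit() else 0)
    total = sum(counts.values())
    G = nx.Graph()
    for lab in labels:
        G.add_node(lab, count=counts[lab], frequency=counts[lab] / total, alleles=vecs[lab])
    if len(labels) == 1:
        return G

    edges = sorted(
        (
            (stepwise_distance(vecs[u], vecs[v], motif_lengths), u, v)
            for u, v in itertools.combinations(labels, 2)
        ),
        key=lambda e: e[0],
    )
    # group by weight; within a weight class test connectivity against the
    # forest built from strictly smaller weights only (tie edges all kept)
    forest = nx.utils.UnionFind(labels)
    i = 0
    while i < len(edges):
        j = i
        while j < len(edges) and np.isclose(edges[j][0], edges[i][0]):
            j += 1
        tier = edges[i:j]
        added = [(w, u, v) for w, u, v in tier if forest[u] != forest[v]]
        for w, u, v in added:
            G.add_edge(u, v, weight=w)
        for _, u, v in added:
            forest.union(u, v)
        i = j
    return G


def _unbiased_h(counts: np.ndarray) -> float:
    """Unbiased haplotypic diversity n/(n-1) * (1 - sum p^2)."""
    n = counts.sum()
    if n < 2:
        return np.nan
    p = counts / n
    return n / (n - 1) * (1.0 - float((p**2).sum()))


def _pons_petit_point(count_mat: np.ndarray) -> tuple[float, float, float]:
    """(hS, hT, GST) from a populations x haplotypes count matrix."""
    ns = count_mat.sum(axis=1).astype(float)
    k = count_mat.shape[0]
    hk = np.array([_unbiased_h(row) for row in count_mat])
    hs = float(np.nanmean(hk))
    n_harm = k / (1.0 / ns).sum()
    p = count_mat / ns[:, None]
    p_bar = p.mean(axis=0)
    ht = 1.0 - float((p_bar**2).sum()) + hs / (n_harm * k)
    gst = (ht - hs) / ht if ht > 0 else np.nan
    return hs, ht, gst


def pons_petit(haplotypes: pd.DataFrame) -> dict:
    """hS, hT and GST over populations with jackknife standard errors.

    Within-population diversity is the unbiased estimator; total diversity
    carries the small-sample correction via the harmonic-mean sample size.
    Populations with fewer than 2 typed individuals are excluded (warned).
    SEs are delete-one-population jackknife estimates.
    """
    tab = pd.crosstab(haplotypes["pop_id"], haplotypes["haplotype_label"])
    small = tab.sum(axis=1) < 2
    if small.any():
        logger.warning("pons_petit: excluding populations with n<2: %s",
                       list(tab.index[small]))
        tab = tab[~small]
    if len(tab) < 2:
        raise ValueError("need at least two populations with n >= 2")
    mat = tab.to_numpy(float)
    hs, ht, gst = _pons_petit_point(mat)

    # jackknife over populations
    stats = []
    for i in range(mat.shape[0]):
        sub = np.delete(mat, i, axis=0)
        if sub.shape[0] >= 2:
            stats.append(_pons_petit_point(sub))
    stats = np.array(stats, float)
    J = stats.shape[0]
    if J > 1:
        ses = np.sqrt((J - 1) / J * ((stats - stats.mean(axis=0)) ** 2).sum(axis=0))
    else:
        ses = np.full(3, np.nan)

    per_pop = pd.Series(
        [_unbiased_h(row) for row in mat], index=tab.index, name="hS"
    )
    return {
        "hS": hs, "hS_se": float(ses[0]),
        "hT": ht, "hT_se": float(ses[1]),
        "GST": float(gst) if np.isfinite(gst) else np.nan,
        "GST_se": float(ses[2]) if np.isfinite(gst) else np.nan,
        "per_population": per_pop,
    }


def compare_groups(hs_a, hs_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney test between two groups of per-population
    diversities; exact null distribution for small samples, normal
    approximation with tie correction otherwise."""
    a = np.asarray(hs_a, float)
    b = np.asarray(hs_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "asymptotic" if (has_ties or min(a.size, b.size) > 8) else "exact"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
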