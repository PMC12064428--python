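"""Bayesian admixture inference for diploid multilocus genotypes.

A collapsed-free Gibbs sampler over (gene-copy cluster assignments, cluster
allele frequencies, individual membership vectors q), with optional
population-location prior, plus the machinery around replicate runs:
deviance-based lnP(X|K) estimation, label alignment across runs, clustering
of runs into modes, and the population-assignment count metrics used to
choose K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from oakintro.genotype_io import GenotypeMatrix

__all__ = [
    "RunResult",
    "ModeGroup",
    "fit_admixture",
    "estimate_lnP",
    "align_runs",
    "similarity_score",
    "detect_modes",
    "puechmaille_metrics",
    "evaluate_K",
]


@dataclass
class RunResult:
    q: np.ndarray  # (n, K), rows sum to 1
    loglik_trace: np.ndarray  # post-burn-in, thinned
    lnP: float
    seed: int
    K: int
    flags: list[str] = field(default_factory=list)


@dataclass
class ModeGroup:
    member_runs: list[int]
    mean_q: np.ndarray
    similarity: float


def _recode(G: GenotypeMatrix):
    """Dense allele indices (n, L, 2) with -1 missing, plus per-locus counts."""
    n, L = G.n_individuals, G.n_loci
    n_alleles = np.empty(L, dtype=np.int64)
    idx = np.empty((n, L, 2), dtype=np.int64)
    for l in range(L):
        sizes, code = G.allele_index(l)
        if sizes.size == 0:
            raise ValueError(f"locus {G.loci[l]} has no typed alleles")
        n_alleles[l] = sizes.size
        idx[:, l, :] = code
    return idx, n_alleles


def _sample_dirichlet_rows(rng, conc: np.ndarray) -> np.ndarray:
    """Row-wise Dirichlet draws via gamma variates (vectorized)."""
    g = rng.gamma(np.maximum(conc, 1e-12))
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=-1, keepdims=True)


def fit_admixture(
    G: GenotypeMatrix,
    K: int,
    burnin: int = 2000,
    iters: int = 4000,
    thin: int = 10,
    prior_model: str = "independent",
    locprior_pops=None,
    seed: int = 0,
    alpha: float = 1.0,
    update_alpha: bool = True,
    drift_F: float = 0.05,
) -> RunResult:
    """Gibbs sampler for the admixture model.

    Sweeps alternate (i) gene-copy cluster assignments given q and the
    frequencies, (ii) Dirichlet-conjugate frequency updates given the
    assignment counts, (iii) per-individual q from Dirichlet(alpha + counts).
    With ``update_alpha`` (the default, mirroring common practice) the
    symmetric admixture concentration gets a log-scale Metropolis update
    each sweep under a uniform prior on (0, 10]. Missing gene copies are
    skipped. ``prior_model='correlated'`` shrinks
    frequencies towards the pooled empirical frequencies with strength
    (1-F)/F instead of a flat prior. ``locprior_pops`` (parallel pop labels)
    replaces the flat q prior with a population-level Dirichlet mean updated
    each sweep — an approximation of the location-aware prior.

    The reported q is the posterior mean over thinned post-burn-in sweeps;
    ``lnP`` is the mean-minus-half-variance estimator on the log-likelihood
    trace.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if burnin <= 0 or iters <= 0:
        raise ValueError("burnin and iters must be positive")
    if prior_model not in ("independent", "correlated"):
        raise ValueError(f"unknown prior_model {prior_model!r}")

    rng = np.random.default_rng(seed)
    idx, n_alleles = _recode(G)
    n, L = G.n_individuals, G.n_loci
    A = int(n_alleles.max())
    valid = idx >= 0  # (n, L, 2)
    flags: list[str] = []
    if (n_alleles == 1).all() and K > 1:
        flags.append("monomorphic dataset with K > 1")

    if K == 1:
        q = np.ones((n, 1))
        # likelihood under pooled frequencies; constant trace
        ll = _loglik(idx, valid, q, _empirical_freqs(idx, valid, n_alleles, A)[None])
        trace = np.full(max(iters // max(thin, 1), 2), ll)
        return RunResult(q, trace, estimate_lnP(trace), seed, 1, flags)

    # frequency prior
    lam = np.zeros((L, A))
    for l in range(L):
        lam[l, : n_alleles[l]] = 1.0
    if prior_model == "correlated":
        emp = _empirical_freqs(idx, valid, n_alleles, A)
        lam = emp * (1.0 - drift_F) / drift_F
        lam[emp == 0] = 0.0

    pop_codes = None
    if locprior_pops is not None:
        labels = {p: i for i, p in enumerate(dict.fromkeys(locprior_pops))}
        pop_codes = np.array([labels[p] for p in locprior_pops])
        n_pops = len(labels)

    # init
    q = rng.dirichlet(np.full(K, alpha), size=n)
    p = _sample_dirichlet_rows(rng, np.broadcast_to(lam, (K, L, A)).copy())

    ii, ll_, cc = np.nonzero(valid)
    flat_i, flat_l, flat_a = ii, ll_, idx[ii, ll_, cc]

    total = burnin + iters
    q_sum = np.zeros((n, K))
    n_kept = 0
    trace = []
    for sweep in range(total):
        # (i) assignment probabilities for every valid gene copy
        pa = p[:, flat_l, flat_a]  # (K, m)
        w = (q[flat_i].T * pa).T  # (m, K)
        w_sum = w.sum(axis=1, keepdims=True)
        np.maximum(w_sum, 1e-300, out=w_sum)
        w /= w_sum
        u = rng.random(w.shape[0])
        z = (u[:, None] > np.cumsum(w, axis=1)).sum(axis=1)
        np.clip(z, 0, K - 1, out=z)

        # (ii) frequency update
        counts = np.zeros((K, L, A))
        np.add.at(counts, (z, flat_l, flat_a), 1.0)
        conc = lam[None] + counts
        p = _sample_dirichlet_rows(rng, conc)
        # zero out padding / unsupported alleles
        p[conc == 0] = 0.0
        p /= p.sum(axis=-1, keepdims=True)

        # (iii) q update
        n_ik = np.zeros((n, K))
        np.add.at(n_ik, (flat_i, z), 1.0)
        if pop_codes is None:
            q = _sample_dirichlet_rows(rng, alpha + n_ik)
            if update_alpha:
                alpha = _metropolis_alpha(rng, alpha, q, K)
        else:
            # population-mean prior: eta_p ~ Dir(1 + pop assignment counts),
            # q_i ~ Dir(alpha * K * eta_p + counts)
            pop_counts = np.zeros((n_pops, K))
            np.add.at(pop_counts, (pop_codes[flat_i], z), 1.0)
            eta = _sample_dirichlet_rows(rng, 1.0 + pop_counts)
            q = _sample_dirichlet_rows(rng, alpha * K * eta[pop_codes] + n_ik)

        if sweep >= burnin and (sweep - burnin) % thin == 0:
            trace.append(_loglik(idx, valid, q, p))
            q_sum += q
            n_kept += 1

    q_mean = q_sum / n_kept
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    trace = np.asarray(trace)
    return RunResult(q_mean, trace, estimate_lnP(trace), seed, K, flags)


ALPHA_MAX = 10.0


def _metropolis_alpha(rng, alpha, q, K, step=0.3):
    """Log-scale random-walk update of the symmetric Dirichlet concentration
    of the q prior, uniform prior on (0, ALPHA_MAX]."""
    from scipy.special import gammaln as _gl

    prop = alpha * np.exp(step * rng.standard_normal())
    if not 0 < prop <= ALPHA_MAX:
        return alpha
    n = q.shape[0]
    sum_log_q = np.log(np.maximum(q, 1e-300)).sum()

    def logpost(a):
        return n * (_gl(K * a) - K * _gl(a)) + (a - 1.0) * sum_log_q

    # Jacobian of the log-scale proposal: + log(prop/alpha)
    log_accept = logpost(prop) - logpost(alpha) + np.log(prop / alpha)
    if np.log(rng.random()) < log_accept:
        return prop
    return alpha


def _empirical_freqs(idx, valid, n_alleles, A):
    L = n_alleles.size
    freqs = np.zeros((L, A))
    for l in range(L):
        a = idx[:, l, :][valid[:, l, :]]
        counts = np.bincount(a, minlength=A).astype(float)
        freqs[l] = counts / counts.sum()
    return freqs


def _loglik(idx, valid, q, p) -> float:
    """log P(X | q, p) summed over valid gene copies."""
    ii, ll_, cc = np.nonzero(valid)
    pa = p[:, ll_, idx[ii, ll_, cc]]  # (K, m)
    mix = np.einsum("mk,km->m", q[ii], pa)
    return float(np.log(np.maximum(mix, 1e-300)).sum())


def estimate_lnP(loglik_trace) -> float:
    """mean(trace) - var(trace)/2, the deviance-based evidence estimator.

    Variance is the sample variance (ddof=1), so {0, 2} -> 1 - 2/2 = 0.
    """
    t = np.asarray(loglik_trace, float)
    if t.size < 2:
        raise ValueError("trace must have length >= 2")
    return float(t.mean() - t.var(ddof=1) / 2.0)


def _match_permutation(Q: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Permutation sigma maximizing sum_i sum_k Q[i, sigma[k]] * ref[i, k]."""
    score = Q.T @ ref  # (K, K): score[j, k] = agreement of run col j with ref col k
    _row, col = linear_sum_assignment(-score.T)
    return col  # col[k] = run column assigned to reference column k


def align_runs(runs: list[RunResult]) -> tuple[list[RunResult], list[np.ndarray]]:
    """Permute cluster labels of each run to a common labelling.

    The reference starts as the first run's q and is refined incrementally
    with the mean of the runs aligned so far; each match solves the
    assignment problem exactly.
    """
    if not runs:
        return [], []
    K = runs[0].K
    n = runs[0].q.shape[0]
    for r in runs:
        if r.K != K or r.q.shape[0] != n:
            raise ValueError("all runs must share K and individuals")
    ref = runs[0].q.copy()
    aligned, perms = [], []
    for i, run in enumerate(runs):
        perm = _match_permutation(run.q, ref)
        q_new = run.q[:, perm]
        aligned.append(RunResult(q_new, run.loglik_trace, run.lnP, run.seed, run.K, run.flags))
        perms.append(perm)
        ref = (ref * i + q_new) / (i + 1) if i else q_new
    return aligned, perms


def similarity_score(q_a: np.ndarray, q_b: np.ndarray) -> float:
    """G' = 1 - ||Qa - Qb||_F / sqrt(2 n); 1 for identical matrices."""
    q_a = np.asarray(q_a, float)
    q_b = np.asarray(q_b, float)
    if q_a.shape != q_b.shape:
        raise ValueError("q matrices must have identical shape")
    n = q_a.shape[0]
    return float(1.0 - np.linalg.norm(q_a - q_b) / np.sqrt(2.0 * n))


def detect_modes(aligned_runs: list[RunResult], threshold: float = 0.9) -> list[ModeGroup]:
    """Group aligned runs by single linkage on pairwise similarity.

    Runs join one mode whenever some pair between the groups scores at or
    above ``threshold``. Modes are ordered by size (major mode first).
    """
    m = len(aligned_runs)
    if m == 0:
        return []
    sim = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            sim[i, j] = sim[j, i] = similarity_score(aligned_runs[i].q, aligned_runs[j].q)
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(m):
        for j in range(i + 1, m):
            if sim[i, j] >= threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(i)
    modes = []
    for members in groups.values():
        mean_q = np.mean([aligned_runs[i].q for i in members], axis=0)
        if len(members) > 1:
            pair_scores = [sim[i, j] for a, i in enumerate(members) for j in members[a + 1:]]
            mean_sim = float(np.mean(pair_scores))
        else:
            mean_sim = 1.0
        modes.append(ModeGroup(members, mean_q, mean_sim))
    modes.sort(key=lambda g: (-len(g.member_runs), g.member_runs))
    return modes


def puechmaille_metrics(
    runs: list[RunResult], pop_ids, threshold: float = 0.5
) -> dict[str, float]:
    """Population-assignment cluster counts across replicate runs.

    Per run, population-level q is summarized two ways (median and mean of
    member individuals' q per cluster); the per-run statistic is the number
    of clusters with at least one population at or above ``threshold``.
    MedMedK/MedMeanK are medians of that count across runs, MaxMedK/
    MaxMeanK the maxima.
    """
    pop_ids = [str(p) for p in pop_ids]
    pops: dict[str, list[int]] = {}
    for i, p in enumerate(pop_ids):
        pops.setdefault(p, []).append(i)
    if not pops or any(len(v) == 0 for v in pops.values()):
        raise ValueError("empty population")

    counts_med, counts_mean = [], []
    for run in runs:
        med = np.array([np.median(run.q[rows], axis=0) for rows in pops.values()])
        mean = np.array([np.mean(run.q[rows], axis=0) for rows in pops.values()])
        counts_med.append(int(((med >= threshold).any(axis=0)).sum()))
        counts_mean.append(int(((mean >= threshold).any(axis=0)).sum()))
    return {
        "MedMedK": float(np.median(counts_med)),
        "MedMeanK": float(np.median(counts_mean)),
        "MaxMedK": float(np.max(counts_med)),
        "MaxMeanK": float(np.max(counts_mean)),
    }


METRIC_NAMES = ("MedMedK", "MedMeanK", "MaxMedK", "MaxMeanK")


def evaluate_K(
    runs_by_K: dict[int, list[RunResult]],
    pop_ids,
    similarity_threshold: float = 0.9,
    q_threshold: float = 0.5,
) -> dict:
    """Per-K report for the two-criterion selection rule.

    criterion 1: at least one assignment-count metric increased vs K-1;
    criterion 2: replicate runs are non-conflicting (a single mode, or the
    major mode internally coherent and all mode means mutually similar).
    Returns per-K entries and the largest K passing both.
    """
    ks = sorted(runs_by_K)
    report: dict[int, dict] = {}
    prev_metrics = None
    for K in ks:
        runs = runs_by_K[K]
        aligned, _ = align_runs(runs)
        metrics = puechmaille_metrics(aligned, pop_ids, q_threshold)
        modes = detect_modes(aligned, similarity_threshold)
        if prev_metrics is None:
            crit1 = True
        else:
            crit1 = any(metrics[m] > prev_metrics[m] for m in METRIC_NAMES)
        conflict = modes[0].similarity < similarity_threshold
        for a in range(len(modes)):
            for b in range(a + 1, len(modes)):
                if similarity_score(modes[a].mean_q, modes[b].mean_q) < similarity_threshold:
                    conflict = True
        crit2 = not conflict
        lnp = [r.lnP for r in runs]
        report[K] = {
            "metrics": metrics,
            "n_modes": len(modes),
            "modes": modes,
            "criterion1": crit1,
            "criterion2": crit2,
            "lnP_mean": float(np.mean(lnp)),
            "lnP_sd": float(np.std(lnp, ddof=1)) if len(lnp) > 1 else 0.0,
        }
        prev_metrics = metrics
    passing = [K for K in ks if report[K]["criterion1"] and report[K]["criterion2"]]
    if not passing:
        warnings.warn("no K passes both criteria", stacklevel=2)
    return {"per_K": report, "selected_K": max(passing) if passing else None}
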