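"""Synthetic SSR dataset generator with known ground truth.

Generates diploid nuclear genotypes under an admixture model with
drift-correlated cluster allele frequencies, haploid chloroplast haplotypes
on a stepwise-mutation ladder, and per-population environmental covariates
that drive a configured introgression level through a logit-linear model.
Every stage is seeded through independent substreams of one root seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from oakintro.genotype_io import GenotypeMatrix

__all__ = [
    "PopSpec",
    "SimConfig",
    "SimTruth",
    "simulate_allele_frequencies",
    "simulate_admixed_genotypes",
    "simulate_cp_haplotypes",
    "simulate_environment",
    "inject_missing",
    "simulate_dataset",
]

# membership-proportion midpoints of the three hybrid categories, used when
# drawing "exact" truth q for category-planted individuals
Q_MID_PURE = 0.9375
Q_MID_ADMIXED = 0.75
Q_MID_HIGHLY = 0.5


@dataclass
class PopSpec:
    pop_id: str
    region: str
    coordinate: tuple[float, float]
    n_individuals: int


@dataclass
class SimConfig:
    """Knobs for one synthetic dataset.

    ``drift_F`` is the per-cluster drift parameter of the correlated
    frequency model, strictly inside (0, 1). ``env_coefficients`` act on the
    logit of the population introgression index; ``env_precision`` is the
    beta-distribution precision of the realized index around its expectation.
    """

    n_clusters: int = 3
    n_loci_nuclear: int = 16
    n_loci_cp: int = 8
    alleles_per_locus: int = 8
    pops: list[PopSpec] = field(default_factory=list)
    drift_F: float | list[float] = 0.2
    admixture_alpha: float = 1.0
    missing_rate: float = 0.02
    env_intercept: float = -1.5
    env_coefficients: list[float] = field(default_factory=lambda: [-0.8, 0.4])
    env_precision: float = 30.0
    cluster_species: dict[int, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        for name in ("n_loci_nuclear", "n_loci_cp", "alleles_per_locus"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.env_precision <= 0:
            raise ValueError("env_precision must be positive")
        if self.admixture_alpha <= 0:
            raise ValueError("admixture_alpha must be positive")
        for f in self.drift_vector():
            if not 0 < f < 1:
                raise ValueError("drift_F values must lie strictly in (0, 1)")
        if self.cluster_species is None:
            # last cluster is the non-focal species, the rest are intraspecific
            # clusters of the focal species
            self.cluster_species = {
                k: ("focal" if k < self.n_clusters - 1 or self.n_clusters == 1 else "other")
                for k in range(self.n_clusters)
            }

    def drift_vector(self) -> np.ndarray:
        if np.isscalar(self.drift_F):
            return np.full(self.n_clusters, float(self.drift_F))
        f = np.asarray(self.drift_F, float)
        if f.shape != (self.n_clusters,):
            raise ValueError("drift_F list length must equal n_clusters")
        return f

    def rng(self, stage: str) -> np.random.Generator:
        """Independent substream per pipeline stage (stable across processes)."""
        tag = zlib.crc32(stage.encode())
        return np.random.default_rng(np.random.SeedSequence((self.seed, tag)))


@dataclass
class SimTruth:
    true_q: np.ndarray
    true_frequencies: np.ndarray
    true_introgression: pd.DataFrame
    true_haplotype: pd.DataFrame | None = None
    cluster_species: dict[int, str] | None = None
    missing_positions: np.ndarray | None = None


def simulate_allele_frequencies(
    config: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Cluster-specific allele frequencies under the drift (F) model.

    Ancestral per-locus frequencies come from a flat Dirichlet; each
    cluster's frequencies are Dirichlet-distributed around the ancestral
    vector with concentration (1 - F_k)/F_k, so small F means tight
    correlation with the ancestral pool.
    """
    rng = config.rng("frequencies") if rng is None else rng
    K, L, A = config.n_clusters, config.n_loci_nuclear, config.alleles_per_locus
    if A < 2:
        raise ValueError("alleles_per_locus must be >= 2")
    fvec = config.drift_vector()
    ancestral = rng.dirichlet(np.ones(A), size=L)  # (L, A)
    freqs = np.empty((K, L, A))
    for k in range(K):
        conc = (1.0 - fvec[k]) / fvec[k]
        if not np.isfinite(conc) or conc <= 0:
            raise ValueError("drift_F produced non-finite concentration")
        for l in range(L):
            freqs[k, l] = rng.dirichlet(ancestral[l] * conc)
    return freqs


def allele_size_ladder(n_loci: int, n_alleles: int, motif_start: int = 100) -> np.ndarray:
    """Integer allele sizes per locus on a dinucleotide repeat ladder."""
    starts = motif_start + 20 * np.arange(n_loci)
    return starts[:, None] + 2 * np.arange(n_alleles)[None, :]


def simulate_admixed_genotypes(
    frequencies: np.ndarray,
    true_q: np.ndarray,
    rng: np.random.Generator,
    individual_ids=None,
    pop_ids=None,
    sizes: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Draw diploid genotypes: per gene copy, a source cluster from q then
    an allele from that cluster's frequency vector."""
    frequencies = np.asarray(frequencies, float)
    true_q = np.asarray(true_q, float)
    K, L, A = frequencies.shape
    n = true_q.shape[0]
    if true_q.shape[1] != K:
        raise ValueError(f"q has {true_q.shape[1]} clusters, frequencies have {K}")
    if not np.allclose(true_q.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("q rows must sum to 1")
    if sizes is None:
        sizes = allele_size_ladder(L, A)

    # source cluster for each of the 2*n*L gene copies
    z = np.empty((n, L, 2), dtype=np.int64)
    u = rng.random((n, L, 2))
    cum_q = np.cumsum(true_q, axis=1)
    z = (u[..., None] > cum_q[:, None, None, :]).sum(axis=-1)

    # allele index given source cluster, per locus
    calls = np.empty((n, L, 2), dtype=np.int64)
    u2 = rng.random((n, L, 2))
    for l in range(L):
        cum_f = np.cumsum(frequencies[:, l, :], axis=1)  # (K, A)
        a_idx = (u2[:, l, :, None] > cum_f[z[:, l, :], :]).sum(axis=-1)
        calls[:, l, :] = sizes[l, a_idx]

    if individual_ids is None:
        individual_ids = [f"ind{i + 1}" for i in range(n)]
    if pop_ids is None:
        pop_ids = ["pop1"] * n
    loci = [f"L{l + 1}" for l in range(L)]
    return GenotypeMatrix(list(individual_ids), list(pop_ids), loci, calls)


def simulate_cp_haplotypes(
    config: SimConfig,
    lineage_map: dict[str, tuple[str, tuple[int, ...]]],
    rng: np.random.Generator | None = None,
    minor_rate: float = 0.0,
) -> pd.DataFrame:
    """Haploid chloroplast haplotypes per individual.

    ``lineage_map`` assigns each population a (lineage label, founder allele
    vector). With probability ``minor_rate`` an individual carries a minor
    haplotype: the founder shifted by one repeat step (+/-1) at one locus.
    """
    rng = config.rng("cp") if rng is None else rng
    if not 0 <= minor_rate < 1:
        raise ValueError("minor_rate must be in [0, 1)")
    rows = []
    for pop in config.pops:
        lineage, founder = lineage_map[pop.pop_id]
        founder = np.asarray(founder, dtype=np.int64)
        if founder.shape != (config.n_loci_cp,):
            raise ValueError(
                f"founder haplotype for {pop.pop_id} has length {founder.size}, "
                f"expected {config.n_loci_cp}"
            )
        for i in range(pop.n_individuals):
            hap = founder.copy()
            if minor_rate > 0 and rng.random() < minor_rate:
                locus = rng.integers(config.n_loci_cp)
                hap[locus] += rng.choice([-1, 1])
            rows.append(
                {
                    "individual_id": f"{pop.pop_id}_ind{i + 1}",
                    "pop_id": pop.pop_id,
                    "haplotype": "-".join(str(a) for a in hap),
                    "lineage": lineage,
                }
            )
    return pd.DataFrame(rows)


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


def simulate_environment(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-population covariates and an environment-driven introgression target.

    Covariates are standard normal; the expected index is
    inverse-logit(intercept + X @ beta); the realized index is beta-distributed
    about that mean with the configured precision, then discretized to
    admixed / highly-admixed counts realizable with n individuals.
    """
    rng = config.rng("environment") if rng is None else rng
    beta = np.asarray(config.env_coefficients, float)
    p_cov = beta.size
    if covariate_names is None:
        covariate_names = [f"env{j + 1}" for j in range(p_cov)]
    if len(covariate_names) != p_cov:
        raise ValueError("covariate_names length must match env_coefficients")
    n_pops = len(config.pops)
    X = rng.standard_normal((n_pops, p_cov))
    mu = np.clip(_inv_logit(config.env_intercept + X @ beta), 1e-9, 1 - 1e-9)
    phi = config.env_precision
    realized = rng.beta(mu * phi, (1 - mu) * phi) if n_pops else np.empty(0)

    rows = []
    for p, pop in enumerate(config.pops):
        n = pop.n_individuals
        # realize (n_had + 0.5 n_ad)/n as closely as n allows:
        # 2*n_had + n_ad = round(2 n I)
        t = int(round(2 * n * realized[p]))
        if t > 2 * n:
            raise ValueError(f"index {realized[p]:.3f} infeasible for n={n}")
        n_had, n_ad = t // 2, t % 2
        if n_had + n_ad > n:
            raise ValueError(f"index {realized[p]:.3f} infeasible for n={n}")
        row = {
            "pop_id": pop.pop_id,
            "region": pop.region,
            "n_individuals": n,
            "expected_index": mu[p],
            "true_index": (n_had + 0.5 * n_ad) / n,
            "n_admixed": n_ad,
            "n_highly_admixed": n_had,
        }
        row.update({name: X[p, j] for j, name in enumerate(covariate_names)})
        rows.append(row)
    return pd.DataFrame(rows)


def inject_missing(
    G: GenotypeMatrix, rate: float, rng: np.random.Generator
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Locus dropout: both gene copies go missing together with prob ``rate``.

    Returns the masked matrix and the boolean (n, L) truth mask of positions
    that were knocked out.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    mask = rng.random((G.n_individuals, G.n_loci)) < rate
    calls = G.calls.copy()
    calls[mask] = G.missing
    out = GenotypeMatrix(
        list(G.individual_ids), list(G.pop_ids), list(G.loci), calls, G.missing
    )
    return out, mask


def _category_truth_q(config: SimConfig, env: pd.DataFrame, rng) -> tuple[np.ndarray, list[str], list[str]]:
    """Exact-category q rows for every individual.

    Focal-species membership sits at the category midpoint (pure 0.9375,
    admixed 0.75, highly admixed 0.5); it is split across the focal species'
    intraspecific clusters according to the population's region, the
    remainder goes to the non-focal cluster(s).
    """
    K = config.n_clusters
    species = config.cluster_species
    focal = [k for k in range(K) if species[k] == "focal"]
    other = [k for k in range(K) if species[k] != "focal"] or focal
    regions = sorted({p.region for p in config.pops})

    q_rows, ids, pops = [], [], []
    env = env.set_index("pop_id")
    for pop in config.pops:
        rec = env.loc[pop.pop_id]
        n = pop.n_individuals
        n_had = int(rec["n_highly_admixed"])
        n_ad = int(rec["n_admixed"])
        cats = ["highly_admixed"] * n_had + ["admixed"] * n_ad
        cats += ["pure"] * (n - len(cats))
        # dominant intraspecific cluster follows the region label round-robin
        home = focal[regions.index(pop.region) % len(focal)]
        for i, cat in enumerate(cats):
            qf = {"pure": Q_MID_PURE, "admixed": Q_MID_ADMIXED, "highly_admixed": Q_MID_HIGHLY}[cat]
            row = np.zeros(K)
            # 90% of focal mass on the home cluster, rest spread evenly
            if len(focal) > 1:
                row[focal] = qf * 0.1 / (len(focal) - 1)
            row[home] = qf if len(focal) == 1 else qf * 0.9
            row[other] += (1 - qf) / len(other)
            q_rows.append(row)
            ids.append(f"{pop.pop_id}_ind{i + 1}")
            pops.append(pop.pop_id)
    return np.array(q_rows), ids, pops


def simulate_dataset(config: SimConfig, lineage_map=None) -> tuple[GenotypeMatrix, SimTruth, pd.DataFrame]:
    """Full synthetic bundle: genotypes, truth tables, environment table.

    Individual categories are planted at exact category midpoints so that
    downstream classification on the true q reproduces the configured
    introgression index exactly.
    """
    if not config.pops:
        raise ValueError("config.pops is empty")
    env = simulate_environment(config)
    freqs = simulate_allele_frequencies(config)
    true_q, ids, pops = _category_truth_q(config, env, config.rng("categories"))
    G = simulate_admixed_genotypes(freqs, true_q, config.rng("genotypes"), ids, pops)
    G, miss = inject_missing(G, config.missing_rate, config.rng("missing"))

    hap = None
    if lineage_map is not None:
        hap = simulate_cp_haplotypes(config, lineage_map)

    truth = SimTruth(
        true_q=true_q,
        true_frequencies=freqs,
        true_introgression=env[["pop_id", "true_index", "expected_index"]].copy(),
        true_haplotype=hap,
        cluster_species=dict(config.cluster_species),
        missing_positions=miss,
    )
    return G, truth, env
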