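"""Bayesian attribution of sink reads to individual source samples.

The model mirrors the SourceTracker generative story: each read of a sink
(palm) sample carries a latent label naming the source environment it came
from — one of the known source samples, or an extra "unknown" environment
absorbing reads no known source explains.  Known sources keep fixed
taxon profiles, smoothed with a pseudocount ``alpha1``; the unknown
source's profile is built up from the sink reads currently assigned to it,
smoothed with ``alpha2``; a symmetric pseudocount ``beta`` acts as the
prior over source membership.  Inference is collapsed Gibbs sampling over
read labels, restarted from independent random initialisations so the
spread across recorded draws yields a standard deviation for every
proportion.

:func:`exact_posterior` computes the same posterior by brute-force
enumeration of all label vectors and exists purely as a small-instance
oracle.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .io_tables import OtuTable, SampleMetadata, rarefy

__all__ = [
    "SourceSet",
    "GibbsParams",
    "MixingEstimate",
    "fit_sink",
    "fit_all",
    "exact_posterior",
    "write_mixing_estimates",
    "UNKNOWN_LABEL",
]

UNKNOWN_LABEL = "Unknown"


@dataclass
class SourceSet:
    """Fixed taxon-count profiles of the candidate source samples."""

    source_ids: list[str]
    m: np.ndarray  # taxa x sources, non-negative ints

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=np.int64)
        if self.m.ndim != 2 or self.m.shape[1] != len(self.source_ids):
            raise ValueError("m must be taxa x len(source_ids)")
        if np.any(self.m < 0):
            raise ValueError("negative source counts")
        if len(set(self.source_ids)) != len(self.source_ids):
            raise ValueError("duplicate source IDs")

    @property
    def tau(self) -> int:
        return self.m.shape[0]

    @property
    def n_sources(self) -> int:
        return self.m.shape[1]

    @classmethod
    def from_table(cls, table: OtuTable, source_ids: list[str]) -> "SourceSet":
        idx = [table.sample_index(s) for s in source_ids]
        return cls(list(source_ids), table.counts[:, idx].copy())

    def phi(self, alpha1: float) -> np.ndarray:
        """Smoothed per-source taxon distributions phi[t, v]."""
        col = self.m.sum(axis=0).astype(np.float64)
        return (self.m + alpha1) / (col + self.tau * alpha1)


@dataclass
class GibbsParams:
    """Sampler configuration.

    The defaults follow the conventional SourceTracker settings: weak
    smoothing of known source profiles (``alpha1``), stronger smoothing of
    the unknown environment (``alpha2``), a membership pseudocount ``beta``,
    and ten independent restarts each contributing one recorded draw after
    burn-in, so mean and SD are taken over ten draws.
    """

    alpha1: float = 0.001
    alpha2: float = 0.1
    beta: float = 10.0
    restarts: int = 10
    burnin: int = 100
    draws_per_restart: int = 1
    delay: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.alpha2, self.beta) <= 0:
            raise ValueError("pseudocounts must be positive")
        if self.restarts < 1 or self.burnin < 0 or self.draws_per_restart < 1 or self.delay < 1:
            raise ValueError("invalid chain schedule")
        if self.restarts * self.draws_per_restart < 2:
            raise ValueError("need at least 2 recorded draws to estimate an SD")

    @property
    def n_draws(self) -> int:
        return self.restarts * self.draws_per_restart


@dataclass
class MixingEstimate:
    """Posterior mixing proportions of one sink over sources + unknown.

    ``proportions_mean``/``proportions_sd`` are ordered as
    ``source_ids + [UNKNOWN_LABEL]``; ``draw_proportions`` keeps the raw
    per-draw vectors (n_draws x K) so site-level sums retain draw-level
    covariance when aggregated downstream.
    """

    sink_id: str
    source_ids: list[str]
    proportions_mean: np.ndarray
    proportions_sd: np.ndarray
    n_draws: int
    depth: int
    draw_proportions: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        s = float(np.sum(self.proportions_mean))
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"mean proportions sum to {s}, not 1")
        if len(self.proportions_mean) != len(self.source_ids) + 1:
            raise ValueError("proportion vector length != n_sources + 1")

    @property
    def labels(self) -> list[str]:
        return list(self.source_ids) + [UNKNOWN_LABEL]

    @property
    def assignment_counts(self) -> np.ndarray:
        """Mean read counts per source (+unknown); sums to the sink depth."""
        return self.proportions_mean * self.depth

    def proportion(self, label: str) -> float:
        return float(self.proportions_mean[self.labels.index(label)])


# ---------------------------------------------------------------------------
# Gibbs kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_chain(read_taxa, phi, alpha2, beta, tau, burnin, n_draws, delay, seed):
    np.random.seed(seed)
    n = read_taxa.shape[0]
    V = phi.shape[1]
    K = V + 1
    z = np.empty(n, np.int64)
    nv = np.zeros(K, np.int64)
    q = np.zeros(tau, np.int64)
    Q = 0
    for i in range(n):
        k = np.random.randint(0, K)
        z[i] = k
        nv[k] += 1
        if k == V:
            q[read_taxa[i]] += 1
            Q += 1
    draws = np.zeros((n_draws, K))
    p = np.empty(K)
    recorded = 0
    sweep = 0
    while recorded < n_draws:
        for i in range(n):
            t = read_taxa[i]
            k_old = z[i]
            nv[k_old] -= 1
            if k_old == V:
                q[t] -= 1
                Q -= 1
            s = 0.0
            for v in range(V):
                p[v] = phi[t, v] * (nv[v] + beta)
                s += p[v]
            p[V] = ((q[t] + alpha2) / (Q + tau * alpha2)) * (nv[V] + beta)
            s += p[V]
            u = np.random.random() * s
            acc = 0.0
            k_new = K - 1
            for v in range(K):
                acc += p[v]
                if u < acc:
                    k_new = v
                    break
            z[i] = k_new
            nv[k_new] += 1
            if k_new == V:
                q[t] += 1
                Q += 1
        sweep += 1
        if sweep > burnin and (sweep - burnin) % delay == 0:
            for v in range(K):
                draws[recorded, v] = nv[v] / n
            recorded += 1
    return draws


def _expand_reads(sink_counts: np.ndarray) -> np.ndarray:
    return np.repeat(np.arange(len(sink_counts), dtype=np.int64),
                     np.asarray(sink_counts, dtype=np.int64))


def _chain_seed(master: int, restart: int) -> int:
    return int((master * np.int64(2654435761) + restart * 40503 + 1) % (2**31 - 1))


def fit_sink(sink_counts: np.ndarray, sources: SourceSet,
             params: GibbsParams, sink_id: str = "sink") -> MixingEstimate:
    """Attribute one sink's reads across sources + unknown.

    Runs ``params.restarts`` independent chains; each burns in, then
    records ``draws_per_restart`` draws spaced ``delay`` sweeps apart.
    Mean and SD are pooled over all recorded draws.
    """
    sink_counts = np.asarray(sink_counts, dtype=np.int64)
    if sink_counts.shape[0] != sources.tau:
        raise ValueError(
            f"sink has {sink_counts.shape[0]} taxa but sources have {sources.tau}")
    n = int(sink_counts.sum())
    if n <= 0:
        raise ValueError("sink has no reads")
    reads = _expand_reads(sink_counts)
    phi = sources.phi(params.alpha1)
    all_draws = np.empty((params.n_draws, sources.n_sources + 1))
    for r in range(params.restarts):
        d = _run_chain(reads, phi, params.alpha2, params.beta, sources.tau,
                       params.burnin, params.draws_per_restart, params.delay,
                       _chain_seed(params.seed, r))
        all_draws[r * params.draws_per_restart:(r + 1) * params.draws_per_restart] = d
    mean = all_draws.mean(axis=0)
    mean = mean / mean.sum()  # guard fp drift; draws each sum to 1 exactly
    sd = all_draws.std(axis=0, ddof=1)
    return MixingEstimate(sink_id, list(sources.source_ids), mean, sd,
                          params.n_draws, depth=n, draw_proportions=all_draws)


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

_ENUM_MAX_READS = 10


def exact_posterior(sink_counts: np.ndarray, sources: SourceSet,
                    params: GibbsParams) -> np.ndarray:
    """Exact posterior mean assignment proportions by full enumeration.

    Sums the collapsed joint over every label vector in
    ``(n_sources+1)**n_reads``; usable only for tiny instances and refused
    above 10 reads.
    """
    sink_counts = np.asarray(sink_counts, dtype=np.int64)
    n = int(sink_counts.sum())
    if n > _ENUM_MAX_READS:
        raise ValueError(f"enumeration limited to {_ENUM_MAX_READS} reads, got {n}")
    if sink_counts.shape[0] != sources.tau:
        raise ValueError("taxa axes misaligned")
    reads = _expand_reads(sink_counts)
    V = sources.n_sources
    K = V + 1
    tau = sources.tau
    phi = sources.phi(params.alpha1)
    a2, beta = params.alpha2, params.beta

    total_w = 0.0
    acc = np.zeros(K)
    z = np.zeros(n, dtype=np.int64)
    # odometer enumeration over K^n label vectors
    while True:
        nv = np.bincount(z, minlength=K)
        w = 1.0
        # membership prior: rising factorials of beta
        for v in range(K):
            for j in range(nv[v]):
                w *= beta + j
        # known-source likelihood
        for i in range(n):
            if z[i] < V:
                w *= phi[reads[i], z[i]]
        # unknown-source (Polya urn) likelihood
        q = np.bincount(reads[z == V], minlength=tau)
        Qtot = int(q.sum())
        for t in range(tau):
            for j in range(q[t]):
                w *= a2 + j
        for j in range(Qtot):
            w /= tau * a2 + j
        total_w += w
        acc += w * nv / n
        # increment odometer
        pos = n - 1
        while pos >= 0 and z[pos] == K - 1:
            z[pos] = 0
            pos -= 1
        if pos < 0:
            break
        z[pos] += 1
    return acc / total_w


# ---------------------------------------------------------------------------
# cohort driver
# ---------------------------------------------------------------------------

def _sink_seed(master_seed: int, sink_id: str) -> int:
    return int((master_seed + zlib.crc32(sink_id.encode())) % (2**31 - 1))


def fit_all(table: OtuTable, metadata: SampleMetadata, params: GibbsParams,
            sink_depth: int = 1000, rarefy_sinks: bool = True,
            rarefy_sources: bool = False) -> list[MixingEstimate]:
    """Fit every palm in the table as a sink against all non-palm samples.

    Sinks never appear as sources.  Each sink gets a chain seed derived by
    stable hashing of its sample ID with the master seed, so results are
    reproducible and independent of palm order.  By default sinks are
    rarefied to ``sink_depth`` reads and sources are used at full depth.
    """
    palms = [s for s in metadata.palms() if s in table.sample_ids]
    if not palms:
        raise ValueError("no palm samples present in table")
    source_ids = [s for s in metadata.non_palms() if s in table.sample_ids]
    if not source_ids:
        raise ValueError("no non-palm source samples present in table")
    sources = SourceSet.from_table(table, source_ids)
    if rarefy_sources:
        m = np.stack([rarefy(sources.m[:, j], sink_depth,
                             _sink_seed(params.seed + 7, source_ids[j]))
                      for j in range(sources.n_sources)], axis=1)
        sources = SourceSet(source_ids, m)
    estimates = []
    for palm in palms:
        counts = table.sample_counts(palm)
        seed = _sink_seed(params.seed, palm)
        if rarefy_sinks and counts.sum() > sink_depth:
            counts = rarefy(counts, sink_depth, seed)
        p = GibbsParams(alpha1=params.alpha1, alpha2=params.alpha2,
                        beta=params.beta, restarts=params.restarts,
                        burnin=params.burnin,
                        draws_per_restart=params.draws_per_restart,
                        delay=params.delay, seed=seed)
        estimates.append(fit_sink(counts, sources, p, sink_id=palm))
    return estimates


def write_mixing_estimates(estimates: list[MixingEstimate], out_dir) -> None:
    """Write mixing_proportions.tsv / mixing_proportions_sd.tsv.

    Rows are sinks, columns every source sample ID plus "Unknown".
    """
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = estimates[0].labels
    mean = pd.DataFrame([e.proportions_mean for e in estimates],
                        index=[e.sink_id for e in estimates], columns=labels)
    sd = pd.DataFrame([e.proportions_sd for e in estimates],
                      index=[e.sink_id for e in estimates], columns=labels)
    mean.index.name = "SampleID"
    sd.index.name = "SampleID"
    mean.to_csv(out / "mixing_proportions.tsv", sep="\t")
    sd.to_csv(out / "mixing_proportions_sd.tsv", sep="\t")


def read_mixing_estimates(out_dir, depth: int = 1000) -> list[MixingEstimate]:
    """Reload estimates written by :func:`write_mixing_estimates`.

    Draw-level vectors are not persisted; SDs come from the SD table and
    n_draws is unknown (set to 10, the default schedule).
    """
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    mean = pd.read_csv(out / "mixing_proportions.tsv", sep="\t", index_col=0)
    sd = pd.read_csv(out / "mixing_proportions_sd.tsv", sep="\t", index_col=0)
    labels = list(mean.columns)
    if labels[-1] != UNKNOWN_LABEL:
        raise ValueError("last column of mixing_proportions.tsv must be 'Unknown'")
    ests = []
    for sink in mean.index:
        m = mean.loc[sink].to_numpy(float)
        m = m / m.sum()
        ests.append(MixingEstimate(str(sink), labels[:-1], m,
                                   sd.loc[sink].to_numpy(float),
                                   n_draws=10, depth=depth))
    return ests
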