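"""Cluster-based permutation statistics for paired sensor-space contrasts.

The family-wise-error problem of testing every (channel, time) sample is
handled with the nonparametric max-cluster approach: paired t-tests at all
samples, clustering of suprathreshold samples that are adjacent in time or
space (with an optional at-least-two-neighboring-channels pruning rule),
cluster mass defined as the sum of member t-values (t_maxsum), and a Monte
Carlo null distribution of the per-permutation maximum |mass| built by
randomly exchanging the paired conditions (per-subject sign flips of the
difference maps).

The interface follows the model/results idiom::

    model = ClusterPermutationTest(phasic, tonic, labels=chs, times_ms=t,
                                   window_ms=(350, 650))
    res = model.fit(n_permutations=5000, seed=7)
    print(res.summary())

Pointwise single-channel permutation tests (for the ECG confound analysis)
and Benjamini-Hochberg FDR correction live here as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .montage import channel_adjacency

DEFAULT_WINDOW_MS = (350.0, 650.0)
DEFAULT_N_PERMUTATIONS = 5000


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Paired t maps
# ---------------------------------------------------------------------------


def paired_t_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Paired-sample t statistic at every (channel, time) sample.

    ``a`` and ``b`` are (n_subjects, n_channels, n_times); df = n - 1.
    Samples with zero-variance differences get t = 0 (degenerate points).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StatsError("paired data must have identical shapes")
    n = a.shape[0]
    if n < 3:
        raise StatsError("need at least 3 subjects for a paired t map")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def t_critical(df: int, alpha: float = 0.05) -> float:
    """Two-tailed critical t value."""
    return float(t_dist.ppf(1.0 - alpha / 2.0, df))


# ---------------------------------------------------------------------------
# Cluster formation
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    """A connected suprathreshold spatio-temporal region."""

    channels: np.ndarray  # channel index per member sample
    times: np.ndarray  # time index per member sample
    sign: int  # +1 or -1
    mass: float  # sum of member t values (t_maxsum)
    p_value: float | None = None

    @property
    def channel_set(self) -> np.ndarray:
        return np.unique(self.channels)

    @property
    def time_range(self) -> tuple[int, int]:
        return int(self.times.min()), int(self.times.max())


class _ClusterEngine:
    """Precomputed spatio-temporal neighborhood for one grid shape."""

    def __init__(self, adjacency: np.ndarray, n_times: int,
                 min_neighbors: int = 2):
        self.adj = np.asarray(adjacency, dtype=bool)
        if self.adj.shape[0] != self.adj.shape[1]:
            raise StatsError("adjacency must be square")
        if self.adj.any() and (
            np.diag(self.adj).any() or not (self.adj == self.adj.T).all()
        ):
            raise StatsError("adjacency must be symmetric and irreflexive")
        self.n_ch = self.adj.shape[0]
        self.n_t = n_times
        self.min_neighbors = min_neighbors
        self.adj_f = self.adj.astype(np.float64)
        self.pairs = np.argwhere(np.triu(self.adj, k=1))  # spatial pairs

    def _prune(self, mask: np.ndarray) -> np.ndarray:
        """Keep suprathreshold samples with >= min_neighbors suprathreshold
        spatial neighbors at the same time point."""
        if self.min_neighbors <= 0:
            return mask
        counts = self.adj_f @ mask
        return mask & (counts >= self.min_neighbors)

    def _components(self, mask: np.ndarray):
        """Connected components of a (n_ch, n_t) boolean mask under
        temporal adjacency + spatial channel adjacency.

        Yields (channels, times) index arrays, one pair per component.
        """
        flat = np.flatnonzero(mask.ravel())
        if flat.size == 0:
            return
        k = flat.size
        pos = np.full(self.n_ch * self.n_t, -1, dtype=np.int64)
        pos[flat] = np.arange(k)
        # temporal edges
        tmask = mask[:, :-1] & mask[:, 1:]
        ch_i, t_i = np.nonzero(tmask)
        u = pos[ch_i * self.n_t + t_i]
        v = pos[ch_i * self.n_t + t_i + 1]
        # spatial edges
        us, vs = [u], [v]
        if self.pairs.size:
            smask = mask[self.pairs[:, 0]] & mask[self.pairs[:, 1]]
            p_i, t_s = np.nonzero(smask)
            us.append(pos[self.pairs[p_i, 0] * self.n_t + t_s])
            vs.append(pos[self.pairs[p_i, 1] * self.n_t + t_s])
        u = np.concatenate(us)
        v = np.concatenate(vs)
        graph = sparse.coo_matrix(
            (np.ones(u.size), (u, v)), shape=(k, k)
        ).tocsr()
        n_comp, labels = connected_components(graph, directed=False)
        ch_of = flat // self.n_t
        t_of = flat % self.n_t
        for c in range(n_comp):
            sel = labels == c
            yield ch_of[sel], t_of[sel]

    def clusters(self, tmap: np.ndarray, tcrit: float) -> list[Cluster]:
        out: list[Cluster] = []
        for sign in (1, -1):
            mask = self._prune(sign * tmap > tcrit)
            for chans, times in self._components(mask):
                out.append(
                    Cluster(
                        channels=chans,
                        times=times,
                        sign=sign,
                        mass=float(tmap[chans, times].sum()),
                    )
                )
        out.sort(key=lambda c: -abs(c.mass))
        return out

    def max_mass(self, tmap: np.ndarray, tcrit: float) -> float:
        best = 0.0
        for sign in (1, -1):
            mask = self._prune(sign * tmap > tcrit)
            for chans, times in self._components(mask):
                best = max(best, abs(float(tmap[chans, times].sum())))
        return best


def form_clusters(
    tmap: np.ndarray,
    adjacency: np.ndarray,
    df: int,
    alpha: float = 0.05,
    min_neighbors: int = 2,
) -> list[Cluster]:
    """Connected suprathreshold clusters of a (channels x times) t map.

    Thresholding at the two-tailed critical t for ``df``; positive and
    negative excursions cluster separately; a suprathreshold sample is
    retained only if at least ``min_neighbors`` of its spatial neighbors
    are also suprathreshold (0 disables pruning).
    """
    tmap = np.asarray(tmap, dtype=float)
    if not np.isfinite(tmap).all():
        raise StatsError("t map contains non-finite values")
    engine = _ClusterEngine(adjacency, tmap.shape[1], min_neighbors)
    return engine.clusters(tmap, t_critical(df, alpha))


# ---------------------------------------------------------------------------
# The permutation model
# ---------------------------------------------------------------------------


@dataclass
class ClusterPermutationResults:
    """Observed clusters, their Monte-Carlo p values, and the null."""

    clusters: list[Cluster]
    null_distribution: np.ndarray
    tmap: np.ndarray
    n_permutations: int
    alpha: float
    window_ms: tuple[float, float] | None
    times_ms: np.ndarray | None
    labels: list[str] | None
    seed: int | None
    min_neighbors: int
    n_degenerate: int = 0

    @property
    def max_mass(self) -> float:
        return max((abs(c.mass) for c in self.clusters), default=0.0)

    def significant(self, alpha_per_tail: float = 0.025) -> list[Cluster]:
        """Clusters significant at the per-tail level (two-tailed 0.05
        overall by default)."""
        return [c for c in self.clusters if c.p_value is not None
                and c.p_value < alpha_per_tail]

    def cluster_window_ms(self, cluster: Cluster) -> tuple[float, float]:
        if self.times_ms is None:
            raise StatsError("results carry no time axis")
        lo, hi = cluster.time_range
        return float(self.times_ms[lo]), float(self.times_ms[hi])

    def cluster_channels(self, cluster: Cluster) -> list[str]:
        if self.labels is None:
            return [str(i) for i in cluster.channel_set]
        return [self.labels[i] for i in cluster.channel_set]

    def to_dict(self) -> dict:
        out = {
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
            "min_neighbors": self.min_neighbors,
            "seed": self.seed,
            "window_ms": list(self.window_ms) if self.window_ms else None,
            "null_max_mass_quantiles": {
                q: float(np.quantile(self.null_distribution, q))
                for q in (0.5, 0.95, 0.975, 0.99)
            } if self.null_distribution.size else {},
            "clusters": [],
        }
        for c in self.clusters:
            d = {
                "sign": c.sign,
                "mass": c.mass,
                "p_value": c.p_value,
                "channels": self.cluster_channels(c),
            }
            if self.times_ms is not None:
                d["window_ms"] = list(self.cluster_window_ms(c))
            out["clusters"].append(d)
        return out

    def summary(self) -> str:
        lines = [
            "Cluster-based permutation test (paired, sign-flip null)",
            f"  permutations: {self.n_permutations}"
            f"   cluster-forming alpha: {self.alpha}"
            f"   min spatial neighbors: {self.min_neighbors}",
        ]
        if self.window_ms:
            lines.append(
                f"  analysis window: {self.window_ms[0]:.0f}-"
                f"{self.window_ms[1]:.0f} ms"
            )
        if not self.clusters:
            lines.append("  no suprathreshold clusters")
        for i, c in enumerate(self.clusters):
            sign = "+" if c.sign > 0 else "-"
            row = (
                f"  cluster {i + 1} ({sign}): t_maxsum = {c.mass:.2f}, "
                f"p = {c.p_value:.4f}" if c.p_value is not None
                else f"  cluster {i + 1} ({sign}): t_maxsum = {c.mass:.2f}"
            )
            if self.times_ms is not None:
                lo, hi = self.cluster_window_ms(c)
                row += f", {lo:.1f}-{hi:.1f} ms"
            row += f", channels: {' '.join(self.cluster_channels(c))}"
            lines.append(row)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the observed max-|mass| against the permutation null."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.null_distribution, bins=40, color="0.7",
                label="null max |mass|")
        ax.axvline(self.max_mass, color="C3", label="observed")
        ax.set_xlabel("max |cluster mass|")
        ax.set_ylabel("permutations")
        ax.legend()
        return ax


class ClusterPermutationTest:
    """Paired spatio-temporal cluster permutation model.

    Parameters
    ----------
    a, b : ndarray, (n_subjects, n_channels, n_times)
        Per-subject condition averages (e.g. phasic vs tonic HEP).
    labels : list of str, optional
        Channel names; used to build the 10-20 adjacency when
        ``adjacency`` is not given, and for reporting.
    times_ms : ndarray, optional
        Time axis; required when ``window_ms`` is set.
    window_ms : (float, float), optional
        Restrict the test to this window (default 350-650 ms post-R).
    alpha : float
        Cluster-forming threshold (two-tailed).
    min_neighbors : int
        Spatial-neighbor pruning (0 disables).
    """

    def __init__(
        self,
        a: np.ndarray,
        b: np.ndarray,
        labels: list[str] | None = None,
        times_ms: np.ndarray | None = None,
        adjacency: np.ndarray | None = None,
        window_ms: tuple[float, float] | None = DEFAULT_WINDOW_MS,
        alpha: float = 0.05,
        min_neighbors: int = 2,
    ):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape or a.ndim != 3:
            raise StatsError(
                "paired data must be equal-shape (subjects, channels, times)"
            )
        if adjacency is None:
            if labels is None:
                raise StatsError("need channel labels or an adjacency matrix")
            adjacency = channel_adjacency(labels)
        if adjacency.shape[0] != a.shape[1]:
            raise StatsError("adjacency does not cover all channels")
        if window_ms is not None:
            if times_ms is None:
                raise StatsError("window_ms requires a time axis")
            times_ms = np.asarray(times_ms, dtype=float)
            lo, hi = window_ms
            if not lo < hi:
                raise StatsError(f"empty analysis window {window_ms}")
            if lo < times_ms[0] - 1e-9 or hi > times_ms[-1] + 1e-9:
                raise StatsError("analysis window outside the epoch span")
            sel = (times_ms >= lo) & (times_ms <= hi)
            a, b = a[:, :, sel], b[:, :, sel]
            times_ms = times_ms[sel]
        self.a, self.b = a, b
        self.labels = labels
        self.times_ms = times_ms
        self.adjacency = np.asarray(adjacency, dtype=bool)
        self.window_ms = window_ms
        self.alpha = alpha
        self.min_neighbors = min_neighbors

    def fit(
        self,
        n_permutations: int = DEFAULT_N_PERMUTATIONS,
        seed: int | None = None,
    ) -> ClusterPermutationResults:
        """Run the Monte-Carlo sign-flip permutation test."""
        if n_permutations < 100:
            warnings.warn(
                f"{n_permutations} permutations gives a coarse p resolution",
                stacklevel=2,
            )
        n, n_ch, n_t = self.a.shape
        d = self.a - self.b
        df = n - 1
        tcrit = t_critical(df, self.alpha)
        engine = _ClusterEngine(self.adjacency, n_t, self.min_neighbors)

        tmap = paired_t_map(self.a, self.b)
        n_degenerate = int((np.std(d, axis=0, ddof=1) == 0).sum())
        clusters = engine.clusters(tmap, tcrit)

        D = d.reshape(n, n_ch * n_t)
        ssq0 = (D**2).sum(axis=0)
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        chunk = 256
        done = 0
        while done < n_permutations:
            k = min(chunk, n_permutations - done)
            signs = rng.choice([-1.0, 1.0], size=(k, n))
            sums = signs @ D
            mean = sums / n
            var = (ssq0[None, :] - n * mean**2) / (n - 1)
            var = np.maximum(var, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                tperm = mean / np.sqrt(var / n)
            tperm[~np.isfinite(tperm)] = 0.0
            for i in range(k):
                null[done + i] = engine.max_mass(
                    tperm[i].reshape(n_ch, n_t), tcrit
                )
            done += k

        for c in clusters:
            c.p_value = float(
                (1 + np.sum(null >= abs(c.mass))) / (1 + n_permutations)
            )
        return ClusterPermutationResults(
            clusters=clusters,
            null_distribution=null,
            tmap=tmap,
            n_permutations=n_permutations,
            alpha=self.alpha,
            window_ms=self.window_ms,
            times_ms=self.times_ms,
            labels=self.labels,
            seed=seed,
            min_neighbors=self.min_neighbors,
            n_degenerate=n_degenerate,
        )


def cluster_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    adjacency: np.ndarray | None = None,
    labels: list[str] | None = None,
    times_ms: np.ndarray | None = None,
    window_ms: tuple[float, float] | None = DEFAULT_WINDOW_MS,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    alpha: float = 0.05,
    min_neighbors: int = 2,
    seed: int | None = None,
) -> ClusterPermutationResults:
    """Functional wrapper around :class:`ClusterPermutationTest`."""
    model = ClusterPermutationTest(
        a, b, labels=labels, times_ms=times_ms, adjacency=adjacency,
        window_ms=window_ms, alpha=alpha, min_neighbors=min_neighbors,
    )
    return model.fit(n_permutations=n_permutations, seed=seed)


# ---------------------------------------------------------------------------
# Pointwise permutation test (single channel) and FDR
# ---------------------------------------------------------------------------


def pointwise_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-time-point paired permutation test on single-channel waveforms.

    ``a`` and ``b`` are (n_subjects, n_times).  At each time point the
    observed paired t is compared two-tailed against the sign-flip null of
    t values at that same time point.  Returns ``(t_observed, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise StatsError("paired data must be equal-shape (subjects, times)")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations", stacklevel=2)
    n, n_t = a.shape
    if n < 3:
        raise StatsError("need at least 3 subjects")
    d = a - b
    ssq0 = (d**2).sum(axis=0)
    t_obs = paired_t_map(a[:, None, :], b[:, None, :])[0]
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    sums = signs @ d
    mean = sums / n
    var = np.maximum((ssq0[None, :] - n * mean**2) / (n - 1), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = mean / np.sqrt(var / n)
    t_null[~np.isfinite(t_null)] = 0.0
    exceed = (np.abs(t_null) >= np.abs(t_obs)[None, :]).sum(axis=0)
    p = (1 + exceed) / (1 + n_permutations)
    return t_obs, p


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise StatsError("p values must lie in [0, 1]")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)
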