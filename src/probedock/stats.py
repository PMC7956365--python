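"""Pose-benchmark statistics: RMSD, success rate, distribution summaries,
and rank-based group comparison (Kruskal–Wallis with Dunn post-hoc).

Docking accuracy is judged by the RMSD between a docked pose and the
experimental ligand conformation, computed in the shared receptor frame
without superposition; a pose under 2.0 Å counts as a prediction success
(strictly under — 2.0 itself is a failure).  Protocols are compared on their
RMSD distributions with the Kruskal–Wallis rank test, followed by Dunn's
pairwise mean-rank comparisons with Bonferroni and Holm adjustment.

Dunn p-values follow the one-sided convention: ``p = P(Z > |z|)``, half the
two-sided value.  Many references report two-sided Dunn p-values; the
one-sided form is used here (and stated in the result object) so that a
z of 0 maps to p = 0.5.  Both adjustments operate on these one-sided values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptyInputError

__all__ = [
    "PoseRecord", "BenchmarkTable", "DunnResult",
    "rmsd", "symmetry_aware_rmsd", "success_rate", "summarize",
    "kruskal_wallis", "dunn_posthoc", "filter_complete",
    "plot_rmsd_distributions",
]


@dataclass(frozen=True)
class PoseRecord:
    """RMSD of one docked complex under one protocol."""

    complex_id: str
    protocol: str
    rmsd: float

    def __post_init__(self):
        if not (np.isfinite(self.rmsd) and self.rmsd >= 0):
            raise ValueError(f"{self.complex_id}/{self.protocol}: "
                             f"rmsd must be finite and non-negative")


class BenchmarkTable:
    """Per-complex, per-protocol RMSD records backed by a DataFrame.

    (complex_id, protocol) pairs are unique; a complex is *complete* when it
    carries a finite RMSD under every protocol in the table.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"complex_id", "protocol", "rmsd"}
        if not required.issubset(df.columns):
            raise ValueError(f"benchmark table needs columns {sorted(required)}")
        if df.duplicated(subset=["complex_id", "protocol"]).any():
            raise ValueError("duplicate (complex_id, protocol) pairs")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list[PoseRecord]) -> "BenchmarkTable":
        return cls(pd.DataFrame(
            [(r.complex_id, r.protocol, r.rmsd) for r in records],
            columns=["complex_id", "protocol", "rmsd"]))

    @classmethod
    def from_csv(cls, path) -> "BenchmarkTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def protocols(self) -> list[str]:
        return sorted(self.df["protocol"].unique())

    @property
    def complexes(self) -> list[str]:
        return sorted(self.df["complex_id"].unique())

    def complete_complexes(self) -> list[str]:
        wide = self.df.pivot(index="complex_id", columns="protocol", values="rmsd")
        wide = wide.reindex(columns=self.protocols)
        ok = wide.notna().all(axis=1) & np.isfinite(wide).all(axis=1)
        return sorted(wide.index[ok])

    def group(self, protocol: str) -> np.ndarray:
        return self.df.loc[self.df["protocol"] == protocol, "rmsd"].to_numpy()

    def groups(self) -> dict[str, np.ndarray]:
        return {p: self.group(p) for p in self.protocols}

    def __len__(self) -> int:
        return len(self.df)


def filter_complete(table: BenchmarkTable) -> BenchmarkTable:
    """Keep only complexes docked successfully under every protocol.

    Cross-protocol comparisons are only fair on the common set of complexes,
    since a protocol that fails on the hard cases would otherwise look better
    than it is.
    """
    keep = set(table.complete_complexes())
    return BenchmarkTable(table.df[table.df["complex_id"].isin(keep)])


def rmsd(coords_a, coords_b) -> float:
    """Root-mean-square deviation between matched coordinate sets, Å.

    No superposition is applied: docked and experimental poses share the
    receptor frame, so displacement is measured in place.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shapes must match as (N, 3); "
                         f"got {a.shape} and {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def symmetry_aware_rmsd(coords_a, coords_b, elements, bonds) -> float:
    """Minimum RMSD over element-preserving automorphisms of the bond graph.

    Optional and off the default path: plain :func:`rmsd` assumes matched
    atom order, which over-penalizes symmetric ligands (e.g. a flipped
    benzene ring).  This variant enumerates graph automorphisms that preserve
    elements and takes the smallest RMSD.  Exponential in the worst case;
    intended for small ligands.
    """
    import networkx as nx

    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    g = nx.Graph()
    g.add_nodes_from((i, {"element": el}) for i, el in enumerate(elements))
    g.add_edges_from((i, j) for i, j, *_ in bonds)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda u, v: u["element"] == v["element"])
    best = np.inf
    for mapping in matcher.isomorphisms_iter():
        perm = [mapping[i] for i in range(len(elements))]
        best = min(best, rmsd(a, b[perm]))
    return best


def success_rate(rmsds, cutoff: float = 2.0) -> float:
    """Fraction of poses strictly under the cutoff (default 2.0 Å).

    The boundary is exclusive: an RMSD exactly at the cutoff is a failure.
    """
    arr = np.asarray(rmsds, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("cannot compute a success rate of zero poses")
    return float(np.mean(arr < cutoff))


def summarize(rmsds) -> dict[str, float]:
    """Distribution summary: count, mean, sample std, min, quartiles, max.

    Std uses n−1 in the denominator (0 by convention for a single value);
    quartiles use linear interpolation between order statistics.
    """
    arr = np.asarray(rmsds, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("cannot summarize zero values")
    return {
        "count": int(arr.size),
        "mean": float(arr.mean()),
        "std": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "min": float(arr.min()),
        "q25": float(np.percentile(arr, 25)),
        "median": float(np.percentile(arr, 50)),
        "q75": float(np.percentile(arr, 75)),
        "max": float(arr.max()),
    }


def _check_groups(groups):
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    for i, g in enumerate(arrs):
        if g.size == 0:
            raise EmptyInputError(f"group {i} is empty")
    return arrs


def _tie_counts(pooled_ranked):
    _, counts = np.unique(pooled_ranked, return_counts=True)
    return counts[counts > 1]


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; p from χ²(k−1).

    H = 12/(N(N+1)) · Σ R_i²/n_i − 3(N+1), divided by the tie-correction
    factor 1 − Σ(t³−t)/(N³−N) over tied groups of size t; mid-ranks are used.
    All-identical data yields H = 0, p = 1 by convention.
    """
    arrs = _check_groups(groups)
    pooled = np.concatenate(arrs)
    n = pooled.size
    ranks = sps.rankdata(pooled)  # mid-ranks
    h = 0.0
    start = 0
    for g in arrs:
        r_sum = ranks[start:start + g.size].sum()
        h += r_sum ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    ties = _tie_counts(pooled)
    correction = 1.0 - np.sum(ties ** 3 - ties) / (n ** 3 - n)
    if correction == 0.0:
        return 0.0, 1.0
    h /= correction
    p = float(sps.chi2.sf(h, df=len(arrs) - 1))
    return float(h), p


@dataclass(frozen=True)
class DunnResult:
    """One pairwise Dunn comparison.

    ``p`` is the one-sided tail probability P(Z > |z|); ``p_bonf`` and
    ``p_holm`` adjust it over all k(k−1)/2 pairs, so p ≤ p_holm ≤ p_bonf.
    """

    group_i: str
    group_j: str
    z: float
    mean_rank_i: float
    mean_rank_j: float
    p: float
    p_bonf: float
    p_holm: float


def dunn_posthoc(groups, labels: list[str] | None = None) -> list[DunnResult]:
    """Dunn's pairwise mean-rank comparisons after Kruskal–Wallis.

    z_ij = (W_i − W_j) / SE_ij with pooled mid-ranks, where
    SE_ij = sqrt[(N(N+1)/12 − T)(1/n_i + 1/n_j)] and
    T = Σ(t³−t)/(12(N−1)) corrects for ties.  When the tie-corrected variance
    vanishes (all values identical) z = 0 and p = 0.5 by the one-sided
    convention.  Bonferroni multiplies by the number of pairs; Holm applies
    the usual step-down with monotonicity enforcement.  Both clamp at 1.
    """
    arrs = _check_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    if len(labels) != len(arrs):
        raise ValueError("labels must match groups in length")
    pooled = np.concatenate(arrs)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in arrs:
        mean_ranks.append(ranks[start:start + g.size].mean())
        start += g.size
    ties = _tie_counts(pooled)
    tie_term = np.sum(ties ** 3 - ties) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(len(arrs)), 2))
    m = len(pairs)
    zs, ps = [], []
    for i, j in pairs:
        var = base_var * (1.0 / arrs[i].size + 1.0 / arrs[j].size)
        if var <= 0:
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
        zs.append(z)
        ps.append(float(sps.norm.sf(abs(z))))

    p_bonf = [min(1.0, m * p) for p in ps]
    # Holm step-down on the one-sided p-values
    order = np.argsort(ps, kind="stable")
    p_holm = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * ps[idx]))
        p_holm[idx] = running

    return [
        DunnResult(group_i=labels[i], group_j=labels[j], z=float(zs[k]),
                   mean_rank_i=float(mean_ranks[i]), mean_rank_j=float(mean_ranks[j]),
                   p=ps[k], p_bonf=p_bonf[k], p_holm=p_holm[k])
        for k, (i, j) in enumerate(pairs)
    ]


def plot_rmsd_distributions(table: BenchmarkTable, path) -> None:
    """Box-plus-strip plot of per-protocol RMSD distributions, saved to path."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = table.groups()
    fig, ax = plt.subplots(figsize=(1.8 * max(4, len(groups)), 4.5))
    names = list(groups)
    ax.boxplot([groups[p] for p in names], tick_labels=names, showfliers=False)
    rng = np.random.default_rng(0)
    for k, p in enumerate(names, start=1):
        vals = groups[p]
        jitter = rng.uniform(-0.15, 0.15, size=vals.size)
        ax.plot(k + jitter, vals, ".", alpha=0.5, markersize=4)
    ax.axhline(2.0, color="grey", linestyle="--", linewidth=1)
    ax.set_ylabel("RMSD (Å)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
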