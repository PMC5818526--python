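"""Statistical comparisons between habitat classes.

Alpha-diversity indices are compared across habitat groups with a
normality-gated procedure: one-way ANOVA plus Tukey's HSD when the
Shapiro-Wilk test on the ANOVA residuals does not reject normality
(p >= 0.05), otherwise Kruskal-Wallis followed by Dunn's pairwise tests
with Holm adjustment. Pairwise outcomes are condensed into a compact
letter display (groups sharing a letter do not differ significantly).

Beta-diversity matrices are compared with a one-factor PERMANOVA;
spatial structure is checked with Moran's I (inverse-distance weights,
Monte-Carlo permutation) and a Mantel test. All permutation p-values use
the +1 rule, p = (#{permuted >= observed} + 1) / (n_perm + 1), so p is
never zero and the tests are exactly valid under exchangeability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of one permutation test."""

    statistic_name: str
    observed: float
    p: float
    n_permutations: int
    seed: int
    r_squared: float | None = None
    null_mean: float | None = None


@dataclass(frozen=True)
class GroupComparisonResult:
    """Outcome of a gated multi-group comparison of one index."""

    index_name: str
    method: str  # "anova+tukey" | "kruskal+dunn"
    statistic: float
    p: float
    shapiro_p: float
    pairwise: pd.DataFrame = field(repr=False)  # group_a, group_b, p_adj
    letters: dict[str, str] = field(default_factory=dict)


def _compact_letter_display(
    groups: list[str], nonsignificant: set[tuple[str, str]]
) -> dict[str, str]:
    """Letters such that two groups share a letter iff their difference is
    not significant; letters are the maximal cliques of the
    'not-different' graph, ordered by first member."""
    adj = {g: {g} for g in groups}
    for a, b in nonsignificant:
        adj[a].add(b)
        adj[b].add(a)
    cliques: list[set[str]] = []
    for r in range(len(groups), 0, -1):
        for combo in itertools.combinations(groups, r):
            s = set(combo)
            if any(s <= c for c in cliques):
                continue
            if all(b in adj[a] for a, b in itertools.combinations(combo, 2)):
                cliques.append(s)
    cliques.sort(key=lambda c: min(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g] += letter
    return letters


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Dunn's z tests on rank sums with tie correction, Holm-adjusted."""
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1))
    groups = list(dict.fromkeys(labels))
    mean_rank = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    rows = []
    for a, b in itertools.combinations(groups, 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "statistic": z, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def compare_groups(
    values: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    index_name: str = "index",
    alpha: float = ALPHA,
) -> GroupComparisonResult:
    """Normality-gated multi-group comparison with pairwise letters.

    Shapiro-Wilk on the one-way ANOVA residuals decides the route:
    p >= 0.05 -> ANOVA + Tukey HSD; p < 0.05 -> Kruskal-Wallis + Dunn
    (Holm-adjusted). Requires >= 2 groups with >= 2 observations each.
    """
    values = np.asarray(values, float)
    labels = np.asarray(groups)
    group_ids = list(dict.fromkeys(labels))
    if len(group_ids) < 2:
        raise ValueError("at least 2 groups are required")
    samples = [values[labels == g] for g in group_ids]
    small = [g for g, s in zip(group_ids, samples) if len(s) < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 observations: {small}")

    residuals = np.concatenate([s - s.mean() for s in samples])
    shapiro_p = float(stats.shapiro(residuals).pvalue)

    if shapiro_p >= alpha:
        method = "anova+tukey"
        fres = stats.f_oneway(*samples)
        statistic, p = float(fres.statistic), float(fres.pvalue)
        tuk = stats.tukey_hsd(*samples)
        rows = []
        for i, j in itertools.combinations(range(len(group_ids)), 2):
            rows.append(
                {
                    "group_a": group_ids[i],
                    "group_b": group_ids[j],
                    "statistic": float(tuk.statistic[i, j]),
                    "p_raw": float(tuk.pvalue[i, j]),
                    "p_adj": float(tuk.pvalue[i, j]),  # Tukey is family-wise already
                }
            )
        pairwise = pd.DataFrame(rows)
    else:
        method = "kruskal+dunn"
        kres = stats.kruskal(*samples)
        statistic, p = float(kres.statistic), float(kres.pvalue)
        pairwise = _dunn_pairwise(values, labels)

    nonsig = {
        (r.group_a, r.group_b)
        for r in pairwise.itertuples()
        if r.p_adj >= alpha
    }
    letters = _compact_letter_display(list(group_ids), nonsig)
    return GroupComparisonResult(
        index_name=index_name,
        method=method,
        statistic=statistic,
        p=p,
        shapiro_p=shapiro_p,
        pairwise=pairwise,
        letters=letters,
    )


def _validate_distance_matrix(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(dist)) > 1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(dist < 0):
        raise ValueError("distances must be non-negative")
    return dist


def _permanova_ss(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray):
    """Within-group sum of squared distances for batched group indicators.

    ``onehot`` has shape (n_perm, n_groups, n); returns per-permutation
    SS_within (pairs within each group, divided by group size).
    """
    # sum_{i<j in g} d2 = 0.5 * 1g' D2 1g
    quad = np.einsum("pgi,ij,pgj->pg", onehot, d2, onehot)
    return 0.5 * (quad / sizes).sum(axis=1)


def permanova(
    dist: np.ndarray | pd.DataFrame,
    groups: np.ndarray | pd.Series,
    n_perm: int = 9999,
    seed: int = 0,
) -> PermutationResult:
    """One-factor PERMANOVA on a distance matrix.

    pseudo-F = (SS_among / (g - 1)) / (SS_within / (N - g)) where the sums
    of squares are computed from squared distances (SS_total over all
    pairs divided by N; SS_within over within-group pairs divided by group
    size). Significance by permuting group labels, +1 rule.
    """
    if isinstance(dist, pd.DataFrame):
        dist = dist.to_numpy()
    dist = _validate_distance_matrix(dist)
    labels = np.asarray(groups)
    n = len(labels)
    if dist.shape[0] != n:
        raise ValueError("groups length must match the distance matrix")
    group_ids, codes = np.unique(labels, return_inverse=True)
    g = len(group_ids)
    sizes = np.bincount(codes).astype(float)
    if np.any(sizes < 2):
        raise ValueError("every group needs at least 2 sites")

    d2 = dist**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def pseudo_f(code_rows: np.ndarray) -> np.ndarray:
        onehot = (code_rows[:, None, :] == np.arange(g)[None, :, None]).astype(float)
        ss_within = _permanova_ss(d2, onehot, sizes)
        ss_among = ss_total - ss_within
        # zero within-group spread gives an infinite F; it still ranks
        with np.errstate(divide="ignore", invalid="ignore"):
            return (ss_among / (g - 1)) / (ss_within / (n - g))

    f_obs = float(pseudo_f(codes[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    f_null = pseudo_f(perms)
    p = (np.count_nonzero(f_null >= f_obs) + 1) / (n_perm + 1)
    ss_within_obs = float(_permanova_ss(d2, (codes[None, None, :] == np.arange(g)[None, :, None]).astype(float), sizes)[0])
    r2 = (ss_total - ss_within_obs) / ss_total
    return PermutationResult(
        statistic_name="pseudo-F",
        observed=f_obs,
        p=float(p),
        n_permutations=n_perm,
        seed=seed,
        r_squared=float(r2),
    )


def morans_i(
    values: np.ndarray,
    coords: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
) -> PermutationResult:
    """Moran's I with inverse-distance weights and Monte-Carlo inference.

    w_ij = 1 / d_ij (w_ii = 0); I = (n / S0) * z'Wz / z'z with z the
    centered values. The two-sided Monte-Carlo p doubles the smaller tail
    (each tail with the +1 rule), capped at 1.
    """
    values = np.asarray(values, float)
    coords = np.asarray(coords, float)
    n = len(values)
    if n < 4:
        raise ValueError("Moran's I needs at least 4 sites")
    if np.ptp(values) == 0:
        raise ValueError("variable is constant")
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("duplicate coordinates give an infinite weight")
    w = np.zeros((n, n))
    w[off] = 1.0 / d[off]
    s0 = w.sum()

    def moran(z: np.ndarray) -> float:
        return float((n / s0) * (z @ w @ z) / (z @ z))

    z = values - values.mean()
    i_obs = moran(z)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = moran(rng.permutation(z))
    p_hi = (np.count_nonzero(null >= i_obs) + 1) / (n_perm + 1)
    p_lo = (np.count_nonzero(null <= i_obs) + 1) / (n_perm + 1)
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    return PermutationResult(
        statistic_name="Moran I",
        observed=i_obs,
        p=float(p),
        n_permutations=n_perm,
        seed=seed,
        null_mean=float(null.mean()),
    )


def mantel(
    dist_a: np.ndarray | pd.DataFrame,
    dist_b: np.ndarray | pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
) -> PermutationResult:
    """Mantel test: Pearson r between two distance matrices' lower
    triangles, one-sided (greater) p by permuting one matrix's site order."""
    if isinstance(dist_a, pd.DataFrame):
        dist_a = dist_a.to_numpy()
    if isinstance(dist_b, pd.DataFrame):
        dist_b = dist_b.to_numpy()
    a = _validate_distance_matrix(dist_a)
    b = _validate_distance_matrix(dist_b)
    if a.shape != b.shape:
        raise ValueError("matrices must share the same site ordering and size")
    n = a.shape[0]
    tri = np.tril_indices(n, -1)
    x = a[tri]
    if np.ptp(x) == 0 or np.ptp(b[tri]) == 0:
        raise ValueError("a matrix has a constant lower triangle")

    def corr(bm: np.ndarray) -> float:
        y = bm[tri]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        if corr(b[np.ix_(idx, idx)]) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermutationResult(
        statistic_name="Mantel r",
        observed=r_obs,
        p=float(p),
        n_permutations=n_perm,
        seed=seed,
        r_squared=float(r_obs**2),
    )
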