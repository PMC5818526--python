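"""Pairwise beta diversity with turnover/nestedness partitioning.

Taxonomic beta diversity follows Baselga's incidence-based partition:
total dissimilarity is Sorensen (beta_sor), turnover is Simpson
(beta_sim), and nestedness-resultant dissimilarity is their difference
(beta_nes = beta_sor - beta_sim).

Functional beta diversity applies the same partition to trait space. In
the default ``volume`` mode, the occupied grid cells of each community
TPD play the role of species (shared / unique cell counts feed the
Baselga formulas). The alternative ``overlap`` mode works on probability
mass: total = 1 - sum of cellwise minima, with the nested share
proportional to the asymmetry of the two communities' exclusive masses.

Bray-Curtis distances on occurrence counts support the spatial
autocorrelation checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tpd import CommunityTPD, _check_same_grid

COMPONENTS = ("total", "turnover", "nested")


@dataclass(frozen=True)
class BetaComponents:
    """One pair's dissimilarity partition: total = turnover + nested."""

    total: float
    turnover: float
    nested: float


@dataclass(frozen=True)
class BetaMatrices:
    """Symmetric site x site matrices for each partition component."""

    site_ids: tuple[str, ...]
    total: np.ndarray
    turnover: np.ndarray
    nested: np.ndarray
    flavor: str  # "taxonomic" | "functional"

    def component(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        ids = list(self.site_ids)
        return {
            c: pd.DataFrame(self.component(c), index=ids, columns=ids)
            for c in COMPONENTS
        }


def baselga_pair(a: float, b: float, c: float) -> BetaComponents:
    """Baselga partition from shared (a) and unique (b, c) element counts.

    beta_sor = (b + c) / (2a + b + c); beta_sim = min(b, c) / (a + min(b, c))
    with the 0/0 convention -> 0; beta_nes = beta_sor - beta_sim.
    Works for species counts (taxonomic) or occupied-cell counts
    (functional volume mode).
    """
    if a < 0 or b < 0 or c < 0:
        raise ValueError("a, b, c must be non-negative")
    if a + b + c == 0:
        raise ValueError("a + b + c must be positive")
    total = (b + c) / (2 * a + b + c)
    m = min(b, c)
    turnover = 0.0 if a + m == 0 else m / (a + m)
    return BetaComponents(total=total, turnover=turnover, nested=total - turnover)


def _assemble(site_ids, pair_fn, flavor) -> BetaMatrices:
    n = len(site_ids)
    mats = {c: np.zeros((n, n)) for c in COMPONENTS}
    for i in range(n):
        for j in range(i + 1, n):
            comps = pair_fn(i, j)
            for c in COMPONENTS:
                v = getattr(comps, c)
                mats[c][i, j] = mats[c][j, i] = v
    return BetaMatrices(site_ids=tuple(site_ids), flavor=flavor, **mats)


def taxonomic_beta(occurrences: pd.DataFrame) -> BetaMatrices:
    """Baselga partition of taxonomic dissimilarity for all site pairs.

    ``occurrences`` is the site x species count matrix; counts are reduced
    to presence/absence (the partition is incidence-based).
    """
    if len(occurrences) < 2:
        raise ValueError("at least 2 sites are required")
    pres = occurrences.to_numpy() > 0
    empty = ~pres.any(axis=1)
    if empty.any():
        bad = occurrences.index[empty].tolist()
        raise ValueError(f"sites with zero species present: {bad}")

    def pair(i, j):
        a = int(np.count_nonzero(pres[i] & pres[j]))
        b = int(np.count_nonzero(pres[i] & ~pres[j]))
        c = int(np.count_nonzero(~pres[i] & pres[j]))
        return baselga_pair(a, b, c)

    return _assemble(list(occurrences.index), pair, "taxonomic")


def functional_beta(tpdcs: list[CommunityTPD], mode: str = "volume") -> BetaMatrices:
    """Functional beta diversity between community TPDs.

    mode="volume" (default): occupied cells act as species in the Baselga
    partition. mode="overlap": total = 1 - sum(min(p, q)); the nested
    component is total * |P_A - P_B| / (P_A + P_B), where P_X is community
    X's probability mass on cells outside the other community's support
    (0/0 -> 0); turnover is the remainder.
    """
    if mode not in ("volume", "overlap"):
        raise ValueError(f"unknown functional beta mode: {mode!r}")
    if len(tpdcs) < 2:
        raise ValueError("at least 2 communities are required")
    _check_same_grid(*tpdcs)
    supports = [t.support for t in tpdcs]

    def pair_volume(i, j):
        si, sj = supports[i], supports[j]
        a = int(np.count_nonzero(si & sj))
        b = int(np.count_nonzero(si & ~sj))
        c = int(np.count_nonzero(~si & sj))
        return baselga_pair(a, b, c)

    def pair_overlap(i, j):
        p, q = tpdcs[i].probabilities, tpdcs[j].probabilities
        total = 1.0 - float(np.minimum(p, q).sum())
        pa = float(p[~supports[j]].sum())  # i's mass outside j's support
        pb = float(q[~supports[i]].sum())
        denom = pa + pb
        nested = 0.0 if denom == 0 else total * abs(pa - pb) / denom
        return BetaComponents(total=total, turnover=total - nested, nested=nested)

    pair = pair_volume if mode == "volume" else pair_overlap
    return _assemble([t.site_id for t in tpdcs], pair, "functional")


def bray_curtis(occurrences: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis distance matrix on occurrence counts.

    BC(x, y) = 1 - 2 * sum(min(x, y)) / (sum(x) + sum(y)); undefined when
    both sites are empty.
    """
    counts = occurrences.to_numpy(float)
    if np.any(counts < 0):
        raise ValueError("occurrence counts must be non-negative")
    n = len(occurrences)
    d = np.zeros((n, n))
    totals = counts.sum(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            denom = totals[i] + totals[j]
            if denom == 0:
                raise ValueError(
                    f"Bray-Curtis undefined: sites "
                    f"{occurrences.index[i]!r} and {occurrences.index[j]!r} are both empty"
                )
            shared = np.minimum(counts[i], counts[j]).sum()
            d[i, j] = d[j, i] = 1.0 - 2.0 * shared / denom
    return pd.DataFrame(d, index=occurrences.index, columns=occurrences.index)
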