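"""Overlap statistics: one-sided hypergeometric tests, odds ratios, FDR, batches.

The basic object is the 2x2 overlap table between two gene sets drawn from
a universe of N genes:

    a = k          (in both)         b = n1 - k   (set 1 only)
    c = n2 - k     (set 2 only)      d = N - n1 - n2 + k  (neither)

The p-value is the upper tail of the hypergeometric distribution,
P(X >= k) with population N, n1 successes and n2 draws — a one-sided
overrepresentation test ("a larger intersection than expected by chance").
The odds ratio reported by default is the sample cross-product ratio
a*d / (b*c); the conditional maximum-likelihood estimate used by some
Fisher-test implementations is available via ``or_estimator="conditional"``.

Batch analyses (one overlap test per node's HCT set) adjust p-values with
Benjamini–Hochberg across all nodes of the batch in a single call.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .consensome import HCTSet
from .genesets import GeneSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    """One 2x2 overlap test: counts, odds ratio, one-sided p, optional q."""

    k: int
    n1: int
    n2: int
    N: int
    odds_ratio: float
    p: float
    q: float | None = None
    or_infinite: bool = False

    @property
    def table(self) -> tuple[int, int, int, int]:
        """Cells (a, b, c, d) of the 2x2 table."""
        return (
            self.k,
            self.n1 - self.k,
            self.n2 - self.k,
            self.N - self.n1 - self.n2 + self.k,
        )


def _as_keys(s: GeneSet | Iterable[str]) -> frozenset[str]:
    if isinstance(s, GeneSet):
        return s.join_keys
    if isinstance(s, HCTSet):
        return frozenset(str(g).strip().upper() for g in s.genes)
    return frozenset(str(g).strip().upper() for g in s)


def sample_odds_ratio(k: int, n1: int, n2: int, N: int) -> tuple[float, bool]:
    """Cross-product odds ratio a*d/(b*c); (0, False) at k = 0, (inf, True)
    when a margin is exhausted with k > 0."""
    a, b, c, d = k, n1 - k, n2 - k, N - n1 - n2 + k
    if a == 0:
        return 0.0, False
    if b * c == 0:
        return math.inf, True
    return (a * d) / (b * c), False


def overlap_from_counts(
    k: int, n1: int, n2: int, N: int, or_estimator: str = "sample"
) -> OverlapResult:
    """Overlap test from the four margins alone."""
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ValueError(f"set sizes n1={n1}, n2={n2} exceed universe N={N}")
    if not (max(0, n1 + n2 - N) <= k <= min(n1, n2)):
        raise ValueError(
            f"overlap k={k} impossible for margins n1={n1}, n2={n2}, N={N}"
        )
    p = float(stats.hypergeom.sf(k - 1, N, n1, n2))
    if or_estimator == "sample":
        or_, infinite = sample_odds_ratio(k, n1, n2, N)
    elif or_estimator == "conditional":
        a, b, c, d = k, n1 - k, n2 - k, N - n1 - n2 + k
        or_ = float(stats.contingency.odds_ratio([[a, b], [c, d]]).statistic)
        infinite = math.isinf(or_)
    else:
        raise ValueError(f"unknown or_estimator {or_estimator!r}")
    return OverlapResult(k=k, n1=n1, n2=n2, N=N, odds_ratio=or_, p=p,
                         or_infinite=infinite)


def overlap_test(
    set1: GeneSet | Iterable[str],
    set2: GeneSet | Iterable[str],
    universe: int,
    or_estimator: str = "sample",
) -> OverlapResult:
    """One-sided overrepresentation test between two gene sets.

    Symbols are compared on their case-normalized keys, so a mouse set and
    a pre-mapped human set can be intersected directly.  Symmetric in its
    two set arguments.
    """
    keys1, keys2 = _as_keys(set1), _as_keys(set2)
    k = len(keys1 & keys2)
    n1, n2 = len(keys1), len(keys2)
    if universe < len(keys1 | keys2):
        raise ValueError(
            f"universe {universe} smaller than the union of the sets "
            f"({len(keys1 | keys2)})"
        )
    return overlap_from_counts(k, n1, n2, universe, or_estimator=or_estimator)


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bky_reject(pvalues: Sequence[float] | np.ndarray, fdr: float = 0.10) -> np.ndarray:
    """Rejection flags of the two-stage adaptive linear step-up procedure
    (Benjamini, Krieger & Yekutieli 2006) at FDR level ``fdr``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=fdr, method="fdr_tsbky")[0]


def hct_intersection_analysis(
    query: GeneSet,
    hcts: Mapping[str, HCTSet],
    universe: int = 30000,
    annotations: Mapping[str, dict] | None = None,
    or_estimator: str = "sample",
) -> pd.DataFrame:
    """Overlap of a query gene set with every node's HCT set, FDR across nodes.

    Returns one row per node with the 2x2 counts, odds ratio, one-sided p,
    Benjamini–Hochberg q computed across all nodes of the batch, and
    significance flags at q < 0.05 and q < 0.01, sorted by ascending
    (q, p).  A failing node-level test is reported in the ``error`` column
    without aborting the batch.
    """
    if len(hcts) == 0:
        raise ValueError("no HCT sets supplied")
    if len(query) == 0:
        raise ValueError("query gene set is empty")
    annotations = annotations or {}
    rows = []
    for node in sorted(hcts):
        ann = dict(annotations.get(node, {}))
        row = {
            "node": node,
            "category": ann.get("category", ""),
            "class": ann.get("class", ""),
            "family": ann.get("family", ""),
        }
        try:
            res = overlap_test(query, hcts[node], universe,
                               or_estimator=or_estimator)
            row.update(
                k=res.k, n1=res.n1, n2=res.n2, N=res.N,
                odds_ratio=res.odds_ratio, p=res.p, error="",
            )
        except ValueError as exc:
            log.warning("node %s: overlap test failed: %s", node, exc)
            row.update(k=np.nan, n1=len(query), n2=len(hcts[node]),
                       N=universe, odds_ratio=np.nan, p=np.nan,
                       error=str(exc))
        rows.append(row)
    tab = pd.DataFrame(rows)
    ok = tab["p"].notna()
    tab["q"] = np.nan
    if ok.any():
        tab.loc[ok, "q"] = bh_fdr(tab.loc[ok, "p"].to_numpy())
    tab["sig05"] = tab["q"] < 0.05
    tab["sig01"] = tab["q"] < 0.01
    tab = tab.sort_values(["q", "p", "node"], kind="mergesort").reset_index(drop=True)
    tab.attrs["universe"] = universe
    tab.attrs["cutoff"] = next(iter(hcts.values())).cutoff
    return tab


def phenotype_node_enrichment(
    significant_nodes: Iterable[str],
    node_universe: Iterable[str],
    phenotype_genes: GeneSet | Iterable[str],
) -> OverlapResult:
    """Overrepresentation of phenotype-annotated genes among significant nodes.

    Nodes are matched to phenotype annotations through the genes encoding
    them (case-normalized symbols).  N is the number of tested nodes, n1
    the significant nodes, n2 the tested nodes whose encoding gene carries
    the phenotype annotation.
    """
    universe_keys = _as_keys(node_universe)
    sig_keys = _as_keys(significant_nodes)
    stray = sig_keys - universe_keys
    if stray:
        raise ValueError(f"nodes not in the tested universe: {sorted(stray)[:5]}")
    pheno_keys = _as_keys(phenotype_genes)
    n2_keys = universe_keys & pheno_keys
    return overlap_from_counts(
        k=len(sig_keys & n2_keys),
        n1=len(sig_keys),
        n2=len(n2_keys),
        N=len(universe_keys),
    )


@dataclass(frozen=True)
class DoubleLogPoint:
    """Scatter coordinates x = log10(OR), y = log10(-log10 p)."""

    x: float
    y: float
    plottable: bool
    note: str = ""


def doublelog_coords(
    odds_ratio: float, p: float, p_floor: float = 1e-300
) -> DoubleLogPoint:
    """Double-log coordinates used to spread points over a huge p-value range.

    Points with p >= 0.999 or OR = 0 have no finite coordinates and are
    returned flagged as unplottable rather than dropped; p = 0 is clipped
    to ``p_floor`` and flagged.
    """
    if odds_ratio < 0:
        raise ValueError(f"odds ratio must be >= 0, got {odds_ratio}")
    if not (0 <= p <= 1):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    note = ""
    if p == 0:
        p = p_floor
        note = f"p clipped to {p_floor:g}"
    if p >= 0.999 or odds_ratio == 0:
        return DoubleLogPoint(math.nan, math.nan, False,
                              note or "p ~ 1 or OR = 0")
    x = math.log10(odds_ratio)
    y = math.log10(-math.log10(p))
    return DoubleLogPoint(x, y, True, note)


def write_intersection_table(tab: pd.DataFrame, path) -> None:
    """Write an HCT-intersection table with a provenance header comment."""
    with open(path, "w") as fh:
        fh.write(
            f"# universe={tab.attrs.get('universe', 'NA')} "
            f"hct_cutoff={tab.attrs.get('cutoff', 'NA')}\n"
        )
        tab.to_csv(fh, sep="\t", index=False)
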