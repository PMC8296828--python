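"""Consensomes: per-node ranked target-gene lists from ChIP-Seq peak strengths.

A consensome summarizes, for one signaling-pathway node (typically a
transcription factor used as ChIP immunoprecipitation antigen), the
regulatory evidence for every gene: the mean peak strength across all of
that node's datasets, the resulting rank (1 = strongest) and a percentile.
Genes at or above a cutoff percentile (default 95) form the node's
high-confidence transcriptional targets (HCTs).

Averaging convention: a (dataset, gene) pair with no record contributes
strength 0 to that gene's mean, i.e. the mean is the sum of recorded
strengths divided by the node's dataset count.  Genes whose mean strength
is 0 are excluded from the ranked list entirely — they are "not targeted",
not bottom-ranked.

Percentile convention: percentile = 100 * (M - rank) / M with M the number
of ranked genes, so that the top gene of 200 sits at 99.5 and "95th
percentile" means exactly the top 5% when M is divisible by 20.  Tied mean
strengths share the most favorable percentile of their tie block (and the
averaged rank), so a tie straddling the HCT boundary is included
all-or-none.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

TARGET_COLUMNS = ("dataset_id", "node", "gene", "strength")


@dataclass
class Consensome:
    """Ranked target list for one node.

    ``table`` has one row per gene with mean strength > 0, columns
    ``gene, mean_strength, rank, percentile``, sorted by ascending rank.
    """

    node: str
    table: pd.DataFrame
    n_datasets: int
    annotation: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def percentile_of(self, gene: str) -> float:
        """Percentile of ``gene`` (case-insensitive), NaN if unranked."""
        key = gene.strip().upper()
        hit = self.table.loc[self.table["gene"].str.upper() == key, "percentile"]
        return float(hit.iloc[0]) if len(hit) else float("nan")


@dataclass(frozen=True)
class HCTSet:
    """High-confidence transcriptional targets of one node."""

    node: str
    cutoff: float
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


def validate_peak_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TARGET_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peak-strength table missing columns: {missing}")
    if (table["strength"] < 0).any():
        raise ValueError("peak-strength table has negative strengths")
    if table.duplicated(subset=["dataset_id", "node", "gene"]).any():
        raise ValueError("duplicate (dataset_id, node, gene) records")
    nodes_per_ds = table.groupby("dataset_id")["node"].nunique()
    bad = nodes_per_ds[nodes_per_ds > 1]
    if len(bad):
        raise ValueError(
            f"datasets mapped to more than one node: {bad.index.tolist()[:5]}"
        )
    return table


def build_consensomes(
    table: pd.DataFrame,
    node_annotations: Mapping[str, dict] | pd.DataFrame | None = None,
) -> dict[str, Consensome]:
    """Build one :class:`Consensome` per node from a peak-strength table.

    ``node_annotations`` optionally maps node id to its pathway annotation
    (category, class, family), mirroring how an IP antigen is mapped to its
    pathway node.
    """
    if len(table) == 0:
        raise ValueError("peak-strength table is empty")
    validate_peak_table(table)
    ann: dict[str, dict] = {}
    if isinstance(node_annotations, pd.DataFrame):
        ann = {
            str(r["node"]): {
                k: r[k] for k in ("category", "class", "family") if k in r
            }
            for _, r in node_annotations.iterrows()
        }
    elif node_annotations:
        ann = {str(k): dict(v) for k, v in node_annotations.items()}

    out: dict[str, Consensome] = {}
    for node, sub in table.groupby("node", sort=True):
        n_ds = sub["dataset_id"].nunique()
        mean = sub.groupby("gene", sort=False)["strength"].sum() / n_ds
        mean = mean[mean > 0]
        if mean.empty:
            log.warning("node %s: no gene with positive mean strength", node)
            out[str(node)] = Consensome(
                node=str(node),
                table=pd.DataFrame(
                    columns=["gene", "mean_strength", "rank", "percentile"]
                ),
                n_datasets=int(n_ds),
                annotation=ann.get(str(node), {}),
            )
            continue
        m = len(mean)
        strengths = mean.to_numpy()
        # rank 1 = strongest; ties share the averaged rank for reporting and
        # the tie block's minimum rank (= maximum percentile) for thresholds
        rank_avg = rankdata(-strengths, method="average")
        rank_min = rankdata(-strengths, method="min")
        pct = 100.0 * (m - rank_min) / m
        cons = (
            pd.DataFrame(
                {
                    "gene": mean.index.to_numpy(),
                    "mean_strength": strengths,
                    "rank": rank_avg,
                    "percentile": pct,
                }
            )
            .sort_values(["rank", "gene"], kind="mergesort")
            .reset_index(drop=True)
        )
        out[str(node)] = Consensome(
            node=str(node),
            table=cons,
            n_datasets=int(n_ds),
            annotation=ann.get(str(node), {}),
        )
    return out


def extract_hcts(consensome: Consensome, cutoff: float = 95.0) -> HCTSet:
    """Genes at or above ``cutoff`` percentile of a consensome.

    Membership is percentile >= cutoff, with a floor of
    ceil((100 - cutoff)/100 * M) genes so that short lists (where even the
    top gene's percentile falls below the cutoff) still yield their top
    fraction; ties at the boundary are included all-or-none.
    """
    if not (0 < cutoff < 100):
        raise ValueError(f"cutoff must be in (0, 100), got {cutoff}")
    tab = consensome.table
    if len(tab) == 0:
        log.warning("node %s: empty consensome, empty HCT set", consensome.node)
        return HCTSet(consensome.node, cutoff, frozenset())
    m = len(tab)
    k_floor = math.ceil((100.0 - cutoff) / 100.0 * m)
    # percentile of the k_floor-th ranked gene; table is sorted by rank
    floor_pct = float(tab["percentile"].iloc[k_floor - 1])
    effective = min(cutoff, floor_pct)
    genes = frozenset(tab.loc[tab["percentile"] >= effective, "gene"])
    return HCTSet(consensome.node, cutoff, genes)


def read_ranked_targets(path: str | Path, window_kb: int | None = 5) -> pd.DataFrame:
    """Read a ranked-target TSV (``dataset_id, node, gene, strength``).

    If the file carries a ``window_kb`` column (the promoter-window
    stringency of the upstream resource: 1, 5 or 10 kb from the TSS), rows
    at other stringencies than ``window_kb`` are dropped and counted in the
    log.  Pass ``window_kb=None`` to keep all rows.
    """
    # keep_default_na: sentinel strings like "NA" must surface as parse
    # errors with a line number, not silently become missing values
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                      keep_default_na=False)
    missing = [c for c in TARGET_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns: {missing}")
    strength = pd.to_numeric(raw["strength"], errors="coerce")
    bad = strength.isna()
    if bad.any():
        # +2: header line plus 1-based indexing
        lineno = int(bad.idxmax()) + 2
        raise ValueError(
            f"{path}: line {lineno}: unparseable strength "
            f"{raw.loc[bad.idxmax(), 'strength']!r}"
        )
    table = raw.assign(strength=strength)
    if "window_kb" in table.columns and window_kb is not None:
        windows = pd.to_numeric(table["window_kb"], errors="coerce")
        keep = windows == window_kb
        dropped = int((~keep).sum())
        if dropped:
            log.info(
                "%s: dropped %d rows outside the %d kb stringency window",
                path, dropped, window_kb,
            )
        table = table.loc[keep]
    table = table[list(TARGET_COLUMNS)].reset_index(drop=True)
    return validate_peak_table(table)


def write_ranked_targets(table: pd.DataFrame, path: str | Path) -> None:
    validate_peak_table(table)
    table.to_csv(path, sep="\t", index=False, columns=list(TARGET_COLUMNS))


def write_consensomes(consensomes: Mapping[str, Consensome],
                      path: str | Path) -> None:
    """Write consensomes to one stacked TSV (node, gene, mean_strength, rank, percentile)."""
    frames = []
    for node in sorted(consensomes):
        tab = consensomes[node].table.copy()
        tab.insert(0, "node", node)
        frames.append(tab)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
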