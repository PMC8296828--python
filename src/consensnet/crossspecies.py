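"""Cross-species conservation: ortholog mapping, shared gene sets, conserved nodes.

Mouse and human gene symbols are joined through an explicit ortholog map
(one-to-many supported) on case-normalized symbols.  On top of the mapping
this module offers:

* gene-level overlap between a mouse set and a (mapped) human set, with
  the same hypergeometric statistics as any other overlap;
* enrichment of functional enzyme classes (e.g. E2 ubiquitin-conjugating,
  E3 ubiquitin ligase) within a cross-species intersection, against an
  annotated-genome universe;
* a conservation matrix comparing a gene's consensome percentile for
  orthologous nodes in both species, keeping nodes where the gene is a
  high-confidence target in at least one (or both) species;
* node-level conservation: how many of one species' significant regulators
  are also significant in the other.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .consensome import Consensome
from .enrichment import OverlapResult, overlap_from_counts, overlap_test
from .genesets import GeneSet, normalize_symbols

log = logging.getLogger(__name__)


@dataclass
class OrthologMap:
    """Directed ortholog pairs between two species.

    ``pairs`` has columns ``src_gene, dst_gene``; lookups use the
    case-normalized source symbol and return display-form targets.
    """

    pairs: pd.DataFrame
    src_species: str
    dst_species: str

    def __post_init__(self) -> None:
        missing = [c for c in ("src_gene", "dst_gene") if c not in self.pairs.columns]
        if missing:
            raise ValueError(f"ortholog map missing columns: {missing}")
        dup = self.pairs.duplicated(subset=["src_gene", "dst_gene"])
        if dup.any():
            raise ValueError("ortholog map contains duplicate pairs")
        self._lookup: dict[str, set[str]] = {}
        for src, dst in self.pairs[["src_gene", "dst_gene"]].itertuples(index=False):
            self._lookup.setdefault(str(src).strip().upper(), set()).add(str(dst))

    def __len__(self) -> int:
        return len(self.pairs)

    def targets_of(self, symbol: str) -> set[str]:
        return set(self._lookup.get(symbol.strip().upper(), set()))

    def inverted(self) -> "OrthologMap":
        inv = self.pairs.rename(
            columns={"src_gene": "dst_gene", "dst_gene": "src_gene"}
        )[["src_gene", "dst_gene"]]
        return OrthologMap(inv, self.dst_species, self.src_species)

    @classmethod
    def from_tsv(cls, path: str | Path, src_species: str,
                 dst_species: str) -> "OrthologMap":
        pairs = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        return cls(pairs, src_species, dst_species)

    def to_tsv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False,
                          columns=["src_gene", "dst_gene"])


def map_orthologs(
    genes: GeneSet,
    omap: OrthologMap,
    policy: str = "any",
) -> tuple[GeneSet, frozenset[str]]:
    """Map a gene set into the ortholog map's target species.

    Under the default ``"any"`` policy a target-species gene is included
    as soon as at least one source gene maps to it (so one-to-many
    mappings fan out).  Returns the mapped set and the source symbols that
    had no ortholog; unmapped symbols are also logged.
    """
    if policy != "any":
        raise ValueError(f"unknown mapping policy {policy!r}")
    if genes.species != omap.src_species:
        raise ValueError(
            f"gene set is {genes.species} but map source is {omap.src_species}"
        )
    mapped: set[str] = set()
    unmapped: set[str] = set()
    for sym in genes.symbols:
        targets = omap.targets_of(sym)
        if targets:
            mapped |= targets
        else:
            unmapped.add(sym)
    if unmapped:
        log.info("%d/%d symbols had no ortholog", len(unmapped), len(genes))
    return (
        GeneSet(genes.name, omap.dst_species, frozenset(mapped)),
        frozenset(unmapped),
    )


def cross_species_gene_overlap(
    set_a: GeneSet,
    set_b: GeneSet,
    omap: OrthologMap,
    universe: int = 30000,
) -> tuple[GeneSet, OverlapResult]:
    """Overlap of two gene sets from different species through an ortholog map.

    ``set_b`` is mapped into ``set_a``'s species (the map is inverted
    automatically if supplied in the opposite direction), the intersection
    is taken on normalized symbols, and the usual one-sided hypergeometric
    test is applied with the caller's universe.  The returned intersection
    keeps ``set_a``'s display spellings.
    """
    if omap.src_species != set_b.species:
        if omap.dst_species == set_b.species:
            omap = omap.inverted()
        else:
            raise ValueError(
                f"ortholog map ({omap.src_species}->{omap.dst_species}) does "
                f"not connect {set_b.species} to {set_a.species}"
            )
    mapped_b, _unmapped = map_orthologs(set_b, omap)
    inter_keys = set_a.join_keys & mapped_b.join_keys
    display = frozenset(
        s for s in set_a.symbols if s.strip().upper() in inter_keys
    )
    intersection = GeneSet(
        f"{set_a.name}&{set_b.name}", set_a.species, display
    )
    result = overlap_test(set_a, mapped_b, universe)
    return intersection, result


def enzyme_class_enrichment(
    intersection: GeneSet,
    class_annotations: pd.DataFrame,
    classes_of_interest: Iterable[str],
    universe: int = 24703,
    n_class_in_universe: int | None = None,
) -> OverlapResult:
    """Overrepresentation of functional classes within an intersection set.

    ``class_annotations`` has columns ``gene, category, class, family``
    and must cover every intersection gene.  ``n_class_in_universe`` is
    the number of class-member genes in the whole annotated universe; when
    the annotation table only covers the intersection itself it cannot be
    inferred and must be supplied for a calibrated p-value (otherwise the
    class count within the table is used, which makes k and n1 exact but
    the p-value conservative only for a table that spans the universe).
    """
    for col in ("gene", "class"):
        if col not in class_annotations.columns:
            raise ValueError(f"class-annotation table missing column {col!r}")
    ann_keys = {str(g).strip().upper() for g in class_annotations["gene"]}
    missing = intersection.join_keys - ann_keys
    if missing:
        raise KeyError(
            f"intersection genes without class annotation: {sorted(missing)[:5]}"
        )
    classes = set(classes_of_interest)
    in_class = class_annotations["class"].isin(classes)
    class_keys = {
        str(g).strip().upper()
        for g in class_annotations.loc[in_class, "gene"]
    }
    k = len(intersection.join_keys & class_keys)
    n1 = len(intersection)
    n2 = n_class_in_universe if n_class_in_universe is not None else len(class_keys)
    return overlap_from_counts(k=k, n1=n1, n2=n2, N=universe)


def _percentile_lookup(consensomes: Mapping[str, Consensome]) -> dict[str, dict[str, float]]:
    """node key -> {gene key -> percentile}, all case-normalized."""
    out: dict[str, dict[str, float]] = {}
    for node, cons in consensomes.items():
        tab = cons.table
        out[str(node).strip().upper()] = dict(
            zip(tab["gene"].str.upper(), tab["percentile"].astype(float))
        )
    return out


def conservation_matrix(
    genes: GeneSet | Sequence[str],
    mouse_consensomes: Mapping[str, Consensome],
    human_consensomes: Mapping[str, Consensome],
    omap: OrthologMap,
    cutoff: float = 95.0,
    rule: str = "any",
) -> pd.DataFrame:
    """Per-(gene, node) consensome percentiles in both species.

    For every query gene and every node present (by normalized symbol) in
    both species' consensome collections, reports the mouse and human
    percentile of the gene/its ortholog and whether each reaches the HCT
    cutoff.  Node columns are retained only where the inclusion ``rule``
    holds for at least one query gene: ``"any"`` keeps nodes where a gene
    is an HCT in at least one species, ``"both"`` requires both.  Genes
    absent from both species' consensomes yield rows flagged ``absent``.
    The rule and cutoff are recorded in ``DataFrame.attrs``.
    """
    if rule not in ("any", "both"):
        raise ValueError(f"unknown inclusion rule {rule!r}")
    symbols = list(genes.symbols) if isinstance(genes, GeneSet) else list(genes)
    m_pct = _percentile_lookup(mouse_consensomes)
    h_pct = _percentile_lookup(human_consensomes)
    shared_nodes = sorted(set(m_pct) & set(h_pct))

    rows = []
    for sym in sorted(symbols):
        key = sym.strip().upper()
        # ortholog keys on the human side (identity key counts as ortholog
        # when the map carries it; fall back to the normalized key itself)
        ortho_keys = {
            t.strip().upper() for t in omap.targets_of(sym)
        } or {key}
        for node in shared_nodes:
            mp = m_pct[node].get(key, np.nan)
            hp_candidates = [h_pct[node][t] for t in ortho_keys if t in h_pct[node]]
            hp = max(hp_candidates) if hp_candidates else np.nan
            rows.append(
                {
                    "gene": sym,
                    "node": node,
                    "mouse_percentile": mp,
                    "human_percentile": hp,
                    "mouse_hct": bool(mp >= cutoff) if not np.isnan(mp) else False,
                    "human_hct": bool(hp >= cutoff) if not np.isnan(hp) else False,
                    "absent": np.isnan(mp) and np.isnan(hp),
                }
            )
    mat = pd.DataFrame(rows)
    if len(mat):
        if rule == "any":
            keep_cell = mat["mouse_hct"] | mat["human_hct"]
        else:
            keep_cell = mat["mouse_hct"] & mat["human_hct"]
        kept_nodes = set(mat.loc[keep_cell, "node"])
        mat = mat[mat["node"].isin(kept_nodes)].reset_index(drop=True)
    mat.attrs["rule"] = rule
    mat.attrs["cutoff"] = cutoff
    return mat


def conserved_node_overlap(
    sig_nodes_a: Iterable[str],
    tested_nodes_a: Iterable[str],
    sig_nodes_b: Iterable[str],
    omap: OrthologMap,
) -> tuple[OverlapResult, frozenset[str]]:
    """Are species B's significant nodes also significant in species A?

    Species-B significant nodes are mapped into species A; orthologs never
    tested in A are excluded (and returned).  The resulting test has
    n1 = mapped-and-tested B nodes, k = those also significant in A,
    n2 = all significant A nodes, N = all tested A nodes.
    """
    tested_a = {str(n).strip().upper() for n in tested_nodes_a}
    sig_a = {str(n).strip().upper() for n in sig_nodes_a}
    if not sig_a <= tested_a:
        raise ValueError("significant species-A nodes must be among tested nodes")
    mapped_b: set[str] = set()
    for node in sig_nodes_b:
        targets = omap.targets_of(str(node))
        mapped_b |= {t.strip().upper() for t in targets} or {str(node).strip().upper()}
    untested = frozenset(mapped_b - tested_a)
    if untested:
        log.info("%d mapped nodes were not tested in species A", len(untested))
    mapped_tested = mapped_b & tested_a
    result = overlap_from_counts(
        k=len(mapped_tested & sig_a),
        n1=len(mapped_tested),
        n2=len(sig_a),
        N=len(tested_a),
    )
    return result, untested
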