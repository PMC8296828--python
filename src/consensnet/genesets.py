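"""Gene sets: derivation from differential-expression tables, GMT/TSV I/O, symbol handling.

A differential-expression (DE) table holds one row per gene with the
prone/resistant fold change (linear scale), its log2, and an unadjusted
p-value.  Weight-gain-prone ("up") and weight-gain-resistant ("down") gene
sets are derived by strict thresholds on fold change and p-value
(defaults: FC > 1.25 up, FC < 0.75 down, p < 0.05).

Gene symbols follow species case conventions (mouse Title-case, human
UPPER-case); cross-species joins always go through the case-normalized
UPPER key while display forms are preserved.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MOUSE = "mouse"
HUMAN = "human"
SPECIES = (MOUSE, HUMAN)

DE_COLUMNS = ("gene", "fc", "log2fc", "p")


def normalize_symbols(symbols: Iterable[str], species: str) -> list[str]:
    """Return canonical join keys (stripped, UPPER-case) for ``symbols``.

    The join key is species-independent so that mouse Title-case and human
    UPPER-case spellings of orthologous genes collide; display forms are
    kept by callers.  Idempotent: normalizing a normalized key is a no-op.
    """
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    return [str(s).strip().upper() for s in symbols]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols tagged with a species.

    ``symbols`` keeps the display spellings as given; ``join_keys`` exposes
    the case-normalized forms used for all overlap computations.
    """

    name: str
    species: str
    symbols: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(
                f"unknown species {self.species!r}; expected one of {SPECIES}"
            )
        object.__setattr__(self, "symbols", frozenset(self.symbols))

    @property
    def join_keys(self) -> frozenset[str]:
        return frozenset(normalize_symbols(self.symbols, self.species))

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip().upper() in self.join_keys


def validate_de_table(de: pd.DataFrame) -> pd.DataFrame:
    """Check DE-table invariants; returns the (unmodified) table.

    Requires columns ``gene, fc, log2fc, p``; fold changes strictly
    positive and consistent with their log2 within 1e-9 on the log scale;
    p-values in [0, 1]; genes unique.
    """
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    if de["gene"].duplicated().any():
        dups = de.loc[de["gene"].duplicated(), "gene"].head(5).tolist()
        raise ValueError(f"DE table has duplicate genes, e.g. {dups}")
    if (de["fc"] <= 0).any():
        raise ValueError("DE table has non-positive fold changes")
    if ((de["p"] < 0) | (de["p"] > 1)).any():
        raise ValueError("DE table has p-values outside [0, 1]")
    if not np.allclose(de["log2fc"], np.log2(de["fc"]), atol=1e-9, rtol=0.0):
        raise ValueError("log2fc column inconsistent with fc column")
    return de


def derive_de_gene_sets(
    de: pd.DataFrame,
    fc_up: float = 1.25,
    fc_down: float = 0.75,
    p_max: float = 0.05,
    species: str = MOUSE,
    name_up: str = "up",
    name_down: str = "down",
) -> tuple[GeneSet, GeneSet]:
    """Split a DE table into up- and down-regulated gene sets.

    Thresholds are strict, matching the convention "FC > 1.25, p < 0.05":
    up = {g : fc > fc_up and p < p_max}; down = {g : fc < fc_down and
    p < p_max}.  The sets are disjoint for any fc_down < fc_up.
    """
    if not (0 < fc_down < 1 < fc_up):
        raise ValueError(
            f"thresholds must satisfy 0 < fc_down < 1 < fc_up, got "
            f"fc_down={fc_down}, fc_up={fc_up}"
        )
    if not (0 < p_max <= 1):
        raise ValueError(f"p_max must be in (0, 1], got {p_max}")
    validate_de_table(de)
    sig = de["p"] < p_max
    up = frozenset(de.loc[sig & (de["fc"] > fc_up), "gene"])
    down = frozenset(de.loc[sig & (de["fc"] < fc_down), "gene"])
    return (
        GeneSet(name_up, species, up),
        GeneSet(name_down, species, down),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a DE TSV with columns ``gene, fc, log2fc, p``.

    A missing ``log2fc`` column is reconstructed from ``fc``.
    """
    de = pd.read_csv(path, sep="\t", comment="#")
    if "log2fc" not in de.columns and "fc" in de.columns:
        de["log2fc"] = np.log2(de["fc"])
    return validate_de_table(de[list(DE_COLUMNS)])


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    validate_de_table(de)
    de.to_csv(path, sep="\t", index=False, columns=list(DE_COLUMNS))


def read_gmt(path: str | Path, species: str = MOUSE) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, symbols...)."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need name, description "
                    f"and at least one symbol"
                )
            name, _desc, *symbols = fields
            if name in seen:
                raise ValueError(f"{path}: duplicate gene-set name {name!r}")
            seen.add(name)
            symbols = [s for s in symbols if s.strip()]
            if len(symbols) != len(set(symbols)):
                log.warning(
                    "%s: line %d: duplicated symbols in set %r were deduplicated",
                    path, lineno, name,
                )
            sets.append(GeneSet(name, species, frozenset(symbols)))
    if not sets:
        raise ValueError(f"{path}: empty gene-set file")
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    names = [gs.name for gs in sets]
    if len(names) != len(set(names)):
        raise ValueError("duplicate gene-set names")
    with open(path, "w") as fh:
        for gs in sets:
            desc = descriptions.get(gs.name, gs.species)
            fh.write("\t".join([gs.name, desc, *sorted(gs.symbols)]) + "\n")


def read_symbol_list(path: str | Path, name: str, species: str = MOUSE) -> GeneSet:
    """Read a one-column TSV of gene symbols into a single GeneSet."""
    with open(path) as fh:
        symbols = [line.strip() for line in fh if line.strip()]
    if not symbols:
        raise ValueError(f"{path}: empty gene-set file")
    if len(symbols) != len(set(symbols)):
        log.warning("%s: duplicated symbols were deduplicated", path)
    return GeneSet(name, species, frozenset(symbols))


def read_gene_sets(path: str | Path, fmt: str = "gmt",
                   species: str = MOUSE) -> list[GeneSet]:
    if fmt == "gmt":
        return read_gmt(path, species=species)
    if fmt == "tsv":
        return [read_symbol_list(path, name=Path(path).stem, species=species)]
    raise ValueError(f"unknown gene-set format {fmt!r}; expected 'gmt' or 'tsv'")
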