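"""Config-driven orchestration: simulate/load inputs, run every stage, manifest.

A run is described by a single mapping (typically a YAML file) holding
either a ``simulate`` block (:class:`~consensnet.synthetic.SimConfig`
fields) or paths to real input files, plus thresholds and universe sizes.
Each run writes all stage outputs into one directory together with a
``manifest.json`` recording the resolved configuration verbatim, every
output file with its SHA-256 checksum and row count, and headline
statistics (number of significant nodes, DE set sizes).  Given the same
config and seed the outputs are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import cohort as _cohort
from . import consensome as _consensome
from . import crossspecies as _crossspecies
from . import enrichment as _enrichment
from . import genesets as _genesets
from . import synthetic as _synthetic

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Validated top-level run description."""

    outdir: Path
    seed: int = 0
    simulate: _synthetic.SimConfig | None = None
    targets_path: Path | None = None
    de_path: Path | None = None
    fc_up: float = 1.25
    fc_down: float = 0.75
    p_max: float = 0.05
    hct_cutoff: float = 95.0
    q_sig: float = 0.05
    gene_universe: int = 30000
    spp_universe: int = 24703
    species: str = "mouse"

    def __post_init__(self) -> None:
        if not (0 < self.fc_down < 1 < self.fc_up):
            raise ValueError(
                f"fc_down/fc_up invalid: need 0 < fc_down < 1 < fc_up, got "
                f"fc_down={self.fc_down}, fc_up={self.fc_up}"
            )
        if not (0 < self.p_max <= 1):
            raise ValueError(f"p_max out of range: {self.p_max}")
        if not (0 < self.hct_cutoff < 100):
            raise ValueError(f"hct_cutoff out of range: {self.hct_cutoff}")
        if not (0 < self.q_sig < 1):
            raise ValueError(f"q_sig out of range: {self.q_sig}")
        if self.gene_universe < 1 or self.spp_universe < 1:
            raise ValueError("universe sizes must be positive")
        if self.simulate is None and (self.targets_path is None
                                      or self.de_path is None):
            raise ValueError(
                "either a simulate block or targets_path + de_path is required"
            )

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        seed = int(raw.get("seed", 0))
        sim_cfg = None
        if sim is not None:
            sim = dict(sim)
            sim.setdefault("seed", seed)
            try:
                sim_cfg = _synthetic.SimConfig(**sim)
            except TypeError as exc:
                raise ValueError(f"invalid simulate block: {exc}") from exc
        kwargs: dict[str, Any] = {"simulate": sim_cfg}
        for key in ("fc_up", "fc_down", "p_max", "hct_cutoff", "q_sig"):
            if key in raw:
                kwargs[key] = float(raw.pop(key))
        for key in ("gene_universe", "spp_universe", "seed"):
            if key in raw:
                kwargs[key] = int(raw.pop(key))
        for key in ("targets_path", "de_path"):
            if key in raw:
                kwargs[key] = Path(raw.pop(key))
        if "species" in raw:
            kwargs["species"] = str(raw.pop(key := "species"))
        if "outdir" not in raw:
            raise ValueError("config missing required key 'outdir'")
        kwargs["outdir"] = Path(raw.pop("outdir"))
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_mapping(raw)

    def resolved(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out["outdir"] = str(self.outdir)
        for key in ("targets_path", "de_path"):
            if out[key] is not None:
                out[key] = str(out[key])
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _count_rows(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for line in fh if line.strip() and not line.startswith("#"))


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and return the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    if config.simulate is not None:
        sim_cfg = config.simulate.replace(seed=config.seed)
        sim_paths = _synthetic.simulate_to_dir(sim_cfg, outdir / "inputs")
        files.update({f"input_{k}": v for k, v in sim_paths.items()})
        targets_path, de_path = sim_paths["targets"], sim_paths["de"]
        universe = sim_cfg.n_genes
    else:
        targets_path, de_path = config.targets_path, config.de_path
        universe = config.gene_universe

    de = _genesets.read_de_table(de_path)
    up, down = _genesets.derive_de_gene_sets(
        de, fc_up=config.fc_up, fc_down=config.fc_down, p_max=config.p_max,
        species=config.species, name_up="prone", name_down="resistant",
    )
    genesets_path = outdir / "de_gene_sets.gmt"
    _genesets.write_gmt(
        [up, down], genesets_path,
        descriptions={
            "prone": f"fc>{config.fc_up} p<{config.p_max}",
            "resistant": f"fc<{config.fc_down} p<{config.p_max}",
        },
    )
    files["de_gene_sets"] = genesets_path

    corpus = _consensome.read_ranked_targets(targets_path)
    consensomes = _consensome.build_consensomes(corpus)
    cons_path = outdir / "consensomes.tsv"
    _consensome.write_consensomes(consensomes, cons_path)
    files["consensomes"] = cons_path
    hcts = {
        node: _consensome.extract_hcts(c, cutoff=config.hct_cutoff)
        for node, c in consensomes.items()
    }

    intersections: dict[str, pd.DataFrame] = {}
    for label, query in (("prone", up), ("resistant", down)):
        if len(query) == 0:
            log.warning("%s gene set empty; skipping intersection analysis", label)
            continue
        tab = _enrichment.hct_intersection_analysis(
            query, hcts, universe=universe
        )
        path = outdir / f"hct_intersections_{label}.tsv"
        _enrichment.write_intersection_table(tab, path)
        files[f"hct_intersections_{label}"] = path
        intersections[label] = tab

    enrich_stats: dict[str, Any] = {}
    if config.simulate is not None and "prone" in intersections:
        # phenotype enrichment against the simulated annotation sets
        _omap, phenotype, _hwgbmi = _synthetic.gen_aux_maps(
            sim_cfg, _synthetic.gen_regulatory_corpus(sim_cfg)[1]
        )
        tab = intersections["prone"]
        sig_nodes = tab.loc[tab["q"] < config.q_sig, "node"].tolist()
        if sig_nodes:
            res = _enrichment.phenotype_node_enrichment(
                sig_nodes, tab["node"].tolist(), phenotype
            )
            enrich_stats["phenotype_node_enrichment"] = {
                "k": res.k, "n1": res.n1, "n2": res.n2, "N": res.N,
                # null marks an infinite cross-product OR (empty off-cell)
                "odds_ratio": res.odds_ratio if math.isfinite(res.odds_ratio)
                else None,
                "p": res.p,
            }

    manifest: dict[str, Any] = {
        "config": config.resolved(),
        "universe": universe,
        "files": {
            name: {
                "path": str(path.relative_to(outdir)),
                "sha256": _sha256(path),
                "n_rows": _count_rows(path),
            }
            for name, path in sorted(files.items())
        },
        "stats": {
            "n_up_genes": len(up),
            "n_down_genes": len(down),
            "n_nodes_tested": len(hcts),
            **{
                f"n_sig_nodes_{label}": int((tab["q"] < config.q_sig).sum())
                for label, tab in intersections.items()
            },
            **enrich_stats,
        },
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("pipeline complete: %s", manifest_path)
    return manifest
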