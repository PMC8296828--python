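"""Synthetic regulatory corpus, DE tables, ortholog/phenotype maps and cohorts.

Every input of the analysis pipeline can be generated here with known
planted structure, so each downstream stage is testable without any
external download:

* a ChIP-Seq-like peak-strength corpus: per node, a handful of datasets in
  which that node's true target genes carry log-normal peak strengths and
  a random background of other genes carries small exponential noise;
* a differential-expression table produced by simulating per-gene log2
  expression for a prone and a resistant cohort and applying Welch's
  t-test — planted "prone" genes get a positive mean log2 fold change
  (a configurable fraction of them drawn from the driver nodes' true
  targets, which is what makes the drivers recoverable downstream),
  planted "resistant" genes the mirror image, all other genes are null;
* an ortholog map (mouse Title-case <-> human UPPER-case, with optional
  dropped and one-to-many entries), a phenotype gene set overlapping the
  driver-node symbols, and a human weight/BMI-like gene set seeded from
  planted prone genes;
* a cohort table of 14-day body-weight and daily-intake trajectories with
  planted gain-prone and gain-resistant animals, and a matched qPCR Ct
  table with planted group effects.

Determinism: every generator draws from its own stream seeded as
(config seed, fixed per-generator offset), so identical config + seed
reproduce outputs exactly and adding a generator never perturbs another.

Default sizes and effect levels mirror the mouse study design this
package models: a 30,000-gene universe, 389 up- / 169 down-regulated
genes, 40 animals with 5 + 5 extreme cohorts gaining 6.3 g vs 1.3 g over
14 days, and intakes of 3.1 vs 2.6 g/day.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSet, HUMAN, MOUSE
from . import consensome as _consensome
from . import genesets as _genesets
from .crossspecies import OrthologMap

log = logging.getLogger(__name__)

# fixed per-generator sub-stream offsets
_STREAM_CORPUS = 0
_STREAM_DE = 1
_STREAM_AUX = 2
_STREAM_COHORT = 3
_STREAM_QPCR = 4

# study-scale fractions used when planted DE counts are not set explicitly
_UP_FRACTION = 389 / 30000
_DOWN_FRACTION = 169 / 30000


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic corpus.

    Counts are strictly positive; ``driver_enrichment`` is the fraction of
    planted prone genes drawn from the driver nodes' true targets;
    ``noise_sd`` scales both peak-strength dispersion (log-normal sigma,
    exponential background scale) and per-sample expression noise (log2
    units).  ``n_up_genes``/``n_down_genes`` default to the study-scale
    fractions of ``n_genes`` (389 and 169 per 30,000).
    """

    n_genes: int = 30000
    n_nodes: int = 20
    datasets_per_node: tuple[int, int] = (2, 4)
    n_driver_nodes: int = 1
    targets_per_node: int = 500
    driver_enrichment: float = 0.8
    de_effect_lfc: float = 1.0
    noise_sd: float = 0.5
    n_prone: int = 5
    n_resistant: int = 5
    seed: int = 0
    # derived-scale knobs
    n_up_genes: int | None = None
    n_down_genes: int | None = None
    background_rate: float = 0.1
    target_strength: float = 10.0
    # cohort trajectories (grams, grams/day)
    n_animals: int = 40
    prone_gain: float = 6.3
    resistant_gain: float = 1.3
    gain_sd: float = 0.3
    mid_gain: float = 3.5
    mid_gain_sd: float = 0.5
    prone_intake: float = 3.1
    resistant_intake: float = 2.6
    intake_sd: float = 0.2
    n_days: int = 14
    baseline_weight: float = 19.0
    weight_jitter: float = 0.05
    # auxiliary maps
    ortholog_drop_rate: float = 0.0
    many_to_many_rate: float = 0.0
    phenotype_overlap_rate: float = 1.0
    phenotype_background: int = 20
    hwgbmi_size: int = 157
    hwgbmi_prone_fraction: float = 0.25

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_nodes", "n_driver_nodes", "targets_per_node",
                     "n_prone", "n_resistant", "n_animals", "n_days"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        lo, hi = self.datasets_per_node
        if not (1 <= lo <= hi):
            raise ValueError(
                f"datasets_per_node must be an increasing pair >= 1, got {(lo, hi)}"
            )
        for name in ("driver_enrichment", "background_rate",
                     "ortholog_drop_rate", "many_to_many_rate",
                     "phenotype_overlap_rate", "hwgbmi_prone_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.n_driver_nodes > self.n_nodes:
            raise ValueError("n_driver_nodes cannot exceed n_nodes")
        if self.targets_per_node > self.n_genes:
            raise ValueError("targets_per_node cannot exceed n_genes")
        if self.n_prone + self.n_resistant > self.n_animals:
            raise ValueError("cohorts larger than the number of animals")
        n_up, n_down = self.planted_counts()
        if n_up + n_down > self.n_genes:
            raise ValueError("planted DE genes exceed the gene universe")

    def planted_counts(self) -> tuple[int, int]:
        n_up = self.n_up_genes
        n_down = self.n_down_genes
        if n_up is None:
            n_up = max(1, round(_UP_FRACTION * self.n_genes))
        if n_down is None:
            n_down = max(1, round(_DOWN_FRACTION * self.n_genes))
        return int(n_up), int(n_down)

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth used as the oracle by recovery tests."""

    driver_nodes: frozenset[str]
    true_targets: dict[str, frozenset[str]]
    planted_prone_genes: frozenset[str]
    planted_resistant_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.driver_nodes <= set(self.true_targets):
            raise ValueError("driver nodes must be generated nodes")
        if self.planted_prone_genes & self.planted_resistant_genes:
            raise ValueError("planted prone/resistant sets must be disjoint")


@dataclass(frozen=True)
class PlantedCohorts:
    """Which animals were drawn from which gain distribution."""

    prone: frozenset[str]
    resistant: frozenset[str]


def _rng(cfg: SimConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), offset])


def gene_universe(cfg: SimConfig) -> list[str]:
    """Mouse-convention (Title-case) synthetic gene symbols."""
    width = max(5, len(str(cfg.n_genes)))
    return [f"Simg{i:0{width}d}" for i in range(cfg.n_genes)]


# ---------------------------------------------------------------------------
# regulatory corpus
# ---------------------------------------------------------------------------

def gen_regulatory_corpus(cfg: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-(dataset, node, gene) peak strengths plus the planted truth.

    True targets draw log-normal strengths centred on
    ``target_strength`` with sigma ``noise_sd`` in every dataset of their
    node; a ``background_rate`` fraction of the other genes draws small
    exponential noise (scale ``noise_sd``) per dataset.  Planted DE gene
    sets are fixed here too (they depend on the driver targets), so the
    whole truth object is available before any expression is simulated.
    """
    rng = _rng(cfg, _STREAM_CORPUS)
    genes = np.array(gene_universe(cfg))
    nodes = rng.choice(genes, size=cfg.n_nodes, replace=False)
    drivers = frozenset(nodes[: cfg.n_driver_nodes])

    lo, hi = cfg.datasets_per_node
    records: list[pd.DataFrame] = []
    true_targets: dict[str, frozenset[str]] = {}
    n_bg = int(round(cfg.background_rate * cfg.n_genes))
    for node in nodes:
        targets = rng.choice(genes, size=cfg.targets_per_node, replace=False)
        true_targets[str(node)] = frozenset(targets)
        non_targets = np.setdiff1d(genes, targets, assume_unique=False)
        n_ds = int(rng.integers(lo, hi + 1))
        for j in range(n_ds):
            ds_id = f"{node}_ds{j}"
            t_strength = rng.lognormal(
                mean=np.log(cfg.target_strength), sigma=cfg.noise_sd,
                size=len(targets),
            )
            frames = [
                pd.DataFrame(
                    {"dataset_id": ds_id, "node": str(node),
                     "gene": targets, "strength": t_strength}
                )
            ]
            if n_bg and len(non_targets):
                bg_genes = rng.choice(
                    non_targets, size=min(n_bg, len(non_targets)), replace=False
                )
                bg_strength = rng.exponential(scale=cfg.noise_sd,
                                              size=len(bg_genes))
                frames.append(
                    pd.DataFrame(
                        {"dataset_id": ds_id, "node": str(node),
                         "gene": bg_genes, "strength": bg_strength}
                    )
                )
            records.extend(frames)
    table = pd.concat(records, ignore_index=True)

    # plant the DE gene sets: a driver_enrichment fraction of prone genes
    # comes from the union of driver-node true targets
    n_up, n_down = cfg.planted_counts()
    driver_pool = np.array(
        sorted(set().union(*(true_targets[d] for d in drivers)))
    )
    n_from_drivers = min(round(cfg.driver_enrichment * n_up), len(driver_pool))
    from_drivers = rng.choice(driver_pool, size=n_from_drivers, replace=False)
    rest_pool = np.setdiff1d(genes, from_drivers)
    rest = rng.choice(rest_pool, size=n_up - n_from_drivers, replace=False)
    prone = frozenset(map(str, np.concatenate([from_drivers, rest])))
    down_pool = np.setdiff1d(genes, np.array(sorted(prone)))
    resistant = frozenset(
        map(str, rng.choice(down_pool, size=n_down, replace=False))
    )
    truth = SyntheticTruth(
        driver_nodes=frozenset(map(str, drivers)),
        true_targets=true_targets,
        planted_prone_genes=prone,
        planted_resistant_genes=resistant,
    )
    return table, truth


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def gen_de_table(cfg: SimConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Simulate a two-cohort DE table by per-gene Welch t-tests.

    Each gene's log2 expression is drawn for ``n_prone`` prone and
    ``n_resistant`` resistant samples around +/- half its planted log2
    fold change (``de_effect_lfc`` for prone genes, the negative for
    resistant genes, 0 for null genes) with per-sample noise ``noise_sd``.
    The reported fold change is the realized group difference and the
    p-value the Welch two-sided p — so in null mode
    (``de_effect_lfc = 0``) p-values are uniform by construction.
    """
    genes = gene_universe(cfg)
    universe = set(genes)
    planted = truth.planted_prone_genes | truth.planted_resistant_genes
    if not planted <= universe:
        raise ValueError("truth genes are not drawn from this config's universe")
    if cfg.n_prone < 2 or cfg.n_resistant < 2:
        raise ValueError("need at least two samples per cohort for a t-test")
    rng = _rng(cfg, _STREAM_DE)
    mu = np.zeros(len(genes))
    idx = {g: i for i, g in enumerate(genes)}
    for g in truth.planted_prone_genes:
        mu[idx[g]] = cfg.de_effect_lfc
    for g in truth.planted_resistant_genes:
        mu[idx[g]] = -cfg.de_effect_lfc
    prone_mat = rng.normal(loc=mu / 2.0, scale=cfg.noise_sd,
                           size=(cfg.n_prone, len(genes)))
    res_mat = rng.normal(loc=-mu / 2.0, scale=cfg.noise_sd,
                         size=(cfg.n_resistant, len(genes)))
    lfc = prone_mat.mean(axis=0) - res_mat.mean(axis=0)
    test = stats.ttest_ind(prone_mat, res_mat, axis=0, equal_var=False)
    de = pd.DataFrame(
        {
            "gene": genes,
            "fc": 2.0 ** lfc,
            "log2fc": lfc,
            "p": test.pvalue,
        }
    )
    return _genesets.validate_de_table(de)


# ---------------------------------------------------------------------------
# auxiliary maps and gene sets
# ---------------------------------------------------------------------------

def gen_aux_maps(
    cfg: SimConfig, truth: SyntheticTruth
) -> tuple[OrthologMap, GeneSet, GeneSet]:
    """Ortholog map, phenotype gene set and a human weight/BMI-like set.

    The ortholog map is identity-up-to-case (mouse Title-case to human
    UPPER-case) with ``ortholog_drop_rate`` of entries removed and
    ``many_to_many_rate`` of the remainder duplicated to a second,
    paralog-like human symbol.  The phenotype set contains a
    ``phenotype_overlap_rate`` fraction of the driver-node symbols plus
    ``phenotype_background`` other genes.  The human set contains
    orthologs of a ``hwgbmi_prone_fraction`` of its ``hwgbmi_size``
    members drawn from the planted prone genes, the rest from non-planted
    genes.
    """
    rng = _rng(cfg, _STREAM_AUX)
    genes = np.array(gene_universe(cfg))

    n_drop = int(round(cfg.ortholog_drop_rate * len(genes)))
    dropped = set(map(str, rng.choice(genes, size=n_drop, replace=False)))
    kept = [g for g in genes if g not in dropped]
    pairs = pd.DataFrame(
        {"src_gene": kept, "dst_gene": [g.upper() for g in kept]}
    )
    n_multi = int(round(cfg.many_to_many_rate * len(kept)))
    if n_multi:
        multi_src = rng.choice(np.array(kept), size=n_multi, replace=False)
        extra = pd.DataFrame(
            {"src_gene": multi_src,
             "dst_gene": [f"{g.upper()}L1" for g in multi_src]}
        )
        pairs = pd.concat([pairs, extra], ignore_index=True)
    omap = OrthologMap(pairs, src_species=MOUSE, dst_species=HUMAN)

    drivers = sorted(truth.driver_nodes)
    n_in = int(round(cfg.phenotype_overlap_rate * len(drivers)))
    in_drivers = list(map(str, rng.choice(np.array(drivers), size=n_in,
                                          replace=False))) if n_in else []
    bg_pool = np.setdiff1d(genes, np.array(drivers))
    n_bg = min(cfg.phenotype_background, len(bg_pool))
    background = list(map(str, rng.choice(bg_pool, size=n_bg, replace=False)))
    phenotype = GeneSet(
        "synthetic_phenotype", MOUSE, frozenset(in_drivers + background)
    )

    prone = np.array(sorted(truth.planted_prone_genes))
    size = min(cfg.hwgbmi_size, len(genes))
    n_from_prone = min(int(round(cfg.hwgbmi_prone_fraction * size)), len(prone))
    from_prone = rng.choice(prone, size=n_from_prone, replace=False)
    other_pool = np.setdiff1d(genes, prone)
    others = rng.choice(other_pool, size=size - n_from_prone, replace=False)
    hwgbmi = GeneSet(
        "synthetic_hwg_bmi", HUMAN,
        frozenset(str(g).upper() for g in np.concatenate([from_prone, others])),
    )
    return omap, phenotype, hwgbmi


# ---------------------------------------------------------------------------
# cohort trajectories and qPCR
# ---------------------------------------------------------------------------

def gen_cohort_phenotypes(cfg: SimConfig) -> tuple[pd.DataFrame, PlantedCohorts]:
    """Body-weight and intake trajectories with planted gain groups.

    ``n_prone`` animals draw their total 14-day gain from
    N(prone_gain, gain_sd), ``n_resistant`` from N(resistant_gain,
    gain_sd) and the remainder from N(mid_gain, mid_gain_sd); weights
    interpolate linearly from a ~19 g baseline with per-day jitter.
    Intake rows cover days 1..n_days (no day-0 intake), weights days
    0..n_days.
    """
    rng = _rng(cfg, _STREAM_COHORT)
    n = cfg.n_animals
    ids = np.array([f"m{i:03d}" for i in range(1, n + 1)])
    shuffled = rng.permutation(ids)
    prone_ids = set(shuffled[: cfg.n_prone])
    resistant_ids = set(shuffled[cfg.n_prone: cfg.n_prone + cfg.n_resistant])

    rows = []
    for aid in ids:
        if aid in prone_ids:
            gain = rng.normal(cfg.prone_gain, cfg.gain_sd)
            intake_mu = cfg.prone_intake
        elif aid in resistant_ids:
            gain = rng.normal(cfg.resistant_gain, cfg.gain_sd)
            intake_mu = cfg.resistant_intake
        else:
            gain = rng.normal(cfg.mid_gain, cfg.mid_gain_sd)
            intake_mu = (cfg.prone_intake + cfg.resistant_intake) / 2.0
        w0 = rng.normal(cfg.baseline_weight, 0.5)
        for day in range(cfg.n_days + 1):
            weight = w0 + gain * day / cfg.n_days
            if 0 < day < cfg.n_days:
                weight += rng.normal(0.0, cfg.weight_jitter)
            intake = (
                rng.normal(intake_mu, cfg.intake_sd) if day >= 1 else np.nan
            )
            rows.append(
                {"animal_id": aid, "day": day,
                 "body_weight": max(weight, 1e-6), "intake": intake}
            )
    table = pd.DataFrame(rows)
    return table, PlantedCohorts(frozenset(map(str, prone_ids)),
                                 frozenset(map(str, resistant_ids)))


DEFAULT_QPCR_EFFECTS = {
    # planted log2 prone/resistant expression ratios of appetite genes
    "Agrp": 1.5, "Hcrt": 1.0, "Pmch": 1.0, "Pomc": -1.0, "Cartpt": -0.8,
}
QPCR_HOUSEKEEPING = ("Pgk1", "Hprt")


def gen_qpcr_table(
    cfg: SimConfig,
    effects: Mapping[str, float] | None = None,
    housekeeping: Sequence[str] = QPCR_HOUSEKEEPING,
    ct_sd: float = 0.1,
) -> pd.DataFrame:
    """Long-format qPCR Ct table for the two extreme cohorts.

    ``effects`` maps target gene -> planted log2 prone/resistant
    expression ratio; higher expression means a lower Ct, so a prone
    sample's target Ct is reduced by the effect.  Housekeeping genes sit
    near Ct 20, targets near Ct 25, all with ``ct_sd`` technical noise.
    """
    effects = dict(DEFAULT_QPCR_EFFECTS if effects is None else effects)
    rng = _rng(cfg, _STREAM_QPCR)
    rows = []
    samples = [(f"P{i+1}", "prone") for i in range(cfg.n_prone)] + [
        (f"R{i+1}", "resistant") for i in range(cfg.n_resistant)
    ]
    for sample_id, group in samples:
        for hk in housekeeping:
            rows.append(
                {"sample_id": sample_id, "group": group, "gene": hk,
                 "ct": rng.normal(20.0, ct_sd)}
            )
        for gene, lfc in effects.items():
            shift = -lfc / 2.0 if group == "prone" else lfc / 2.0
            rows.append(
                {"sample_id": sample_id, "group": group, "gene": gene,
                 "ct": rng.normal(25.0 + shift, ct_sd)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization of a full simulated input bundle
# ---------------------------------------------------------------------------

def simulate_to_dir(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write every simulated pipeline input under ``outdir``.

    Produces ranked-target TSV, DE TSV, ortholog TSV, phenotype and
    human-set GMTs, cohort CSV, qPCR CSV and a JSON record of the planted
    truth; returns the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corpus, truth = gen_regulatory_corpus(cfg)
    de = gen_de_table(cfg, truth)
    omap, phenotype, hwgbmi = gen_aux_maps(cfg, truth)
    cohort_table, planted = gen_cohort_phenotypes(cfg)
    qpcr = gen_qpcr_table(cfg)

    paths = {
        "targets": outdir / "ranked_targets.tsv",
        "de": outdir / "de_table.tsv",
        "orthologs": outdir / "orthologs.tsv",
        "gene_sets": outdir / "aux_gene_sets.gmt",
        "cohort": outdir / "cohort.csv",
        "qpcr": outdir / "qpcr.csv",
        "truth": outdir / "truth.json",
    }
    _consensome.write_ranked_targets(corpus, paths["targets"])
    _genesets.write_de_table(de, paths["de"])
    omap.to_tsv(paths["orthologs"])
    _genesets.write_gmt([phenotype, hwgbmi], paths["gene_sets"])
    cohort_table.to_csv(paths["cohort"], index=False)
    qpcr.to_csv(paths["qpcr"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "driver_nodes": sorted(truth.driver_nodes),
                "true_targets": {
                    n: sorted(t) for n, t in sorted(truth.true_targets.items())
                },
                "planted_prone_genes": sorted(truth.planted_prone_genes),
                "planted_resistant_genes": sorted(truth.planted_resistant_genes),
                "planted_prone_animals": sorted(planted.prone),
                "planted_resistant_animals": sorted(planted.resistant),
            },
            fh, indent=1, sort_keys=True,
        )
    return paths
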