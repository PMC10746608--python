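"""Seeded synthetic scenarios with planted signal, for end-to-end validation.

The generator emulates the statistical structure the pipeline assumes: a
background universe of gene symbols, a TF catalog, a ChIP-seq-style
TF-target library (several experiment sets per TF), pathway libraries, a
selected-gene list in which the planted core TFs are both members and
upstream regulators of many other members, and an interaction table with a
planted hub.  Ground truth (planted TFs, planted pathways, planted hub) is
returned alongside, so recovery and calibration are exactly measurable.

Symbols are synthetic (``TF0001``, ``G000001``, ...) and carry no real gene
semantics.  Sampling order is fixed (universe, TF target sets in TF order,
pathways, selected list, interactions) so that one seed always yields the
same artifacts, byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np

from .io import (
    GeneList,
    GeneSet,
    GeneSetLibrary,
    InteractionTable,
    TFCatalog,
    write_gene_list,
    write_gmt,
    write_interactions,
)

__all__ = [
    "ScenarioParams",
    "SyntheticScenario",
    "generate_scenario",
    "strong_params",
    "null_params",
]


@dataclass(frozen=True)
class ScenarioParams:
    """Generator knobs.  Defaults are the "strong" preset: a universe of
    22,000 genes (the usual protein-coding count), five planted core TFs
    with 300-gene target sets, a 200-gene selected list with ten-fold
    over-representation of planted targets, and a planted interaction hub.
    """

    universe_size: int = 22000
    n_tfs: int = 60
    n_planted_core_tfs: int = 5
    n_experiments_per_tf: tuple[int, int] = (1, 3)
    target_set_size: tuple[int, int] = (200, 400)
    planted_target_set_size: int = 300
    n_pathways: int = 50
    n_planted_pathways: int = 3
    pathway_size: tuple[int, int] = (50, 300)
    planted_pathway_size: int = 100
    selected_list_size: int = 200
    enrichment_strength: float = 10.0
    ppi_density: float = 0.05
    hub_connect_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.n_tfs + self.n_planted_core_tfs > self.universe_size:
            raise ValueError("TF catalog does not fit in the universe")
        if self.selected_list_size > self.universe_size:
            raise ValueError("selected list larger than the universe")
        if self.n_planted_core_tfs > min(self.n_tfs, self.selected_list_size):
            raise ValueError("planted core TFs must fit in catalog and selected list")
        if self.enrichment_strength < 1:
            raise ValueError("enrichment_strength must be >= 1")
        if max(self.target_set_size[1], self.pathway_size[1],
               self.planted_target_set_size) > self.universe_size:
            raise ValueError("set sizes exceed the universe")
        if not (0 <= self.ppi_density <= 1 and 0 <= self.hub_connect_fraction <= 1):
            raise ValueError("densities must be probabilities")


def strong_params(**overrides) -> ScenarioParams:
    """The strong-signal preset (the defaults)."""
    return ScenarioParams(**overrides)


def null_params(**overrides) -> ScenarioParams:
    """A reduced no-signal scenario for type-I calibration: universe 2,000,
    50 decoy TFs with one 50-gene experiment each, a uniformly drawn
    100-gene selected list, and nothing planted."""
    base = dict(
        universe_size=2000,
        n_tfs=50,
        n_planted_core_tfs=0,
        n_experiments_per_tf=(1, 1),
        target_set_size=(50, 50),
        planted_target_set_size=50,
        n_pathways=20,
        n_planted_pathways=0,
        pathway_size=(20, 100),
        planted_pathway_size=50,
        selected_list_size=100,
        enrichment_strength=1.0,
    )
    base.update(overrides)
    return ScenarioParams(**base)


@dataclass(frozen=True)
class SyntheticScenario:
    """All five generated input artifacts plus the planted ground truth."""

    params: ScenarioParams
    seed: int
    universe: tuple[str, ...]
    catalog: TFCatalog
    tf_library: GeneSetLibrary
    pathway_library: GeneSetLibrary
    selected_genes: GeneList
    interactions: InteractionTable
    ground_truth: dict = field(default_factory=dict)

    @property
    def planted_core_tfs(self) -> tuple[str, ...]:
        return tuple(self.ground_truth.get("planted_core_tfs", ()))

    @property
    def planted_hub(self) -> Optional[str]:
        return self.ground_truth.get("planted_hub")

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the five artifacts (plus ground truth) as the plain-text
        formats the readers consume; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "selected_genes": out / "selected_genes.txt",
            "tf_catalog": out / "tf_catalog.txt",
            "tf_targets": out / "tf_targets.gmt",
            "pathways": out / "pathways.gmt",
            "interactions": out / "interactions.tsv",
            "universe": out / "universe.txt",
            "ground_truth": out / "ground_truth.json",
        }
        write_gene_list(self.selected_genes, paths["selected_genes"])
        write_gene_list(sorted(self.catalog.symbols), paths["tf_catalog"])
        write_gmt(self.tf_library, paths["tf_targets"])
        write_gmt(self.pathway_library, paths["pathways"])
        write_interactions(self.interactions, paths["interactions"])
        write_gene_list(list(self.universe), paths["universe"])
        paths["ground_truth"].write_text(
            json.dumps(
                {**self.ground_truth, "seed": self.seed,
                 "params": dataclasses.asdict(self.params)},
                indent=2, sort_keys=True, default=list,
            ) + "\n"
        )
        return paths


@lru_cache(maxsize=8)
def _universe_symbols(n_tfs: int, universe_size: int) -> tuple[str, ...]:
    tfs = tuple(f"TF{i + 1:04d}" for i in range(n_tfs))
    genes = tuple(f"G{i + 1:06d}" for i in range(universe_size - n_tfs))
    return tfs + genes


def generate_scenario(
    params: Optional[ScenarioParams] = None,
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
) -> SyntheticScenario:
    """Generate one complete scenario; deterministic given (params, seed).

    Construction, in fixed order:

    1. Universe: the TF symbols followed by filler gene symbols.
    2. TF-target library: per TF (planted TFs first), a number of
       experiment sets drawn uniformly in ``n_experiments_per_tf``, each a
       uniform without-replacement draw from the universe (planted TFs use
       ``planted_target_set_size``, decoys a uniform size in
       ``target_set_size``).  No TF's targets get preferential treatment
       here — the planted signal lives entirely in the selected list.
    3. Pathway library: ``n_planted_pathways`` sets drawn from the union of
       planted TFs' targets (so they end up enriched in every planted TF's
       target list), the rest uniform decoys.
    4. Selected list: the planted core TFs themselves, then a mixture in
       which a gene comes from the planted target union with probability
       ``enrichment_strength`` times that union's base rate (binomially
       many), the rest uniform outside the union.  At strength exactly 1
       the list is drawn uniformly from the universe.
    5. Interactions: Erdős–Rényi edges among catalog TFs at ``ppi_density``,
       plus the planted hub (the first planted TF) wired to
       ``hub_connect_fraction`` of the other TFs.
    """
    p = params if params is not None else ScenarioParams()
    rng = np.random.default_rng(seed)
    universe = _universe_symbols(p.n_tfs, p.universe_size)
    uni_arr = np.array(universe)
    tf_symbols = universe[: p.n_tfs]
    planted = tuple(tf_symbols[: p.n_planted_core_tfs])
    catalog = TFCatalog(symbols=frozenset(tf_symbols))

    # 2. TF-target library
    lo_e, hi_e = p.n_experiments_per_tf
    lo_t, hi_t = p.target_set_size
    tf_sets: list[GeneSet] = []
    targets_by_tf: dict[str, set[str]] = {}
    for tf in tf_symbols:
        n_exp = int(rng.integers(lo_e, hi_e + 1))
        targets_by_tf[tf] = set()
        for j in range(n_exp):
            size = (
                p.planted_target_set_size
                if tf in planted
                else int(rng.integers(lo_t, hi_t + 1))
            )
            members = frozenset(uni_arr[rng.choice(p.universe_size, size, replace=False)])
            targets_by_tf[tf] |= members
            tf_sets.append(
                GeneSet(
                    name=f"{tf} EXP{j + 1} SIM",
                    description="synthetic ChIP-seq-style experiment",
                    members=members,
                    tf_symbol=tf,
                )
            )
    tf_library = GeneSetLibrary(
        library_id="sim_tf_targets",
        sets=tuple(tf_sets),
        background_size=p.universe_size,
        background_universe=frozenset(universe),
    )

    planted_union = sorted(set().union(*(targets_by_tf[tf] for tf in planted))) if planted else []

    # 3. pathway library: planted pathways draw an equal share from every
    # planted TF's target set, so each one is genuinely enriched for (and
    # hence shared across) all planted TFs
    path_sets: list[GeneSet] = []
    per_tf_targets = {tf: np.array(sorted(targets_by_tf[tf])) for tf in planted}
    for i in range(p.n_planted_pathways):
        if not planted:
            break
        share = max(1, p.planted_pathway_size // len(planted))
        members: set[str] = set()
        for tf in planted:
            pool = per_tf_targets[tf]
            take = min(share, len(pool))
            members |= set(pool[rng.choice(len(pool), take, replace=False)])
        path_sets.append(
            GeneSet(name=f"Planted pathway {i + 1}",
                    description="stratified draw from planted TFs' target sets",
                    members=frozenset(members))
        )
    lo_p, hi_p = p.pathway_size
    for i in range(p.n_pathways - len(path_sets)):
        size = int(rng.integers(lo_p, hi_p + 1))
        members = frozenset(uni_arr[rng.choice(p.universe_size, size, replace=False)])
        path_sets.append(
            GeneSet(name=f"Decoy pathway {i + 1:03d}", description="uniform decoy", members=members)
        )
    pathway_library = GeneSetLibrary(
        library_id="sim_pathways",
        sets=tuple(path_sets),
        background_size=p.universe_size,
        background_universe=frozenset(universe),
    )

    # 4. selected list
    selected: list[str] = list(planted)
    m = p.selected_list_size - len(selected)
    taken = set(selected)
    if p.enrichment_strength == 1.0 or not planted_union:
        pool = np.array([g for g in universe if g not in taken])
        selected.extend(pool[rng.choice(len(pool), m, replace=False)])
    else:
        union_set = set(planted_union)
        union_pool = np.array([g for g in planted_union if g not in taken])
        rest_pool = np.array([g for g in universe if g not in taken and g not in union_set])
        base_rate = len(union_pool) / p.universe_size
        p_union = min(1.0, p.enrichment_strength * base_rate)
        c = int(rng.binomial(m, p_union))
        c = min(c, len(union_pool))
        c = max(c, m - len(rest_pool))
        selected.extend(union_pool[rng.choice(len(union_pool), c, replace=False)])
        selected.extend(rest_pool[rng.choice(len(rest_pool), m - c, replace=False)])
    selected_genes = GeneList.from_iterable(selected, label=f"sim_selected_seed{seed}")

    # 5. interactions
    pairs: list[tuple[str, str]] = []
    n_tf = len(tf_symbols)
    if n_tf > 1 and p.ppi_density > 0:
        mask = rng.random((n_tf, n_tf)) < p.ppi_density
        for i in range(n_tf):
            for j in range(i + 1, n_tf):
                if mask[i, j]:
                    pairs.append((tf_symbols[i], tf_symbols[j]))
    hub = planted[0] if planted else None
    if hub is not None and p.hub_connect_fraction > 0:
        others = [t for t in tf_symbols if t != hub]
        n_conn = int(np.ceil(p.hub_connect_fraction * len(others)))
        picked = rng.choice(len(others), n_conn, replace=False)
        pairs.extend((hub, others[i]) for i in sorted(picked))
    interactions = InteractionTable.from_pairs(pairs, source="sim")

    ground_truth = {
        "planted_core_tfs": list(planted),
        "planted_hub": hub,
        "planted_pathways": [s.name for s in path_sets if s.name.startswith("Planted")],
        "planted_target_union_size": len(planted_union),
        "decoy_tfs": [t for t in tf_symbols if t not in planted],
    }
    scenario = SyntheticScenario(
        params=p, seed=seed, universe=universe, catalog=catalog,
        tf_library=tf_library, pathway_library=pathway_library,
        selected_genes=selected_genes, interactions=interactions,
        ground_truth=ground_truth,
    )
    if out_dir is not None:
        scenario.write(out_dir)
    return scenario
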