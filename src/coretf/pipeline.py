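"""The four inference stages for core-TF calling.

1. ``select_tfs`` — cross the selected-gene list with a TF census, giving
   the TFs that are themselves under selection ("list 1").
2. ``tf_target_enrichment`` — test every ChIP-seq experiment set of a
   TF-target library for over-representation in the selected-gene list,
   adjust across experiments, collapse to the best record per TF, and keep
   TFs below the threshold ("list 2").
3. ``call_core_tfs`` — intersect the two lists; the survivors carry both
   kinds of evidence (selected *and* upstream of many selected genes) and
   are the candidate core regulators.
4. ``shared_enrichments`` — profile each core TF's known target list
   against pathway libraries and intersect the enriched pathway names
   across TFs, exposing the biology the core TFs jointly control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .enrichment import EnrichmentRecord, EnrichmentTable, combine_libraries, enrich
from .io import GeneList, GeneSetLibrary, TFCatalog, normalize_symbol

logger = logging.getLogger("coretf")

__all__ = [
    "TFEvidence",
    "CoreTFReport",
    "SharedPathwayResult",
    "select_tfs",
    "tf_target_enrichment",
    "call_core_tfs",
    "shared_enrichments",
]


@dataclass(frozen=True)
class TFEvidence:
    """Both evidence channels for one TF: membership in the selected-gene
    list, and its best target-set enrichment (collapsed over experiments)."""

    tf: str
    in_selected_list: bool
    target_enrichment: Optional[EnrichmentRecord] = None
    n_experiments: int = 0

    def __post_init__(self) -> None:
        if (self.target_enrichment is not None) != (self.n_experiments >= 1):
            raise ValueError(
                f"{self.tf}: target_enrichment must be present iff n_experiments >= 1"
            )


@dataclass(frozen=True)
class CoreTFReport:
    """List 1 (selected TFs), list 2 (target-enriched TFs), their
    intersection, and per-TF evidence."""

    list1: tuple[str, ...]
    list2: tuple[str, ...]
    core: tuple[str, ...]
    evidence: Mapping[str, TFEvidence] = field(default_factory=dict)
    parameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = tuple(sorted(set(self.list1) & set(self.list2)))
        if tuple(sorted(self.core)) != expected:
            raise ValueError("core is not the intersection of list1 and list2")

    def to_json_dict(self) -> dict:
        evidence = []
        for tf in sorted(set(self.list1) | set(self.list2) | set(self.evidence)):
            ev = self.evidence.get(tf)
            row: dict[str, object] = {
                "tf": tf,
                "in_selected_list": tf in self.list1,
                "in_core": tf in self.core,
                "n_experiments": ev.n_experiments if ev else 0,
            }
            if ev and ev.target_enrichment is not None:
                r = ev.target_enrichment
                row.update(
                    best_set_name=r.set_name, k=r.k, K=r.K, n=r.n, N=r.N,
                    p_raw=r.p_raw, p_adj=r.p_adj,
                )
            evidence.append(row)
        return {
            "parameters": dict(self.parameters),
            "list1": list(self.list1),
            "list2": list(self.list2),
            "core_tfs": list(self.core),
            "evidence": evidence,
        }


@dataclass(frozen=True)
class SharedPathwayResult:
    """Per-TF enriched pathway identifiers and their cross-TF intersection.

    ``per_tf_enriched`` maps each usable TF to the (library_id, set_name)
    pairs enriched below threshold; ``shared`` holds the pathway names (one
    representative spelling per case-insensitive name) enriched for *every*
    usable TF.  TFs without target data are listed in ``excluded_tfs`` and
    do not constrain the intersection.
    """

    per_tf_enriched: Mapping[str, frozenset[tuple[str, str]]]
    shared: tuple[str, ...]
    tfs_considered: tuple[str, ...]
    excluded_tfs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        shared_keys = {s.casefold() for s in self.shared}
        for tf in self.tfs_considered:
            names = {name.casefold() for _, name in self.per_tf_enriched[tf]}
            if not shared_keys <= names:
                raise ValueError(f"shared pathways not all enriched for {tf}")


def select_tfs(selected_genes: GeneList, catalog: TFCatalog) -> list[str]:
    """TF-census members present in the selected-gene list (list 1), sorted.

    Symbols are alias-resolved through the catalog when an alias map is
    supplied; matches are reported under their canonical catalog spelling.
    """
    if len(selected_genes) == 0:
        raise ValueError("empty selected-gene list")
    if len(catalog) == 0:
        raise ValueError("empty TF catalog")
    hits = {
        catalog.resolve(sym)
        for sym in selected_genes
        if catalog.resolve(sym) in catalog.symbols
    }
    logger.info(
        "select_tfs: %d of %d selected genes are catalog TFs",
        len(hits), len(selected_genes),
    )
    return sorted(hits)


def tf_target_enrichment(
    selected_genes: GeneList,
    tf_library: GeneSetLibrary,
    threshold: float = 0.01,
    adjust: str = "bh",
    collapse: str = "min",
) -> tuple[list[str], dict[str, TFEvidence]]:
    """TFs whose experimentally demonstrated targets are over-represented
    in the selected-gene list (list 2), plus per-TF evidence.

    Enrichment and multiplicity adjustment run at the experiment level
    (every set of the library); records are then collapsed to one per TF.
    ``collapse="min"`` keeps the record with minimal adjusted p (tie-break:
    larger overlap k, then set name) — the value a reader takes from a
    multi-row TF query.  ``collapse="bonferroni"`` additionally multiplies
    that best adjusted p by the TF's experiment count, a conservative
    alternative.  List 2 contains the TFs whose collapsed adjusted p is
    strictly below ``threshold``, sorted.
    """
    if collapse not in ("min", "bonferroni"):
        raise ValueError(f"unknown collapse mode {collapse!r}")
    by_tf = tf_library.sets_by_tf()
    if not by_tf:
        raise ValueError(
            f"library {tf_library.library_id!r} carries no tf_symbol annotations; "
            "read it with parse_tf_names=True"
        )
    table = enrich(selected_genes, tf_library, threshold=threshold, adjust=adjust)
    rec_by_name = {r.set_name: r for r in table.records}

    evidence: dict[str, TFEvidence] = {}
    for tf, sets in by_tf.items():
        recs = [rec_by_name[s.name] for s in sets]
        best = min(recs, key=lambda r: (r.p_adj, -r.k, r.set_name))
        if collapse == "bonferroni" and len(recs) > 1:
            best = EnrichmentRecord(
                library_id=best.library_id, set_name=best.set_name,
                k=best.k, K=best.K, n=best.n, N=best.N,
                odds_ratio=best.odds_ratio, p_raw=best.p_raw,
                p_adj=min(1.0, best.p_adj * len(recs)),
                overlap_members=best.overlap_members,
            )
        evidence[tf] = TFEvidence(
            tf=tf, in_selected_list=tf in selected_genes.symbol_set,
            target_enrichment=best, n_experiments=len(recs),
        )
    # strict inequality at the cutoff; a threshold of exactly 1 disables
    # filtering (every TF with >= 1 experiment passes)
    list2 = sorted(
        tf for tf, ev in evidence.items()
        if ev.target_enrichment is not None
        and (ev.target_enrichment.p_adj < threshold or threshold >= 1)
    )
    logger.info(
        "tf_target_enrichment: %d of %d TFs below adjusted p < %g",
        len(list2), len(evidence), threshold,
    )
    return list2, evidence


def call_core_tfs(
    list1: Sequence[str],
    list2: Sequence[str],
    evidence: Optional[Mapping[str, TFEvidence]] = None,
    parameters: Optional[Mapping[str, object]] = None,
) -> CoreTFReport:
    """Intersect the two candidate lists into the core-TF report.

    The intersection is on normalized symbols; an empty core is legitimate
    (warned, not an error).  Commutative and idempotent by construction.
    """
    l1 = tuple(dict.fromkeys(normalize_symbol(s) for s in list1))
    l2 = tuple(dict.fromkeys(normalize_symbol(s) for s in list2))
    core = tuple(sorted(set(l1) & set(l2)))
    if not core:
        logger.warning("call_core_tfs: empty intersection of %d- and %d-TF lists", len(l1), len(l2))
    ev = dict(evidence) if evidence else {}
    for tf in set(l1) | set(l2):
        if tf not in ev:
            ev[tf] = TFEvidence(tf=tf, in_selected_list=tf in l1)
    return CoreTFReport(
        list1=l1, list2=l2, core=core, evidence=ev,
        parameters=dict(parameters) if parameters else {},
    )


def shared_enrichments(
    tf_target_sets: Mapping[str, GeneList],
    pathway_libraries: Iterable[GeneSetLibrary],
    threshold: float = 0.01,
) -> SharedPathwayResult:
    """Pathways enriched in *every* core TF's target list.

    Each TF's target list is enriched against every pathway library; the
    per-library tables are pooled (no cross-library re-adjustment) and set
    names with adjusted p strictly below ``threshold`` are kept.  The
    cross-TF intersection matches set names case-insensitively across
    libraries, the granularity at which pathway names are usually reported.
    TFs with an empty target list are excluded (and reported) rather than
    forcing the intersection empty.
    """
    libraries = list(pathway_libraries)
    if not libraries:
        raise ValueError("no pathway libraries supplied")
    usable = {tf: gl for tf, gl in tf_target_sets.items() if len(gl) > 0}
    excluded = tuple(sorted(set(tf_target_sets) - set(usable)))
    if len(usable) < 2:
        raise ValueError(
            f"need >= 2 TFs with non-empty target sets, have {len(usable)} "
            f"(excluded: {list(excluded)})"
        )
    per_tf: dict[str, frozenset[tuple[str, str]]] = {}
    per_tf_namekeys: dict[str, set[str]] = {}
    for tf in sorted(usable):
        tables = [enrich(usable[tf], lib, threshold=threshold) for lib in libraries]
        combined = combine_libraries(tables)
        hits = combined.significant()
        per_tf[tf] = frozenset((r.library_id, r.set_name) for r in hits)
        per_tf_namekeys[tf] = {r.set_name.casefold() for r in hits}
    shared_keys = set.intersection(*per_tf_namekeys.values())
    # one representative spelling per case-insensitive key, deterministic
    representative: dict[str, str] = {}
    for tf in sorted(per_tf):
        for _, name in sorted(per_tf[tf]):
            key = name.casefold()
            if key in shared_keys and (key not in representative or name < representative[key]):
                representative[key] = name
    shared = tuple(sorted(representative.values()))
    if excluded:
        logger.info("shared_enrichments: excluded TFs without target data: %s", list(excluded))
    return SharedPathwayResult(
        per_tf_enriched=per_tf,
        shared=shared,
        tfs_considered=tuple(sorted(usable)),
        excluded_tfs=excluded,
    )
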