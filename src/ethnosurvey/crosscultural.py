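"""Cross-cultural set-partition analysis of plant knowledge.

Given the set of items (taxa, or species-use pairs) quoted by each of *k*
cultural groups, the exact Venn partition assigns every quoted item to the
unique nonempty subset of groups that quote it, yielding up to ``2^k - 1``
pairwise-disjoint regions whose union is the set of all quoted items.  The
region keyed by the full group set is the *shared core*; singleton-keyed
regions hold each group's idiosyncratic items.  Overlap percentages are
relative to the union of all quoted items of that kind.

Also here: novelty flagging — comparing the surveyed taxa and uses against
a prior-literature table to find first reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping

import pandas as pd

from .data_model import SurveyDataset, Vocabulary, normalize_scientific_name
from .indices import FALLBACK_CATEGORY, round_index

__all__ = [
    "VennPartition",
    "NoveltyReport",
    "group_item_sets",
    "venn_partition",
    "shared_core",
    "unique_to",
    "overlap_percent",
    "region_table",
    "compare_to_literature",
]

Item = Hashable


@dataclass
class VennPartition:
    """Exact partition of quoted items over nonempty group subsets.

    ``regions`` maps each realised subset of groups (as a frozenset) to
    the items quoted by exactly that subset; empty regions are omitted.
    """

    groups: tuple[str, ...]
    regions: dict[frozenset[str], frozenset[Item]]
    item_kind: str = "taxon"

    @property
    def universe(self) -> frozenset[Item]:
        out: set[Item] = set()
        for items in self.regions.values():
            out |= items
        return frozenset(out)


@dataclass
class NoveltyReport:
    """Per-species novelty status against a prior-literature table."""

    table: pd.DataFrame  # columns: species_id, scientific_name, status, evidence

    def with_status(self, status: str) -> list[str]:
        sel = self.table[self.table["status"] == status]
        return sel["scientific_name"].tolist()


def group_item_sets(
    ds: SurveyDataset,
    item_kind: str = "taxon",
    granularity: str = "ailment",
    vocab: Vocabulary | None = None,
) -> dict[str, set[Item]]:
    """Items quoted by each group: species ids, or (species, use) pairs.

    Group membership comes from the per-species group flags in aggregate
    mode, and from the citing informants' linguistic groups in raw mode.
    Use units are (species_id, ailment term) at ``"ailment"`` granularity
    and (species_id, category code) at ``"category"`` granularity.
    """
    if item_kind not in {"taxon", "use"}:
        raise ValueError(f"unknown item kind {item_kind!r}")
    if granularity not in {"ailment", "category"}:
        raise ValueError(f"unknown use granularity {granularity!r}")
    if not ds.groups:
        raise ValueError("dataset declares no groups")
    vocab = vocab or ds.vocabulary

    def use_label(term: str) -> str:
        if granularity == "ailment":
            return term
        code = vocab.category_of(term) if vocab else None
        return code or FALLBACK_CATEGORY

    sets: dict[str, set[Item]] = {g: set() for g in ds.groups}
    if ds.mode == "raw" and ds.use_reports:
        inf_group = {i.informant_id: i.linguistic_group for i in ds.informants}
        for r in ds.use_reports:
            g = inf_group.get(r.informant_id)
            if g is None:
                continue
            if item_kind == "taxon":
                sets[g].add(r.species_id)
            else:
                sets[g].add((r.species_id, use_label(r.ailment)))
    else:
        for s in ds.species:
            for g in s.groups:
                if g not in sets:
                    continue
                if item_kind == "taxon":
                    sets[g].add(s.species_id)
                else:
                    sets[g].update((s.species_id, use_label(a)) for a in s.ailments)
    return sets


def venn_partition(
    sets: Mapping[str, Iterable[Item]], item_kind: str = "taxon"
) -> VennPartition:
    """Partition the union of per-group item sets by exact membership."""
    if len(sets) < 2:
        raise ValueError("venn partition needs at least 2 groups")
    groups = tuple(sets.keys())
    frozen = {g: set(v) for g, v in sets.items()}
    universe: set[Item] = set().union(*frozen.values())
    membership: dict[Item, frozenset[str]] = {
        item: frozenset(g for g in groups if item in frozen[g]) for item in universe
    }
    regions: dict[frozenset[str], set[Item]] = {}
    for item, key in membership.items():
        regions.setdefault(key, set()).add(item)
    return VennPartition(
        groups=groups,
        regions={k: frozenset(v) for k, v in regions.items()},
        item_kind=item_kind,
    )


def shared_core(p: VennPartition) -> frozenset[Item]:
    """Items quoted by every group (empty if no item is universal)."""
    return p.regions.get(frozenset(p.groups), frozenset())


def unique_to(p: VennPartition, group: str) -> frozenset[Item]:
    """Items quoted by exactly one group."""
    if group not in p.groups:
        raise ValueError(f"unknown group {group!r}; partition has {p.groups}")
    return p.regions.get(frozenset({group}), frozenset())


def overlap_percent(p: VennPartition, subset: Iterable[str]) -> float:
    """Region size as a percentage of all quoted items, half-up at 2 dp."""
    key = frozenset(subset)
    if not key:
        raise ValueError("subset must be nonempty")
    unknown = key - set(p.groups)
    if unknown:
        raise ValueError(f"unknown group(s) {sorted(unknown)}")
    total = len(p.universe)
    if total == 0:
        return 0.0
    return round_index(100.0 * len(p.regions.get(key, ())) / total, 2)


def region_table(p: VennPartition) -> pd.DataFrame:
    """One row per nonempty region: subset label, size, percent, items."""
    rows = []
    total = len(p.universe)
    for key in sorted(p.regions, key=lambda k: (len(k), sorted(k))):
        items = p.regions[key]
        rows.append(
            {
                "subset": "+".join(sorted(key)),
                "n_groups": len(key),
                "size": len(items),
                "percent": round_index(100.0 * len(items) / total, 2) if total else 0.0,
                "items": "; ".join(sorted(map(str, items))),
            }
        )
    return pd.DataFrame(rows, columns=["subset", "n_groups", "size", "percent", "items"])


def compare_to_literature(ds: SurveyDataset, lit: pd.DataFrame) -> NoveltyReport:
    """Flag each surveyed species against a prior-literature table.

    A species absent from the table is a ``novel_taxon``; present without
    any matching use term, a ``novel_use``; otherwise
    ``previously_reported``.  Names are compared after normalisation
    (case-fold, authorities stripped, infraspecific rank retained).
    """
    required = {"species_name", "use_term"}
    missing = required - set(lit.columns)
    if missing:
        raise ValueError(f"literature table missing column(s) {sorted(missing)}")

    lit_norm = lit.assign(_name=[normalize_scientific_name(n) for n in lit["species_name"]])
    by_name: dict[str, pd.DataFrame] = {
        name: grp for name, grp in lit_norm.groupby("_name")
    }

    rows = []
    for s in ds.species:
        name = normalize_scientific_name(s.scientific_name)
        hits = by_name.get(name)
        if hits is None:
            # retry at binomial rank so an infraspecific survey record can
            # match species-rank literature
            binom = " ".join(name.split(" ")[:2])
            hits = by_name.get(binom)
        if hits is None:
            status, evidence = "novel_taxon", ""
        else:
            uses = {str(u).strip().lower() for u in hits["use_term"]}
            recorded = {a.lower() for a in s.ailments}
            if uses & recorded:
                status = "previously_reported"
            else:
                status = "novel_use"
            if "source_id" in hits.columns:
                evidence = "; ".join(sorted(set(hits["source_id"])))
            else:
                evidence = "; ".join(str(i) for i in hits.index)
        rows.append(
            {
                "species_id": s.species_id,
                "scientific_name": s.scientific_name,
                "status": status,
                "evidence": evidence,
            }
        )
    return NoveltyReport(
        table=pd.DataFrame(rows, columns=["species_id", "scientific_name", "status", "evidence"])
    )
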