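"""Quantitative ethnobotany indices and descriptive frequency summaries.

Three classic indices quantify how a community cites its medicinal flora:

* **RFC** (relative frequency of citation) ``= FC / N`` — the share of all
  *N* respondents citing a species for any purpose (``FC`` = distinct
  citing informants).
* **ICF** (informant consensus factor) ``= (Nur - Nt) / (Nur - 1)`` per
  disease category — 1 when every use report in the category converges on
  a single taxon (``Nur`` use reports over ``Nt`` taxa), 0 when every
  report cites a different taxon; undefined at ``Nur = 1``.
* **FL** (fidelity level) ``= 100 * Ip / Iu`` per (species, purpose) —
  the percentage of a species' citing informants (``Iu``) who cite it for
  one specific purpose (``Ip``).

All three are computed at full precision; display rounding is a separate
half-up decimal step (:func:`round_index`), matching how such tables are
conventionally printed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .data_model import (
    DiseaseCategory,
    SurveyDataset,
    Vocabulary,
    normalize_scientific_name,
)

__all__ = [
    "BoundaryWarning",
    "IndexTable",
    "FrequencyTable",
    "compute_rfc",
    "compute_icf",
    "compute_fl",
    "round_index",
    "categorize_ailments",
    "frequency_summary",
    "rank_species",
    "build_index_table",
    "aggregate_survey",
]

FALLBACK_CATEGORY = "OTH"


class BoundaryWarning(UserWarning):
    """An index reached a boundary its definition treats as degenerate."""


# ---------------------------------------------------------------------------
# Scalar index functions
# ---------------------------------------------------------------------------


def compute_rfc(fc: int, n: int) -> float:
    """Relative frequency of citation FC/N at full precision.

    The definition bounds RFC strictly inside (0, 1); fc = 0 and fc = n are
    legal datasets, so the boundary is reported as a warning, not an error.
    """
    if n < 1:
        raise ValueError(f"respondent total n must be >= 1, got {n}")
    if not 0 <= fc <= n:
        raise ValueError(f"fc must lie in [0, n={n}], got {fc}")
    if fc in (0, n):
        warnings.warn(
            f"RFC boundary: fc={fc} of n={n} lies outside the open interval (0, 1)",
            BoundaryWarning,
            stacklevel=2,
        )
    return fc / n


def compute_icf(nur: int, nt: int) -> float | None:
    """Informant consensus factor (Nur - Nt)/(Nur - 1), or None when Nur = 1.

    The single-report case has a zero denominator and no defined consensus;
    it is flagged explicitly rather than silently coerced to 0 or 1.
    """
    if nur < 1:
        raise ValueError(f"use-report count nur must be >= 1, got {nur}")
    if nt < 1:
        raise ValueError(f"taxon count nt must be >= 1, got {nt}")
    if nt > nur:
        raise ValueError(f"nt={nt} cannot exceed nur={nur}")
    if nur == 1:
        return None
    return (nur - nt) / (nur - 1)


def compute_fl(ip: int, iu: int) -> float:
    """Fidelity level 100*Ip/Iu (percent) at full precision."""
    if iu < 1:
        raise ValueError(f"iu must be >= 1, got {iu}")
    if not 0 <= ip <= iu:
        raise ValueError(f"ip must lie in [0, iu={iu}], got {ip}")
    return 100.0 * ip / iu


def round_index(x: float, places: int = 2) -> float:
    """Round half-up to ``places`` decimals (0.005 → 0.01, 0.6548… → 0.65).

    Printed index tables use half-up rounding; Python's builtin ``round``
    is half-even, so a Decimal quantisation is used instead.
    """
    if places < 0:
        raise ValueError("places must be >= 0")
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


@dataclass
class IndexTable:
    """Per-species, per-category and per-(species, purpose) index tables.

    ``per_species``: species_id, scientific_name, fc, rfc.
    ``per_category``: category, nt, nur, icf (NaN where undefined).
    ``per_fidelity``: species, purpose, ip, iu, fl.
    Full-precision values; round with :func:`round_index` for display.
    """

    per_species: pd.DataFrame
    per_category: pd.DataFrame
    per_fidelity: pd.DataFrame
    n: int

    def rounded(self, places: int = 2) -> "IndexTable":
        ps = self.per_species.assign(
            rfc=[round_index(v, places) for v in self.per_species["rfc"]]
        )
        pc = self.per_category.assign(
            icf=[
                float("nan") if pd.isna(v) else round_index(v, places)
                for v in self.per_category["icf"]
            ]
        )
        pf = self.per_fidelity.assign(
            fl=[round_index(v, places) for v in self.per_fidelity["fl"]]
        )
        return IndexTable(ps, pc, pf, self.n)


@dataclass
class FrequencyTable:
    """Term counts for one descriptive dimension with a stated denominator.

    Habit and family are one-per-species (counts sum to the species total);
    part, preparation and route admit several terms per species, so the
    denominator is the number of species-term incidences.
    """

    dimension: str
    table: pd.DataFrame  # columns: term, count, percent
    denominator: int
    basis: str


_EXCLUSIVE_DIMENSIONS = {"habit", "family"}
_INCIDENCE_DIMENSIONS = {"part", "preparation", "route"}


def frequency_summary(ds: SurveyDataset, dimension: str) -> FrequencyTable:
    """Count species (or species-term incidences) along one dimension."""
    if dimension in _EXCLUSIVE_DIMENSIONS:
        terms = [getattr(s, dimension) for s in ds.species]
        basis = "species"
    elif dimension in _INCIDENCE_DIMENSIONS:
        attr = {"part": "parts_used", "preparation": "preparations", "route": "routes"}[
            dimension
        ]
        terms = [t for s in ds.species for t in sorted(getattr(s, attr))]
        basis = "species-term incidences"
    else:
        raise ValueError(
            f"unsupported dimension {dimension!r}; expected one of "
            f"{sorted(_EXCLUSIVE_DIMENSIONS | _INCIDENCE_DIMENSIONS)}"
        )
    counts = pd.Series(terms, dtype=object).value_counts()
    denom = int(counts.sum())
    table = pd.DataFrame(
        {
            "term": counts.index,
            "count": counts.to_numpy(),
            "percent": [round_index(100.0 * c / denom, 1) for c in counts],
        }
    ).reset_index(drop=True)
    return FrequencyTable(dimension=dimension, table=table, denominator=denom, basis=basis)


def categorize_ailments(
    ds: SurveyDataset,
    vocab: Vocabulary | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Aggregate species and use reports into disease categories.

    ``nt`` counts distinct species used in the category, once per category
    for a multi-category species: in raw mode a species counts where it
    has at least one use report (so ``nt <= nur`` always holds); in
    aggregate mode it counts where it lists an ailment.  ``nur`` is the
    category's use-report total: counted from raw reports, or taken from
    the stored per-category totals in aggregate mode.  Unresolvable terms
    raise in strict mode and fall into ``OTH`` (with a warning) otherwise.
    """
    vocab = vocab or ds.vocabulary
    if vocab is None:
        raise ValueError("no vocabulary available to map ailment terms")

    def resolve(term: str) -> str:
        code = vocab.category_of(term, strict=strict)
        if code is None:
            warnings.warn(
                f"ailment term {term!r} not in vocabulary; binned under "
                f"{FALLBACK_CATEGORY}",
                UserWarning,
                stacklevel=2,
            )
            code = FALLBACK_CATEGORY
        return code

    nt: dict[str, set[str]] = {}
    nur: dict[str, int] = {}
    if ds.mode == "raw":
        for r in ds.use_reports:
            code = resolve(r.ailment)
            nur[code] = nur.get(code, 0) + 1
            nt.setdefault(code, set()).add(r.species_id)
    else:
        for s in ds.species:
            for term in s.ailments:
                nt.setdefault(resolve(term), set()).add(s.species_id)
        for cat in ds.categories:
            if cat.nur is not None:
                nur[cat.code] = cat.nur

    codes = sorted(set(nt) | set(nur))
    return pd.DataFrame(
        {
            "category": codes,
            "nt": [len(nt.get(c, ())) for c in codes],
            "nur": [nur.get(c, 0) for c in codes],
        }
    )


def build_index_table(
    ds: SurveyDataset, vocab: Vocabulary | None = None, strict: bool = False
) -> IndexTable:
    """Compute the full index table for a dataset in either mode.

    Aggregate mode reads FC/UM and per-category (Nt, Nur) from the stored
    counts (including category exemplar rows); raw mode derives everything
    by counting use reports.
    """
    n = ds.n_informants

    # --- per species: FC and RFC ------------------------------------------
    if ds.mode == "raw":
        counts = ds.citation_counts()
        fcs = {s.species_id: counts.get(s.species_id, 0) for s in ds.species}
    else:
        fcs = {s.species_id: (s.fc or 0) for s in ds.species}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BoundaryWarning)
        per_species = pd.DataFrame(
            {
                "species_id": [s.species_id for s in ds.species],
                "scientific_name": [s.scientific_name for s in ds.species],
                "fc": [fcs[s.species_id] for s in ds.species],
                "rfc": [compute_rfc(fcs[s.species_id], n) for s in ds.species],
            }
        )

    # --- per category: Nt, Nur, ICF ---------------------------------------
    if ds.mode == "aggregate" and any(c.nt is not None for c in ds.categories):
        cat_rows = [
            (c.code, c.nt, c.nur)
            for c in ds.categories
            if c.nt is not None and c.nur is not None
        ]
        per_category = pd.DataFrame(cat_rows, columns=["category", "nt", "nur"])
    else:
        per_category = categorize_ailments(ds, vocab, strict=strict)
    per_category["icf"] = [
        float("nan") if (icf := compute_icf(int(nur), int(nt))) is None else icf
        for nt, nur in zip(per_category["nt"], per_category["nur"])
    ]

    # --- per (species, purpose): FL ----------------------------------------
    fid_rows: list[tuple[str, str, int, int, float]] = []
    if ds.mode == "raw":
        by_species: dict[str, dict[str, set[str]]] = {}
        for r in ds.use_reports:
            by_species.setdefault(r.species_id, {}).setdefault(r.ailment, set()).add(
                r.informant_id
            )
        names = {s.species_id: s.scientific_name for s in ds.species}
        for sid in sorted(by_species):
            iu = fcs[sid]
            if iu == 0:
                continue
            purposes = by_species[sid]
            # principal purpose: most-cited ailment, alphabetical tie-break
            principal = max(sorted(purposes), key=lambda a: len(purposes[a]))
            ip = len(purposes[principal])
            fid_rows.append((names[sid], principal, ip, iu, compute_fl(ip, iu)))
    else:
        for s in ds.species:
            if s.um is not None and s.fc:
                purpose = s.ailments[0] if s.ailments else ""
                fid_rows.append(
                    (s.scientific_name, purpose, s.um, s.fc, compute_fl(s.um, s.fc))
                )
        # category exemplar rows carry their own printed (UM, FC) pairs,
        # which supersede the species table for the same taxon (binomial
        # match, authorities and infraspecific rank ignored)
        def _binomial(name: str) -> str:
            return " ".join(normalize_scientific_name(name).split(" ")[:2])

        for c in ds.categories:
            if c.exemplar_fc and c.exemplar_um is not None:
                ex = _binomial(c.exemplar_species)
                fid_rows = [r for r in fid_rows if _binomial(r[0]) != ex]
                fid_rows.append(
                    (
                        c.exemplar_species,
                        c.exemplar_uses,
                        c.exemplar_um,
                        c.exemplar_fc,
                        compute_fl(c.exemplar_um, c.exemplar_fc),
                    )
                )
    per_fidelity = pd.DataFrame(
        fid_rows, columns=["species", "purpose", "ip", "iu", "fl"]
    )

    return IndexTable(
        per_species=per_species,
        per_category=per_category,
        per_fidelity=per_fidelity,
        n=n,
    )


def rank_species(
    tbl: IndexTable, metric: str = "rfc", tie_rule: str = "alphabetical"
) -> pd.DataFrame:
    """Order species (or fidelity rows) by a metric, descending.

    Ties are broken alphabetically by scientific name by default, or left
    in input order under the ``"stable"`` rule; tied rows are flagged.
    """
    if metric in {"rfc", "fc"}:
        df, label = tbl.per_species.copy(), "scientific_name"
    elif metric == "fl":
        df, label = tbl.per_fidelity.copy(), "species"
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    if tie_rule == "alphabetical":
        df = df.sort_values(
            by=[metric, label], ascending=[False, True], kind="mergesort"
        )
    elif tie_rule == "stable":
        df = df.sort_values(by=metric, ascending=False, kind="mergesort")
    else:
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    df = df.reset_index(drop=True)
    df["tied"] = df[metric].duplicated(keep=False)
    return df


# ---------------------------------------------------------------------------
# Raw → aggregate
# ---------------------------------------------------------------------------


def aggregate_survey(ds: SurveyDataset, vocab: Vocabulary | None = None) -> SurveyDataset:
    """Collapse a raw-mode dataset to aggregate mode.

    Stores per-species FC (distinct citing informants) and UM (informants
    citing the principal purpose) and per-category (Nt, Nur) totals, then
    drops the use reports.  Index tables computed from the result equal
    those computed from the raw dataset directly.
    """
    from dataclasses import replace

    if ds.mode != "raw":
        raise ValueError("aggregate_survey expects a raw-mode dataset")
    vocab = vocab or ds.vocabulary

    by_species: dict[str, dict[str, set[str]]] = {}
    for r in ds.use_reports:
        by_species.setdefault(r.species_id, {}).setdefault(r.ailment, set()).add(
            r.informant_id
        )
    species = []
    for s in ds.species:
        purposes = by_species.get(s.species_id, {})
        cited = set().union(*purposes.values()) if purposes else set()
        fc = len(cited)
        um = None
        if purposes:
            principal = max(sorted(purposes), key=lambda a: len(purposes[a]))
            um = len(purposes[principal])
        species.append(replace(s, fc=fc, um=um))

    cat_totals = categorize_ailments(ds, vocab).set_index("category")
    existing = {c.code: c for c in ds.categories}
    categories = []
    for code in cat_totals.index:
        base = existing.get(code) or (
            (vocab.categories.get(code) if vocab else None)
            or DiseaseCategory(code=code, description=code)
        )
        categories.append(
            replace(
                base,
                nt=int(cat_totals.loc[code, "nt"]),
                nur=int(cat_totals.loc[code, "nur"]),
            )
        )

    return SurveyDataset(
        informants=list(ds.informants),
        species=species,
        use_reports=[],
        categories=categories,
        mode="aggregate",
        groups=ds.groups,
        vocabulary=vocab,
    )
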