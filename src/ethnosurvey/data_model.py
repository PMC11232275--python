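"""Domain model for ethnomedicinal survey data.

An ethnomedicinal survey records which informants cite which plant species
for which ailments.  The atomic observation is the *use report*: one
informant citing one species for one ailment.  Published surveys, however,
frequently report only aggregate counts — the frequency of citation FC
(distinct informants per species) and per-category use-report totals — so
the dataset container supports two modes:

``raw``
    Individual use reports are present; FC, use-mention and category
    totals are derivable by counting.
``aggregate``
    Only the published counts are stored (per-species FC/UM, per-category
    Nt/Nur); the use-report table is empty.

The module also ships a curated fixture: the Kohistan (north Pakistan)
wild-medicinal-plant survey of five linguistic groups (Kohistani, Shina,
Bateri, Pushto, Gujjari) — 281 informants in 20 villages, 96 species, and
twelve ICPC-2 disease categories — transcribed into the aggregate-mode
tables this package reads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "HABITS",
    "PARTS",
    "PREPARATIONS",
    "ROUTES",
    "Informant",
    "SpeciesRecord",
    "UseReport",
    "DiseaseCategory",
    "SurveyDataset",
    "ValidationIssue",
    "ValidationReport",
    "Vocabulary",
    "SchemaError",
    "VocabularyError",
    "canonical_term",
    "normalize_scientific_name",
    "load_vocabulary",
    "load_survey",
    "write_survey",
    "validate_dataset",
    "kohistan_fixture",
    "kohistan_literature",
    "fixture_path",
]

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

HABITS = frozenset({"herb", "shrub", "tree", "climber"})

PARTS = frozenset(
    {
        "aerial part",
        "leaves",
        "roots",
        "stem",
        "flower",
        "fruit",
        "seed",
        "bark",
        "resin",
        "rind",
        "milk/latex",
        "branches",
    }
)

PREPARATIONS = frozenset(
    {
        "powder",
        "paste",
        "decoction",
        "infusion",
        "extract",
        "fresh part",
        "ash",
        "oil",
        "tea",
    }
)

ROUTES = frozenset({"oral", "topical", "inhalation/smoke"})

# Family names with a conserved alternative spelling; applied only when a
# dataset is loaded with canonicalize_families=True so that counts over the
# fixture match the printed table verbatim by default.
FAMILY_SYNONYMS = {"compositae": "Asteraceae", "leguminosae": "Fabaceae"}

_LIST_SEP = ";"
_LOCAL_NAME_RE = re.compile(r"^(?P<name>.+?)\s*\[(?P<tags>[^\]]*)\]$")


class SchemaError(ValueError):
    """A table is missing a required column or has a malformed cell."""


class VocabularyError(ValueError):
    """A term cannot be resolved against the controlled vocabulary."""


def canonical_term(term: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Lower-case, trim and collapse whitespace; then apply synonym mapping."""
    t = re.sub(r"\s+", " ", term.strip()).lower()
    if synonyms:
        t = synonyms.get(t, t)
    return t


def normalize_scientific_name(name: str) -> str:
    """Case-folded binomial with authorities stripped, infraspecific rank kept.

    ``"Plocama brevifolia subsp. Brevifolia Rubiaceae"`` → ``"plocama
    brevifolia subsp. brevifolia"``.  Author strings are dropped by keeping
    only the first two epithets plus any ``subsp.``/``var.`` qualifier.
    """
    toks = re.sub(r"\s+", " ", name.strip()).split(" ")
    if not toks or not toks[0]:
        return ""
    out = toks[:2]
    for i, tok in enumerate(toks[2:], start=2):
        low = tok.lower().rstrip(".")
        if low in {"subsp", "ssp", "var"} and i + 1 < len(toks):
            out.extend([low + ".", toks[i + 1]])
            break
    return " ".join(out).lower()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Informant:
    informant_id: str
    village: str
    linguistic_group: str
    gender: str  # "M" or "F"
    age: int | None = None  # years; surveys may publish only ranges


@dataclass(frozen=True)
class SpeciesRecord:
    """One species row: taxonomy, local names, remedy descriptors, counts.

    ``fc`` is the frequency of citation (distinct citing informants) and
    ``um`` the use mentions for the species' principal purpose; both are
    stored in aggregate mode and derived from use reports in raw mode.
    ``groups`` holds the linguistic groups that quote the species.
    """

    species_id: str
    scientific_name: str
    family: str
    local_names: tuple[tuple[str, str], ...]  # (name, language tag)
    habit: str
    parts_used: frozenset[str]
    preparations: frozenset[str]
    routes: frozenset[str]
    ailments: tuple[str, ...]
    voucher_id: str = ""
    groups: frozenset[str] = frozenset()
    fc: int | None = None
    um: int | None = None


@dataclass(frozen=True)
class UseReport:
    informant_id: str
    species_id: str
    ailment: str
    part: str = ""
    preparation: str = ""
    route: str = ""


@dataclass(frozen=True)
class DiseaseCategory:
    """An ICPC-2-style ailment category, optionally with stored aggregates.

    ``nt``/``nur`` are the published per-category taxon and use-report
    totals; the exemplar fields hold the category's highest-fidelity
    species with its purpose-specific (``exemplar_um``) and total
    (``exemplar_fc``) citation counts.
    """

    code: str
    description: str
    ailment_terms: frozenset[str] = frozenset()
    nt: int | None = None
    nur: int | None = None
    exemplar_species: str = ""
    exemplar_uses: str = ""
    exemplar_fc: int | None = None
    exemplar_um: int | None = None


@dataclass(frozen=True)
class ValidationIssue:
    locator: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def summary(self) -> str:
        lines = [f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"]
        for kind, issues in (("ERROR", self.errors), ("WARNING", self.warnings)):
            lines.extend(f"{kind} [{i.rule}] {i.locator}: {i.message}" for i in issues)
        return "\n".join(lines)


@dataclass
class Vocabulary:
    """Synonym map plus the ailment-term → disease-category mapping."""

    synonyms: dict[str, str] = field(default_factory=dict)
    categories: dict[str, DiseaseCategory] = field(default_factory=dict)
    group_codes: dict[str, str] = field(default_factory=dict)  # tag → group name

    def __post_init__(self) -> None:
        self._term_to_code: dict[str, str] = {}
        for code, cat in self.categories.items():
            for term in cat.ailment_terms:
                if term in self._term_to_code and self._term_to_code[term] != code:
                    raise VocabularyError(
                        f"ailment term {term!r} mapped to both "
                        f"{self._term_to_code[term]!r} and {code!r}"
                    )
                self._term_to_code[term] = code

    def category_of(self, term: str, strict: bool = False) -> str | None:
        """Resolve an ailment term to a category code.

        Unresolved terms return ``None`` in lenient mode (callers bin them
        under ``OTH``) and raise :class:`VocabularyError` in strict mode.
        """
        code = self._term_to_code.get(canonical_term(term, self.synonyms))
        if code is None and strict:
            raise VocabularyError(f"ailment term {term!r} not in vocabulary")
        return code

    def canonical(self, term: str) -> str:
        return canonical_term(term, self.synonyms)


@dataclass
class SurveyDataset:
    """Informants, species records and use reports with shared vocabularies."""

    informants: list[Informant]
    species: list[SpeciesRecord]
    use_reports: list[UseReport]
    categories: list[DiseaseCategory]
    mode: str  # "raw" or "aggregate"
    groups: tuple[str, ...] = ()
    vocabulary: Vocabulary | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"raw", "aggregate"}:
            raise ValueError(f"unknown dataset mode {self.mode!r}")
        if not self.groups:
            self.groups = tuple(
                sorted({i.linguistic_group for i in self.informants})
            )

    # -- convenience lookups ------------------------------------------------

    @property
    def n_informants(self) -> int:
        """N: the total number of respondents."""
        return len(self.informants)

    @property
    def species_by_id(self) -> dict[str, SpeciesRecord]:
        return {s.species_id: s for s in self.species}

    @property
    def informants_by_id(self) -> dict[str, Informant]:
        return {i.informant_id: i for i in self.informants}

    def category(self, code: str) -> DiseaseCategory:
        for cat in self.categories:
            if cat.code == code:
                return cat
        raise KeyError(code)

    def citation_counts(self) -> dict[str, int]:
        """Distinct-informant citation count per species from use reports."""
        cited: dict[str, set[str]] = {}
        for r in self.use_reports:
            cited.setdefault(r.species_id, set()).add(r.informant_id)
        return {sid: len(inf) for sid, inf in cited.items()}


# ---------------------------------------------------------------------------
# Vocabulary I/O
# ---------------------------------------------------------------------------


def load_vocabulary(path: str | Path) -> Vocabulary:
    """Read a YAML vocabulary: synonym map, group codes, term→category map."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    categories = {}
    for code, spec in (raw.get("categories") or {}).items():
        categories[code] = DiseaseCategory(
            code=code,
            description=spec.get("description", ""),
            ailment_terms=frozenset(
                canonical_term(t) for t in spec.get("terms", [])
            ),
        )
    return Vocabulary(
        synonyms={
            canonical_term(k): canonical_term(v)
            for k, v in (raw.get("synonyms") or {}).items()
        },
        categories=categories,
        group_codes=dict(raw.get("groups") or {}),
    )


# ---------------------------------------------------------------------------
# Tabular readers / writers
# ---------------------------------------------------------------------------

_INFORMANT_COLS = ["informant_id", "village", "linguistic_group", "gender", "age"]
_SPECIES_COLS = [
    "species_id",
    "scientific_name",
    "family",
    "local_names",
    "voucher_id",
    "habit",
    "parts_used",
    "preparations",
    "routes",
    "ailments",
    "groups",
    "fc",
    "um",
]
_REPORT_COLS = ["informant_id", "species_id", "ailment", "part", "preparation", "route"]
_CATEGORY_COLS = [
    "code",
    "description",
    "ailments",
    "nbt",
    "nur",
    "exemplar_species",
    "exemplar_uses",
    "exemplar_fc",
    "exemplar_um",
]


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _split_list(cell: str) -> list[str]:
    return [p.strip() for p in cell.split(_LIST_SEP) if p.strip()]


def _parse_local_names(cell: str) -> tuple[tuple[str, str], ...]:
    pairs: list[tuple[str, str]] = []
    for chunk in _split_list(cell):
        m = _LOCAL_NAME_RE.match(chunk)
        if not m:
            pairs.append((chunk, ""))
            continue
        tags = [t.strip() for t in m.group("tags").split(",") if t.strip()]
        pairs.extend((m.group("name"), tag) for tag in (tags or [""]))
    return tuple(pairs)


def _format_local_names(pairs: Iterable[tuple[str, str]]) -> str:
    by_name: dict[str, list[str]] = {}
    order: list[str] = []
    for name, tag in pairs:
        if name not in by_name:
            order.append(name)
        by_name.setdefault(name, [])
        if tag:
            by_name[name].append(tag)
    chunks = []
    for name in order:
        tags = by_name[name]
        chunks.append(f"{name} [{','.join(tags)}]" if tags else name)
    return f"{_LIST_SEP} ".join(chunks)


def _opt_int(cell: str, where: str) -> int | None:
    cell = cell.strip()
    if not cell:
        return None
    try:
        return int(cell)
    except ValueError as exc:
        raise SchemaError(f"{where}: expected integer, got {cell!r}") from exc


def _canon_set(
    cell: str, vocab: Vocabulary | None, known: frozenset[str], what: str, strict: bool
) -> frozenset[str]:
    synonyms = vocab.synonyms if vocab else None
    terms = frozenset(canonical_term(t, synonyms) for t in _split_list(cell))
    if strict:
        unknown = terms - known
        if unknown:
            raise VocabularyError(f"unknown {what} term(s): {sorted(unknown)}")
    return terms


def load_survey(
    informant_path: str | Path,
    species_path: str | Path,
    reports_path: str | Path | None = None,
    vocab_path: str | Path | None = None,
    category_path: str | Path | None = None,
    strict: bool = False,
    canonicalize_families: bool = False,
) -> SurveyDataset:
    """Load a survey from delimiter-separated text tables.

    The dataset is returned in raw mode when ``reports_path`` is given and
    aggregate mode otherwise.  Referential-integrity checks are deferred to
    :func:`validate_dataset`; only schema and (in strict mode) vocabulary
    problems raise here.
    """
    vocab = load_vocabulary(vocab_path) if vocab_path else None
    syn = vocab.synonyms if vocab else None

    inf_df = _read_table(informant_path, _INFORMANT_COLS)
    informants = [
        Informant(
            informant_id=row.informant_id.strip(),
            village=row.village.strip(),
            linguistic_group=row.linguistic_group.strip(),
            gender=row.gender.strip().upper(),
            age=_opt_int(row.age, f"informants.age ({row.informant_id})"),
        )
        for row in inf_df.itertuples()
    ]

    sp_df = _read_table(species_path, [c for c in _SPECIES_COLS if c not in ("groups", "fc", "um")])
    species = []
    for row in sp_df.itertuples():
        family = row.family.strip()
        if canonicalize_families:
            family = FAMILY_SYNONYMS.get(family.lower(), family)
        habit = canonical_term(row.habit, syn)
        if strict and habit not in HABITS:
            raise VocabularyError(f"unknown habit {habit!r} for {row.species_id}")
        species.append(
            SpeciesRecord(
                species_id=row.species_id.strip(),
                scientific_name=re.sub(r"\s+", " ", row.scientific_name.strip()),
                family=family,
                local_names=_parse_local_names(row.local_names),
                habit=habit,
                parts_used=_canon_set(row.parts_used, vocab, PARTS, "part", strict),
                preparations=_canon_set(
                    row.preparations, vocab, PREPARATIONS, "preparation", strict
                ),
                routes=_canon_set(row.routes, vocab, ROUTES, "route", strict),
                ailments=tuple(
                    canonical_term(t, syn) for t in _split_list(row.ailments)
                ),
                voucher_id=row.voucher_id.strip(),
                groups=frozenset(
                    # group cells may use short language tags; expand them
                    (vocab.group_codes.get(g, g) if vocab else g)
                    for g in _split_list(
                        getattr(row, "groups", "").replace(",", _LIST_SEP)
                    )
                ),
                fc=_opt_int(getattr(row, "fc", ""), f"species.fc ({row.species_id})"),
                um=_opt_int(getattr(row, "um", ""), f"species.um ({row.species_id})"),
            )
        )

    use_reports: list[UseReport] = []
    mode = "aggregate"
    if reports_path is not None:
        mode = "raw"
        rep_df = _read_table(reports_path, ["informant_id", "species_id", "ailment"])
        for row in rep_df.itertuples():
            use_reports.append(
                UseReport(
                    informant_id=row.informant_id.strip(),
                    species_id=row.species_id.strip(),
                    ailment=canonical_term(row.ailment, syn),
                    part=canonical_term(getattr(row, "part", ""), syn),
                    preparation=canonical_term(getattr(row, "preparation", ""), syn),
                    route=canonical_term(getattr(row, "route", ""), syn),
                )
            )

    categories: list[DiseaseCategory] = []
    if category_path is not None:
        cat_df = _read_table(category_path, ["code", "description"])
        for row in cat_df.itertuples():
            base = vocab.categories.get(row.code) if vocab else None
            categories.append(
                DiseaseCategory(
                    code=row.code.strip(),
                    description=row.description.strip(),
                    ailment_terms=base.ailment_terms if base else frozenset(),
                    nt=_opt_int(getattr(row, "nbt", ""), f"categories.nbt ({row.code})"),
                    nur=_opt_int(getattr(row, "nur", ""), f"categories.nur ({row.code})"),
                    exemplar_species=getattr(row, "exemplar_species", "").strip(),
                    exemplar_uses=getattr(row, "exemplar_uses", "").strip(),
                    exemplar_fc=_opt_int(getattr(row, "exemplar_fc", ""), row.code),
                    exemplar_um=_opt_int(getattr(row, "exemplar_um", ""), row.code),
                )
            )
    elif vocab is not None:
        categories = [vocab.categories[c] for c in sorted(vocab.categories)]

    # In raw mode, derive missing per-species citation counts from reports.
    if mode == "raw":
        counts = None
        if any(s.fc is None for s in species):
            cited: dict[str, set[str]] = {}
            for r in use_reports:
                cited.setdefault(r.species_id, set()).add(r.informant_id)
            counts = {sid: len(v) for sid, v in cited.items()}
        if counts is not None:
            species = [
                s if s.fc is not None else replace(s, fc=counts.get(s.species_id, 0))
                for s in species
            ]

    return SurveyDataset(
        informants=informants,
        species=species,
        use_reports=use_reports,
        categories=categories,
        mode=mode,
        vocabulary=vocab,
    )


def write_survey(ds: SurveyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset back to its three-table text form.

    Rows are emitted in canonical (id-sorted) order so that a write/load
    round trip is byte-stable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    inf_rows = [
        {
            "informant_id": i.informant_id,
            "village": i.village,
            "linguistic_group": i.linguistic_group,
            "gender": i.gender,
            "age": "" if i.age is None else i.age,
        }
        for i in sorted(ds.informants, key=lambda i: i.informant_id)
    ]
    paths["informants"] = out / "informants.csv"
    pd.DataFrame(inf_rows, columns=_INFORMANT_COLS).to_csv(paths["informants"], index=False)

    sp_rows = [
        {
            "species_id": s.species_id,
            "scientific_name": s.scientific_name,
            "family": s.family,
            "local_names": _format_local_names(s.local_names),
            "voucher_id": s.voucher_id,
            "habit": s.habit,
            "parts_used": f"{_LIST_SEP} ".join(sorted(s.parts_used)),
            "preparations": f"{_LIST_SEP} ".join(sorted(s.preparations)),
            "routes": f"{_LIST_SEP} ".join(sorted(s.routes)),
            "ailments": f"{_LIST_SEP} ".join(s.ailments),
            "groups": ",".join(sorted(s.groups)),
            "fc": "" if s.fc is None else s.fc,
            "um": "" if s.um is None else s.um,
        }
        for s in sorted(ds.species, key=lambda s: s.species_id)
    ]
    paths["species"] = out / "species.csv"
    pd.DataFrame(sp_rows, columns=_SPECIES_COLS).to_csv(paths["species"], index=False)

    if ds.mode == "raw":
        rep_rows = [
            {
                "informant_id": r.informant_id,
                "species_id": r.species_id,
                "ailment": r.ailment,
                "part": r.part,
                "preparation": r.preparation,
                "route": r.route,
            }
            for r in sorted(
                ds.use_reports, key=lambda r: (r.informant_id, r.species_id, r.ailment)
            )
        ]
        paths["use_reports"] = out / "use_reports.csv"
        pd.DataFrame(rep_rows, columns=_REPORT_COLS).to_csv(
            paths["use_reports"], index=False
        )

    if ds.categories:
        cat_rows = [
            {
                "code": c.code,
                "description": c.description,
                "ailments": f"{_LIST_SEP} ".join(sorted(c.ailment_terms)),
                "nbt": "" if c.nt is None else c.nt,
                "nur": "" if c.nur is None else c.nur,
                "exemplar_species": c.exemplar_species,
                "exemplar_uses": c.exemplar_uses,
                "exemplar_fc": "" if c.exemplar_fc is None else c.exemplar_fc,
                "exemplar_um": "" if c.exemplar_um is None else c.exemplar_um,
            }
            for c in ds.categories
        ]
        paths["categories"] = out / "categories.csv"
        pd.DataFrame(cat_rows, columns=_CATEGORY_COLS).to_csv(
            paths["categories"], index=False
        )

    vocab = ds.vocabulary
    if vocab is None and any(c.ailment_terms for c in ds.categories):
        vocab = Vocabulary(
            categories={c.code: c for c in ds.categories},
        )
    if vocab is not None:
        doc = {
            "groups": vocab.group_codes,
            "synonyms": vocab.synonyms,
            "categories": {
                code: {
                    "description": cat.description,
                    "terms": sorted(cat.ailment_terms),
                }
                for code, cat in sorted(vocab.categories.items())
            },
        }
        paths["vocabulary"] = out / "vocabulary.yaml"
        with open(paths["vocabulary"], "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True, allow_unicode=True)
    return paths


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_dataset(ds: SurveyDataset, strict: bool = False) -> ValidationReport:
    """Check every dataset invariant; report, never raise or mutate.

    Strict mode escalates vocabulary and data-quality warnings (unknown
    controlled-vocabulary terms, ages outside the study's 20–80 range) to
    errors.
    """
    rep = ValidationReport()

    def issue(locator: str, rule: str, msg: str, *, warn: bool = False) -> None:
        bucket = rep.warnings if (warn and not strict) else rep.errors
        bucket.append(ValidationIssue(locator, rule, msg))

    n = ds.n_informants
    if n == 0:
        rep.errors.append(ValidationIssue("dataset", "no-informants", "N must be > 0"))

    seen_inf: set[str] = set()
    declared_groups = set(ds.groups)
    for i in ds.informants:
        if i.informant_id in seen_inf:
            issue(i.informant_id, "dup-informant", "duplicate informant_id")
        seen_inf.add(i.informant_id)
        if i.linguistic_group not in declared_groups:
            issue(
                i.informant_id,
                "unknown-group",
                f"linguistic group {i.linguistic_group!r} not declared",
            )
        if i.gender not in {"M", "F", ""}:
            issue(i.informant_id, "bad-gender", f"gender {i.gender!r} not M/F")
        if i.age is not None and not (20 <= i.age <= 80):
            issue(i.informant_id, "age-range", f"age {i.age} outside 20-80", warn=True)

    tag_names = {
        tag for s in ds.species for _, tag in s.local_names if tag
    }
    vocab = ds.vocabulary
    if vocab and vocab.group_codes:
        known_tags = set(vocab.group_codes) | set(vocab.group_codes.values())
        for tag in sorted(tag_names - known_tags):
            issue("species", "unknown-language-tag", f"tag {tag!r} unmapped", warn=True)

    seen_sp: set[str] = set()
    for s in ds.species:
        loc = s.species_id
        if s.species_id in seen_sp:
            issue(loc, "dup-species", "duplicate species_id")
        seen_sp.add(s.species_id)
        if s.habit not in HABITS:
            issue(loc, "bad-habit", f"habit {s.habit!r} not in {sorted(HABITS)}", warn=True)
        for term_set, known, rule in (
            (s.parts_used, PARTS, "bad-part"),
            (s.preparations, PREPARATIONS, "bad-preparation"),
            (s.routes, ROUTES, "bad-route"),
        ):
            for t in sorted(term_set - known):
                issue(loc, rule, f"term {t!r} outside controlled vocabulary", warn=True)
        if s.fc is not None:
            if s.fc < 0:
                issue(loc, "fc-negative", f"fc {s.fc} < 0")
            if n and s.fc > n:
                issue(loc, "fc-exceeds-n", f"fc {s.fc} exceeds N={n}")
        if s.um is not None:
            if s.fc is None:
                issue(loc, "um-without-fc", "um present but fc missing")
            elif not (0 <= s.um <= s.fc):
                issue(loc, "um-range", f"um {s.um} outside [0, fc={s.fc}]")
        if ds.mode == "aggregate" and s.fc is None:
            issue(loc, "fc-missing", "aggregate mode requires fc for every species")
        if s.groups and not s.groups <= declared_groups:
            issue(
                loc,
                "unknown-group",
                f"groups {sorted(s.groups - declared_groups)} not declared",
            )
        if not s.ailments:
            issue(loc, "no-ailments", "species lists no ailments", warn=True)

    for idx, r in enumerate(ds.use_reports):
        loc = f"use_report[{idx}]"
        if r.informant_id not in seen_inf:
            issue(loc, "unknown-informant", f"informant {r.informant_id!r} not found")
        if r.species_id not in seen_sp:
            issue(loc, "unknown-species", f"species {r.species_id!r} not found")
        if not r.ailment:
            issue(loc, "empty-ailment", "use report has an empty ailment term")

    if ds.mode == "raw":
        counts = ds.citation_counts()
        for s in ds.species:
            if s.fc is not None and s.fc != counts.get(s.species_id, 0):
                issue(
                    s.species_id,
                    "fc-mismatch",
                    f"stored fc={s.fc} but {counts.get(s.species_id, 0)} distinct "
                    "informants cite the species",
                )

    seen_codes: set[str] = set()
    term_owner: dict[str, str] = {}
    for c in ds.categories:
        if c.code in seen_codes:
            issue(c.code, "dup-category", "duplicate category code")
        seen_codes.add(c.code)
        for t in c.ailment_terms:
            if term_owner.get(t, c.code) != c.code:
                issue(
                    c.code,
                    "ambiguous-term",
                    f"ailment term {t!r} also mapped to {term_owner[t]!r}",
                )
            term_owner[t] = c.code
        if c.nt is not None and c.nur is not None and c.nt > c.nur:
            issue(c.code, "nt-exceeds-nur", f"Nt={c.nt} > Nur={c.nur}")

    return rep


# ---------------------------------------------------------------------------
# Packaged fixture
# ---------------------------------------------------------------------------

_FIXTURE_PKG = "ethnosurvey.fixtures.kohistan"


def fixture_path(filename: str) -> Path:
    """Path of a packaged Kohistan fixture file."""
    return Path(resources.files(_FIXTURE_PKG) / filename)


def kohistan_fixture(canonicalize_families: bool = False) -> SurveyDataset:
    """The packaged Kohistan survey transcription (aggregate mode).

    Twenty villages across five valleys (281 informants in five linguistic
    groups), 96 wild-medicinal-plant species with local names, remedy
    descriptors and citation counts, and twelve ICPC-2 disease categories
    with their published taxon/use-report totals and highest-fidelity
    exemplar species.
    """
    return load_survey(
        informant_path=fixture_path("informants.csv"),
        species_path=fixture_path("species.csv"),
        reports_path=None,
        vocab_path=fixture_path("vocabulary.yaml"),
        category_path=fixture_path("category_stats.csv"),
        canonicalize_families=canonicalize_families,
    )


def kohistan_literature() -> pd.DataFrame:
    """The packaged prior-literature stub used for novelty flagging.

    A curated stub, not a bibliography: one row per previously reported
    taxon (with its recorded use), so that taxa absent from it are flagged
    as first reports.
    """
    return pd.read_csv(fixture_path("literature_stub.csv"), dtype=str, keep_default_na=False)
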