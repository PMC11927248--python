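"""Questionnaire data model: item scales, recode rules, factor specifications.

A questionnaire is described declaratively (YAML or JSON) so that the cleaning
and scoring rules are data, not code.  Every item carries:

* its response scale — Likert (3-7 points), binary, or categorical — with the
  scored labels in *raw administration order* (index = raw code);
* the set of non-scored labels ("Don't know", "Not relevant", ...) that never
  receive a value;
* a reverse-coding flag: scored code = ``c - 1 - raw`` for negatively phrased
  items, so that after cleaning a higher code always means better treatment;
* an optional recode rule mapping raw labels directly to scored codes, to the
  NON_SCORED marker, or to MEDIAN_IMPUTE (resolved later at column level),
  including merged categories that collapse to one code.

Scored codes are 0-based integers, worst -> best after recode + reverse; all
downstream arithmetic (normalization, scoring) assumes this orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

SPEC_VERSION = "1"


class _Marker:
    """Singleton sentinel for special cell states."""

    __slots__ = ("name",)

    def __init__(self, name: str):
        self.name = name

    def __repr__(self) -> str:
        return self.name


#: response carries no value (excluded from scoring; imputed for factor analysis)
NON_SCORED = _Marker("NON_SCORED")
#: response to be replaced by the item's column median
MEDIAN_IMPUTE = _Marker("MEDIAN_IMPUTE")

SCALE_KINDS = ("likert", "binary", "categorical")


class SchemaError(ValueError):
    """Raised with the full list of schema violations, not just the first."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class ResponseScale:
    """Scale metadata of one item.

    ``scored_labels`` are ordered worst -> best *after* any recode/reverse;
    ``n_scored_categories`` is the ``c_i`` of the normalization q/(c_i - 1).
    """

    kind: str
    scored_labels: tuple[str, ...]
    non_scored_labels: frozenset[str] = frozenset()

    @property
    def n_scored_categories(self) -> int:
        return len(self.scored_labels)

    def validate(self, prefix: str = "") -> list[str]:
        errs = []
        if self.kind not in SCALE_KINDS:
            errs.append(f"{prefix}unknown scale kind {self.kind!r}")
        if self.n_scored_categories < 2:
            errs.append(f"{prefix}needs >= 2 scored categories")
        if len(set(self.scored_labels)) != len(self.scored_labels):
            errs.append(f"{prefix}duplicate scored labels")
        overlap = set(self.scored_labels) & self.non_scored_labels
        if overlap:
            errs.append(f"{prefix}labels both scored and non-scored: {sorted(overlap)}")
        return errs


@dataclass(frozen=True)
class RecodeRule:
    """Explicit raw-label -> code mapping for one item.

    ``mapping`` values are scored codes (int), NON_SCORED, or MEDIAN_IMPUTE;
    ``merged_categories`` documents label sets collapsed onto a single code.
    """

    item_id: str
    mapping: dict[str, object]
    merged_categories: tuple[frozenset[str], ...] = ()

    def validate(self, item: "ItemDefinition") -> list[str]:
        errs = []
        c = item.scale.n_scored_categories
        all_labels = set(item.scale.scored_labels) | set(item.scale.non_scored_labels)
        mapped = set(self.mapping)
        # the mapping must be total over the declared labels; it may contain
        # additional raw-only aliases (e.g. merged source categories)
        missing = sorted(all_labels - mapped)
        if missing:
            errs.append(f"item {item.item_id!r}: recode misses labels {missing}")
        for lbl, code in self.mapping.items():
            if isinstance(code, int) and not 0 <= code < c:
                errs.append(f"item {item.item_id!r}: recode of {lbl!r} -> {code} outside 0..{c-1}")
            elif not isinstance(code, int) and code not in (NON_SCORED, MEDIAN_IMPUTE):
                errs.append(f"item {item.item_id!r}: recode of {lbl!r} has invalid target {code!r}")
        for group in self.merged_categories:
            codes = {self.mapping.get(lbl) for lbl in group}
            if len(codes) != 1:
                errs.append(
                    f"item {item.item_id!r}: merged labels {sorted(group)} map to several codes"
                )
        return errs


@dataclass(frozen=True)
class ItemDefinition:
    item_id: str
    prompt_key: str
    scale: ResponseScale
    reverse_coded: bool = False
    recode: RecodeRule | None = None


@dataclass
class QuestionnaireSchema:
    """Ordered collection of item definitions (the questionnaire contract)."""

    items: list[ItemDefinition]
    version: str = SPEC_VERSION

    def __post_init__(self):
        self._by_id = {it.item_id: it for it in self.items}

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def __getitem__(self, item_id: str) -> ItemDefinition:
        return self._by_id[item_id]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id

    def __len__(self) -> int:
        return len(self.items)

    def n_categories(self) -> "np.ndarray":
        import numpy as np

        return np.array([it.scale.n_scored_categories for it in self.items])

    def validate(self) -> list[str]:
        errs: list[str] = []
        if not self.items:
            errs.append("schema has no items")
        seen: set[str] = set()
        for it in self.items:
            if it.item_id in seen:
                errs.append(f"duplicate item id {it.item_id!r}")
            seen.add(it.item_id)
            errs.extend(it.scale.validate(prefix=f"item {it.item_id!r}: "))
            if it.recode is not None:
                errs.extend(it.recode.validate(it))
        return errs


@dataclass(frozen=True)
class FactorSpec:
    """One factor's signed pattern loadings w_i over schema items."""

    factor_name: str
    loadings: tuple[tuple[str, float], ...]

    @property
    def item_ids(self) -> list[str]:
        return [i for i, _ in self.loadings]

    def weight(self, item_id: str) -> float:
        for i, w in self.loadings:
            if i == item_id:
                return w
        raise KeyError(item_id)


@dataclass(frozen=True)
class DomainGrouping:
    """Partition of factors into responsiveness vs respectful treatment."""

    responsiveness_factors: tuple[str, ...]
    respectful_factors: tuple[str, ...]

    def validate(self, factor_names: list[str]) -> list[str]:
        errs = []
        resp, respect = set(self.responsiveness_factors), set(self.respectful_factors)
        if resp & respect:
            errs.append(f"factors in both domains: {sorted(resp & respect)}")
        uncovered = set(factor_names) - resp - respect
        if uncovered:
            errs.append(f"factors in neither domain: {sorted(uncovered)}")
        return errs


# ---------------------------------------------------------------------------
# operations


def apply_recode(raw_label: str, item: ItemDefinition):
    """Resolve one raw label to a scored code, NON_SCORED or MEDIAN_IMPUTE.

    When the item carries a recode rule the rule is total and authoritative
    (its codes are already in the scored orientation).  Without one, the
    label's index in ``scored_labels`` (stored worst -> best) is the scored
    code.  The ``reverse_coded`` flag applies only to *numeric* raw codes,
    whose administered coding runs opposite to the scored orientation; label
    lookups are orientation-free by construction.
    """
    if item.recode is not None:
        try:
            return item.recode.mapping[raw_label]
        except KeyError:
            raise KeyError(
                f"item {item.item_id!r}: unknown label {raw_label!r}"
            ) from None
    if raw_label in item.scale.non_scored_labels:
        return NON_SCORED
    try:
        return item.scale.scored_labels.index(raw_label)
    except ValueError:
        raise KeyError(f"item {item.item_id!r}: unknown label {raw_label!r}") from None


def reverse_code(value: int, c: int) -> int:
    """Flip a scored code: 0 <-> c-1.  Involution: applying twice is identity."""
    if not 0 <= value <= c - 1:
        raise ValueError(f"code {value} outside 0..{c - 1}")
    return c - 1 - value


# ---------------------------------------------------------------------------
# serialization

_SENTINEL_NAMES = {"NON_SCORED": NON_SCORED, "MEDIAN_IMPUTE": MEDIAN_IMPUTE}


def _load_doc(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _dump_doc(doc: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=1))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))


def load_schema(path) -> QuestionnaireSchema:
    """Load and validate a questionnaire schema file (YAML or JSON)."""
    doc = _load_doc(path)
    items = []
    for entry in doc.get("items", []):
        labels = tuple(str(x) for x in entry["labels"])
        scale = ResponseScale(
            kind=entry["kind"],
            scored_labels=labels,
            non_scored_labels=frozenset(str(x) for x in entry.get("non_scored", [])),
        )
        recode = None
        if entry.get("recode"):
            mapping = {
                str(lbl): _SENTINEL_NAMES.get(code, code)
                for lbl, code in entry["recode"]["mapping"].items()
            }
            merged = tuple(
                frozenset(str(x) for x in grp)
                for grp in entry["recode"].get("merged", [])
            )
            recode = RecodeRule(entry["id"], mapping, merged)
        items.append(
            ItemDefinition(
                item_id=str(entry["id"]),
                prompt_key=str(entry.get("prompt", entry["id"])),
                scale=scale,
                reverse_coded=bool(entry.get("reverse", False)),
                recode=recode,
            )
        )
    schema = QuestionnaireSchema(items=items, version=str(doc.get("spec_version", SPEC_VERSION)))
    errs = schema.validate()
    for entry in doc.get("items", []):
        declared = int(entry.get("n_categories", len(entry["labels"])))
        if declared != len(entry["labels"]):
            errs.append(
                f"item {entry['id']!r}: n_categories={declared} but {len(entry['labels'])} labels"
            )
    if errs:
        raise SchemaError(errs)
    return schema


def dump_schema(schema: QuestionnaireSchema, path) -> None:
    doc = {"spec_version": schema.version, "items": []}
    for it in schema.items:
        entry = {
            "id": it.item_id,
            "prompt": it.prompt_key,
            "kind": it.scale.kind,
            "n_categories": it.scale.n_scored_categories,
            "labels": list(it.scale.scored_labels),
            "non_scored": sorted(it.scale.non_scored_labels),
            "reverse": it.reverse_coded,
        }
        if it.recode is not None:
            entry["recode"] = {
                "mapping": {
                    lbl: (code.name if isinstance(code, _Marker) else code)
                    for lbl, code in it.recode.mapping.items()
                },
                "merged": [sorted(grp) for grp in it.recode.merged_categories],
            }
        doc["items"].append(entry)
    _dump_doc(doc, path)


def load_factor_specs(path) -> list[FactorSpec]:
    """Load a factor specification file: ``factors: [{name, items: [{id, loading}]}]``."""
    doc = _load_doc(path)
    specs = []
    seen_items: dict[str, str] = {}
    errs = []
    for entry in doc.get("factors", []):
        loadings = tuple(
            (str(x["id"]), float(x["loading"])) for x in entry["items"]
        )
        for iid, w in loadings:
            if w == 0:
                errs.append(f"factor {entry['name']!r}: zero loading on {iid!r}")
            if iid in seen_items:
                errs.append(
                    f"item {iid!r} appears in factors {seen_items[iid]!r} and {entry['name']!r}"
                )
            seen_items[iid] = entry["name"]
        specs.append(FactorSpec(str(entry["name"]), loadings))
    if errs:
        raise SchemaError(errs)
    return specs


def dump_factor_specs(specs: list[FactorSpec], path) -> None:
    doc = {
        "spec_version": SPEC_VERSION,
        "factors": [
            {
                "name": s.factor_name,
                "items": [{"id": i, "loading": float(w)} for i, w in s.loadings],
            }
            for s in specs
        ],
    }
    _dump_doc(doc, path)


def load_grouping(path) -> DomainGrouping:
    doc = _load_doc(path)
    return DomainGrouping(
        responsiveness_factors=tuple(doc["responsiveness"]),
        respectful_factors=tuple(doc["respectful"]),
    )


def dump_grouping(grouping: DomainGrouping, path) -> None:
    _dump_doc(
        {
            "spec_version": SPEC_VERSION,
            "responsiveness": list(grouping.responsiveness_factors),
            "respectful": list(grouping.respectful_factors),
        },
        path,
    )


# ---------------------------------------------------------------------------
# bundled fixtures

_FIXDIR = Path(__file__).parent / "fixtures"


def default_schema() -> QuestionnaireSchema:
    """The bundled 36-item respectful-maternity-care questionnaire schema.

    The prompts and scales are a documented reconstruction of the instrument
    (the original administration metadata is not public); the schema file is
    the contract, so corrected metadata can be dropped in without code change.
    """
    return load_schema(_FIXDIR / "questionnaire_schema.yaml")


def default_factor_specs() -> list[FactorSpec]:
    """The published six-factor pattern-loading solution used as default weights."""
    return load_factor_specs(_FIXDIR / "six_factor_solution.yaml")


def default_grouping() -> DomainGrouping:
    return load_grouping(_FIXDIR / "domain_grouping.yaml")
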