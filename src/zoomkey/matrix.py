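"""Taxon × character matrices and their facet schemas.

A multi-access (matrix) key scores each taxon against a set of characters.
Characters are either *categorical* (an ordered vocabulary of state labels;
a taxon may be scored for several states at once, e.g. an achene that can be
trigonous or lenticular) or *numeric* (an inclusive range of measurements,
e.g. blade width 2–10 mm). A score may also be UNKNOWN, which is distinct
from any state and from zero: unknown scores never eliminate a taxon.

The on-disk form is a CSV dialect modelled on matrix-key exports (Lucid and
kin): one header row, the first column holding the taxon name, categorical
characters as single columns with multi-state cells joined by a separator
(default ``|``), and numeric characters as paired ``Name:min`` / ``Name:max``
columns. A single column whose every non-empty cell parses as a number is
read as a numeric character of degenerate ranges ``[v, v]``; pin a
controlled vocabulary in :class:`MatrixConfig` to force categorical reading.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field


class _Unknown:
    """Singleton marker for a missing score."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNKNOWN"

    def __bool__(self) -> bool:
        return False


#: The missing-score sentinel. Never coerced to a state label or to 0.
UNKNOWN = _Unknown()

CATEGORICAL = "categorical"
NUMERIC = "numeric"


class MatrixError(ValueError):
    """Base class for matrix schema and validation failures."""


class MatrixSchemaError(MatrixError):
    pass


class MatrixDialectError(MatrixError):
    pass


@dataclass(frozen=True)
class CharacterDef:
    """One character (facet) of the key.

    Parameters
    ----------
    name
        Short label; unique within a matrix.
    kind
        ``"categorical"`` or ``"numeric"``.
    states
        Ordered state vocabulary (categorical only; ≥1 entry, unique).
    units
        Free-text measurement units (numeric only; may be empty).
    """

    name: str
    kind: str
    states: tuple[str, ...] = ()
    units: str = ""

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise MatrixSchemaError("character name must be non-empty")
        if self.kind not in (CATEGORICAL, NUMERIC):
            raise MatrixSchemaError(f"unknown character kind {self.kind!r}")
        if self.kind == CATEGORICAL:
            if len(self.states) < 1:
                raise MatrixSchemaError(
                    f"categorical character {self.name!r} needs at least one state"
                )
            if len(set(self.states)) != len(self.states):
                raise MatrixSchemaError(
                    f"character {self.name!r} has duplicate state labels"
                )
        elif self.states:
            raise MatrixSchemaError(
                f"numeric character {self.name!r} must not declare states"
            )


@dataclass
class TaxonScore:
    """Scores of one taxon: character name → frozenset of state labels,
    ``(min, max)`` float pair, or :data:`UNKNOWN`.

    Characters absent from ``values`` are treated as UNKNOWN.
    """

    taxon: str
    values: dict = field(default_factory=dict)

    def get(self, character: str):
        return self.values.get(character, UNKNOWN)


@dataclass
class Matrix:
    """An ordered character list plus an ordered taxon list."""

    characters: list[CharacterDef] = field(default_factory=list)
    taxa: list[TaxonScore] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [c.name for c in self.characters]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise MatrixSchemaError(f"duplicate character names: {dupes}")
        taxon_names = [t.taxon for t in self.taxa]
        if len(set(taxon_names)) != len(taxon_names):
            dupes = sorted({n for n in taxon_names if taxon_names.count(n) > 1})
            raise MatrixSchemaError(f"duplicate taxon names: {dupes}")
        by_name = {c.name: c for c in self.characters}
        for t in self.taxa:
            for cname, value in t.values.items():
                if cname not in by_name:
                    raise MatrixSchemaError(
                        f"taxon {t.taxon!r} scores undeclared character {cname!r}"
                    )
                char = by_name[cname]
                if value is UNKNOWN:
                    continue
                if char.kind == CATEGORICAL:
                    if not isinstance(value, frozenset):
                        raise MatrixSchemaError(
                            f"{t.taxon!r}/{cname!r}: categorical score must be a frozenset"
                        )
                    bad = value - set(char.states)
                    if bad:
                        raise MatrixSchemaError(
                            f"{t.taxon!r}/{cname!r}: unknown state labels {sorted(bad)}"
                        )
                else:
                    lo, hi = value
                    if not (math.isfinite(lo) and math.isfinite(hi)):
                        raise MatrixSchemaError(
                            f"{t.taxon!r}/{cname!r}: non-finite range"
                        )
                    if lo > hi:
                        raise MatrixSchemaError(
                            f"{t.taxon!r}/{cname!r}: min {lo} > max {hi}"
                        )

    @property
    def character_names(self) -> list[str]:
        return [c.name for c in self.characters]

    def character(self, name: str) -> CharacterDef:
        for c in self.characters:
            if c.name == name:
                return c
        raise KeyError(name)

    def taxon(self, name: str) -> TaxonScore:
        for t in self.taxa:
            if t.taxon == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class MatrixConfig:
    """Dialect options for reading and writing matrix CSV.

    multivalue_sep
        Separator between state labels inside one categorical cell.
    vocabularies
        Optional controlled vocabularies: character name → ordered state
        tuple. Pinning a vocabulary forces categorical reading and makes
        labels outside the vocabulary an error instead of being collected.
    numeric_units
        Optional units per numeric character name.
    infer_numeric
        Treat a single column whose non-empty cells all parse as numbers
        as a numeric character of degenerate ranges.
    label_cap
        Maximum facet label length for :func:`facet_schema`.
    """

    multivalue_sep: str = "|"
    vocabularies: dict = field(default_factory=dict)
    numeric_units: dict = field(default_factory=dict)
    infer_numeric: bool = True
    label_cap: int = 40


_MIN_SUFFIX = ":min"
_MAX_SUFFIX = ":max"


def _is_number(text: str) -> bool:
    try:
        float(text)
    except ValueError:
        return False
    return True


def parse_matrix(csv_text: str, config: MatrixConfig | None = None) -> Matrix:
    """Parse a matrix CSV (RFC-4180 quoting) into a validated :class:`Matrix`.

    The header's first column names the taxon column (the label itself is
    ignored); every other column is a character column or half of a
    ``Name:min`` / ``Name:max`` numeric pair. Empty cells become UNKNOWN and
    all labels are whitespace-trimmed. Categorical state vocabularies are
    inferred from the data in order of first appearance unless pinned in
    ``config.vocabularies``.
    """
    cfg = config or MatrixConfig()
    rows = list(csv.reader(io.StringIO(csv_text)))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise MatrixSchemaError("empty CSV: header row required")
    header = [h.strip() for h in rows[0]]
    if len(header) < 1:
        raise MatrixSchemaError("header must contain at least the taxon column")

    # Column plan: (character name, kind, min-col index, max-col index | col index)
    columns = header[1:]
    if len(set(columns)) != len(columns):
        dupes = sorted({c for c in columns if columns.count(c) > 1})
        raise MatrixSchemaError(f"duplicate header columns: {dupes}")

    plan: list[tuple[str, str, tuple[int, ...]]] = []
    seen_numeric: dict[str, dict[str, int]] = {}
    order: list[str] = []
    for idx, col in enumerate(columns, start=1):
        if col.endswith(_MIN_SUFFIX) or col.endswith(_MAX_SUFFIX):
            base, suffix = col.rsplit(":", 1)
            base = base.strip()
            seen_numeric.setdefault(base, {})[suffix] = idx
            if base not in order:
                order.append(base)
        else:
            if col in seen_numeric:
                raise MatrixSchemaError(
                    f"column {col!r} conflicts with numeric pair columns"
                )
            plan.append((col, "single", (idx,)))
            order.append(col)
    for base, halves in seen_numeric.items():
        if set(halves) != {"min", "max"}:
            raise MatrixSchemaError(
                f"numeric character {base!r} needs both '{base}:min' and '{base}:max'"
            )
    plan_by_name = {name: (name, tag, cols) for name, tag, cols in plan}
    for base, halves in seen_numeric.items():
        if base in plan_by_name:
            raise MatrixSchemaError(
                f"character {base!r} appears both as a plain column and a numeric pair"
            )
        plan_by_name[base] = (base, "pair", (halves["min"], halves["max"]))
    ordered_plan = [plan_by_name[name] for name in order]

    def cell(row: list[str], idx: int) -> str:
        return row[idx].strip() if idx < len(row) else ""

    # First pass: collect raw cells per character and decide kinds.
    taxa_rows: list[tuple[str, list[str]]] = []
    seen_taxa: set[str] = set()
    for rownum, row in enumerate(rows[1:], start=2):
        taxon = row[0].strip() if row else ""
        if not taxon:
            raise MatrixSchemaError(f"row {rownum}: empty taxon name")
        if taxon in seen_taxa:
            raise MatrixSchemaError(f"row {rownum}: duplicate taxon name {taxon!r}")
        seen_taxa.add(taxon)
        taxa_rows.append((taxon, row))

    characters: list[CharacterDef] = []
    kinds: dict[str, str] = {}
    inferred_states: dict[str, list[str]] = {}
    for name, tag, cols in ordered_plan:
        if tag == "pair":
            kinds[name] = NUMERIC
            continue
        if name in cfg.vocabularies:
            kinds[name] = CATEGORICAL
            continue
        raw = [cell(row, cols[0]) for _, row in taxa_rows]
        nonempty = [v for v in raw if v]
        if (
            cfg.infer_numeric
            and nonempty
            and all(_is_number(v) for v in nonempty)
        ):
            kinds[name] = NUMERIC
        else:
            kinds[name] = CATEGORICAL

    for name, tag, cols in ordered_plan:
        if kinds[name] == NUMERIC:
            characters.append(
                CharacterDef(name, NUMERIC, units=cfg.numeric_units.get(name, ""))
            )
            continue
        if name in cfg.vocabularies:
            states = tuple(cfg.vocabularies[name])
        else:
            collected: list[str] = []
            for _, row in taxa_rows:
                raw = cell(row, cols[0])
                if not raw:
                    continue
                for label in raw.split(cfg.multivalue_sep):
                    label = label.strip()
                    if label and label not in collected:
                        collected.append(label)
            states = tuple(collected) if collected else ("present",)
        inferred_states[name] = list(states)
        characters.append(CharacterDef(name, CATEGORICAL, states=states))

    char_by_name = {c.name: c for c in characters}
    taxa: list[TaxonScore] = []
    for taxon, row in taxa_rows:
        values: dict = {}
        for name, tag, cols in ordered_plan:
            char = char_by_name[name]
            if tag == "pair":
                lo_raw, hi_raw = cell(row, cols[0]), cell(row, cols[1])
                if not lo_raw and not hi_raw:
                    continue  # UNKNOWN
                if not lo_raw or not hi_raw:
                    raise MatrixSchemaError(
                        f"{taxon!r}/{name!r}: both min and max required (or neither)"
                    )
                lo, hi = float(lo_raw), float(hi_raw)
                if lo > hi:
                    raise MatrixSchemaError(
                        f"{taxon!r}/{name!r}: min {lo} > max {hi}"
                    )
                values[name] = (lo, hi)
            else:
                raw = cell(row, cols[0])
                if not raw:
                    continue  # UNKNOWN
                if char.kind == NUMERIC:
                    v = float(raw)
                    values[name] = (v, v)
                else:
                    labels = frozenset(
                        s.strip() for s in raw.split(cfg.multivalue_sep) if s.strip()
                    )
                    if not labels:
                        continue
                    bad = labels - set(char.states)
                    if bad:
                        # only possible with a pinned vocabulary
                        raise MatrixSchemaError(
                            f"{taxon!r}/{name!r}: labels {sorted(bad)} not in the "
                            "controlled vocabulary"
                        )
                    values[name] = labels
        taxa.append(TaxonScore(taxon, values))

    return Matrix(characters, taxa)


def write_matrix(matrix: Matrix, config: MatrixConfig | None = None) -> str:
    """Serialize a matrix so that ``parse_matrix(write_matrix(m)) == m``.

    Categorical cells join their state labels with the multi-value separator
    in vocabulary order; UNKNOWN scores are written as empty cells. Fails
    loudly (``MatrixDialectError``) if a state label contains the separator,
    or if a categorical character's labels would be re-read as numbers —
    silent round-trip corruption is never allowed.
    """
    cfg = config or MatrixConfig()
    header = ["Taxon"]
    for char in matrix.characters:
        if char.kind == NUMERIC:
            header += [f"{char.name}{_MIN_SUFFIX}", f"{char.name}{_MAX_SUFFIX}"]
        else:
            for state in char.states:
                if cfg.multivalue_sep in state:
                    raise MatrixDialectError(
                        f"state label {state!r} of {char.name!r} contains the "
                        f"multi-value separator {cfg.multivalue_sep!r}; choose a "
                        "different separator"
                    )
            if (
                cfg.infer_numeric
                and char.name not in cfg.vocabularies
                and all(_is_number(s) for s in char.states)
            ):
                raise MatrixDialectError(
                    f"categorical character {char.name!r} has all-numeric state "
                    "labels and would be re-read as numeric; pin it in "
                    "MatrixConfig.vocabularies"
                )
            header.append(char.name)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(header)
    for t in matrix.taxa:
        row = [t.taxon]
        for char in matrix.characters:
            value = t.get(char.name)
            if char.kind == NUMERIC:
                if value is UNKNOWN:
                    row += ["", ""]
                else:
                    lo, hi = value
                    row += [_fmt_num(lo), _fmt_num(hi)]
            else:
                if value is UNKNOWN:
                    row.append("")
                else:
                    ordered = [s for s in char.states if s in value]
                    row.append(cfg.multivalue_sep.join(ordered))
        writer.writerow(row)
    return buf.getvalue()


def _fmt_num(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


@dataclass(frozen=True)
class FacetCategory:
    """One facet of the collection: a display name and a CXML value type."""

    name: str
    type: str  # "String" | "Number"


def facet_schema(
    matrix: Matrix, max_label_len: int | None = None, config: MatrixConfig | None = None
) -> list[FacetCategory]:
    """Derive the ordered facet categories from a matrix.

    One category per character, in matrix order: categorical → ``String``
    (multi-valued permitted), numeric → ``Number``. Names longer than the
    cap are truncated — facet panes reward brevity — and a post-truncation
    collision is an error rather than a silent merge.
    """
    cfg = config or MatrixConfig()
    cap = cfg.label_cap if max_label_len is None else max_label_len
    categories: list[FacetCategory] = []
    truncated_from: dict[str, list[str]] = {}
    for char in matrix.characters:
        label = char.name[:cap]
        truncated_from.setdefault(label, []).append(char.name)
        categories.append(
            FacetCategory(label, "Number" if char.kind == NUMERIC else "String")
        )
    collisions = {k: v for k, v in truncated_from.items() if len(v) > 1}
    if collisions:
        detail = "; ".join(f"{k!r} <- {v}" for k, v in sorted(collisions.items()))
        raise MatrixSchemaError(f"facet label collision after truncation: {detail}")
    return categories
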