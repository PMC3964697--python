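"""Identification semantics: analytic pruning, histograms, normalization.

A visual key is a hybrid of two identification styles. The *analytic* step
prunes the taxon list with a multi-access matrix key: the user selects
character states in any order and taxa inconsistent with every selection
are discarded, the classic four-panel accounting of characters available /
chosen and entities available / discarded. The *gestalt* step then compares
the surviving taxa by image. Two query-time views support it: a histogram
of the remaining taxa grouped by a character (e.g. species with trigonous
achenes tallied by Canadian province), and a normalization view that keeps
exactly one designated representative image per taxon (e.g. the one line
drawing per species by a single illustrator) so side-by-side comparison is
one-to-one.

Matching semantics, fixed explicitly:

* within a character the selected states are a disjunction, across
  characters a conjunction;
* a taxon whose score for a selected character is UNKNOWN is retained —
  missing data must never eliminate a candidate;
* numeric characters match by inclusive interval overlap between the
  taxon's stored range and the selected interval.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

from .collection import SPECIES_FACET, CollectionItem
from .matrix import CATEGORICAL, NUMERIC, UNKNOWN, Matrix

logger = logging.getLogger(__name__)


class QueryError(ValueError):
    pass


@dataclass
class FilterQuery:
    """Selected states / intervals per character, plus an optional
    normalization representative ``(facet_name, value)``."""

    selections: dict = field(default_factory=dict)
    representative: tuple | None = None

    def validate(self, matrix: Matrix) -> None:
        chars = {c.name: c for c in matrix.characters}
        for cname, sel in self.selections.items():
            if cname not in chars:
                raise QueryError(f"query references unknown character {cname!r}")
            char = chars[cname]
            if char.kind == CATEGORICAL:
                if not isinstance(sel, (set, frozenset)):
                    raise QueryError(
                        f"{cname!r}: categorical selection must be a set of states"
                    )
                bad = set(sel) - set(char.states)
                if bad:
                    raise QueryError(f"{cname!r}: unknown states {sorted(bad)}")
            else:
                a, b = sel
                if a > b:
                    raise QueryError(f"{cname!r}: interval min {a} > max {b}")


@dataclass
class Partition:
    """Outcome of a filter: the four information panels."""

    remaining: list[str]
    eliminated: list[str]
    characters_chosen: list[str]
    characters_available: list[str]

    def to_json(self) -> dict:
        return {
            "remaining": self.remaining,
            "eliminated": self.eliminated,
            "characters_chosen": self.characters_chosen,
            "characters_available": self.characters_available,
        }


UNSCORED_BUCKET = "(unscored)"


@dataclass
class HistogramResult:
    group_by: str
    buckets: dict  # ordered state-label -> count, "(unscored)" last

    def to_json(self) -> dict:
        return {"group_by": self.group_by, "buckets": dict(self.buckets)}


def _matches(char, score, sel) -> bool:
    """One taxon, one selected character. UNKNOWN retains."""
    if score is UNKNOWN:
        return True
    if char.kind == CATEGORICAL:
        return bool(score & set(sel))
    lo, hi = score
    a, b = sel
    return lo <= b and a <= hi


def apply_filter(matrix: Matrix, query: FilterQuery) -> Partition:
    """Partition the taxa: a taxon remains iff it matches every selection."""
    query.validate(matrix)
    chars = {c.name: c for c in matrix.characters}
    remaining, eliminated = [], []
    for t in matrix.taxa:
        ok = all(
            _matches(chars[cname], t.get(cname), sel)
            for cname, sel in query.selections.items()
        )
        (remaining if ok else eliminated).append(t.taxon)
    chosen = [c.name for c in matrix.characters if c.name in query.selections]
    available = [c.name for c in matrix.characters if c.name not in query.selections]
    return Partition(remaining, eliminated, chosen, available)


def histogram(matrix: Matrix, query: FilterQuery, group_by: str) -> HistogramResult:
    """Per-state counts of the remaining taxa for a categorical character.

    A multi-valued taxon increments every state it is scored for; UNKNOWN
    taxa fall in the "(unscored)" bucket. For a single-valued character the
    bucket total (including unscored) equals the number of remaining taxa.
    """
    chars = {c.name: c for c in matrix.characters}
    if group_by not in chars:
        raise QueryError(f"unknown grouping character {group_by!r}")
    char = chars[group_by]
    if char.kind == NUMERIC:
        raise QueryError(
            f"{group_by!r} is numeric; configure a binning to histogram it"
        )
    part = apply_filter(matrix, query)
    remaining = set(part.remaining)
    buckets = {state: 0 for state in char.states}
    buckets[UNSCORED_BUCKET] = 0
    for t in matrix.taxa:
        if t.taxon not in remaining:
            continue
        score = t.get(group_by)
        if score is UNKNOWN:
            buckets[UNSCORED_BUCKET] += 1
        else:
            for state in char.states:
                if state in score:
                    buckets[state] += 1
    return HistogramResult(group_by, buckets)


@dataclass
class NormalizedView:
    """One representative item per taxon, plus the bookkeeping around it."""

    items: list[CollectionItem]
    missing_taxa: list[str]
    warnings: list[str] = field(default_factory=list)


def normalize_view(
    items: list[CollectionItem],
    representative: tuple,
    taxon_facet: str = SPECIES_FACET,
) -> NormalizedView:
    """Keep only items matching the representative facet value, at most one
    per taxon.

    Mirrors the one-line-drawing-per-species normalization: selecting the
    designated illustrator leaves a uniform set for one-to-one comparison,
    and taxa lacking such an image drop out of the view (reported in
    ``missing_taxa``). Several matching items for one taxon is resolved
    deterministically — lexicographically smallest item name wins — with a
    warning.
    """
    facet_name, value = representative
    taxa_seen: list[str] = []
    by_taxon: dict[str, list[CollectionItem]] = {}
    for item in items:
        taxon = (item.facets.get(taxon_facet) or (item.name,))[0]
        if taxon not in by_taxon:
            by_taxon[taxon] = []
            taxa_seen.append(taxon)
        values = item.facets.get(facet_name, ())
        if any(v == value for v in values):
            by_taxon[taxon].append(item)

    kept: list[CollectionItem] = []
    missing: list[str] = []
    warnings: list[str] = []
    for taxon in taxa_seen:
        matches = by_taxon[taxon]
        if not matches:
            missing.append(taxon)
            continue
        if len(matches) > 1:
            msg = (
                f"taxon {taxon!r}: {len(matches)} items match "
                f"{facet_name}={value!r}; keeping the lexicographically first"
            )
            warnings.append(msg)
            logger.warning(msg)
        kept.append(min(matches, key=lambda it: it.name))
    return NormalizedView(kept, missing, warnings)


def shannon_entropy(counts: list[int]) -> float:
    """−Σ p·log₂p over non-zero counts, in bits."""
    total = sum(counts)
    if total == 0:
        return 0.0
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


def rank_characters(matrix: Matrix, partition: Partition) -> list[tuple[str, float]]:
    """Order the available characters by how informatively they split the
    remaining taxa (descending Shannon entropy; ties keep matrix order).

    A convenience aid for choosing the next character, not part of the
    classic key semantics. UNKNOWN scores are excluded from a character's
    distribution; numeric characters use the distribution of distinct
    stored ranges among the remaining taxa.
    """
    if len(partition.remaining) < 2:
        return []
    remaining = set(partition.remaining)
    chars = {c.name: c for c in matrix.characters}
    scored: list[tuple[str, float]] = []
    for cname in partition.characters_available:
        char = chars[cname]
        if char.kind == CATEGORICAL:
            counts = {state: 0 for state in char.states}
            for t in matrix.taxa:
                if t.taxon not in remaining:
                    continue
                value = t.get(cname)
                if value is UNKNOWN:
                    continue
                for state in char.states:
                    if state in value:
                        counts[state] += 1
            h = shannon_entropy(list(counts.values()))
        else:
            ranges: dict[tuple, int] = {}
            for t in matrix.taxa:
                if t.taxon not in remaining:
                    continue
                value = t.get(cname)
                if value is UNKNOWN:
                    continue
                ranges[value] = ranges.get(value, 0) + 1
            h = shannon_entropy(list(ranges.values()))
        scored.append((cname, h))
    order = {c.name: i for i, c in enumerate(matrix.characters)}
    return sorted(scored, key=lambda kv: (-kv[1], order[kv[0]]))


# ---------------------------------------------------------------------------
# JSON query serialization (CLI surface)
# ---------------------------------------------------------------------------

def query_from_json(text: str, matrix: Matrix) -> FilterQuery:
    """Parse ``{"selections": {char: [states] | {"min": a, "max": b}},
    "representative": [facet, value]}``."""
    doc = json.loads(text)
    chars = {c.name: c for c in matrix.characters}
    selections: dict = {}
    for cname, raw in doc.get("selections", {}).items():
        if cname not in chars:
            raise QueryError(f"query references unknown character {cname!r}")
        if isinstance(raw, dict):
            a = raw.get("min", -math.inf)
            b = raw.get("max", math.inf)
            selections[cname] = (float(a), float(b))
        else:
            selections[cname] = frozenset(str(s) for s in raw)
    rep = doc.get("representative")
    query = FilterQuery(selections, tuple(rep) if rep else None)
    query.validate(matrix)
    return query
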