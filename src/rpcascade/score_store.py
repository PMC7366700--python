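"""Sparse bipartite score tables and validated-interaction label sets.

The score table holds one initial prediction score in [0, 1] per
(entity_a, entity_b) pair — for the miRNA-target use case, entity_a is a
miRNA, entity_b a gene, and the score an integrative predictor confidence.
The table is sparse: only a subset of all possible pairs carries a score,
and per-entity view sizes vary widely. Both axes are indexed so that the
One-to-All view of any single entity is cheap to extract.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field

__all__ = [
    "ScoreTable",
    "LabelSet",
    "FilterReport",
    "load_scores",
    "write_scores",
    "load_labels",
    "filter_labels",
    "entity_view",
]


@dataclass
class ScoreTable:
    """Sparse map (entity_a, entity_b) -> score with per-axis indices.

    ``pairs`` is the authoritative list; ``index_a`` / ``index_b`` map each
    entity id to the positions of its pairs within that list.
    """

    pairs: list[tuple[str, str, float]] = field(default_factory=list)
    index_a: dict[str, list[int]] = field(default_factory=dict)
    index_b: dict[str, list[int]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str, float]]) -> "ScoreTable":
        table = cls(pairs=list(pairs))
        table._reindex()
        return table

    def _reindex(self) -> None:
        self.index_a = {}
        self.index_b = {}
        seen: set[tuple[str, str]] = set()
        for pos, (a, b, score) in enumerate(self.pairs):
            key = (a, b)
            if key in seen:
                raise ValueError(f"duplicate pair {key!r}")
            seen.add(key)
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"score {score} for pair {key!r} outside [0, 1]")
            self.index_a.setdefault(a, []).append(pos)
            self.index_b.setdefault(b, []).append(pos)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, key: tuple[str, str]) -> bool:
        a, b = key
        return any(self.pairs[i][1] == b for i in self.index_a.get(a, ()))

    def score_of(self, a: str, b: str) -> float:
        for i in self.index_a.get(a, ()):
            if self.pairs[i][1] == b:
                return self.pairs[i][2]
        raise KeyError(f"pair ({a!r}, {b!r}) not in score table")

    @property
    def entities_a(self) -> list[str]:
        return list(self.index_a)

    @property
    def entities_b(self) -> list[str]:
        return list(self.index_b)


@dataclass
class LabelSet:
    """Validated positives plus (optionally sampled) negatives.

    ``recency_tag`` carries an optional version label per positive, used to
    hold out recently validated interactions as the test split.
    """

    positives: set[tuple[str, str]] = field(default_factory=set)
    recency_tag: dict[tuple[str, str], str] = field(default_factory=dict)
    negatives: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"{len(overlap)} pairs labelled both positive and negative")


@dataclass
class FilterReport:
    genes_removed: int
    pairs_removed: int
    labels_removed: int


def _open_text(path) -> io.TextIOBase:
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def _looks_like_header(fields: list[str]) -> bool:
    # A header line is one whose score column does not parse as a float.
    try:
        float(fields[2])
    except (ValueError, IndexError):
        return True
    return False


def load_scores(
    path,
    *,
    header: str = "auto",
    duplicates: str = "error",
    clip: bool = False,
) -> ScoreTable:
    """Read a 3-column ``a<TAB>b<TAB>score`` TSV into a :class:`ScoreTable`.

    Parameters
    ----------
    header
        ``"auto"`` (skip a first line whose third column is not numeric),
        ``"present"`` or ``"absent"``.
    duplicates
        ``"error"`` (default — duplicates indicate corrupt input) or
        ``"keep-max"`` to resolve repeated (a, b) keys to their maximum score.
    clip
        Clip scores into [0, 1] instead of rejecting out-of-range values.
    """
    if duplicates not in ("error", "keep-max"):
        raise ValueError(f"unknown duplicate policy {duplicates!r}")
    rows: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and header != "absent":
                if header == "present" or _looks_like_header(fields):
                    continue
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected 3 tab-separated columns, got {len(fields)}")
            a, b = fields[0], fields[1]
            try:
                score = float(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed score {fields[2]!r}") from exc
            if score != score or score in (float("inf"), float("-inf")):
                raise ValueError(f"line {lineno}: non-finite score")
            if not (0.0 <= score <= 1.0):
                if clip:
                    score = min(1.0, max(0.0, score))
                else:
                    raise ValueError(f"line {lineno}: score {score} outside [0, 1] (use clip=True to clamp)")
            key = (a, b)
            if key in rows:
                if duplicates == "error":
                    raise ValueError(f"line {lineno}: duplicate pair {key!r}")
                rows[key] = max(rows[key], score)
            else:
                rows[key] = score
                order.append(key)
    if not rows:
        raise ValueError("no pairs: score file is empty")
    return ScoreTable.from_pairs([(a, b, rows[(a, b)]) for a, b in order])


def write_scores(table: ScoreTable, path, *, header: bool = False) -> None:
    """Write a score table back to TSV at full float precision (round-trips)."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("entity_a\tentity_b\tscore\n")
        for a, b, score in table.pairs:
            fh.write(f"{a}\t{b}\t{score!r}\n")


def load_labels(path) -> LabelSet:
    """Read a 2- or 3-column ``a<TAB>b[<TAB>recency_tag]`` TSV of positives."""
    positives: set[tuple[str, str]] = set()
    tags: dict[tuple[str, str], str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected at least 2 columns")
            key = (fields[0], fields[1])
            tag = fields[2] if len(fields) > 2 and fields[2] else None
            if key in positives:
                if tags.get(key) != tag:
                    raise ValueError(f"line {lineno}: pair {key!r} repeated with conflicting tags")
                continue
            positives.add(key)
            if tag is not None:
                tags[key] = tag
    return LabelSet(positives=positives, recency_tag=tags)


def filter_labels(
    table: ScoreTable,
    labels: LabelSet,
    *,
    symmetric: bool = False,
) -> tuple[ScoreTable, LabelSet, FilterReport]:
    """Drop gene-side entities lacking any validated positive.

    The One-to-All construction needs at least one validated data point per
    gene to anchor its local context, so genes (entity_b) with zero positives
    are removed along with all their pairs. Labelled pairs absent from the
    score table are dropped from the label set. ``symmetric=True`` applies
    the same rule to the entity_a axis (off by default: only the gene axis
    is filtered in the miRNA-target setting).
    """
    pos_b = {b for (_, b) in labels.positives}
    keep_b = {b for b in table.index_b if b in pos_b}
    if symmetric:
        pos_a = {a for (a, _) in labels.positives}
        keep_a = {a for a in table.index_a if a in pos_a}
    else:
        keep_a = set(table.index_a)

    kept_pairs = [(a, b, s) for a, b, s in table.pairs if b in keep_b and a in keep_a]
    new_table = ScoreTable.from_pairs(kept_pairs)
    kept_keys = {(a, b) for a, b, _ in kept_pairs}

    new_pos = {p for p in labels.positives if p in kept_keys}
    new_tags = {p: t for p, t in labels.recency_tag.items() if p in new_pos}
    new_neg = {p for p in labels.negatives if p in kept_keys}
    if not new_pos:
        raise ValueError("filtering removed every positive label")

    report = FilterReport(
        genes_removed=len(table.index_b) - len(new_table.index_b),
        pairs_removed=len(table) - len(new_table),
        labels_removed=len(labels.positives) - len(new_pos),
    )
    return new_table, LabelSet(new_pos, new_tags, new_neg), report


def entity_view(table: ScoreTable, axis: str, entity_id: str) -> list[tuple[str, float]]:
    """All scored partners of one entity from one perspective.

    ``axis="A"`` returns (entity_b, score) partners of an entity_a id;
    ``axis="B"`` the reverse. Order is unspecified.
    """
    if axis not in ("A", "B"):
        raise ValueError(f"axis must be 'A' or 'B', got {axis!r}")
    index = table.index_a if axis == "A" else table.index_b
    if entity_id not in index:
        raise KeyError(f"unknown entity {entity_id!r} on axis {axis}")
    partner_col = 1 if axis == "A" else 0
    return [(table.pairs[i][partner_col], table.pairs[i][2]) for i in index[entity_id]]
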