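"""Annotated binary trait matrices.

A :class:`TraitMatrix` holds taxa x characters presence/absence data with an
explicit missing state, plus optional per-character annotations used across
the robustness analyses: a dependency *level* (1-4, lower = more independent),
a *category* label (e.g. part of speech, or structure vs patterning), and a
positive *weight* that multiplies the character's log-likelihood contribution.

States are stored as an int8 array with codes ``0`` (absent), ``1`` (present)
and ``-1`` (missing, written as ``?`` on disk).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    FormatError,
    MissingReferenceError,
    ValidationError,
)

ABSENT = 0
PRESENT = 1
MISSING = -1

_SYMBOL_TO_CODE = {"0": ABSENT, "1": PRESENT, "?": MISSING}
_CODE_TO_SYMBOL = {ABSENT: "0", PRESENT: "1", MISSING: "?"}


@dataclass
class TraitMatrix:
    """Binary trait matrix with per-character annotations.

    Parameters
    ----------
    taxa:
        Ordered, unique taxon labels (rows).
    states:
        ``(n_taxa, n_characters)`` int8 array of {0, 1, -1} codes.
    char_ids:
        Ordered character labels (columns).
    levels:
        Optional per-character dependency level in {1, 2, 3, 4}.
    categories:
        Optional per-character category label.
    weights:
        Per-character positive likelihood weight, default all 1.
    """

    taxa: list[str]
    states: np.ndarray
    char_ids: list[str]
    levels: np.ndarray | None = None
    categories: list[str] | None = None
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2:
            raise ValidationError("states must be a 2-D taxa x characters array")
        n_taxa, n_chars = self.states.shape
        if len(self.taxa) != n_taxa:
            raise ValidationError(
                f"{len(self.taxa)} taxa labels for {n_taxa} state rows"
            )
        if len(self.char_ids) != n_chars:
            raise ValidationError(
                f"{len(self.char_ids)} character ids for {n_chars} state columns"
            )
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValidationError(f"duplicate taxon labels: {dupes}")
        if len(set(self.char_ids)) != len(self.char_ids):
            raise ValidationError("duplicate character ids")
        bad = ~np.isin(self.states, (ABSENT, PRESENT, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-binary state {self.states[i, j]} at taxon "
                f"{self.taxa[i]!r}, character {self.char_ids[j]!r}"
            )
        if self.levels is not None:
            self.levels = np.asarray(self.levels, dtype=int)
            if self.levels.shape != (n_chars,):
                raise ValidationError("levels must have one entry per character")
        if self.categories is not None:
            self.categories = list(self.categories)
            if len(self.categories) != n_chars:
                raise ValidationError("categories must have one entry per character")
        if self.weights is None:
            self.weights = np.ones(n_chars)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n_chars,):
            raise ValidationError("weights must have one entry per character")
        if not (self.weights > 0).all():
            raise ValidationError("character weights must be > 0")

    # ------------------------------------------------------------------ #

    @property
    def n_taxa(self) -> int:
        return self.states.shape[0]

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]

    def taxon_index(self, label: str) -> int:
        try:
            return self.taxa.index(label)
        except ValueError:
            raise MissingReferenceError(f"unknown taxon {label!r}") from None

    def copy(self) -> "TraitMatrix":
        return TraitMatrix(
            taxa=list(self.taxa),
            states=self.states.copy(),
            char_ids=list(self.char_ids),
            levels=None if self.levels is None else self.levels.copy(),
            categories=None if self.categories is None else list(self.categories),
            weights=self.weights.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraitMatrix):
            return NotImplemented
        same_levels = (
            (self.levels is None and other.levels is None)
            or (
                self.levels is not None
                and other.levels is not None
                and np.array_equal(self.levels, other.levels)
            )
        )
        return (
            self.taxa == other.taxa
            and self.char_ids == other.char_ids
            and np.array_equal(self.states, other.states)
            and same_levels
            and self.categories == other.categories
            and np.allclose(self.weights, other.weights)
        )


@dataclass
class PartitionScheme:
    """Disjoint grouping of characters with per-partition rate multipliers.

    ``rate_multipliers`` are relative rates; the likelihood renormalises them
    to character-weighted mean 1 so that partition effects are separated from
    the global clock rate.
    """

    name: str
    groups: dict[str, set[str]]
    rate_multipliers: dict[str, float] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, members in self.groups.items():
            overlap = seen & set(members)
            if overlap:
                raise ValidationError(
                    f"partition {label!r} overlaps earlier partitions on {sorted(overlap)}"
                )
            seen |= set(members)
        if self.rate_multipliers is None:
            self.rate_multipliers = {g: 1.0 for g in self.groups}
        if set(self.rate_multipliers) != set(self.groups):
            raise ValidationError("rate multipliers must match partition labels")
        for g, m in self.rate_multipliers.items():
            if not m > 0:
                raise ValidationError(f"rate multiplier for {g!r} must be > 0")

    def validate_cover(self, char_ids: Iterable[str]) -> None:
        covered = set().union(*self.groups.values()) if self.groups else set()
        missing = set(char_ids) - covered
        if missing:
            raise ValidationError(
                f"partition scheme {self.name!r} does not cover characters "
                f"{sorted(missing)[:5]}..."
            )

    def labels_for(self, char_ids: Sequence[str]) -> list[str]:
        """Partition label of each character, in char order."""
        lookup = {c: g for g, members in self.groups.items() for c in members}
        out = []
        for c in char_ids:
            if c not in lookup:
                raise MissingReferenceError(f"character {c!r} not in any partition")
            out.append(lookup[c])
        return out

    @staticmethod
    def from_levels(m: TraitMatrix, name: str = "levels") -> "PartitionScheme":
        if m.levels is None:
            raise MissingReferenceError("matrix has no level annotations")
        groups: dict[str, set[str]] = {}
        for cid, lev in zip(m.char_ids, m.levels):
            groups.setdefault(f"level{lev}", set()).add(cid)
        return PartitionScheme(name=name, groups=groups)

    @staticmethod
    def from_categories(m: TraitMatrix, name: str = "categories") -> "PartitionScheme":
        if m.categories is None:
            raise MissingReferenceError("matrix has no category annotations")
        groups: dict[str, set[str]] = {}
        for cid, cat in zip(m.char_ids, m.categories):
            groups.setdefault(str(cat), set()).add(cid)
        return PartitionScheme(name=name, groups=groups)


# ---------------------------------------------------------------------- #
# I/O
# ---------------------------------------------------------------------- #


def _attach_annotations(m: TraitMatrix, annotations: str) -> TraitMatrix:
    table = pd.read_csv(annotations, dtype={"char_id": str})
    if "char_id" not in table.columns:
        raise FormatError("annotation table must have a 'char_id' column")
    unknown = set(table["char_id"]) - set(m.char_ids)
    if unknown:
        raise MissingReferenceError(
            f"annotation char_id(s) not in matrix: {sorted(unknown)}"
        )
    table = table.set_index("char_id").reindex(m.char_ids)
    if "level" in table.columns:
        if table["level"].isna().any():
            missing = [c for c, v in table["level"].items() if pd.isna(v)]
            raise MissingReferenceError(
                f"characters without a level annotation: {missing[:5]}"
            )
        m.levels = table["level"].astype(int).to_numpy()
    if "category" in table.columns:
        m.categories = table["category"].astype(str).tolist()
    if "weight" in table.columns:
        m.weights = table["weight"].astype(float).to_numpy()
        if not (m.weights > 0).all():
            raise ValidationError("annotation weights must be > 0")
    return m


def read_trait_matrix(
    path: str,
    format: str = "csv",
    annotations: str | None = None,
) -> TraitMatrix:
    """Read a binary trait matrix from CSV or NEXUS.

    CSV layout: first column = taxon label, header row = character ids,
    cells in {0, 1, ?}. NEXUS: standard datatype, symbols "01", missing '?'.
    An optional annotation CSV with columns ``char_id, level, category,
    weight`` attaches per-character metadata.
    """
    if format == "csv":
        m = _read_csv(path)
    elif format == "nexus":
        m = _read_nexus(path)
    else:
        raise FormatError(f"unknown trait matrix format {format!r}")
    if annotations is not None:
        m = _attach_annotations(m, annotations)
    return m


def _read_csv(path: str) -> TraitMatrix:
    df = pd.read_csv(path, index_col=0, dtype=str)
    taxa = [str(t) for t in df.index]
    if len(set(taxa)) != len(taxa):
        raise ValidationError(f"duplicate taxon labels in {path}")
    char_ids = [str(c) for c in df.columns]
    states = np.empty(df.shape, dtype=np.int8)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            cell = str(cell).strip()
            if cell not in _SYMBOL_TO_CODE:
                raise FormatError(
                    f"non-binary symbol {cell!r} at taxon {taxa[i]!r}, "
                    f"character {char_ids[j]!r}"
                )
            states[i, j] = _SYMBOL_TO_CODE[cell]
    return TraitMatrix(taxa=taxa, states=states, char_ids=char_ids)


def _read_nexus(path: str) -> TraitMatrix:
    try:
        cm = dendropy.StandardCharacterMatrix.get(path=path, schema="nexus")
    except Exception as exc:  # dendropy raises several parser error types
        raise FormatError(f"could not parse NEXUS file {path}: {exc}") from exc
    taxa = [t.label for t in cm.taxon_namespace]
    if len(set(taxa)) != len(taxa):
        raise ValidationError(f"duplicate taxon labels in {path}")
    n_chars = max(len(cm[t]) for t in cm.taxon_namespace)
    char_ids = [f"c{j + 1}" for j in range(n_chars)]
    states = np.empty((len(taxa), n_chars), dtype=np.int8)
    for i, taxon in enumerate(cm.taxon_namespace):
        row = cm[taxon]
        if len(row) != n_chars:
            raise FormatError(f"ragged NEXUS matrix at taxon {taxon.label!r}")
        for j, cell in enumerate(row):
            sym = str(cell)
            if sym not in _SYMBOL_TO_CODE:
                raise FormatError(
                    f"non-binary symbol {sym!r} at taxon {taxon.label!r}, "
                    f"character {char_ids[j]!r}"
                )
            states[i, j] = _SYMBOL_TO_CODE[sym]
    return TraitMatrix(taxa=taxa, states=states, char_ids=char_ids)


def write_trait_matrix(m: TraitMatrix, path: str, format: str = "csv") -> None:
    """Write a matrix as CSV or NEXUS (standard datatype, symbols 01)."""
    if format == "csv":
        sym = np.vectorize(_CODE_TO_SYMBOL.get)(m.states)
        pd.DataFrame(sym, index=m.taxa, columns=m.char_ids).to_csv(path)
    elif format == "nexus":
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_characters};\n")
            fh.write('  FORMAT DATATYPE=STANDARD MISSING=? GAP=- SYMBOLS="01";\n')
            fh.write("  MATRIX\n")
            for i, taxon in enumerate(m.taxa):
                row = "".join(_CODE_TO_SYMBOL[int(s)] for s in m.states[i])
                fh.write(f"    {_nexus_label(taxon)} {row}\n")
            fh.write("  ;\nEND;\n")
    else:
        raise FormatError(f"unknown trait matrix format {format!r}")


def _nexus_label(label: str) -> str:
    if any(c in label for c in " ()[]{}/\\,;:=*'\"`<>"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_annotations(m: TraitMatrix, path: str) -> None:
    """Write the per-character annotation table (char_id, level, category, weight)."""
    data: dict[str, object] = {"char_id": m.char_ids}
    if m.levels is not None:
        data["level"] = m.levels
    if m.categories is not None:
        data["category"] = m.categories
    data["weight"] = m.weights
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------- #
# Subsetting, weighting, taxon matching
# ---------------------------------------------------------------------- #


def subset_characters(
    m: TraitMatrix,
    selector: Callable[[int | None, str | None], bool] | None = None,
    *,
    level: int | Iterable[int] | None = None,
    category: str | Iterable[str] | None = None,
) -> TraitMatrix:
    """Restrict a matrix to characters matching a predicate or annotation filter.

    Either pass ``selector(level, category) -> bool``, or use the ``level=`` /
    ``category=`` keyword filters. Taxa and per-character annotations are
    preserved. Selecting zero characters raises
    :class:`~traitphylo.errors.DegenerateInputError`.
    """
    if selector is None:
        levels_wanted = None
        if level is not None:
            levels_wanted = {level} if isinstance(level, int) else set(level)
        cats_wanted = None
        if category is not None:
            cats_wanted = (
                {category} if isinstance(category, str) else set(category)
            )

        def selector(lv: int | None, cat: str | None) -> bool:  # noqa: F811
            if levels_wanted is not None:
                if lv is None:
                    raise MissingReferenceError("matrix has no level annotations")
                if lv not in levels_wanted:
                    return False
            if cats_wanted is not None:
                if cat is None:
                    raise MissingReferenceError("matrix has no category annotations")
                if cat not in cats_wanted:
                    return False
            return True

    keep = []
    for j in range(m.n_characters):
        lv = None if m.levels is None else int(m.levels[j])
        cat = None if m.categories is None else m.categories[j]
        if selector(lv, cat):
            keep.append(j)
    if not keep:
        raise DegenerateInputError(
            "character selection is empty: an analysis on zero characters is meaningless"
        )
    idx = np.asarray(keep)
    return TraitMatrix(
        taxa=list(m.taxa),
        states=m.states[:, idx],
        char_ids=[m.char_ids[j] for j in keep],
        levels=None if m.levels is None else m.levels[idx],
        categories=None if m.categories is None else [m.categories[j] for j in keep],
        weights=m.weights[idx],
    )


def apply_level_weights(m: TraitMatrix, weight_by_level: dict[int, float]) -> TraitMatrix:
    """Set per-character weights from a level -> weight mapping.

    An integer weight ``w`` makes the character contribute to the likelihood
    exactly as if it were duplicated ``w`` times.
    """
    if m.levels is None:
        raise MissingReferenceError("matrix has no level annotations to weight by")
    for w in weight_by_level.values():
        if not w > 0:
            raise ValidationError("level weights must be > 0")
    out = m.copy()
    weights = np.empty(m.n_characters)
    for j, lev in enumerate(m.levels):
        if int(lev) not in weight_by_level:
            raise MissingReferenceError(
                f"no weight given for level {int(lev)} (character {m.char_ids[j]!r})"
            )
        weights[j] = weight_by_level[int(lev)]
    out.weights = weights
    return out


def match_shared_taxa(
    a: TraitMatrix,
    b: TraitMatrix,
    taxon_map: Sequence[tuple[str, str]],
) -> tuple[TraitMatrix, TraitMatrix]:
    """Restrict two matrices to mapped taxon pairs, rows in pair order.

    ``taxon_map`` pairs labels of ``a`` with labels of ``b`` (the datasets may
    name the same society differently, e.g. a language name vs a loom name).
    """
    if len(taxon_map) == 0:
        raise ValidationError("taxon map is empty")
    a_labels = [p[0] for p in taxon_map]
    b_labels = [p[1] for p in taxon_map]
    if len(set(a_labels)) != len(a_labels) or len(set(b_labels)) != len(b_labels):
        raise ValidationError("duplicate pairing in taxon map")
    for lab in a_labels:
        if lab not in a.taxa:
            raise MissingReferenceError(f"mapped label {lab!r} not in first matrix")
    for lab in b_labels:
        if lab not in b.taxa:
            raise MissingReferenceError(f"mapped label {lab!r} not in second matrix")
    return _take_taxa(a, a_labels), _take_taxa(b, b_labels)


def _take_taxa(m: TraitMatrix, labels: Sequence[str]) -> TraitMatrix:
    idx = [m.taxa.index(lab) for lab in labels]
    return TraitMatrix(
        taxa=list(labels),
        states=m.states[np.asarray(idx), :],
        char_ids=list(m.char_ids),
        levels=None if m.levels is None else m.levels.copy(),
        categories=None if m.categories is None else list(m.categories),
        weights=m.weights.copy(),
    )


def merge_characters(a: TraitMatrix, b: TraitMatrix) -> TraitMatrix:
    """Concatenate the characters of two matrices over identical taxa.

    Used by the shared-phylogeny scenario, where two trait systems are
    analysed as one matrix on a single tree. Character ids are prefixed to
    stay unique; annotations are preserved where both sides carry them.
    """
    if a.taxa != b.taxa:
        raise ValidationError("matrices must have identical taxa in identical order")
    char_ids = [f"a:{c}" for c in a.char_ids] + [f"b:{c}" for c in b.char_ids]
    levels = None
    if a.levels is not None and b.levels is not None:
        levels = np.concatenate([a.levels, b.levels])
    categories = None
    if a.categories is not None and b.categories is not None:
        categories = list(a.categories) + list(b.categories)
    return TraitMatrix(
        taxa=list(a.taxa),
        states=np.hstack([a.states, b.states]),
        char_ids=char_ids,
        levels=levels,
        categories=categories,
        weights=np.concatenate([a.weights, b.weights]),
    )
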