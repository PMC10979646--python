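"""Domain types for ordinal evidence scoring.

Each theory of consciousness is credited with a set of *evidence items*:
claims that some empirical phenomenon (visual masking, change blindness,
binocular rivalry, ...) supports the theory.  Every item carries two ordinal
scores:

* **A-score** — the quality of the argument connecting the phenomenon to the
  theory, on a four-step scale ``rejected < coherent_untestable <
  coherent_testable < accepted``.  ``rejected`` items are archived but never
  contribute support.
* **R-score** — the replication robustness of the phenomenon itself, on a
  three-step scale ``low < medium < high`` by default (any number of ordered
  labels is supported).

This module defines the ordinal scales, the evidence/dataset containers,
dataset validation, and the 3x3 count-matrix representation (rows = R-score
high-to-low, columns = A-score best-to-worst with ``rejected`` excluded) that
the quantification layer consumes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "A_LABELS",
    "R_LABELS",
    "MATRIX_ROWS",
    "MATRIX_COLS",
    "OrdinalScale",
    "EvidenceItem",
    "TheoryDataset",
    "Finding",
    "canonical_label",
    "validate_dataset",
    "count_matrix",
    "expand_matrix",
]

#: Canonical A-score labels in ascending rank order (rank 0 .. 3).
A_LABELS: tuple[str, ...] = (
    "rejected",
    "coherent_untestable",
    "coherent_testable",
    "accepted",
)

#: Canonical R-score labels in ascending rank order (rank 0 .. 2).
R_LABELS: tuple[str, ...] = ("low", "medium", "high")

#: Count-matrix row labels: R-score from most to least replicated.
MATRIX_ROWS: tuple[str, ...] = ("high", "medium", "low")

#: Count-matrix column labels: A-score from best to worst, ``rejected`` excluded.
MATRIX_COLS: tuple[str, ...] = (
    "accepted",
    "coherent_testable",
    "coherent_untestable",
)

# Spelled-out variants accepted on input (case-insensitive).
_LABEL_ALIASES: dict[str, str] = {
    "coherent and testable": "coherent_testable",
    "coherent but untestable": "coherent_untestable",
    "coherent_and_testable": "coherent_testable",
    "coherent_but_untestable": "coherent_untestable",
    "c&t": "coherent_testable",
    "c&u": "coherent_untestable",
}


def canonical_label(label: str) -> str:
    """Normalise an ordinal label to its canonical lower-case form.

    Accepts case variants, surrounding whitespace, and the spelled-out forms
    ("Coherent and testable" -> ``coherent_testable``).  Unknown labels are
    returned normalised (lower-cased, spaces collapsed to underscores) so the
    caller can report them.
    """
    norm = re.sub(r"\s+", " ", label.strip().lower())
    if norm in _LABEL_ALIASES:
        return _LABEL_ALIASES[norm]
    return norm.replace(" ", "_")


@dataclass(frozen=True)
class OrdinalScale:
    """An ordered set of labels anchored to an integer value range.

    The lowest label is pinned to ``anchor_min`` and the highest to
    ``anchor_max``; the values of the ``len(labels) - 2`` middle ordinals are
    deliberately *not* fixed — every strictly increasing assignment of
    integers from the open interval ``(anchor_min, anchor_max)`` is
    admissible, and the quantification sweeps them all.

    Parameters
    ----------
    labels
        Ordinal labels in ascending rank order; at least two.
    anchor_min, anchor_max
        Integer values of the lowest and highest label.
    unit
        Semantic unit of the values, e.g. ``"percent"`` for A-values or
        ``"hundredths"`` for R-values.  Informational only.
    """

    labels: tuple[str, ...]
    anchor_min: int
    anchor_max: int
    unit: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) < 2:
            raise ValueError("an ordinal scale needs at least 2 labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"duplicate labels in scale: {self.labels}")
        if not (isinstance(self.anchor_min, int) and isinstance(self.anchor_max, int)):
            raise TypeError("anchors must be integers")
        if self.anchor_min >= self.anchor_max:
            raise ValueError("anchor_min must be strictly below anchor_max")
        if self.n_middles > self.anchor_max - self.anchor_min - 1:
            raise ValueError(
                f"{self.n_middles} middle ordinals cannot fit strictly between "
                f"anchors {self.anchor_min} and {self.anchor_max}"
            )

    @property
    def n_middles(self) -> int:
        """Number of middle ordinals (labels that are neither anchor)."""
        return len(self.labels) - 2

    @property
    def middle_candidates(self) -> range:
        """Integers admissible as middle values: the open anchor interval."""
        return range(self.anchor_min + 1, self.anchor_max)

    def rank(self, label: str) -> int:
        """Rank of *label* on this scale (0 = lowest)."""
        try:
            return self.labels.index(canonical_label(label))
        except ValueError:
            raise KeyError(f"label {label!r} is not on scale {self.labels}") from None


#: Default value scale for A-scores: 1-10 percent, ``rejected`` excluded.
A_VALUE_SCALE = OrdinalScale(
    ("coherent_untestable", "coherent_testable", "accepted"), 1, 10, unit="percent"
)

#: Default value scale for R-scores: 1-10 hundredths.
R_VALUE_SCALE = OrdinalScale(("low", "medium", "high"), 1, 10, unit="hundredths")


@dataclass
class EvidenceItem:
    """One claim of empirical support: a scored (phenomenon, argument) pair.

    ``replication_count`` is the raw number of replications of the phenomenon;
    it is only consumed by the calibration module when deriving R-score
    thresholds from data, never by the quantification itself.
    """

    phenomenon: str
    a_score: str
    r_score: str
    replication_count: int | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        self.a_score = canonical_label(self.a_score)
        self.r_score = canonical_label(self.r_score)

    @property
    def rejected(self) -> bool:
        return self.a_score == "rejected"


@dataclass
class TheoryDataset:
    """A named theory together with its set of proposed evidence items."""

    name: str
    items: list[EvidenceItem] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    def non_rejected(self) -> list[EvidenceItem]:
        return [it for it in self.items if not it.rejected]


@dataclass(frozen=True)
class Finding:
    """A single validation finding."""

    severity: str  # "error" | "warning"
    message: str
    item_index: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = "" if self.item_index is None else f" (item {self.item_index})"
        return f"{self.severity}{loc}: {self.message}"


def validate_dataset(
    dataset: TheoryDataset,
    a_labels: Sequence[str] = A_LABELS,
    r_labels: Sequence[str] = R_LABELS,
) -> list[Finding]:
    """Check a dataset for structural problems.

    Returns an empty list for a well-formed dataset.  Errors are raised for
    unknown ordinal labels, duplicate phenomenon identifiers, empty theory or
    phenomenon names, and negative replication counts.
    """
    findings: list[Finding] = []
    if not dataset.name.strip():
        findings.append(Finding("error", "theory name is empty"))
    seen: dict[str, int] = {}
    for i, item in enumerate(dataset.items):
        if not item.phenomenon.strip():
            findings.append(Finding("error", "phenomenon label is empty", i))
        elif item.phenomenon in seen:
            findings.append(
                Finding(
                    "error",
                    f"duplicate phenomenon {item.phenomenon!r} "
                    f"(first seen at item {seen[item.phenomenon]})",
                    i,
                )
            )
        else:
            seen[item.phenomenon] = i
        if item.a_score not in a_labels:
            findings.append(
                Finding("error", f"unknown a_score label {item.a_score!r}", i)
            )
        if item.r_score not in r_labels:
            findings.append(
                Finding("error", f"unknown r_score label {item.r_score!r}", i)
            )
        if item.replication_count is not None and item.replication_count < 0:
            findings.append(
                Finding("error", "replication_count must be non-negative", i)
            )
    return findings


def count_matrix(
    dataset: TheoryDataset,
    rows: Sequence[str] = MATRIX_ROWS,
    cols: Sequence[str] = MATRIX_COLS,
) -> np.ndarray:
    """Tabulate non-rejected items into an R-score x A-score count matrix.

    Entry ``[r][a]`` is the number of items with that score pair.  Rows run
    high-to-low replication, columns best-to-worst argument; ``rejected``
    items are excluded, so the matrix total equals the number of non-rejected
    items.
    """
    row_idx = {lab: i for i, lab in enumerate(rows)}
    col_idx = {lab: j for j, lab in enumerate(cols)}
    mat = np.zeros((len(rows), len(cols)), dtype=int)
    for item in dataset.items:
        if item.rejected:
            continue
        try:
            mat[row_idx[item.r_score], col_idx[item.a_score]] += 1
        except KeyError as exc:
            raise KeyError(
                f"item {item.phenomenon!r} has score {exc.args[0]!r} outside the "
                "matrix labels; validate the dataset first"
            ) from None
    return mat


def expand_matrix(
    counts: Sequence[Sequence[int]] | np.ndarray,
    theory_name: str = "theory",
    rows: Sequence[str] = MATRIX_ROWS,
    cols: Sequence[str] = MATRIX_COLS,
) -> TheoryDataset:
    """Materialise a count matrix into an explicit dataset.

    The inverse of :func:`count_matrix`: produces one item per matrix count
    with deterministic synthetic phenomenon labels
    ``<theory>_<a-label>_<r-label>_<index>``, so that published count tables
    can be consumed directly.
    """
    mat = np.asarray(counts, dtype=int)
    if mat.shape != (len(rows), len(cols)):
        raise ValueError(f"expected a {len(rows)}x{len(cols)} matrix, got {mat.shape}")
    if (mat < 0).any():
        raise ValueError("count matrix entries must be non-negative")
    items: list[EvidenceItem] = []
    for r, r_lab in enumerate(rows):
        for c, a_lab in enumerate(cols):
            for i in range(mat[r, c]):
                items.append(
                    EvidenceItem(
                        phenomenon=f"{theory_name}_{a_lab}_{r_lab}_{i}",
                        a_score=a_lab,
                        r_score=r_lab,
                    )
                )
    return TheoryDataset(name=theory_name, items=items)
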