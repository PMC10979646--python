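"""Seeded generator of hypothetical theory datasets.

Real, fully scored compilations of the evidence claimed for each theory of
consciousness do not yet exist, so method demonstrations run on synthetic
fields of hypothetical theories.  Each generated theory receives between 20
and 40 evidence items (uniformly), and each item's A- and R-score is drawn
independently from a categorical distribution weighted *away* from the
highest ordinal — reflecting that knock-down evidence is currently rare.

The default weights are the pooled empirical score frequencies of the four
bundled demonstration datasets; both weight vectors are fully configurable.
Reproducibility: a single master seed with a per-theory sub-stream, so
appending a theory to a field never perturbs the earlier ones.

What this generator does *not* emulate: correlations between A- and R-scores
(real arguments about well-replicated phenomena are plausibly better),
theory-specific score profiles, or replication counts and argument texts.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .core import EvidenceItem, TheoryDataset

__all__ = ["GeneratorConfig", "generate_theory", "generate_field", "theory_label"]

# Score categories in best-to-worst order, matching the weight vectors.
_A_CATEGORIES = ("accepted", "coherent_testable", "coherent_untestable")
_R_CATEGORIES = ("high", "medium", "low")

#: Pooled score frequencies of the bundled demonstration datasets (86 items).
DEFAULT_A_WEIGHTS = (0.06, 0.45, 0.49)
DEFAULT_R_WEIGHTS = (0.15, 0.50, 0.35)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic dataset generator.

    ``a_weights`` are probabilities over (accepted, coherent_testable,
    coherent_untestable); ``r_weights`` over (high, medium, low).  By
    default the highest ordinal is the rarest in both.
    """

    n_min: int = 20
    n_max: int = 40
    a_weights: tuple[float, ...] = DEFAULT_A_WEIGHTS
    r_weights: tuple[float, ...] = DEFAULT_R_WEIGHTS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_min <= self.n_max):
            raise ValueError("need 0 < n_min <= n_max")
        for name, w, cats in (
            ("a_weights", self.a_weights, _A_CATEGORIES),
            ("r_weights", self.r_weights, _R_CATEGORIES),
        ):
            w = tuple(float(x) for x in w)
            object.__setattr__(self, name, w)
            if len(w) != len(cats):
                raise ValueError(f"{name} must have {len(cats)} entries")
            if any(x < 0 for x in w):
                raise ValueError(f"{name} must be non-negative")
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")


def theory_label(index: int) -> str:
    """Spreadsheet-style label for the *index*-th theory: A, B, ..., Z, AA, ..."""
    label = ""
    i = index
    while True:
        label = chr(ord("A") + i % 26) + label
        i = i // 26 - 1
        if i < 0:
            return label


def generate_theory(
    name: str,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> TheoryDataset:
    """Draw one hypothetical theory dataset.

    The item count is uniform on ``[n_min, n_max]``; each item's scores are
    independent categorical draws.  Pass an explicit ``rng`` to control the
    stream; otherwise one is seeded from ``config.seed``.
    """
    config = config or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(rng.integers(config.n_min, config.n_max + 1))
    a_idx = rng.choice(len(_A_CATEGORIES), size=n, p=config.a_weights)
    r_idx = rng.choice(len(_R_CATEGORIES), size=n, p=config.r_weights)
    items = [
        EvidenceItem(
            phenomenon=f"{name}_phenomenon_{i:03d}",
            a_score=_A_CATEGORIES[a],
            r_score=_R_CATEGORIES[r],
        )
        for i, (a, r) in enumerate(zip(a_idx, r_idx))
    ]
    return TheoryDataset(name=name, items=items)


def generate_field(
    theory_count: int, config: GeneratorConfig | None = None
) -> list[TheoryDataset]:
    """Draw a field of independent hypothetical theories.

    Theories are named ``Theory_A``, ``Theory_B``, ... and each uses its own
    sub-stream derived from ``(config.seed, index)``, so regenerating with a
    larger count reproduces the earlier theories bit-for-bit.
    """
    if theory_count < 1:
        raise ValueError("theory_count must be >= 1")
    config = config or GeneratorConfig()
    field_sets = []
    for i in range(theory_count):
        rng = np.random.default_rng([config.seed, i])
        field_sets.append(generate_theory(f"Theory_{theory_label(i)}", config, rng))
    return field_sets
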