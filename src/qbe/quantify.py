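"""Sequential credence updating over the grid of middle-ordinal values.

Every theory starts from the same uniform prior, 1 / (number of viable
theories) = 0.04 for the default field of 25.  Each non-rejected evidence
item then updates the running posterior once:

* the **A-value** (in percent) acts as the likelihood factor — an item with
  A-value ``a`` multiplies the posterior by ``1 + a/100`` (multiplicative
  mechanism) or adds ``a/100`` to it (additive alternative);
* the **R-value** (in hundredths) defines the marginal divisor ``1 - r/100``,
  so better-replicated phenomena yield a larger posterior gain.

The anchor ordinals have fixed values (lowest = 1, highest = 10 on both
default scales), but a middle ordinal's value is deliberately left open: the
whole dataset is re-quantified for *every* admissible integer assignment of
the middle values.  With one middle ordinal per scale and anchors (1, 10)
that is 8 x 8 = 64 posteriors per theory; the resulting :class:`PosteriorSet`
grid, not any single number, is the theory's quantified support.

The update is not a normatively correct Bayesian posterior — it is a
Bayes-*inspired* bookkeeping rule — so running posteriors can leave (0, 1).
Every step at which that happens is recorded and handled per
``bound_policy``.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    A_VALUE_SCALE,
    R_VALUE_SCALE,
    OrdinalScale,
    TheoryDataset,
)

__all__ = [
    "QuantConfig",
    "BoundViolation",
    "BoundError",
    "PosteriorSet",
    "enumerate_middle_assignments",
    "resolve_values",
    "update_step",
    "quantify_theory",
    "quantify_field",
    "check_bounds",
]

logger = logging.getLogger("qbe.quantify")

MECHANISMS = ("multiplicative", "additive")
BOUND_POLICIES = ("warn", "error", "ignore")


@dataclass(frozen=True)
class QuantConfig:
    """Quantification parameters.

    ``prior`` defaults to ``1 / theory_count`` (uniform over the field of
    viable theories).  ``a_scale`` values are percent added to the likelihood
    factor; ``r_scale`` values are hundredths defining the marginal divisor.
    """

    theory_count: int = 25
    prior: float | None = None
    mechanism: str = "multiplicative"
    a_scale: OrdinalScale = A_VALUE_SCALE
    r_scale: OrdinalScale = R_VALUE_SCALE
    bound_policy: str = "warn"

    def __post_init__(self) -> None:
        if self.theory_count < 1:
            raise ValueError("theory_count must be positive")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if self.bound_policy not in BOUND_POLICIES:
            raise ValueError(f"bound_policy must be one of {BOUND_POLICIES}")
        if not (0 < self.resolved_prior < 1):
            raise ValueError("prior must lie strictly between 0 and 1")
        if self.a_scale.anchor_min < 1 or self.r_scale.anchor_min < 1:
            raise ValueError("scale anchors must be >= 1")

    @property
    def resolved_prior(self) -> float:
        return self.prior if self.prior is not None else 1.0 / self.theory_count

    def to_dict(self) -> dict:
        return {
            "theory_count": self.theory_count,
            "prior": self.resolved_prior,
            "mechanism": self.mechanism,
            "a_scale": {
                "labels": list(self.a_scale.labels),
                "anchor_min": self.a_scale.anchor_min,
                "anchor_max": self.a_scale.anchor_max,
                "unit": self.a_scale.unit,
            },
            "r_scale": {
                "labels": list(self.r_scale.labels),
                "anchor_min": self.r_scale.anchor_min,
                "anchor_max": self.r_scale.anchor_max,
                "unit": self.r_scale.unit,
            },
            "bound_policy": self.bound_policy,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "QuantConfig":
        kwargs = dict(d)
        for key in ("a_scale", "r_scale"):
            if key in kwargs and isinstance(kwargs[key], Mapping):
                s = kwargs[key]
                kwargs[key] = OrdinalScale(
                    tuple(s["labels"]),
                    int(s["anchor_min"]),
                    int(s["anchor_max"]),
                    s.get("unit", ""),
                )
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Stable digest of the configuration.

        Theories quantified under different configurations must never be
        compared silently; the comparison layer matches these hashes.
        """
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class BoundViolation:
    """A step at which a running posterior left the open interval (0, 1)."""

    a_middles: tuple[int, ...]
    r_middles: tuple[int, ...]
    step_index: int
    value: float


class BoundError(RuntimeError):
    """Raised under ``bound_policy='error'`` when a trajectory leaves (0, 1)."""

    def __init__(self, violation: BoundViolation):
        self.violation = violation
        super().__init__(
            f"posterior left (0, 1) at step {violation.step_index} "
            f"(value {violation.value:.6g}) under middle assignment "
            f"a={violation.a_middles}, r={violation.r_middles}"
        )


def enumerate_middle_assignments(scale: OrdinalScale) -> list[tuple[int, ...]]:
    """All admissible middle-value assignments for *scale*.

    Each assignment is a strictly increasing tuple of integers drawn from the
    open anchor interval, one per middle ordinal, in lexicographic order.
    A two-label scale has no middles and yields the single empty assignment.
    """
    return list(itertools.combinations(scale.middle_candidates, scale.n_middles))


def resolve_values(
    scale: OrdinalScale, assignment: Sequence[int]
) -> dict[str, int]:
    """Map each label of *scale* to its integer value under *assignment*.

    The lowest label gets ``anchor_min``, the highest ``anchor_max``, and the
    middle labels the assignment values in rank order.
    """
    assignment = tuple(assignment)
    if len(assignment) != scale.n_middles:
        raise ValueError(
            f"assignment {assignment} has {len(assignment)} values; "
            f"scale needs {scale.n_middles}"
        )
    if any(b <= a for a, b in zip(assignment, assignment[1:])):
        raise ValueError(f"assignment {assignment} is not strictly increasing")
    if assignment and not (
        scale.anchor_min < assignment[0] and assignment[-1] < scale.anchor_max
    ):
        raise ValueError(
            f"assignment {assignment} leaves the open interval "
            f"({scale.anchor_min}, {scale.anchor_max})"
        )
    values = (scale.anchor_min, *assignment, scale.anchor_max)
    return dict(zip(scale.labels, values))


def update_step(
    posterior: float,
    a_value: int,
    r_value: int,
    mechanism: str = "multiplicative",
) -> float:
    """Advance the running posterior by one evidence item.

    Multiplicative: ``p' = p * (1 + a/100) / (1 - r/100)``.
    Additive:       ``p' = (p + a/100) / (1 - r/100)``.
    """
    if r_value >= 100:
        raise ValueError("r_value must be below 100 (the marginal 1 - r/100 must be positive)")
    marginal = 1.0 - r_value / 100.0
    if mechanism == "multiplicative":
        return posterior * (1.0 + a_value / 100.0) / marginal
    if mechanism == "additive":
        return (posterior + a_value / 100.0) / marginal
    raise ValueError(f"unknown mechanism {mechanism!r}")


@dataclass
class PosteriorSet:
    """The grid of final posteriors for one theory.

    ``entries`` maps each middle-value assignment pair
    ``(a_middles, r_middles)`` to the posterior obtained by folding the
    update over all non-rejected items starting from the prior.  Under the
    default three-label scales anchored (1, 10) the grid has 64 entries.
    """

    theory_name: str
    entries: dict[tuple[tuple[int, ...], tuple[int, ...]], float]
    config: QuantConfig
    bound_violations: list[BoundViolation] = field(default_factory=list)
    n_items: int = 0
    n_rejected: int = 0

    @property
    def posteriors(self) -> np.ndarray:
        """Grid posteriors as a 1-D array in enumeration order."""
        return np.asarray(list(self.entries.values()), dtype=float)

    def __len__(self) -> int:
        return len(self.entries)

    def to_dict(self) -> dict:
        return {
            "theory": self.theory_name,
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "n_items": self.n_items,
            "n_rejected": self.n_rejected,
            "posteriors": [
                {"a_mid": list(a), "r_mid": list(r), "posterior": p}
                for (a, r), p in self.entries.items()
            ],
            "bound_violations": [
                {
                    "a_mid": list(v.a_middles),
                    "r_mid": list(v.r_middles),
                    "step": v.step_index,
                    "value": v.value,
                }
                for v in self.bound_violations
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PosteriorSet":
        config = QuantConfig.from_dict(d["config"])
        entries = {
            (tuple(e["a_mid"]), tuple(e["r_mid"])): float(e["posterior"])
            for e in d["posteriors"]
        }
        violations = [
            BoundViolation(
                tuple(v["a_mid"]), tuple(v["r_mid"]), int(v["step"]), float(v["value"])
            )
            for v in d.get("bound_violations", [])
        ]
        return cls(
            theory_name=d["theory"],
            entries=entries,
            config=config,
            bound_violations=violations,
            n_items=int(d.get("n_items", 0)),
            n_rejected=int(d.get("n_rejected", 0)),
        )


def quantify_theory(dataset: TheoryDataset, config: QuantConfig | None = None) -> PosteriorSet:
    """Quantify one theory's evidence into its posterior grid.

    For every pair of admissible middle-value assignments (A-scale x
    R-scale), the update is folded over all non-rejected items in input
    order starting from the configured prior.  Rejected items are skipped
    (and counted); running posteriors that leave (0, 1) are recorded,
    warned about, or fatal according to ``config.bound_policy``.
    """
    config = config or QuantConfig()
    items = dataset.non_rejected()
    n_rejected = len(dataset.items) - len(items)
    if n_rejected:
        logger.info(
            "%s: skipping %d rejected item(s) of %d",
            dataset.name, n_rejected, len(dataset.items),
        )

    a_assignments = enumerate_middle_assignments(config.a_scale)
    r_assignments = enumerate_middle_assignments(config.r_scale)
    prior = config.resolved_prior

    entries: dict[tuple[tuple[int, ...], tuple[int, ...]], float] = {}
    violations: list[BoundViolation] = []
    for a_mid in a_assignments:
        a_values = resolve_values(config.a_scale, a_mid)
        for r_mid in r_assignments:
            r_values = resolve_values(config.r_scale, r_mid)
            p = prior
            for step, item in enumerate(items):
                p = update_step(
                    p, a_values[item.a_score], r_values[item.r_score], config.mechanism
                )
                logger.debug(
                    "%s a=%s r=%s step %d -> %.6g",
                    dataset.name, a_mid, r_mid, step, p,
                )
                if not (0.0 < p < 1.0):
                    violation = BoundViolation(a_mid, r_mid, step, p)
                    if config.bound_policy == "error":
                        raise BoundError(violation)
                    if config.bound_policy == "warn":
                        violations.append(violation)
                        logger.warning(
                            "%s: posterior %.6g outside (0, 1) at step %d "
                            "(a=%s, r=%s)",
                            dataset.name, p, step, a_mid, r_mid,
                        )
            entries[(a_mid, r_mid)] = p
    return PosteriorSet(
        theory_name=dataset.name,
        entries=entries,
        config=config,
        bound_violations=violations,
        n_items=len(dataset.items),
        n_rejected=n_rejected,
    )


def quantify_field(
    datasets: Iterable[TheoryDataset], config: QuantConfig | None = None
) -> list[PosteriorSet]:
    """Quantify several theories under one shared configuration."""
    config = config or QuantConfig()
    return [quantify_theory(ds, config) for ds in datasets]


def check_bounds(ps: PosteriorSet) -> list[BoundViolation]:
    """Return the per-step bound violations recorded during quantification."""
    return list(ps.bound_violations)
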