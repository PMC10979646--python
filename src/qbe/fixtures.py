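"""Bundled demonstration datasets: four hypothetical theories A-D.

These are the published demonstration count matrices for four hypothetical
theories of consciousness, each tabulating 3 R-score rows (high, medium,
low) by 3 non-rejected A-score columns (accepted, coherent_testable,
coherent_untestable).  ``REFERENCE_STATS`` carries the summary statistics
published alongside them, used by the ``repro-tables`` command to show the
recomputation side by side with the reference values.
"""

from __future__ import annotations

from .core import TheoryDataset, expand_matrix

__all__ = ["DEMO_MATRICES", "REFERENCE_STATS", "demo_datasets"]

#: Rows: R-score (high, medium, low); columns: A-score
#: (accepted, coherent_testable, coherent_untestable).
DEMO_MATRICES: dict[str, list[list[int]]] = {
    "A": [[1, 0, 4], [1, 7, 8], [0, 2, 3]],
    "B": [[0, 2, 1], [0, 6, 3], [0, 4, 4]],
    "C": [[0, 2, 0], [0, 5, 8], [1, 5, 4]],
    "D": [[1, 1, 1], [1, 1, 3], [0, 3, 3]],
}

#: Published reference summary statistics for the demonstration datasets
#: under the default configuration (prior 0.04, multiplicative mechanism,
#: both scales anchored 1-10).  ``ratio_A_B`` is A's mean over B's.
REFERENCE_STATS: dict[str, dict[str, float]] = {
    "mean": {"A": 0.4409, "B": 0.2157, "C": 0.2920, "D": 0.1329},
    "sd": {"A": 0.1940, "B": 0.0744, "C": 0.1218, "D": 0.0219},
    "ratio": {"A_B": 2.0442, "A_C": 1.5099, "A_D": 3.3175},
}


def demo_datasets() -> list[TheoryDataset]:
    """The four demonstration theories, expanded to explicit item lists."""
    return [expand_matrix(mat, name) for name, mat in DEMO_MATRICES.items()]
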