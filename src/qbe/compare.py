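"""Cross-theory comparison of posterior grids.

A theory's quantified support is a *set* of posteriors (one per middle-value
assignment), so comparisons operate on whole grids:

* mean posterior and n-1 sample SD per theory;
* pairwise ratio matrix of unrounded mean posteriors;
* z-scores of each theory's mean against the pooled posteriors of all
  theories (or against the theory means, by option);
* Welch's unequal-variance t-test between two grids, one- or two-tailed;
* trapezoid area under the sorted-posterior curve.

A caveat applies to the inferential statistics: the 64 grid points are a
deterministic sensitivity sweep, not independent draws, so t-test p-values
are descriptive summaries of grid separation rather than sampling-theory
probabilities.  No multiple-testing correction is applied across pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import PosteriorSet

__all__ = [
    "ComparisonReport",
    "TTestResult",
    "mean_posterior",
    "sample_sd",
    "ratio_matrix",
    "z_scores",
    "welch_t_test",
    "auc_sorted",
    "build_report",
    "export_plot_data",
    "plot_report",
]


def _as_array(ps: PosteriorSet | Sequence[float]) -> np.ndarray:
    if isinstance(ps, PosteriorSet):
        return ps.posteriors
    return np.asarray(ps, dtype=float)


def mean_posterior(ps: PosteriorSet | Sequence[float]) -> float:
    """Arithmetic mean of the grid posteriors."""
    x = _as_array(ps)
    if x.size == 0:
        raise ValueError("cannot take the mean of an empty posterior set")
    return float(x.mean())


def sample_sd(ps: PosteriorSet | Sequence[float]) -> float:
    """Standard deviation of the grid posteriors with n-1 denominator."""
    x = _as_array(ps)
    if x.size < 2:
        raise ValueError("sample SD needs at least 2 posteriors")
    return float(x.std(ddof=1))


def ratio_matrix(means: Mapping[str, float]) -> pd.DataFrame:
    """Pairwise ratios of mean posteriors.

    Entry ``[i, j]`` is ``mean_i / mean_j`` computed from the *unrounded*
    means; the diagonal is undefined and stored as NaN (rendered as ``"X"``
    on export).
    """
    names = list(means)
    vals = np.array([means[n] for n in names], dtype=float)
    if (vals <= 0).any():
        raise ValueError("ratio matrix requires strictly positive means")
    mat = vals[:, None] / vals[None, :]
    np.fill_diagonal(mat, np.nan)
    return pd.DataFrame(mat, index=names, columns=names)


def z_scores(
    sets: Sequence[PosteriorSet],
    pooling: str = "all_posteriors",
) -> dict[str, float]:
    """How many SDs each theory's mean lies from the field average.

    ``pooling='all_posteriors'`` (default) anchors on the mean and n-1 SD of
    every grid posterior of every theory pooled together;
    ``pooling='theory_means'`` anchors on the distribution of the theory
    means themselves (in which case the z-scores sum to zero).
    """
    if len(sets) < 2:
        raise ValueError("z-scores need at least 2 theories")
    means = {ps.theory_name: mean_posterior(ps) for ps in sets}
    if pooling == "all_posteriors":
        pool = np.concatenate([ps.posteriors for ps in sets])
    elif pooling == "theory_means":
        pool = np.asarray(list(means.values()))
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    mu = float(pool.mean())
    sigma = float(pool.std(ddof=1))
    if np.ptp(pool) == 0.0 or sigma == 0.0:
        raise ValueError("pooled SD is zero; z-scores are undefined")
    return {name: (m - mu) / sigma for name, m in means.items()}


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    tails: str


def welch_t_test(
    a: PosteriorSet | Sequence[float],
    b: PosteriorSet | Sequence[float],
    tails: str = "two",
) -> TTestResult:
    """Welch's unequal-variance t-test between two posterior grids.

    ``tails='one'`` halves the two-tailed p when the observed direction
    matches the alternative (first sample larger); otherwise the one-tailed
    p is ``1 - p_two/2``.
    """
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    xa, xb = _as_array(a), _as_array(b)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("t-test needs at least 2 posteriors per set")
    if xa.std() == 0 and xb.std() == 0 and xa.mean() == xb.mean():
        raise ValueError("t statistic undefined: zero variance and equal means")
    res = stats.ttest_ind(xa, xb, equal_var=False)
    t, p_two = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    if tails == "two":
        return TTestResult(t, df, p_two, tails)
    p_one = p_two / 2 if t > 0 else 1 - p_two / 2
    return TTestResult(t, df, p_one, tails)


def auc_sorted(ps: PosteriorSet | Sequence[float]) -> float:
    """Trapezoid area under the ascending sorted-posterior curve.

    The n sorted posteriors are placed at equal spacing across the unit
    interval; the trapezoid rule gives
    ``(v_1/2 + v_2 + ... + v_{n-1} + v_n/2) / (n - 1)``.
    """
    x = np.sort(_as_array(ps))
    if x.size < 2:
        raise ValueError("AUC needs at least 2 posteriors")
    return float(np.trapezoid(x, dx=1.0 / (x.size - 1)))


@dataclass
class ComparisonReport:
    """Aggregated cross-theory comparison."""

    theories: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    zscores: dict[str, float]
    aucs: dict[str, float]
    ratios: pd.DataFrame
    t_tests: list[dict]
    pooling: str
    tails: str
    config_hash: str

    def to_dict(self) -> dict:
        ratios = self.ratios.where(pd.notna(self.ratios), other=np.nan)
        return {
            "theories": self.theories,
            "means": self.means,
            "sds": self.sds,
            "z_scores": self.zscores,
            "aucs": self.aucs,
            "ratios": {
                i: {
                    j: ("X" if i == j else float(ratios.loc[i, j]))
                    for j in self.theories
                }
                for i in self.theories
            },
            "t_tests": self.t_tests,
            "pooling": self.pooling,
            "tails": self.tails,
            "config_hash": self.config_hash,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ComparisonReport":
        theories = list(d["theories"])
        mat = np.full((len(theories), len(theories)), np.nan)
        for i, ti in enumerate(theories):
            for j, tj in enumerate(theories):
                v = d["ratios"][ti][tj]
                if v != "X":
                    mat[i, j] = float(v)
        return cls(
            theories=theories,
            means=dict(d["means"]),
            sds=dict(d["sds"]),
            zscores=dict(d["z_scores"]),
            aucs=dict(d["aucs"]),
            ratios=pd.DataFrame(mat, index=theories, columns=theories),
            t_tests=list(d["t_tests"]),
            pooling=d["pooling"],
            tails=d["tails"],
            config_hash=d["config_hash"],
        )

    @classmethod
    def from_json(cls, s: str) -> "ComparisonReport":
        return cls.from_dict(json.loads(s))

    def summary_frame(self) -> pd.DataFrame:
        """Per-theory summary statistics as a tidy DataFrame."""
        return pd.DataFrame(
            {
                "mean_posterior": self.means,
                "sample_sd": self.sds,
                "z_score": self.zscores,
                "auc": self.aucs,
            }
        ).rename_axis("theory")


def build_report(
    sets: Sequence[PosteriorSet],
    pooling: str = "all_posteriors",
    tails: str = "two",
) -> ComparisonReport:
    """Compute the full comparison report for two or more theories.

    All sets must have been quantified under the same configuration;
    mismatched configuration hashes are an error, never silently mixed.
    """
    if len(sets) < 2:
        raise ValueError("comparison needs at least 2 theories")
    hashes = {ps.config.config_hash() for ps in sets}
    if len(hashes) > 1:
        raise ValueError(
            "posterior sets were quantified under different configurations; "
            "re-quantify with a shared config before comparing"
        )
    names = [ps.theory_name for ps in sets]
    if len(set(names)) != len(names):
        raise ValueError("theory names must be unique")
    means = {ps.theory_name: mean_posterior(ps) for ps in sets}
    sds = {ps.theory_name: sample_sd(ps) for ps in sets}
    aucs = {ps.theory_name: auc_sorted(ps) for ps in sets}
    zs = z_scores(sets, pooling=pooling)
    t_tests = []
    by_name = {ps.theory_name: ps for ps in sets}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = welch_t_test(by_name[a], by_name[b], tails=tails)
            t_tests.append(
                {"a": a, "b": b, "t": res.t, "df": res.df, "p": res.p, "tails": tails}
            )
    return ComparisonReport(
        theories=names,
        means=means,
        sds=sds,
        zscores=zs,
        aucs=aucs,
        ratios=ratio_matrix(means),
        t_tests=t_tests,
        pooling=pooling,
        tails=tails,
        config_hash=hashes.pop(),
    )


def export_plot_data(sets: Sequence[PosteriorSet], pooling: str = "all_posteriors") -> dict:
    """Data underlying the standard depictions, as plain lists.

    Returns sorted posterior curves (one per theory), the (mean, sd) pairs
    parameterising a normal-density depiction of each grid, and the
    z-scores — everything needed to render the curves externally.
    """
    curves = {
        ps.theory_name: np.sort(ps.posteriors).tolist() for ps in sets
    }
    normal_params = {
        ps.theory_name: {"mean": mean_posterior(ps), "sd": sample_sd(ps)}
        for ps in sets
    }
    return {
        "sorted_curves": curves,
        "normal_params": normal_params,
        "z_scores": z_scores(sets, pooling=pooling),
    }


def plot_report(sets: Sequence[PosteriorSet], path: str, pooling: str = "all_posteriors") -> None:
    """Render sorted-posterior curves, normal densities and z-score bars.

    Writes a single figure to *path* (format from the extension, SVG/PNG).
    """
    from matplotlib.figure import Figure

    data = export_plot_data(sets, pooling=pooling)
    fig = Figure(figsize=(12, 4))
    ax1, ax2, ax3 = fig.subplots(1, 3)

    for name, curve in data["sorted_curves"].items():
        ax1.plot(np.linspace(0, 1, len(curve)), curve, label=name)
    ax1.set_xlabel("grid fraction (sorted)")
    ax1.set_ylabel("posterior")
    ax1.set_title("Sorted posterior curves")
    ax1.legend(fontsize=8)

    for name, pars in data["normal_params"].items():
        mu, sd = pars["mean"], pars["sd"]
        xs = np.linspace(mu - 4 * sd, mu + 4 * sd, 200)
        ax2.plot(xs, stats.norm.pdf(xs, mu, sd), label=name)
    ax2.set_xlabel("posterior")
    ax2.set_ylabel("density")
    ax2.set_title("Normal depiction of grids")

    zs = data["z_scores"]
    ax3.bar(range(len(zs)), list(zs.values()), tick_label=list(zs))
    ax3.axhline(0.0, color="k", lw=0.8)
    ax3.set_ylabel("z-score")
    ax3.set_title("Support relative to field")

    fig.tight_layout()
    fig.savefig(path)
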