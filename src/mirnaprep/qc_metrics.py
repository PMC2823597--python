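"""Replicate-precision QC: SD-vs-mean profiles, spline trends, RLE.

Preprocessing methods for these arrays are compared by the variability they
leave between biological replicates.  Per gene and per replicate group we
compute the mean and the sample SD of the log2 signal across the group's
arrays; a natural cubic spline (5 knots) fitted to SD against mean gives the
intensity-dependent noise trend.  Relative log expression (RLE) — each
array's signal minus the gene's across-array median — summarizes residual
between-array shifts; after a successful normalization every array's RLE
distribution is centered on zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import dmatrix

from .afe_io import ArrayDesign, ExpressionMatrix, FeatureTable
from .errors import MirnaPrepError
from .summarize import process

__all__ = [
    "SdProfile",
    "SplineTrend",
    "RleSummary",
    "replicate_sd",
    "fit_sd_trend",
    "rle",
    "compare_methods",
]


@dataclass
class SdProfile:
    """Per-gene (mean, SD) of log2 signal within one replicate group."""

    gene_ids: list[str]
    mean_log2: np.ndarray
    sd_log2: np.ndarray
    group_label: str

    def __post_init__(self) -> None:
        if not (len(self.gene_ids) == len(self.mean_log2) == len(self.sd_log2)):
            raise ValueError("inconsistent lengths in SdProfile")
        if (self.sd_log2 < 0).any():
            raise ValueError("negative SD")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "group": self.group_label,
                "mean_log2": self.mean_log2,
                "sd_log2": self.sd_log2,
            }
        )


@dataclass
class SplineTrend:
    """Least-squares natural-cubic-spline fit of SD against mean intensity."""

    knots: np.ndarray          # all knots, ascending (5 by default)
    coefficients: np.ndarray   # basis coefficients of the fitted curve
    fitted: pd.DataFrame       # columns x, y: 100-point evaluation grid

    def predict(self, x) -> np.ndarray:
        basis = _natural_basis(np.asarray(x, float), self.knots)
        return basis @ self.coefficients


@dataclass
class RleSummary:
    """Relative log expression per array: matrix plus five-number summaries."""

    rle_matrix: pd.DataFrame   # gene x array
    summary: pd.DataFrame      # array x (min, q1, median, q3, max)

    @property
    def array_ids(self) -> list[str]:
        return list(self.summary.index)


def replicate_sd(m: ExpressionMatrix, groups: dict[str, str]) -> list[SdProfile]:
    """Mean and sample SD (n-1) per gene within each biological group.

    ``groups`` maps array_id -> group label; every group must contain at
    least 2 arrays, since an SD over one replicate is undefined.
    """
    if m.scale != "log2":
        raise MirnaPrepError("replicate_sd expects log2-scale data")
    df = m.values
    missing = [a for a in df.columns if a not in groups]
    if missing:
        raise MirnaPrepError(f"arrays without group label: {missing}")
    profiles = []
    for label in sorted(set(groups.values())):
        arrays = [a for a in df.columns if groups[a] == label]
        if len(arrays) < 2:
            raise MirnaPrepError(
                f"group {label!r} has {len(arrays)} array(s); need >= 2"
            )
        sub = df[arrays]
        profiles.append(
            SdProfile(
                gene_ids=list(df.index),
                mean_log2=sub.mean(axis=1).to_numpy(),
                sd_log2=sub.std(axis=1, ddof=1).to_numpy(),
                group_label=label,
            )
        )
    return profiles


def _natural_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic regression spline basis with the given (all) knots.

    Built through patsy's ``cr`` with the outer knots as boundary knots, so
    the fit is linear beyond them.  Dimension equals the number of knots.
    """
    return np.asarray(
        dmatrix(
            "cr(x, knots=inner, lower_bound=lb, upper_bound=ub) - 1",
            {"x": x, "inner": knots[1:-1], "lb": knots[0], "ub": knots[-1]},
        )
    )


def fit_sd_trend(profile: SdProfile, n_knots: int = 5) -> SplineTrend:
    """Fit SD ~ natural cubic spline(mean intensity) by least squares.

    Knots sit at the {1/(k+1), ..., k/(k+1)} quantiles of the mean
    intensities (all five knots for the default k = 5), with natural
    (linear) behavior beyond the outer knots.  The fitted curve is returned
    on a 100-point grid spanning the data range.
    """
    x = np.asarray(profile.mean_log2, float)
    y = np.asarray(profile.sd_log2, float)
    if x.size < n_knots + 2:
        raise MirnaPrepError(
            f"need at least {n_knots + 2} points to fit {n_knots}-knot spline"
        )
    if np.ptp(x) == 0:
        raise MirnaPrepError("degenerate mean intensities: zero spread")
    probs = np.arange(1, n_knots + 1) / (n_knots + 1)
    knots = np.quantile(x, probs)
    if np.unique(knots).size < n_knots:
        raise MirnaPrepError("tied knot positions; data too discrete for spline")
    basis = _natural_basis(x, knots)
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    grid = np.linspace(x.min(), x.max(), 100)
    fitted = _natural_basis(grid, knots) @ coef
    return SplineTrend(
        knots=knots,
        coefficients=coef,
        fitted=pd.DataFrame({"x": grid, "y": fitted}),
    )


def rle(m: ExpressionMatrix) -> RleSummary:
    """RLE = signal minus the gene's median across arrays; per-array summary."""
    df = m.values
    if df.shape[1] < 2:
        raise MirnaPrepError("RLE needs at least 2 arrays")
    med = df.median(axis=1)
    r = df.sub(med, axis=0)
    summary = pd.DataFrame(
        {
            "min": r.min(axis=0),
            "q1": r.quantile(0.25, axis=0),
            "median": r.median(axis=0),
            "q3": r.quantile(0.75, axis=0),
            "max": r.max(axis=0),
        }
    )
    summary.index.name = "array_id"
    return RleSummary(rle_matrix=r, summary=summary)


@dataclass
class MethodQc:
    """QC bundle for one preprocessing method."""

    method: str
    expression: ExpressionMatrix
    sd_profiles: list[SdProfile]
    trends: dict[str, SplineTrend]  # group label -> trend
    rle: RleSummary


def compare_methods(tables: list[FeatureTable], groups: dict[str, str],
                    methods: list[str],
                    design: ArrayDesign | None = None) -> dict[str, MethodQc]:
    """Run the requested preprocessing methods and QC each on the shared genes.

    Returns one :class:`MethodQc` per method; use :func:`tidy_sd_table` on
    the result for a long-format (method, gene, group, mean, SD) table.
    """
    if len(methods) < 2:
        raise MirnaPrepError("compare_methods needs at least 2 methods")
    out: dict[str, MethodQc] = {}
    for method in methods:
        em = process(tables, method, design=design)
        profiles = replicate_sd(em, groups)
        trends = {p.group_label: fit_sd_trend(p) for p in profiles}
        out[method] = MethodQc(
            method=method,
            expression=em,
            sd_profiles=profiles,
            trends=trends,
            rle=rle(em),
        )
    return out


def tidy_sd_table(bundles: dict[str, MethodQc]) -> pd.DataFrame:
    """Long-format (method, gene_id, group, mean_log2, sd_log2) table."""
    frames = []
    for method, qc in bundles.items():
        for p in qc.sd_profiles:
            f = p.to_frame()
            f.insert(0, "method", method)
            frames.append(f)
    return pd.concat(frames, ignore_index=True)


def low_intensity_mean_sd(bundle: MethodQc, fraction: float = 1 / 3) -> float:
    """Mean replicate SD in the lowest-intensity stratum, averaged over groups.

    The stratum is the lowest ``fraction`` of genes by mean intensity within
    each group's own profile.
    """
    means = []
    for p in bundle.sd_profiles:
        cutoff = np.quantile(p.mean_log2, fraction)
        mask = p.mean_log2 <= cutoff
        means.append(float(p.sd_log2[mask].mean()))
    return float(np.mean(means))


def plot_sd_trends(bundles: dict[str, MethodQc], path, group: str | None = None):
    """Overlay fitted SD-vs-mean spline trends per method (one PNG/SVG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for method, qc in bundles.items():
        for label, trend in qc.trends.items():
            if group is not None and label != group:
                continue
            ax.plot(trend.fitted["x"], trend.fitted["y"],
                    label=f"{method} ({label})")
    ax.set_xlabel("mean log2 signal")
    ax.set_ylabel("SD across biological replicates")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rle(bundle: MethodQc, path):
    """RLE boxplots, one box per array."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = bundle.rle.rle_matrix
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * r.shape[1]), 4))
    ax.boxplot([r[c].to_numpy() for c in r.columns], tick_labels=list(r.columns))
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel("relative log expression")
    ax.set_title(bundle.method)
    plt.setp(ax.get_xticklabels(), rotation=60, ha="right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
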