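"""Summarization of replicated features into per-microRNA signals.

Two summarization routes are provided:

* the vendor-style total gene signal (TGS): a robust average of the
  background-subtracted replicate-feature signals per probe, scaled by the
  replicate count and accumulated over the gene's probes; and
* the adapted RMA route: per-array background correction (optional),
  quantile normalization of the feature-level data, log2, median over
  replicate features of each distinct probe, and a robust additive fit
  (Tukey's median polish) of signal = microRNA value + probe effect + error
  per gene, whose column effects give the per-array microRNA estimate.

:func:`process` chains these with the normalization primitives into the four
processed signals nor75 / norQ / norRMA / norRMAbg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import normalize
from .afe_io import (
    ArrayDesign,
    ExpressionMatrix,
    FeatureTable,
    ProbeMatrix,
    assemble_matrix,
    infer_design,
)
from .background import correct_background, estimate_bg_params
from .errors import IntegrityError, MirnaPrepError

METHODS = ("nor75", "norQ", "norRMA", "norRMAbg")


@dataclass
class MedianPolishFit:
    """Additive two-way decomposition of a probe x array matrix.

    ``overall + row_effects[i] + col_effects[j] + residuals[i, j]``
    reconstructs the input exactly; at convergence the medians of the row
    and column effects are ~0 (Tukey's identifiability convention).
    """

    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    iterations: int
    converged: bool


@dataclass(frozen=True)
class TgsOptions:
    """How the per-probe robust average of the total gene signal is formed."""

    robust_average: str = "median"  # or "outlier_trimmed_mean"
    multiply_by_probe_count: bool = False

    def __post_init__(self) -> None:
        if self.robust_average not in ("median", "outlier_trimmed_mean"):
            raise ValueError(f"unknown robust_average {self.robust_average!r}")


def collapse_replicates(features: pd.DataFrame, design: ArrayDesign,
                        scale: str = "log2") -> ProbeMatrix:
    """Median over replicate features -> one row per distinct probe.

    ``features`` is the (gene_id, probe_id, replicate)-indexed matrix from
    :func:`mirnaprep.afe_io.assemble_matrix`, on log2 scale in the standard
    pipeline order.  Even replicate counts use the mean-of-the-two-middle
    convention.
    """
    for p, n in design.replicates_per_probe.items():
        if n < 1:
            raise IntegrityError(f"probe {p!r} has zero replicates in design")
    med = features.groupby(level="probe_id", sort=True).median()
    return ProbeMatrix(values=med, scale=scale, gene_of=dict(design.gene_of))


def median_polish(m, tol: float = 0.01, max_iter: int = 10) -> MedianPolishFit:
    """Tukey's median polish: alternately sweep row and column medians.

    Row sweep first.  Iteration stops when the sum of absolute residuals
    shrinks by less than ``tol`` (relative) in one full sweep, or after
    ``max_iter`` sweeps.
    """
    x = np.asarray(m, dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("median_polish expects a non-empty 2-D matrix")
    if not np.isfinite(x).all():
        raise MirnaPrepError("median_polish: non-finite input")
    resid = x.copy()
    nrow, ncol = x.shape
    overall = 0.0
    row_eff = np.zeros(nrow)
    col_eff = np.zeros(ncol)
    prev = np.abs(resid).sum()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row_eff += rmed
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta

        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col_eff += cmed
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta

        total = np.abs(resid).sum()
        if total == 0 or (prev > 0 and (prev - total) < tol * prev):
            converged = True
            break
        prev = total
    # exact reconstruction: recompute residuals from the fitted effects
    resid = x - (overall + row_eff[:, None] + col_eff[None, :])
    return MedianPolishFit(
        overall=float(overall),
        row_effects=row_eff,
        col_effects=col_eff,
        residuals=resid,
        iterations=it,
        converged=converged,
    )


def rma_summarize(pm: ProbeMatrix, design: ArrayDesign) -> ExpressionMatrix:
    """Per-gene median polish of the log2 probe matrix.

    The microRNA estimate for array j is ``overall + col_effects[j]``; the
    probe (row) effects absorb probe affinity.  Single-probe genes pass
    through unchanged.
    """
    if pm.scale != "log2":
        raise MirnaPrepError("rma_summarize expects log2-scale probe data")
    vals = pm.values
    rows = []
    for g in design.gene_ids:
        probes = design.probes_per_gene[g]
        missing = [p for p in probes if p not in vals.index]
        if missing:
            raise IntegrityError(f"gene {g!r}: probes {missing} absent from matrix")
        sub = vals.loc[probes].to_numpy(dtype=float)
        if sub.shape[0] == 1:
            rows.append(sub[0])
        else:
            fit = median_polish(sub)
            rows.append(fit.overall + fit.col_effects)
    out = pd.DataFrame(np.vstack(rows), index=pd.Index(design.gene_ids, name="gene_id"),
                       columns=vals.columns)
    return ExpressionMatrix(values=out, scale="log2", method="norRMA")


def _robust_average(v: np.ndarray, kind: str) -> float:
    if kind == "median":
        return float(np.median(v))
    # outlier-trimmed mean: drop values beyond 1.5*IQR from the quartiles
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    keep = (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)
    return float(v[keep].mean()) if keep.any() else float(np.median(v))


def compute_tgs(tables: list[FeatureTable], design: ArrayDesign,
                opts: TgsOptions | None = None) -> ExpressionMatrix:
    """Vendor-style total gene signal, linear scale, possibly negative.

    Per probe: total probe signal = robust average of the replicate
    background-subtracted signals x replicate count.  Per gene: the sum of
    its probes' total probe signals (with ``multiply_by_probe_count`` the
    per-probe mean of total probe signals is instead multiplied by the probe
    count, which coincides when all probes agree).
    """
    opts = opts or TgsOptions()
    feats = assemble_matrix(tables, design, channel="bgsub_signal")
    grouped_feats = feats.groupby(level="probe_id", sort=True)
    if opts.robust_average == "median":
        probe_totals = grouped_feats.median()
    else:
        probe_totals = grouped_feats.agg(
            lambda v: _robust_average(v.to_numpy(), opts.robust_average)
        )
    reps = pd.Series(design.replicates_per_probe)
    probe_totals = probe_totals.mul(reps.loc[probe_totals.index], axis=0)
    gene_of = pd.Series(design.gene_of)
    grouped = probe_totals.groupby(gene_of.loc[probe_totals.index].to_numpy())
    if opts.multiply_by_probe_count:
        tgs = grouped.mean() * grouped.size().to_numpy()[:, None]
    else:
        tgs = grouped.sum()
    tgs = tgs.loc[design.gene_ids]
    tgs.index.name = "gene_id"
    return ExpressionMatrix(values=tgs, scale="linear", method="TGS_raw")


def process(tables: list[FeatureTable], method: str,
            design: ArrayDesign | None = None,
            tgs_opts: TgsOptions | None = None,
            bg_params: dict | None = None,
            bg_params_log: dict | None = None) -> ExpressionMatrix:
    """Run one of the four preprocessing routes end to end.

    nor75    : TGS -> positivity offset -> 75th-percentile scaling -> log2
    norQ     : TGS -> positivity offset -> quantile normalization -> log2
    norRMA   : raw mean signals -> quantile normalization -> log2 ->
               replicate medians -> median-polish summarization
    norRMAbg : as norRMA with per-array exponential+normal background
               correction of the mean signals first

    ``bg_params`` optionally supplies fixed per-array
    :class:`~mirnaprep.background.BgParams` for norRMAbg instead of
    estimating them; ``bg_params_log`` (optional dict) receives the
    parameters actually used, for QC logging.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if len(tables) < 2:
        raise MirnaPrepError("need at least 2 arrays")
    if design is None:
        design = infer_design(tables)

    if method in ("nor75", "norQ"):
        tgs = compute_tgs(tables, design, tgs_opts)
        lin = normalize.shift_positive(tgs.values)
        if method == "nor75":
            lin = normalize.scale_to_percentile75(lin)
        else:
            lin = normalize.quantile_normalize(lin)
        out = normalize.log2_transform(lin)
        return ExpressionMatrix(values=out, scale="log2", method=method)

    feats = assemble_matrix(tables, design, channel="mean_signal")
    if method == "norRMAbg":
        corrected = {}
        for a in feats.columns:
            if bg_params is not None:
                p = bg_params[a]
            else:
                p = estimate_bg_params(feats[a].to_numpy())
            if bg_params_log is not None:
                bg_params_log[a] = p
            corrected[a] = correct_background(feats[a].to_numpy(), p)
        feats = pd.DataFrame(corrected, index=feats.index)
    qn = normalize.quantile_normalize(feats)
    logged = normalize.log2_transform(qn)
    pm = collapse_replicates(logged, design, scale="log2")
    em = rma_summarize(pm, design)
    return ExpressionMatrix(values=em.values, scale="log2", method=method)
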