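"""Detection-flag filtering of microRNAs.

AFE emits a per-feature IsGeneDetected flag.  Features are aggregated to a
gene-per-array call (majority of features by default), and a microRNA is
kept when it is detected in a sufficient fraction of the arrays of at least
one biological group.  Controls never pass the filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .afe_io import ArrayDesign, ExpressionMatrix, FeatureTable
from .errors import MirnaPrepError

__all__ = ["DetectionCall", "gene_flags", "filter_expressed"]


@dataclass
class DetectionCall:
    """Audit record for one microRNA's pass through the filter."""

    gene_id: str
    per_array: dict[str, int]       # array_id -> 0/1 gene-level flag
    per_group: dict[str, bool]      # group label -> detected in that group
    kept: bool


def gene_flags(tables: list[FeatureTable], design: ArrayDesign,
               threshold: float = 0.5) -> pd.DataFrame:
    """Aggregate feature flags to a gene x array 0/1 matrix.

    A gene counts as detected on an array when the fraction of its features
    flagged 1 exceeds ``threshold`` (strict majority at the default 0.5; use
    0.0 for "any feature" and 1.0 is unreachable — pass e.g. 0.999 for
    "all features" semantics, or use fractions directly).
    """
    if not 0.0 <= threshold <= 1.0:
        raise MirnaPrepError("threshold must lie in [0, 1]")
    cols = {}
    for t in tables:
        exp = t.experimental
        frac = exp.groupby("gene_id")["is_gene_detected"].mean()
        missing = [g for g in design.gene_ids if g not in frac.index]
        if missing:
            raise MirnaPrepError(f"genes without features on {t.array_id!r}: "
                                 f"{missing[:5]}")
        cols[t.array_id] = (frac.loc[design.gene_ids] > threshold).astype(int)
    out = pd.DataFrame(cols)
    out.index = pd.Index(design.gene_ids, name="gene_id")
    return out


def filter_expressed(m: ExpressionMatrix, flags: pd.DataFrame,
                     groups: dict[str, str], min_fraction: float = 1.0
                     ) -> tuple[ExpressionMatrix, list[DetectionCall]]:
    """Keep genes detected in >= ``min_fraction`` of >= 1 group's arrays.

    ``min_fraction`` defaults to 1.0 — detected on every replicate of at
    least one group, the strictest reading of "expressed in at least one
    experimental group".  Returns the filtered matrix and the full audit
    trail (every input gene, kept or not).
    """
    if not 0.0 < min_fraction <= 1.0:
        raise MirnaPrepError("min_fraction must lie in (0, 1]")
    missing = [a for a in m.values.columns if a not in groups]
    if missing:
        raise MirnaPrepError(f"arrays without group label: {missing}")
    labels = sorted(set(groups[a] for a in m.values.columns))
    calls: list[DetectionCall] = []
    kept_ids: list[str] = []
    for g in m.values.index:
        if g not in flags.index:
            raise MirnaPrepError(f"gene {g!r} missing from flag matrix")
        row = flags.loc[g]
        per_group = {}
        for label in labels:
            arrays = [a for a in m.values.columns if groups[a] == label]
            per_group[label] = bool(
                np.mean([row[a] for a in arrays]) >= min_fraction
            )
        kept = any(per_group.values())
        calls.append(
            DetectionCall(
                gene_id=str(g),
                per_array={a: int(row[a]) for a in m.values.columns},
                per_group=per_group,
                kept=kept,
            )
        )
        if kept:
            kept_ids.append(g)
    filtered = ExpressionMatrix(
        values=m.values.loc[kept_ids],
        scale=m.scale,
        method=m.method,
    )
    return filtered, calls


def calls_to_frame(calls: list[DetectionCall]) -> pd.DataFrame:
    """Flatten DetectionCalls to a TSV-ready audit table."""
    rows = []
    for c in calls:
        row: dict = {"gene_id": c.gene_id, "kept": int(c.kept)}
        row.update({f"flag.{a}": v for a, v in c.per_array.items()})
        row.update({f"detected.{g}": int(v) for g, v in c.per_group.items()})
        rows.append(row)
    return pd.DataFrame(rows)
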