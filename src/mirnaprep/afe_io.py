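"""Reading and writing Agilent Feature Extraction (AFE) text exports.

AFE writes one tab-delimited text file per array.  Two dialects circulate:

* the full export with three blocks (FEPARAMS, STATS, FEATURES), each block
  introduced by a ``TYPE`` line listing column types, followed by a header
  line whose first token is the block name and ``DATA`` lines carrying the
  values, the block closed by a ``*`` line;
* a plain single-header TSV holding only the feature columns.

Both are accepted; the dialect is detected from the first token of the file.
Files may be gzip-compressed (``.gz`` suffix).

A parsed file becomes a :class:`FeatureTable`: one row per physical feature
(spot) with the probe name, the microRNA (gene) it interrogates, the raw
mean signal, the background-subtracted signal, the control type and the
AFE detection flag.  Control features are retained — they are needed for QC —
but every downstream normalization and summarization step excludes them.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignConflictError, FormatError, IntegrityError

# AFE v9.5 column vocabulary -> internal names.  Matching is case-insensitive;
# callers may pass their own map to read_afe for other vocabularies.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "ProbeName": "probe_id",
    "SystematicName": "gene_id",
    "gMeanSignal": "mean_signal",
    "gBGSubSignal": "bgsub_signal",
    "ControlType": "control_type",
    "gIsGeneDetected": "is_gene_detected",
    "Row": "row",
    "Col": "col",
}

#: Gene-id prefixes treated as controls even when ControlType == 0.
CONTROL_GENE_PREFIXES: tuple[str, ...] = (
    "NC_", "PC_", "(-)", "(+)", "DarkCorner", "NegativeControl",
)

_INTERNAL_COLUMNS = list(DEFAULT_COLUMN_MAP.values())

_DTYPES = {
    "probe_id": str,
    "gene_id": str,
    "mean_signal": float,
    "bgsub_signal": float,
    "control_type": int,
    "is_gene_detected": int,
    "row": int,
    "col": int,
}


@dataclass
class FeatureTable:
    """All features of one array plus the header metadata of its export."""

    array_id: str
    features: pd.DataFrame  # columns == _INTERNAL_COLUMNS, one row per spot
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.features
        missing = [c for c in _INTERNAL_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"feature table missing columns: {missing}")
        if df[["mean_signal", "bgsub_signal"]].isna().any().any():
            raise IntegrityError("missing numeric cells in feature table")
        if not np.isfinite(df[["mean_signal", "bgsub_signal"]].to_numpy()).all():
            raise IntegrityError("non-finite signal values in feature table")
        if not df["is_gene_detected"].isin([0, 1]).all():
            raise IntegrityError("is_gene_detected flag outside {0,1}")
        if (df["mean_signal"] < 0).any():
            raise IntegrityError("negative mean_signal")
        dup = df.duplicated(subset=["probe_id", "row", "col"])
        if dup.any():
            raise IntegrityError(
                f"duplicate (probe,row,col) triples: "
                f"{df.loc[dup, 'probe_id'].unique()[:5].tolist()}"
            )
        if not self.is_control_mask().eq(False).any():
            raise IntegrityError("no experimental (control_type == 0) features")

    def is_control_mask(self) -> pd.Series:
        """True for control features (nonzero ControlType or control prefix)."""
        df = self.features
        mask = df["control_type"] != 0
        mask |= df["gene_id"].str.startswith(CONTROL_GENE_PREFIXES)
        return mask

    @property
    def experimental(self) -> pd.DataFrame:
        return self.features.loc[~self.is_control_mask()]

    @property
    def n_experimental(self) -> int:
        return int((~self.is_control_mask()).sum())


@dataclass
class ArrayDesign:
    """Probe-to-gene layout shared by all arrays of an experiment.

    ``gene_ids`` is lexicographically ordered; every probe maps to exactly
    one gene and carries a replicate multiplicity (feature count).
    """

    gene_ids: list[str]
    probes_per_gene: dict[str, list[str]]
    replicates_per_probe: dict[str, int]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for g, probes in self.probes_per_gene.items():
            for p in probes:
                if p in seen:
                    raise DesignConflictError(
                        f"probe {p!r} mapped to both {seen[p]!r} and {g!r}"
                    )
                seen[p] = g
        self._gene_of = seen

    @property
    def gene_of(self) -> dict[str, str]:
        return self._gene_of

    def features_per_gene(self, gene_id: str) -> int:
        return sum(self.replicates_per_probe[p] for p in self.probes_per_gene[gene_id])

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class ProbeMatrix:
    """Distinct-probe x array matrix of intensities with probe->gene labels."""

    values: pd.DataFrame  # index probe_id, columns array_id
    scale: str  # "linear" | "log2"
    gene_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.isna().any().any():
            raise IntegrityError("ProbeMatrix contains missing values")


@dataclass
class ExpressionMatrix:
    """Gene x array matrix of summarized microRNA signals."""

    values: pd.DataFrame  # index gene_id, columns array_id
    scale: str  # "linear" | "log2"
    method: str  # "TGS_raw" | "nor75" | "norQ" | "norRMA" | "norRMAbg"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.isna().any().any():
            raise IntegrityError("ExpressionMatrix contains missing values")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _open_text(path) -> io.TextIOBase:
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def _parse_afe_blocks(fh) -> tuple[pd.DataFrame, dict[str, str]]:
    """Parse the 3-block AFE dialect; returns FEATURES frame + header metadata."""
    metadata: dict[str, str] = {}
    features: pd.DataFrame | None = None
    line = fh.readline()
    while line:
        tokens = line.rstrip("\n").split("\t")
        if tokens[0] != "TYPE":
            if tokens[0] in ("", "*"):
                line = fh.readline()
                continue
            raise FormatError(f"expected TYPE line, got {tokens[0]!r}")
        header = fh.readline().rstrip("\n").split("\t")
        block = header[0]
        names = header[1:]
        rows = []
        while True:
            line = fh.readline()
            if not line:
                break
            tokens = line.rstrip("\n").split("\t")
            if tokens[0] == "*":
                line = fh.readline()
                break
            if tokens[0] == "TYPE":
                break
            if tokens[0] != "DATA":
                raise FormatError(f"unexpected row marker {tokens[0]!r} in {block}")
            rows.append(tokens[1:])
        if block in ("FEPARAMS", "STATS"):
            if rows:
                metadata.update(
                    {f"{block}.{k}": v for k, v in zip(names, rows[0])}
                )
        elif block == "FEATURES":
            features = pd.DataFrame(rows, columns=names)
        else:
            raise FormatError(f"unknown AFE block {block!r}")
    if features is None:
        raise FormatError("no FEATURES block found")
    return features, metadata


def read_afe(path, column_map: dict[str, str] | None = None,
             array_id: str | None = None) -> FeatureTable:
    """Read one AFE export (either dialect, optionally gzipped).

    Parameters
    ----------
    path
        File to read.
    column_map
        AFE column name -> internal field name; defaults to the v9.5
        vocabulary.  Matching is case-insensitive.
    array_id
        Identifier for the array; defaults to the file stem.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    with _open_text(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.split("\t")[0] == "TYPE":
            raw, metadata = _parse_afe_blocks(fh)
        else:
            raw = pd.read_csv(fh, sep="\t", dtype=str)
            metadata = {}
    if raw.empty:
        raise FormatError("empty FEATURES block")

    lower_map = {k.lower(): v for k, v in column_map.items()}
    rename = {c: lower_map[c.lower()] for c in raw.columns if c.lower() in lower_map}
    for afe_name, internal in column_map.items():
        if internal not in rename.values():
            raise FormatError(f"missing required column {afe_name!r}")
    df = raw.rename(columns=rename)[_INTERNAL_COLUMNS].copy()
    for c, dt in _DTYPES.items():
        if dt is not str:
            df[c] = pd.to_numeric(df[c], errors="coerce")
            if df[c].isna().any():
                raise IntegrityError(f"missing or non-numeric cells in column {c!r}")
            df[c] = df[c].astype(dt)
    df = df.reset_index(drop=True)

    if array_id is None:
        stem = str(path).rsplit("/", 1)[-1]
        for suffix in (".gz", ".txt", ".tsv"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        array_id = stem
    return FeatureTable(array_id=array_id, features=df, metadata=metadata)


# ---------------------------------------------------------------------------
# design inference & assembly
# ---------------------------------------------------------------------------

def infer_design(tables: list[FeatureTable]) -> ArrayDesign:
    """Derive the probe/gene layout shared by ``tables``.

    Only experimental features count.  Replicate multiplicity is the number
    of features carrying the same probe id on one array.  All arrays must
    agree on the layout; gene order is lexicographic.
    """
    if not tables:
        raise ValueError("no tables given")
    layouts = []
    for t in tables:
        exp = t.experimental
        counts = exp.groupby(["gene_id", "probe_id"]).size().sort_index()
        layouts.append(counts)
    ref = layouts[0]
    for t, counts in zip(tables[1:], layouts[1:]):
        if not ref.index.equals(counts.index):
            sym = ref.index.symmetric_difference(counts.index)
            offending = sorted({p for _, p in sym})[:10]
        elif not (ref == counts).all():
            offending = sorted({p for _, p in ref.index[ref != counts]})[:10]
        else:
            continue
        raise DesignConflictError(
            f"array {t.array_id!r} layout differs from {tables[0].array_id!r}; "
            f"offending probes: {offending}"
        )
    gene_ids = sorted(ref.index.get_level_values(0).unique())
    probes_per_gene: dict[str, list[str]] = {g: [] for g in gene_ids}
    replicates: dict[str, int] = {}
    for (g, p), n in ref.items():
        probes_per_gene[g].append(p)
        replicates[p] = int(n)
    for g in gene_ids:
        probes_per_gene[g].sort()
    return ArrayDesign(gene_ids, probes_per_gene, replicates)


def assemble_matrix(tables: list[FeatureTable], design: ArrayDesign,
                    channel: str = "bgsub_signal") -> pd.DataFrame:
    """Assemble the feature x array matrix for ``channel``.

    Replicate features stay as separate rows; the row index is the
    MultiIndex (gene_id, probe_id, replicate) in deterministic order and the
    columns follow the input table order.  Values are copied bit-exactly.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 arrays")
    if channel not in ("bgsub_signal", "mean_signal"):
        raise ValueError(f"unknown channel {channel!r}")
    index = pd.MultiIndex.from_tuples(
        [
            (g, p, r)
            for g in design.gene_ids
            for p in design.probes_per_gene[g]
            for r in range(design.replicates_per_probe[p])
        ],
        names=["gene_id", "probe_id", "replicate"],
    )
    cols = {}
    for t in tables:
        exp = t.experimental.sort_values(
            ["gene_id", "probe_id", "row", "col"], kind="stable"
        )
        counts = exp.groupby("probe_id").size()
        for p, n in design.replicates_per_probe.items():
            if counts.get(p, 0) != n:
                raise IntegrityError(
                    f"array {t.array_id!r}: probe {p!r} has "
                    f"{counts.get(p, 0)} features, design expects {n}"
                )
        cols[t.array_id] = exp[channel].to_numpy()
    return pd.DataFrame(cols, index=index)


def assemble_bgsub_matrix(tables: list[FeatureTable],
                          design: ArrayDesign) -> pd.DataFrame:
    """Feature x array matrix of AFE background-subtracted signals."""
    return assemble_matrix(tables, design, channel="bgsub_signal")


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_matrix(m: ExpressionMatrix | ProbeMatrix, path) -> None:
    """Write a matrix as TSV: row ids in the first column, array ids as header.

    Floats keep full precision (repr round-trip), so write -> read is
    lossless.
    """
    df = m.values
    if df.empty:
        raise ValueError("refusing to write an empty matrix")
    label = "gene_id" if isinstance(m, ExpressionMatrix) else "probe_id"
    out = df.copy()
    out.index.name = label
    out.to_csv(path, sep="\t", float_format=None)


def read_matrix(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_matrix`."""
    return pd.read_csv(path, sep="\t", index_col=0)
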