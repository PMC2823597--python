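"""Synthetic AFE fixtures emulating the Human microRNA Microarray v2.0.

The emulated layout carries 799 microRNAs, each covered by 16 features:
362 microRNAs with 2 distinct oligo probes, 45 with 3, 390 with 4 and 2 with
a single probe, the 16 features split as evenly as possible across a gene's
probes (2 -> 8+8, 3 -> 6+5+5, 4 -> 4x4, 1 -> 16).  Negative and positive
controls are appended with nonzero ControlType.

The generative intensity model matches the assumptions of the
exponential+normal background model downstream.  For feature f of probe p of
gene g on array a in group G:

    true signal      X = 2^(theta[g,G] + phi[p] + eps),  eps ~ N(0, noise_sd)
    observed signal  S = X + Y,  Y ~ N(bg_mu, bg_sigma) clipped at 0
    bgsub signal     S - bg_mu   (can be negative)

theta[g,G] = log2(s_g) + delta[g,G] with per-gene baseline linear expression
s_g ~ Exp(scale = exp_rate_scale) — so the marginal of X across genes is
exponential, as the background model assumes — plus a normal group effect
delta ~ N(0, group_effect_sd).  Probe affinities phi ~ N(0,
probe_affinity_sd) are fixed across arrays, the property the median-polish
summarization exploits.

A gene is flagged detected on an array when the median of its 16 observed
feature signals exceeds ``detected_threshold``; the default threshold sits
at bg_mu + exp_rate_scale * ln(1/0.355) so that about 35% of genes are
detected, the detected fraction observed on real arrays of this design.
Everything is driven by one integer seed: identical config + seed gives
bit-identical tables.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .afe_io import ArrayDesign, FeatureTable, _INTERNAL_COLUMNS, DEFAULT_COLUMN_MAP
from .errors import MirnaPrepError

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "make_design",
    "simulate_experiment",
    "write_afe",
]

#: (n_genes, n_distinct_oligos) composition of the v2.0 emulation.
DEFAULT_DESIGN_SPEC: tuple[tuple[int, int], ...] = ((362, 2), (45, 3), (390, 4), (2, 1))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generative model; defaults emulate an 8-array study
    (2 tissue groups x 4 biological replicates) on the v2.0 layout."""

    n_arrays_per_group: int = 4
    groups: tuple[str, ...] = ("Fib", "MSC")
    design_spec: tuple[tuple[int, int], ...] = DEFAULT_DESIGN_SPEC
    features_per_gene: int = 16
    theta: pd.DataFrame | None = None  # gene x group log2 expression, or drawn
    probe_affinity_sd: float = 0.5     # log2 units
    noise_sd: float = 0.25             # log2 units
    group_effect_sd: float = 0.5       # log2 units
    bg_mu: float = 50.0                # intensity units
    bg_sigma: float = 10.0             # intensity units
    exp_rate_scale: float = 500.0      # mean of the exponential signal
    detected_threshold: float = 568.0  # on the observed (mean) signal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_arrays_per_group < 1 or not self.groups:
            raise MirnaPrepError("need at least one array in at least one group")
        for sd in (self.probe_affinity_sd, self.noise_sd, self.group_effect_sd,
                   self.bg_sigma):
            if sd < 0:
                raise MirnaPrepError("standard deviations must be non-negative")
        if self.exp_rate_scale <= 0:
            raise MirnaPrepError("exp_rate_scale must be positive")


@dataclass
class SimTruth:
    """Ground truth returned with the simulated tables for recovery tests."""

    theta: pd.DataFrame          # gene x group true log2 expression
    phi: pd.Series               # probe affinity (log2)
    groups: dict[str, str]       # array_id -> group label
    config: SimulationConfig


def make_design(spec=DEFAULT_DESIGN_SPEC, features_per_gene: int = 16
                ) -> ArrayDesign:
    """Build the probe/gene layout for a (n_genes, n_oligos) composition.

    Features are split across a gene's probes as evenly as possible, the
    remainder going to the first probes (16 over 3 oligos -> 6, 5, 5).
    """
    gene_ids: list[str] = []
    probes_per_gene: dict[str, list[str]] = {}
    replicates: dict[str, int] = {}
    idx = 0
    for n_genes, n_oligos in spec:
        if n_genes < 1 or n_oligos < 1:
            raise MirnaPrepError("design_spec entries must be positive")
        if features_per_gene < n_oligos:
            raise MirnaPrepError(
                f"features_per_gene={features_per_gene} < n_oligos={n_oligos}"
            )
        base, extra = divmod(features_per_gene, n_oligos)
        for _ in range(n_genes):
            idx += 1
            g = f"mir-{idx:04d}"
            probes = [f"{g}_p{j + 1}" for j in range(n_oligos)]
            gene_ids.append(g)
            probes_per_gene[g] = probes
            for j, p in enumerate(probes):
                replicates[p] = base + (1 if j < extra else 0)
    return ArrayDesign(sorted(gene_ids), probes_per_gene, replicates)


def _feature_skeleton(design: ArrayDesign) -> pd.DataFrame:
    rows = []
    for g in design.gene_ids:
        for p in design.probes_per_gene[g]:
            for _ in range(design.replicates_per_probe[p]):
                rows.append((g, p))
    return pd.DataFrame(rows, columns=["gene_id", "probe_id"])


def simulate_experiment(cfg: SimulationConfig | None = None
                        ) -> tuple[list[FeatureTable], SimTruth]:
    """Draw one full multi-array experiment from the generative model."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    design = make_design(cfg.design_spec, cfg.features_per_gene)
    genes = design.gene_ids
    probes = sorted(design.replicates_per_probe)

    if cfg.theta is not None:
        theta = cfg.theta.loc[genes, list(cfg.groups)]
    else:
        s = rng.exponential(cfg.exp_rate_scale, len(genes))
        delta = rng.normal(0.0, cfg.group_effect_sd, (len(genes), len(cfg.groups)))
        theta = pd.DataFrame(
            np.log2(s)[:, None] + delta, index=genes, columns=list(cfg.groups)
        )
    phi = pd.Series(rng.normal(0.0, cfg.probe_affinity_sd, len(probes)),
                    index=probes)

    skel = _feature_skeleton(design)
    n_exp = len(skel)
    theta_feat = {G: theta[G].loc[skel["gene_id"]].to_numpy() for G in cfg.groups}
    phi_feat = phi.loc[skel["probe_id"]].to_numpy()
    gene_codes = pd.Categorical(skel["gene_id"], categories=genes).codes

    # controls: 20 negative probes x 8 replicates at pure background, and
    # 4 positive targets x 4 probes x 5 replicates, bright or dim per array
    neg = pd.DataFrame(
        [(f"NC_neg{k + 1:02d}", f"NC_neg{k + 1:02d}_p1") for k in range(20)
         for _ in range(8)],
        columns=["gene_id", "probe_id"],
    )
    pos = pd.DataFrame(
        [(f"PC_t{t + 1}", f"PC_t{t + 1}_p{j + 1}") for t in range(4)
         for j in range(4) for _ in range(5)],
        columns=["gene_id", "probe_id"],
    )

    tables: list[FeatureTable] = []
    groups_map: dict[str, str] = {}
    for G in cfg.groups:
        for r in range(cfg.n_arrays_per_group):
            array_id = f"{G}_rep{r + 1}"
            groups_map[array_id] = G
            eps = rng.normal(0.0, cfg.noise_sd, n_exp)
            x = 2.0 ** (theta_feat[G] + phi_feat + eps)
            y = np.clip(rng.normal(cfg.bg_mu, cfg.bg_sigma, n_exp), 0.0, None)
            mean_signal = x + y
            bgsub = mean_signal - cfg.bg_mu

            med = pd.Series(mean_signal).groupby(gene_codes).median()
            detected = (med > cfg.detected_threshold).astype(int)
            flag = detected.to_numpy()[gene_codes]

            df = skel.copy()
            df["mean_signal"] = mean_signal
            df["bgsub_signal"] = bgsub
            df["control_type"] = 0
            df["is_gene_detected"] = flag

            y_neg = np.clip(rng.normal(cfg.bg_mu, cfg.bg_sigma, len(neg)), 0.0, None)
            dneg = neg.copy()
            dneg["mean_signal"] = y_neg
            dneg["bgsub_signal"] = y_neg - cfg.bg_mu
            dneg["control_type"] = -1
            dneg["is_gene_detected"] = 0

            bright = rng.uniform(6.0, 13.0, 4)  # per-target log2 level, per array
            lvl = np.repeat(bright, 20)
            eps_pos = rng.normal(0.0, cfg.noise_sd, len(pos))
            y_pos = np.clip(rng.normal(cfg.bg_mu, cfg.bg_sigma, len(pos)), 0.0, None)
            xp = 2.0 ** (lvl + eps_pos)
            dpos = pos.copy()
            dpos["mean_signal"] = xp + y_pos
            dpos["bgsub_signal"] = xp + y_pos - cfg.bg_mu
            dpos["control_type"] = 1
            dpos["is_gene_detected"] = 1

            full = pd.concat([df, dneg, dpos], ignore_index=True)
            n = len(full)
            ncol = 164
            full["row"] = np.arange(n) // ncol + 1
            full["col"] = np.arange(n) % ncol + 1
            tables.append(
                FeatureTable(
                    array_id=array_id,
                    features=full[_INTERNAL_COLUMNS].copy(),
                    metadata={"FEPARAMS.Protocol": "synthetic-v2.0-emulation",
                              "FEPARAMS.Seed": str(cfg.seed)},
                )
            )
    return tables, SimTruth(theta=theta, phi=phi, groups=groups_map, config=cfg)


# ---------------------------------------------------------------------------
# writing AFE fixtures
# ---------------------------------------------------------------------------

_AFE_NAME = {v: k for k, v in DEFAULT_COLUMN_MAP.items()}
_TYPE_CODE = {
    "probe_id": "text", "gene_id": "text", "mean_signal": "float",
    "bgsub_signal": "float", "control_type": "integer",
    "is_gene_detected": "integer", "row": "integer", "col": "integer",
}


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_afe(table: FeatureTable, path, dialect: str = "afe") -> None:
    """Write a FeatureTable as an AFE export (either dialect, .gz aware).

    ``dialect="afe"`` writes the 3-block TYPE/FEPARAMS/STATS/FEATURES form;
    ``dialect="tsv"`` a plain single-header TSV.  Floats are written with
    ``repr`` so read-back is bit-exact.
    """
    if dialect not in ("afe", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = _INTERNAL_COLUMNS
    afe_names = [_AFE_NAME[c] for c in cols]
    lines: list[str] = []
    if dialect == "tsv":
        lines.append("\t".join(afe_names))
        for rec in table.features.itertuples(index=False):
            lines.append("\t".join(_fmt(v) for v in rec))
    else:
        meta = table.metadata or {"FEPARAMS.Protocol": "unknown"}
        fe_keys = [k.split(".", 1)[1] for k in meta if k.startswith("FEPARAMS.")]
        fe_vals = [meta[f"FEPARAMS.{k}"] for k in fe_keys]
        if not fe_keys:
            fe_keys, fe_vals = ["Protocol"], ["unknown"]
        lines.append("\t".join(["TYPE"] + ["text"] * len(fe_keys)))
        lines.append("\t".join(["FEPARAMS"] + fe_keys))
        lines.append("\t".join(["DATA"] + [str(v) for v in fe_vals]))
        lines.append("*")
        lines.append("TYPE\tinteger")
        lines.append("STATS\tTotalNumFeatures")
        lines.append(f"DATA\t{len(table.features)}")
        lines.append("*")
        lines.append("\t".join(["TYPE"] + [_TYPE_CODE[c] for c in cols]))
        lines.append("\t".join(["FEATURES"] + afe_names))
        for rec in table.features.itertuples(index=False):
            lines.append("DATA\t" + "\t".join(_fmt(v) for v in rec))
        lines.append("*")
    text = "\n".join(lines) + "\n"
    path = str(path)
    if path.endswith(".gz"):
        with gzip.open(path, "wt", encoding="utf-8") as fh:
            fh.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
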