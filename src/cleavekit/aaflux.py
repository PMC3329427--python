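"""Amino-acid turnover from spent-media concentrations.

Embryos are cultured in small drops; comparing each spent drop against a
matched embryo-free control drop (incubated alongside, to absorb
non-specific degradation/appearance) yields per-embryo, per-hour depletion
or appearance rates:

    rate_i = (C_control,i - C_sample,i) [umol/L] * drop_volume [uL]
             / (n_embryos * hours)     ->  pmol . embryo^-1 . h^-1

with positive = depletion (consumption) and negative = appearance (release
into the medium).  *Turnover* of a profile is the sum of absolute rates.

The detectable panel is 18 amino acids (the 20 proteinogenic ones minus
proline and cysteine, which the o-phthaldialdehyde HPLC chemistry misses).

Clustering follows the analysis convention of the field: amino acids are
clustered with distance 1 - Spearman rho and complete linkage; embryo-group
stage columns with Euclidean distance and Ward linkage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .errors import ArgumentError, FormatError, ValidationError
from .stats import StatResult, pearson_r2

logger = logging.getLogger(__name__)

STAGE_WINDOWS = ("0-24", "24-48", "48-72", "72-96")

#: 20 proteinogenic amino acids minus proline and cysteine
AMINO_ACIDS = (
    "alanine", "arginine", "asparagine", "aspartate", "glutamate",
    "glutamine", "glycine", "histidine", "isoleucine", "leucine",
    "lysine", "methionine", "phenylalanine", "serine", "threonine",
    "tryptophan", "tyrosine", "valine",
)

MEDIA_COLUMNS = (
    "sample_id", "control_id", "group", "stage_window", "n_embryos",
    "hours", "drop_volume_ul", "amino_acid", "conc_umol_l",
)


@dataclass
class SpentMediumSample:
    """One spent culture drop (or embryo-free control drop)."""

    sample_id: str
    group: str
    stage_window: str
    n_embryos: int
    hours: float
    drop_volume: float
    concentrations: dict[str, float]
    control_id: str | None = None

    @property
    def is_control(self) -> bool:
        return self.n_embryos == 0

    def validate(self) -> None:
        if self.stage_window not in STAGE_WINDOWS:
            raise ValidationError(
                f"sample {self.sample_id}: unknown stage window "
                f"{self.stage_window!r}"
            )
        if self.n_embryos < 0:
            raise ValidationError(f"sample {self.sample_id}: negative n_embryos")
        if not self.hours > 0:
            raise ValidationError(f"sample {self.sample_id}: hours must be > 0")
        if not self.drop_volume > 0:
            raise ValidationError(f"sample {self.sample_id}: drop_volume must be > 0")
        for aa, conc in self.concentrations.items():
            if conc < 0:
                raise ValidationError(
                    f"sample {self.sample_id}: negative concentration for {aa}"
                )
            if aa not in AMINO_ACIDS:
                logger.warning(
                    "sample %s: amino acid %r outside the standard 18-name "
                    "panel (passed through)", self.sample_id, aa,
                )


def read_media_csv(path) -> list[SpentMediumSample]:
    """Read the long-format spent-media CSV into sample objects."""
    table = pd.read_csv(path, comment="#")
    missing = [c for c in MEDIA_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    samples: dict[str, SpentMediumSample] = {}
    for _, row in table.iterrows():
        sid = str(row["sample_id"])
        if sid not in samples:
            control = row["control_id"]
            samples[sid] = SpentMediumSample(
                sample_id=sid,
                group=str(row["group"]),
                stage_window=str(row["stage_window"]),
                n_embryos=int(row["n_embryos"]),
                hours=float(row["hours"]),
                drop_volume=float(row["drop_volume_ul"]),
                concentrations={},
                control_id=None if pd.isna(control) or control == "" else str(control),
            )
        samples[sid].concentrations[str(row["amino_acid"])] = float(row["conc_umol_l"])
    out = list(samples.values())
    for s in out:
        s.validate()
    return out


def compute_turnover(
    sample: SpentMediumSample, control: SpentMediumSample, dilution: float = 1.0
) -> dict[str, float]:
    """Per-amino-acid depletion(+)/appearance(-) rate, pmol/embryo/h.

    ``dilution`` rescales raw assay readings back to in-drop concentrations
    (e.g. 12.5 for a 1:12.5 pre-assay dilution); default assumes inputs are
    already corrected.
    """
    if sample.n_embryos == 0:
        raise ArgumentError(
            f"sample {sample.sample_id} has n_embryos = 0 (is it a control?)"
        )
    if control.stage_window != sample.stage_window:
        raise ArgumentError(
            f"control {control.sample_id} stage window {control.stage_window} "
            f"does not match sample {sample.sample_id} "
            f"({sample.stage_window})"
        )
    rates = {}
    for aa, c_sample in sample.concentrations.items():
        if aa not in control.concentrations:
            raise ArgumentError(
                f"amino acid {aa!r} missing from control {control.sample_id}"
            )
        delta = (control.concentrations[aa] - c_sample) * dilution  # umol/L
        # umol/L * uL = pmol
        rates[aa] = delta * sample.drop_volume / (sample.n_embryos * sample.hours)
    return rates


def total_turnover(rates: dict[str, float]) -> float:
    """Sum of absolute depletion/appearance rates."""
    if not rates:
        raise ArgumentError("total_turnover: empty rate mapping")
    return float(sum(abs(v) for v in rates.values()))


@dataclass
class TurnoverMatrix:
    """Amino acids x (group, stage-window) turnover rates with SEM and n.

    Sign convention: positive = depletion (consumption), negative =
    appearance (release).
    """

    values: pd.DataFrame
    sem: pd.DataFrame
    n: pd.DataFrame
    metadata: dict = field(
        default_factory=lambda: {"units": "pmol/embryo/h", "positive": "depletion"}
    )

    def column(self, group: str, stage_window: str) -> pd.Series:
        return self.values[(group, stage_window)]


def build_matrix(
    samples: list[SpentMediumSample],
    controls: list[SpentMediumSample] | None = None,
    dilution: float = 1.0,
) -> TurnoverMatrix:
    """Replicate-averaged turnover matrix with per-cell SEM and n.

    Controls may be passed separately or mixed into ``samples`` (they are
    recognized by n_embryos = 0); each sample's ``control_id`` selects its
    matched control drop.
    """
    if controls is None:
        controls = [s for s in samples if s.is_control]
        samples = [s for s in samples if not s.is_control]
    by_id = {c.sample_id: c for c in controls}
    per_cell: dict[tuple[str, str], dict[str, list[float]]] = {}
    for sample in samples:
        if sample.control_id is None or sample.control_id not in by_id:
            raise ArgumentError(
                f"sample {sample.sample_id}: unmatched control "
                f"{sample.control_id!r}"
            )
        rates = compute_turnover(sample, by_id[sample.control_id], dilution=dilution)
        cell = per_cell.setdefault((sample.group, sample.stage_window), {})
        for aa, rate in rates.items():
            cell.setdefault(aa, []).append(rate)
    if not per_cell:
        raise ArgumentError("no embryo samples to build a matrix from")

    groups = sorted({g for g, _ in per_cell})
    columns = [
        (g, w) for g in groups for w in STAGE_WINDOWS if (g, w) in per_cell
    ]
    for g in groups:
        absent = [w for w in STAGE_WINDOWS if (g, w) not in per_cell]
        if absent:
            logger.warning("group %s: no replicates for stage window(s) %s",
                           g, ", ".join(absent))
    aas = sorted({aa for cell in per_cell.values() for aa in cell},
                 key=lambda a: (AMINO_ACIDS.index(a) if a in AMINO_ACIDS else 99, a))
    idx = pd.MultiIndex.from_tuples(columns, names=["group", "stage_window"])
    values = pd.DataFrame(index=list(aas), columns=idx, dtype=float)
    sem = values.copy()
    counts = pd.DataFrame(0, index=list(aas), columns=idx, dtype=int)
    for (g, w), cell in per_cell.items():
        for aa, reps in cell.items():
            arr = np.asarray(reps, dtype=float)
            values.loc[aa, (g, w)] = arr.mean()
            sem.loc[aa, (g, w)] = (
                arr.std(ddof=1) / math.sqrt(arr.size) if arr.size > 1 else 0.0
            )
            counts.loc[aa, (g, w)] = arr.size
    values.index.name = "amino_acid"
    return TurnoverMatrix(values, sem, counts)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    """Hierarchical clustering of a turnover matrix."""

    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[tuple[str, str]]
    ordered: pd.DataFrame

    def row_newick(self) -> str:
        return linkage_to_newick(self.row_linkage, self.row_order_input)

    def col_newick(self) -> str:
        return linkage_to_newick(
            self.col_linkage, ["|".join(c) for c in self.col_order_input]
        )

    row_order_input: list[str] = field(default_factory=list)
    col_order_input: list[str] = field(default_factory=list)


def cluster_turnover(matrix: TurnoverMatrix, ward_criterion: str = "ward") -> ClusterResult:
    """Cluster amino acids (1 - Spearman, complete) and columns (Euclidean,
    Ward) and return linkages plus the leaf-ordered heatmap table.

    A constant row has undefined Spearman correlation; its distance to every
    other row is set to the maximum (2) with a warning.
    """
    values = matrix.values
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ArgumentError("cluster_turnover needs >= 2 rows and >= 2 columns")
    data = values.to_numpy(dtype=float)

    # Spearman rho = Pearson correlation of row ranks; computed directly so
    # constant rows degrade to NaN entries instead of collapsing the matrix
    ranks = np.apply_along_axis(rankdata, 1, data)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    constant = np.ptp(data, axis=1) == 0
    if constant.any():
        logger.warning(
            "constant turnover row(s) %s: Spearman undefined, distance set "
            "to the maximum (2)",
            ", ".join(values.index[constant]),
        )
    dist = 1.0 - rho
    dist[constant, :] = 2.0
    dist[:, constant] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    row_linkage = hierarchy.linkage(squareform(dist, checks=False), method="complete")

    col_dist = pdist(data.T, metric="euclidean")
    col_linkage = hierarchy.linkage(col_dist, method=ward_criterion)

    row_leaves = hierarchy.leaves_list(row_linkage)
    col_leaves = hierarchy.leaves_list(col_linkage)
    row_order = [values.index[i] for i in row_leaves]
    col_order = [values.columns[i] for i in col_leaves]
    ordered = values.iloc[row_leaves, col_leaves]
    return ClusterResult(
        row_linkage, col_linkage, row_order, col_order, ordered,
        row_order_input=list(values.index),
        col_order_input=["|".join(c) for c in values.columns],
    )


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def profile_correlation(
    matrix: TurnoverMatrix,
    column_a: tuple[str, str],
    column_b: tuple[str, str],
) -> StatResult:
    """Pearson r^2 between two (group, stage) turnover profiles."""
    a = matrix.column(*column_a)
    b = matrix.column(*column_b)
    shared = a.index.intersection(b.index)
    pairs = np.column_stack([a.loc[shared], b.loc[shared]])
    pairs = pairs[~np.isnan(pairs).any(axis=1)]
    if pairs.shape[0] < 3:
        raise ArgumentError("profile_correlation needs >= 3 shared amino acids")
    return pearson_r2(pairs)
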