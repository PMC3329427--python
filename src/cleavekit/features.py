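"""Timing-feature extraction from lineage trees.

Per embryo the variable set is:

* ``div1, div2.1, div2.2, div3.1, div3.4, div4.1, div4.8`` — times (hpa) the
  embryo reaches the 2-, 3-, 4-, 5-, 8-, 9- and 16-cell stages, i.e. pooled
  order statistics of the division-completion times of the whole tree
  (cleavage rounds may overlap in poorly synchronized embryos);
* ``cc1..cc4`` — per-embryo average cycle length (h) of the cells of rounds
  1-4, defined only when every cell of that round divided (a partial average
  over the faster cells would bias slow embryos, see ``partial`` flag);
* ``diff2, diff3, diff4`` — inter-stage durations: the time spent at 3 cells,
  at 5-7 cells, at 9-15 cells (a synchrony measure of sister divisions);
* ``stage2_len..stage4_len`` — entire cleavage-stage lengths, last exit to
  last exit (``stagek_len = divk_last - div(k-1)_last``);
* ``ck1`` — duration of the first cytokinesis.

Features whose defining events were not observed are missing (None/NaN),
never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ArgumentError
from .lineage import EmbryoRecord, LineageTree, build_lineage

#: feature names as used in output tables (columns of the features CSV)
FEATURE_NAMES = (
    "div1",
    "div2.1",
    "div2.2",
    "div3.1",
    "div3.4",
    "div4.1",
    "div4.8",
    "cc1",
    "cc2",
    "cc3",
    "cc4",
    "diff2",
    "diff3",
    "diff4",
    "stage2_len",
    "stage3_len",
    "stage4_len",
    "ck1",
)

_ATTR_FOR_NAME = {name: name.replace(".", "_") for name in FEATURE_NAMES}


@dataclass
class KineticsFeatures:
    """Per-embryo cleavage-timing variables (hpa for div*, hours otherwise)."""

    div1: float | None = None
    div2_1: float | None = None
    div2_2: float | None = None
    div3_1: float | None = None
    div3_4: float | None = None
    div4_1: float | None = None
    div4_8: float | None = None
    cc1: float | None = None
    cc2: float | None = None
    cc3: float | None = None
    cc4: float | None = None
    diff2: float | None = None
    diff3: float | None = None
    diff4: float | None = None
    stage2_len: float | None = None
    stage3_len: float | None = None
    stage4_len: float | None = None
    ck1: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        """Mapping keyed by the public (dotted) feature names."""
        return {name: getattr(self, _ATTR_FOR_NAME[name]) for name in FEATURE_NAMES}


@dataclass
class SpeedClass:
    """Speed classification at the three-cell transition."""

    label: str | None  # fast / intermediate / slow, or None when unscorable
    basis_feature: str = "div2.1"
    cutoffs: tuple[float, float] = (35.0, 41.0)


def compute_features(tree: LineageTree, partial: bool = False) -> KineticsFeatures:
    """Extract the timing variables of one embryo.

    With ``partial=True``, cc_k is averaged over the cells of round k that
    divided even when some did not (off by default; biased for slow embryos).
    """
    feats = KineticsFeatures()
    all_times: list[float] = []
    for k in (1, 2, 3, 4):
        cells = tree.cells_of_round(k)
        all_times.extend(
            c.end_time for c in cells if c.fate == "divided" and c.end_time is not None
        )
        lengths = [c.cycle_length for c in cells if c.cycle_length is not None]
        complete = len(cells) == 2 ** (k - 1) and len(lengths) == len(cells)
        if lengths and (complete or partial):
            setattr(feats, f"cc{k}", sum(lengths) / len(lengths))

    # time the embryo reaches c cells = (c-1)-th smallest division time over
    # the whole tree (cleavage rounds may overlap; any unobserved division
    # lies beyond the horizon, so observed order statistics stay valid)
    all_times.sort()

    def reach(n_cells: int) -> float | None:
        j = n_cells - 1
        return all_times[j - 1] if len(all_times) >= j else None

    feats.div1 = reach(2)
    feats.div2_1 = reach(3)
    feats.div2_2 = reach(4)
    feats.div3_1 = reach(5)
    feats.div3_4 = reach(8)
    feats.div4_1 = reach(9)
    feats.div4_8 = reach(16)

    if feats.div2_1 is not None and feats.div2_2 is not None:
        feats.diff2 = feats.div2_2 - feats.div2_1
    if feats.div3_1 is not None and feats.div3_4 is not None:
        feats.diff3 = feats.div3_4 - feats.div3_1
    if feats.div4_1 is not None and feats.div4_8 is not None:
        feats.diff4 = feats.div4_8 - feats.div4_1

    if feats.div1 is not None and feats.div2_2 is not None:
        feats.stage2_len = feats.div2_2 - feats.div1
    if feats.div2_2 is not None and feats.div3_4 is not None:
        feats.stage3_len = feats.div3_4 - feats.div2_2
    if feats.div3_4 is not None and feats.div4_8 is not None:
        feats.stage4_len = feats.div4_8 - feats.div3_4

    root = tree.root
    if feats.div1 is not None and root.cytokinesis_onset is not None:
        feats.ck1 = feats.div1 - root.cytokinesis_onset
    return feats


def classify_speed(
    features: KineticsFeatures,
    cutoffs: tuple[float, float] = (35.0, 41.0),
    mode: str = "two_group",
) -> SpeedClass:
    """Classify an embryo fast/intermediate/slow by its three-cell time.

    ``three_group``: div2.1 < low -> fast; low <= div2.1 <= high ->
    intermediate; > high -> slow.  ``two_group``: a single cutoff at the
    midpoint of ``cutoffs`` (<= midpoint -> fast).
    """
    low, high = cutoffs
    if not low <= high:
        raise ArgumentError(f"cutoffs must be ordered, got {cutoffs}")
    if mode not in ("two_group", "three_group"):
        raise ArgumentError(f"unknown mode {mode!r}")
    value = features.div2_1
    if value is None:
        return SpeedClass(label=None, cutoffs=cutoffs)
    if mode == "three_group":
        if value < low:
            label = "fast"
        elif value <= high:
            label = "intermediate"
        else:
            label = "slow"
    else:
        midpoint = (low + high) / 2.0
        label = "fast" if value <= midpoint else "slow"
    return SpeedClass(label=label, cutoffs=cutoffs)


def features_frame(
    embryos: list[EmbryoRecord],
    horizon: float | None = None,
    partial: bool = False,
) -> pd.DataFrame:
    """One-row-per-embryo feature table with group/outcome annotations.

    Columns use the public dotted feature names; index is embryo_id.
    """
    rows = {}
    meta = {}
    for embryo in embryos:
        tree = build_lineage(embryo) if horizon is None else build_lineage(embryo, horizon)
        rows[embryo.embryo_id] = compute_features(tree, partial=partial).as_dict()
        meta[embryo.embryo_id] = {
            "group": embryo.group,
            "treatment": embryo.treatment,
            "blastocyst": embryo.outcome_blastocyst,
            "esc": embryo.outcome_esc,
            "fetus": embryo.outcome_fetus,
        }
    feats = pd.DataFrame.from_dict(rows, orient="index").astype(float)
    info = pd.DataFrame.from_dict(meta, orient="index")
    out = pd.concat([info, feats], axis=1)
    out.index.name = "embryo_id"
    return out
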