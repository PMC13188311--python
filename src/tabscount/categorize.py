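"""Comparison of TABS categorization with continuous similarity metrics.

Every unordered pair of conformers of an ensemble gets two labels:

* the **condition** (ground truth axis): the pair's TABS labels are equal
  ("same") or not ("different");
* the **prediction**: a continuous metric thresholded — a similarity
  metric (e.g. shape Tanimoto, higher = more similar) calls the pair
  "same" when ``value >= threshold``, a distance metric (e.g. heavy-atom
  RMSD in Å) when ``value <= threshold``.

From the resulting confusion matrix the positive and negative predictive
values are

    PPV = TP / (TP + FP),    NPV = TN / (TN + FN),

and both equal 1 exactly when the two categorizations agree completely.
Sweeping the threshold over a grid and maximizing an agreement criterion
(by default min(PPV, NPV)) yields the metric threshold that best
reproduces the threshold-free TABS grouping.

Metrics are pluggable: scores come from a CSV table, from a caller
adapter, or from the built-in symmetry-aware heavy-atom RMSD / shape
Tanimoto adapters (both delegating to RDKit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "PairScore",
    "Direction",
    "UndefinedValueError",
    "ppv_npv",
    "confusion_at_threshold",
    "sweep_thresholds",
    "optimal_threshold",
    "flexibility_category",
    "FLEXIBILITY_LOW_BOUND",
    "FLEXIBILITY_HIGH_BOUND",
    "read_pair_scores",
    "write_pair_scores",
    "rmsd_pair_scores",
    "shape_tanimoto_pair_scores",
]

Direction = Literal["similarity", "distance"]

#: nTABS boundaries of the flexibility categories
FLEXIBILITY_LOW_BOUND = 500
FLEXIBILITY_HIGH_BOUND = 10_000


class UndefinedValueError(ValueError):
    """Requested quantity is undefined (zero denominator / empty sweep)."""


class PairScore(NamedTuple):
    """Metric value for one unordered conformer pair (i < j by convention)."""

    conf_i: str
    conf_j: str
    value: float


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def ppv_npv(counts: ConfusionCounts) -> tuple[float | None, float | None]:
    """(PPV, NPV); a value with zero denominator is returned as None.

    Undefined values are reported as missing, never coerced to 0 or 1:
    a threshold that predicts no negatives says nothing about NPV.
    """
    ppv = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    npv = counts.tn / (counts.tn + counts.fn) if counts.tn + counts.fn else None
    return ppv, npv


def _predicts_same(value: float, threshold: float, direction: Direction) -> bool:
    if direction == "similarity":
        return value >= threshold
    if direction == "distance":
        return value <= threshold
    raise ValueError(f"unknown metric direction {direction!r}")


def confusion_at_threshold(
    pairs: Sequence[PairScore],
    tabs_labels: Mapping[str, str],
    threshold: float,
    direction: Direction = "similarity",
) -> ConfusionCounts:
    """Tally conformer pairs against TABS equality at one metric threshold."""
    tp = fp = tn = fn = 0
    for pair in pairs:
        try:
            truth_same = tabs_labels[pair.conf_i] == tabs_labels[pair.conf_j]
        except KeyError as exc:
            raise KeyError(f"conformer {exc.args[0]!r} has no TABS label") from exc
        pred_same = _predicts_same(pair.value, threshold, direction)
        if truth_same and pred_same:
            tp += 1
        elif truth_same:
            fn += 1
        elif pred_same:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def sweep_thresholds(
    pairs: Sequence[PairScore],
    tabs_labels: Mapping[str, str],
    grid: Sequence[float] | None = None,
    direction: Direction = "similarity",
) -> pd.DataFrame:
    """PPV/NPV as a function of the metric threshold.

    *grid* defaults to 101 evenly spaced points spanning the observed
    metric range.  Undefined PPV/NPV appear as NaN.  Columns:
    threshold, ppv, npv, tp, fp, tn, fn.
    """
    if grid is None:
        if not pairs:
            raise ValueError("cannot infer a threshold grid from zero pairs")
        values = [p.value for p in pairs]
        grid = list(np.linspace(min(values), max(values), 101))
    rows = []
    for threshold in grid:
        counts = confusion_at_threshold(pairs, tabs_labels, threshold, direction)
        ppv, npv = ppv_npv(counts)
        rows.append(
            {
                "threshold": float(threshold),
                "ppv": math.nan if ppv is None else ppv,
                "npv": math.nan if npv is None else npv,
                "tp": counts.tp,
                "fp": counts.fp,
                "tn": counts.tn,
                "fn": counts.fn,
            }
        )
    return pd.DataFrame(rows)


def optimal_threshold(
    sweep: pd.DataFrame,
    direction: Direction = "similarity",
    criterion: Literal["min", "product", "fixed-npv"] = "min",
    npv_floor: float = 0.8,
) -> float:
    """Threshold that best reconciles the metric with the TABS grouping.

    ``min`` maximizes min(PPV, NPV) (the symmetric scalar choice),
    ``product`` maximizes PPV·NPV, ``fixed-npv`` maximizes PPV among
    rows with NPV >= *npv_floor*.  Rows with an undefined value are
    ignored.  Ties break toward the stricter "same" call: the larger
    threshold for a similarity metric, the smaller for a distance.
    """
    defined = sweep.dropna(subset=["ppv", "npv"])
    if criterion == "fixed-npv":
        defined = defined[defined["npv"] >= npv_floor]
    if defined.empty:
        raise UndefinedValueError("no sweep row with both PPV and NPV defined")
    if criterion == "min":
        score = np.minimum(defined["ppv"], defined["npv"])
    elif criterion == "product":
        score = defined["ppv"] * defined["npv"]
    elif criterion == "fixed-npv":
        score = defined["ppv"]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    best = defined.loc[score == score.max(), "threshold"]
    return float(best.max() if direction == "similarity" else best.min())


def flexibility_category(ntabs_value: int) -> str:
    """Flexibility class of a molecule from its nTABS.

    low: nTABS < 500; medium: 500 <= nTABS < 10,000; high: >= 10,000.
    """
    if ntabs_value < 1:
        raise ValueError(f"nTABS must be >= 1, got {ntabs_value}")
    if ntabs_value < FLEXIBILITY_LOW_BOUND:
        return "low"
    if ntabs_value < FLEXIBILITY_HIGH_BOUND:
        return "medium"
    return "high"


# ---------------------------------------------------------------------------
# score tables and metric adapters

def read_pair_scores(path: str | Path) -> list[PairScore]:
    """Read a pair-score table (CSV columns conf_i, conf_j, value)."""
    df = pd.read_csv(path, dtype={"conf_i": str, "conf_j": str})
    missing = {"conf_i", "conf_j", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"score CSV lacks columns: {sorted(missing)}")
    return [
        PairScore(row.conf_i, row.conf_j, float(row.value))
        for row in df.itertuples()
    ]


def write_pair_scores(pairs: Sequence[PairScore], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["conf_i", "conf_j", "value"]).to_csv(
        path, index=False
    )


def _conformer_pairs(mol) -> list[tuple[int, int]]:
    ids = [conf.GetId() for conf in mol.GetConformers()]
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]


def rmsd_pair_scores(mol) -> list[PairScore]:
    """Symmetry-aware heavy-atom RMSD (Å) for every conformer pair.

    Superposition is minimized over all automorphism-induced atom
    mappings (RDKit ``GetBestRMS``), consistent with TABS's own symmetry
    handling — a symmetry-naive RMSD would call symmetry-related
    conformers different while TABS calls them the same.  This is a
    distance metric.
    """
    from rdkit import Chem
    from rdkit.Chem import rdMolAlign

    heavy = Chem.RemoveHs(Chem.Mol(mol))
    return [
        PairScore(
            str(i),
            str(j),
            float(rdMolAlign.GetBestRMS(heavy, heavy, prbId=i, refId=j)),
        )
        for i, j in _conformer_pairs(heavy)
    ]


def shape_tanimoto_pair_scores(
    mol, use_colors: bool = True, opt_param: float = 0.5
) -> list[PairScore]:
    """Shape Tanimoto similarity for every conformer pair.

    Thin adapter over the PubChem shape-alignment code integrated in
    RDKit; with *use_colors* the alignment incorporates atom features,
    tying the shape overlap to the molecule's topology.  This is a
    similarity metric in [0, 1].  Mutates a copy, not the input.
    """
    from rdkit import Chem
    from rdkit.Chem import rdShapeAlign

    work = Chem.Mol(mol)
    out = []
    for i, j in _conformer_pairs(work):
        probe = Chem.Mol(work)  # AlignMol moves the probe conformer in place
        shape_sim, _color_sim = rdShapeAlign.AlignMol(
            work,
            probe,
            refConfId=j,
            probeConfId=i,
            useColors=use_colors,
            opt_param=opt_param,
        )
        out.append(PairScore(str(i), str(j), float(shape_sim)))
    return out


def pair_scores_from_adapter(
    mol, adapter: Callable[[object], Sequence[PairScore]]
) -> list[PairScore]:
    """Run a pluggable metric adapter (callable Mol -> PairScores)."""
    return list(adapter(mol))
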