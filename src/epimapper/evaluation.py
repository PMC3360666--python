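"""Confusion-matrix evaluation of predictions against an annotated epitope.

All counting happens on the surface-residue universe of the designated
chain: the annotated epitope residues are the positives and every other
surface residue is a negative.  PE denotes the number of predicted epitopic
residues (TP + FP); sensitivity, specificity and precision are

    Se = TP / (TP + FN),   Sp = TN / (TN + FP),   Pr = TP / PE,

with Pr defined as 0 when nothing is predicted.  The module also ships the
published reference benchmark of the two engines and their combination on 27
antibody–antigen complexes, used for table-level arithmetic checks and
aggregation (unweighted column means).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .candidate_assembly import PredictionSet


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def pe(self) -> int:
        return self.tp + self.fp

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")


@dataclass(frozen=True)
class Metrics:
    se: float
    sp: float
    pr: float

    def rounded(self, ndigits: int = 3) -> "Metrics":
        return Metrics(round(self.se, ndigits), round(self.sp, ndigits), round(self.pr, ndigits))


def confusion(
    predicted: PredictionSet, truth: PredictionSet, universe
) -> ConfusionCounts:
    """Four-way counts of predicted vs annotated residues over ``universe``.

    ``universe`` is an iterable of residue keys (normally the surface
    residues of the chain).  Both sets must be contained in it.
    """
    uni = frozenset(universe)
    for name, s in (("prediction", predicted), ("truth", truth)):
        extra = s.residues - uni
        if extra:
            raise EvaluationError(
                f"{name} contains residues outside the universe: "
                + ", ".join(f"{c}:{n}{i}" for c, n, i in sorted(extra))
            )
    pred, pos = predicted.residues, truth.residues
    tp = len(pred & pos)
    fp = len(pred - pos)
    fn = len(pos - pred)
    tn = len(uni) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity and precision from confusion counts."""
    if c.tp + c.fn == 0:
        raise EvaluationError("sensitivity undefined: empty true epitope")
    se = c.tp / (c.tp + c.fn)
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else 1.0
    pr = c.tp / c.pe if c.pe > 0 else 0.0
    return Metrics(se=se, sp=sp, pr=pr)


def aggregate(rows: list[Metrics]) -> Metrics:
    """Unweighted per-column arithmetic mean over benchmark rows."""
    if not rows:
        raise EvaluationError("cannot aggregate an empty list of metrics")
    n = len(rows)
    return Metrics(
        se=sum(r.se for r in rows) / n,
        sp=sum(r.sp for r in rows) / n,
        pr=sum(r.pr for r in rows) / n,
    )


def load_benchmark(which: str = "engines") -> pd.DataFrame:
    """Reference benchmark tables (27 antibody–antigen cases).

    ``which="engines"`` holds the per-case TP/PE/Se/Sp/Pr of the two engines
    run separately; ``which="ensemble"`` the Intersection/Union sizes,
    Consistency, and the combined operations' TP/PE/Se/Sp/Pr.
    """
    fname = {"engines": "engines_benchmark.tsv", "ensemble": "ensemble_benchmark.tsv"}[which]
    with resources.files("epimapper.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t")


def write_metrics_table(rows: list[tuple[str, ConfusionCounts, Metrics]], path) -> None:
    """TSV with the benchmark column layout: case, TP/PE, Se, Sp, Pr."""
    with open(path, "w") as fh:
        fh.write("case\tTP/PE\tSe\tSp\tPr\n")
        for case, c, m in rows:
            fh.write(f"{case}\t{c.tp}/{c.pe}\t{m.se:.3f}\t{m.sp:.3f}\t{m.pr:.3f}\n")
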