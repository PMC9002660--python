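"""Benchmark classifications against truth labels.

Per category at a chosen level (order, superfamily or clade):

* tp — predicted = truth = category
* fp — predicted = category, truth is a different category
* fn — truth = category, predicted differs or is absent

precision = tp / (tp + fp); sensitivity = tp / (tp + fn).  Unclassified
predictions (and predictions shallower than the requested level) count
against sensitivity only, never as false positives — the standard treatment
of abstentions in classifier comparisons.  Elements whose truth label does
not reach the requested level are excluded from scoring.
"""

from __future__ import annotations

from pathlib import Path
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

from .classification import Classification
from .lineage import Lineage

LEVELS = ("order", "superfamily", "clade")


@dataclass(frozen=True)
class BenchmarkResult:
    """Confusion counts and derived rates for one category."""

    category: str
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> Optional[float]:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None

    @property
    def sensitivity(self) -> Optional[float]:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None


def _as_lineage(label: Union[str, Lineage]) -> Lineage:
    return label if isinstance(label, Lineage) else Lineage.from_string(label)


def score(predicted: Iterable[Classification],
          truth: Mapping[str, Union[str, Lineage]],
          level: str = "superfamily") -> list[BenchmarkResult]:
    """Score predictions against truth at one hierarchy level.

    *truth* maps element id to a truth label ('LTR/Copia' style or a
    Lineage).  Raises when no truth label reaches the requested level.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    truth_cats: dict[str, str] = {}
    for element_id, label in truth.items():
        cat = _as_lineage(label).at_level(level)
        if cat is not None:
            truth_cats[element_id] = cat
    if not truth_cats:
        raise ValueError(
            f"no truth label provides the {level!r} level; cannot score"
        )

    pred_cats: dict[str, Optional[str]] = {}
    for cls in predicted:
        cat = cls.lineage.at_level(level) if cls.lineage is not None else None
        pred_cats[cls.element_id] = cat

    categories = sorted(set(truth_cats.values())
                        | {c for c in pred_cats.values() if c is not None})
    results = []
    for category in categories:
        tp = fp = fn = 0
        for element_id, true_cat in truth_cats.items():
            pred_cat = pred_cats.get(element_id)
            if pred_cat == category and true_cat == category:
                tp += 1
            elif pred_cat == category and true_cat != category:
                fp += 1
            elif true_cat == category and pred_cat != category:
                fn += 1
        results.append(BenchmarkResult(category=category, tp=tp, fp=fp, fn=fn))
    return results


def write_report(results: Iterable[BenchmarkResult],
                 path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("category\ttp\tfp\tfn\tprecision\tsensitivity\n")
        for r in results:
            prec = "NA" if r.precision is None else f"{r.precision:.4f}"
            sens = "NA" if r.sensitivity is None else f"{r.sensitivity:.4f}"
            fh.write(f"{r.category}\t{r.tp}\t{r.fp}\t{r.fn}\t{prec}\t{sens}\n")


def passes_gate(results: Iterable[BenchmarkResult],
                min_precision: float) -> bool:
    """True when every category with defined precision meets the gate."""
    return all(r.precision is None or r.precision >= min_precision
               for r in results)
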