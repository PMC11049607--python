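"""Platform-concordance diagnostics over a (sample x gene) call matrix.

Given a test call set and a truth call set covering the same matrix, the
2x2 contingency table and the standard diagnostic proportions are
computed: sensitivity TP/(TP+FN), specificity TN/(FP+TN), PPV TP/(TP+FP),
NPV TN/(FN+TN), and diagnostic accuracy (TP+TN)/total. Zero-denominator
metrics are reported as undefined, never coerced to 0 or 1. Exact
Clopper-Pearson 95% intervals accompany each proportion in reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd
from scipy.stats import beta as beta_dist

__all__ = ["ConcordanceTable", "compare_calls", "metrics_report",
           "clopper_pearson"]


@dataclass(frozen=True)
class ConcordanceTable:
    """TP/FP/FN/TN counts with derived diagnostic metrics."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @staticmethod
    def _ratio(num: int, denom: int) -> float | None:
        return num / denom if denom else None

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.fp + self.tn)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.fn + self.tn)

    @property
    def accuracy(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.total)


def _event_series(calls: pd.DataFrame) -> pd.Series:
    """Indexed by (sample_id, gene): the effective call class.

    A filtered call counts as neutral (its raw class is provenance only).
    """
    df = calls.set_index(["sample_id", "gene"])
    cls = df["call_class"].where(~df["filtered"], "neutral")
    return cls


def compare_calls(
    test: pd.DataFrame, truth: pd.DataFrame, mode: str = "presence"
) -> ConcordanceTable:
    """2x2 concordance between two call sets on the identical matrix.

    In ``presence`` mode an event is any non-neutral, unfiltered call; a
    true positive is an event in both channels regardless of class. In
    ``exact_class`` mode a matched event must also agree on class; a
    class mismatch counts against sensitivity (the truth event was not
    correctly identified). Mismatched matrices raise, naming the missing
    (sample, gene) pairs.
    """
    if mode not in ("presence", "exact_class"):
        raise ValueError(f"unknown mode {mode!r}")
    a = _event_series(test)
    b = _event_series(truth)
    only_test = a.index.difference(b.index)
    only_truth = b.index.difference(a.index)
    if len(only_test) or len(only_truth):
        raise ValueError(
            "call matrices do not match; "
            f"missing from truth: {list(only_test[:5])}, "
            f"missing from test: {list(only_truth[:5])}"
        )
    if a.index.has_duplicates or b.index.has_duplicates:
        raise ValueError("duplicate (sample, gene) pairs in a call set")

    b = b.reindex(a.index)
    test_event = a != "neutral"
    truth_event = b != "neutral"
    if mode == "presence":
        tp = int((test_event & truth_event).sum())
    else:
        tp = int((test_event & truth_event & (a == b)).sum())
    fp = int((test_event & ~truth_event).sum())
    tn = int((~test_event & ~truth_event).sum())
    fn = int(len(a)) - tp - fp - tn
    return ConcordanceTable(tp=tp, fp=fp, fn=fn, tn=tn)


def clopper_pearson(
    x: int, n: int, confidence: float = 0.95
) -> tuple[float, float] | None:
    """Exact binomial confidence interval for x successes in n trials."""
    if n == 0:
        return None
    alpha = 1.0 - confidence
    lo = 0.0 if x == 0 else float(beta_dist.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(beta_dist.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def metrics_report(table: ConcordanceTable) -> tuple[dict, str]:
    """JSON-able dict and a human-readable rendering of all metrics."""
    defs = {
        "sensitivity": (table.tp, table.tp + table.fn),
        "specificity": (table.tn, table.fp + table.tn),
        "ppv": (table.tp, table.tp + table.fp),
        "npv": (table.tn, table.fn + table.tn),
        "accuracy": (table.tp + table.tn, table.total),
    }
    report = {
        "tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn,
        "total": table.total,
    }
    lines = [
        f"tests: {table.total}  TP={table.tp} FP={table.fp} "
        f"FN={table.fn} TN={table.tn}"
    ]
    for name, (x, n) in defs.items():
        if n == 0:
            report[name] = None
            report[f"{name}_ci95"] = None
            lines.append(f"{name}: undefined (0/0)")
            continue
        value = x / n
        ci = clopper_pearson(x, n)
        report[name] = value
        report[f"{name}_ci95"] = list(ci)
        lines.append(
            f"{name}: {100 * value:.1f}% ({x}/{n}; "
            f"95% CI {100 * ci[0]:.1f}-{100 * ci[1]:.1f}%)"
        )
    return report, "\n".join(lines)


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2)
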