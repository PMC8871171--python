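"""Evaluation of predicted cascade sizes: MRSE, MAPE, WroPerc.

For predicted sizes n_pred and true sizes n over a cascade set:

* MRSE — mean of squared relative errors ((n_pred - n)/n)^2;
* MAPE — mean of absolute relative errors |n_pred - n|/n;
* WroPerc — percentage of cascades whose absolute relative error meets
  or exceeds a tolerance (default 0.5; the comparison is inclusive).

Smaller is better for all three.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_EPS_WRONG = 0.5

__all__ = ["EvalReport", "evaluate", "write_report"]


@dataclass
class EvalReport:
    """The three error statistics plus the per-cascade residual table."""

    mrse: float
    mape: float
    wro_perc: float  # percentage in [0, 100]
    eps_wrong: float
    residuals: pd.DataFrame

    def as_row(self, model: str = "", split: str = "") -> dict:
        return {
            "model": model,
            "split": split,
            "MRSE": self.mrse,
            "MAPE": self.mape,
            "WroPerc": self.wro_perc,
        }


def evaluate(predictions, truths, eps_wrong: float = DEFAULT_EPS_WRONG) -> EvalReport:
    """Score size predictions against true final sizes.

    ``truths`` must be >= 1 (every cascade has at least its root).  The
    WroPerc indicator counts relative errors >= ``eps_wrong``, boundary
    included.
    """
    pred = np.asarray(predictions, dtype=float)
    true = np.asarray(truths, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("predictions and truths must have equal length")
    if pred.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    if np.any(true < 1):
        raise ValueError("true cascade sizes must be >= 1")
    rel = (pred - true) / true
    residuals = pd.DataFrame({"n_pred": pred, "n_true": true, "rel_error": rel})
    return EvalReport(
        mrse=float(np.mean(rel**2)),
        mape=float(np.mean(np.abs(rel))),
        wro_perc=float(100.0 * np.mean(np.abs(rel) >= eps_wrong)),
        eps_wrong=eps_wrong,
        residuals=residuals,
    )


def write_report(rows: list[dict], path: str | Path) -> None:
    """Tab-delimited results table (model, split, MRSE, MAPE, WroPerc)."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
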