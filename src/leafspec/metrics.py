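"""Regression diagnostics reported by the pipeline: PRESS (residual sum
of squares on the stated split), RMSE, MAE and the coefficient of
determination R².

R² here is the determination form 1 - SS_res/SS_tot, which can be
negative for a model worse than the mean; the squared Pearson
correlation is available separately since both conventions circulate
in the calibration literature.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["EvalReport", "press", "rmse", "mae", "r2", "pearson_r2",
           "report", "plot_observed_vs_predicted"]


def _paired(y, yhat, min_len: int = 1):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size < min_len:
        raise ValueError(f"need at least {min_len} pairs")
    return y, yhat


def press(y, yhat) -> float:
    """Residual sum of squares Σ(y - ŷ)² (squared label units)."""
    y, yhat = _paired(y, yhat)
    return float(np.sum((y - yhat) ** 2))


def rmse(y, yhat) -> float:
    """Root mean squared error sqrt(press / n), mg/kg."""
    y, yhat = _paired(y, yhat)
    return float(np.sqrt(press(y, yhat) / y.size))


def mae(y, yhat) -> float:
    """Mean absolute error, mg/kg."""
    y, yhat = _paired(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def r2(y, yhat) -> float:
    """Coefficient of determination 1 - Σ(y-ŷ)²/Σ(y-ȳ)²."""
    y, yhat = _paired(y, yhat, min_len=2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y is constant; R² undefined")
    return 1.0 - press(y, yhat) / ss_tot


def pearson_r2(y, yhat) -> float:
    """Squared Pearson correlation between observed and predicted."""
    y, yhat = _paired(y, yhat, min_len=2)
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("constant vector; correlation undefined")
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


@dataclass
class EvalReport:
    """Press/RMSE/MAE/R² for one split."""

    split: str
    press: float
    rmse: float
    mae: float
    r2: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def _one(split: str, y, yhat) -> EvalReport:
    y, yhat = _paired(y, yhat, min_len=1)
    return EvalReport(split=split, press=press(y, yhat), rmse=rmse(y, yhat),
                      mae=mae(y, yhat),
                      r2=r2(y, yhat) if np.ptp(y) > 0 else float("nan"),
                      n=int(y.size))


def report(y_train, yhat_train, y_test, yhat_test,
           y_val=None, yhat_val=None) -> list[EvalReport]:
    """One :class:`EvalReport` per available split (train/test[/validation])."""
    out = [_one("training", y_train, yhat_train), _one("testing", y_test, yhat_test)]
    if (y_val is None) != (yhat_val is None):
        raise ValueError("validation labels and predictions must come together")
    if y_val is not None:
        out.append(_one("validation", y_val, yhat_val))
    return out


def report_frame(reports: list[EvalReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])


def plot_observed_vs_predicted(y, yhat, ax=None, label: str | None = None):
    """Plain observed-vs-predicted scatter with the identity line."""
    import matplotlib.pyplot as plt

    y, yhat = _paired(y, yhat, min_len=2)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(y, yhat, s=12, alpha=0.7, label=label)
    lo = min(y.min(), yhat.min())
    hi = max(y.max(), yhat.max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    ax.set_xlabel("observed residue (mg/kg)")
    ax.set_ylabel("predicted residue (mg/kg)")
    if label:
        ax.legend()
    return ax
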