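"""ROC/AUC evaluation, Youden cutoffs, the q diagnostic, and the
subject-resampling protocol for real three-observer data.

The diagnostic question is: does an estimated concordance rate separate
truly concordant method pairs (by the signs of the population mean
differences, or by construction in real data) from discordant ones?  AUC is
computed with the rank (Mann-Whitney) convention, ties counted half.  The
operating cutoff is chosen by Youden's index (maximizing TPR - FPR); among
tied maximizers the smallest cutoff is taken, which makes the choice
deterministic.  The q diagnostic is the fraction of datasets whose rate
falls on the correct side of a given cutoff: rate >= cutoff counts as a
"concordant" call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .ccr import conventional_concordance
from .controls import control1_rate, control2_rate, count_control_inputs
from .data import AnalysisConfig, MeasurementSeries, compute_differences
from .errors import EstimationError, EvaluationError, UndefinedRateError
from .mvn import estimate_mvn_params, proposed_rate
from .simulation import methods_for_m

__all__ = [
    "ROCResult",
    "QResult",
    "roc_auc",
    "q_statistic",
    "factor_tables",
    "bootstrap_real_protocol",
]


@dataclass(frozen=True)
class ROCResult:
    """AUC, Youden-optimal cutoff and the ROC polyline."""

    auc: float
    cutoff: float
    roc_points: np.ndarray  # (k, 2) of (FPR, TPR)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "cutoff": self.cutoff,
            "roc_points": np.asarray(self.roc_points).tolist(),
        }


@dataclass(frozen=True)
class QResult:
    """Fraction of rates on the correct side of a cutoff."""

    q: float
    n_star: int
    pattern: int | None = None


def _check_two_classes(labels: np.ndarray):
    if labels.all() or not labels.any():
        raise EvaluationError("both labels must be present to evaluate an ROC")


def roc_auc(scores, labels) -> ROCResult:
    """Rank-based AUC with a Youden-index cutoff.

    Parameters
    ----------
    scores : array of estimated concordance rates.
    labels : boolean array; True marks the truly concordant class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise EvaluationError("scores and labels must be matching 1-d arrays")
    _check_two_classes(labels)
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    youden = tpr - fpr
    best = youden == youden.max()
    # thresholds are decreasing; the smallest cutoff among maximizers is the
    # last one (ignore the sentinel +inf threshold when any finite one ties).
    idx = np.flatnonzero(best)[-1]
    cutoff = float(thresholds[idx])
    return ROCResult(auc=auc, cutoff=cutoff, roc_points=np.column_stack([fpr, tpr]))


def q_statistic(scores, labels, cutoff: float, pattern: int | None = None) -> QResult:
    """q = fraction of scores on the correct side of ``cutoff``.

    A positive-labeled score is correct when >= cutoff; a negative-labeled
    one when < cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size == 0:
        raise EvaluationError("no scores supplied")
    correct = np.where(labels, scores >= cutoff, scores < cutoff)
    return QResult(q=float(correct.mean()), n_star=scores.size, pattern=pattern)


def _label_column(m: int) -> str:
    return "label1" if m == 2 else "label2"


def factor_tables(estimates: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summary tables of a simulation run.

    Returns a dict with:

    ``overall``      AUC per (m, method) over the whole grid.
    ``rho``, ``rho_xy``, ``a``, ``n_subjects``
                     AUC per (m, method) within each level of that factor.
    ``pattern_q``    Per-mean-pattern q at the global Youden cutoffs
                     (cutoffs estimated once per (m, method) from the pooled
                     ROC over all patterns).
    ``cutoffs``      The Youden cutoffs used for ``pattern_q``.
    ``undefined``    Count of undefined rates per (m, method).
    """
    df = estimates
    required = {"m", "method", "rate", "defined", "label1", "label2", "pattern"}
    if not required.issubset(df.columns):
        raise EvaluationError(f"estimates table lacks columns {required - set(df.columns)}")

    undefined = (
        df[~df["defined"]].groupby(["m", "method"]).size().rename("n_undefined")
    ).reset_index()
    df = df[df["defined"]]

    def _auc_cell(m: int, method: str, sub: pd.DataFrame) -> float:
        if sub.empty:
            raise EvaluationError(f"no estimates for m={m}, method={method}")
        return roc_auc(sub["rate"].to_numpy(), sub[_label_column(m)].to_numpy()).auc

    overall_rows = []
    cutoff_rows = []
    for m in sorted(df["m"].unique()):
        for method in methods_for_m(int(m)):
            sub = df[(df["m"] == m) & (df["method"] == method)]
            if sub.empty:
                raise EvaluationError(f"missing estimates for m={m}, method={method}")
            roc = roc_auc(sub["rate"].to_numpy(), sub[_label_column(int(m))].to_numpy())
            overall_rows.append({"m": m, "method": method, "auc": roc.auc})
            cutoff_rows.append({"m": m, "method": method, "cutoff": roc.cutoff})
    overall = pd.DataFrame(overall_rows)
    cutoffs = pd.DataFrame(cutoff_rows)

    tables: dict[str, pd.DataFrame] = {"overall": overall, "cutoffs": cutoffs}
    for factor in ("rho", "rho_xy", "a", "n_subjects"):
        rows = []
        for level in sorted(df[factor].unique()):
            sub_l = df[df[factor] == level]
            for m in sorted(sub_l["m"].unique()):
                for method in methods_for_m(int(m)):
                    sub = sub_l[(sub_l["m"] == m) & (sub_l["method"] == method)]
                    rows.append(
                        {
                            factor: level,
                            "m": m,
                            "method": method,
                            "auc": _auc_cell(int(m), method, sub),
                        }
                    )
        tables[factor] = pd.DataFrame(rows)

    q_rows = []
    cut = {(r["m"], r["method"]): r["cutoff"] for r in cutoff_rows}
    for pattern in sorted(df["pattern"].unique()):
        sub_p = df[df["pattern"] == pattern]
        for m in sorted(sub_p["m"].unique()):
            for method in methods_for_m(int(m)):
                sub = sub_p[(sub_p["m"] == m) & (sub_p["method"] == method)]
                if sub.empty:
                    continue
                res = q_statistic(
                    sub["rate"].to_numpy(),
                    sub[_label_column(int(m))].to_numpy(),
                    cut[(m, method)],
                    pattern=int(pattern),
                )
                q_rows.append(
                    {"pattern": pattern, "m": m, "method": method, "q": res.q}
                )
    tables["pattern_q"] = pd.DataFrame(q_rows)
    tables["undefined"] = undefined
    return tables


def _pair_rates(
    ref_values: np.ndarray,
    tst_values: np.ndarray,
    m: int,
    quantile: float,
    qmc_options: dict | None,
) -> dict[str, float]:
    """All four estimators on one resampled pair; NaN marks undefined."""
    from .data import DifferencePairs

    diffs_full = DifferencePairs(
        x=np.diff(ref_values, axis=1), y=np.diff(tst_values, axis=1)
    )
    pooled = np.abs(np.concatenate([diffs_full.x.ravel(), diffs_full.y.ravel()]))
    a = float(np.quantile(pooled, quantile))
    cfg = AnalysisConfig(a=a, T=diffs_full.n_times, m=m)
    out: dict[str, float] = {"a": a}
    try:
        out["proposal"] = proposed_rate(
            estimate_mvn_params(diffs_full), cfg, tol=5e-4, qmc_options=qmc_options
        ).rate
    except (UndefinedRateError, EstimationError):
        out["proposal"] = np.nan
    try:
        out["ccr"] = conventional_concordance(diffs_full, a).rate
    except UndefinedRateError:
        out["ccr"] = np.nan
    try:
        inputs = count_control_inputs(diffs_full, a)
        out["control1"] = control1_rate(inputs, m)
        out["control2"] = control2_rate(inputs, m)
    except UndefinedRateError:
        out["control1"] = np.nan
        out["control2"] = np.nan
    return out


def bootstrap_real_protocol(
    series_j: MeasurementSeries,
    series_r: MeasurementSeries,
    series_s: MeasurementSeries,
    *,
    n_iterations: int = 1000,
    subjects_per_draw: int = 10,
    seed: int = 0,
    m: int = 2,
    quantile: float = 0.10,
    qmc_options: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, ROCResult], pd.DataFrame]:
    """Subject-resampling evaluation on three aligned measurement series.

    J and R are two observers of the gold-standard method and S an automatic
    machine.  Each iteration draws ``subjects_per_draw`` subjects with
    replacement (the same draw for all pairs), forms the pairs (J,R), (R,S)
    and (J,S), sets the exclusion-zone half-width to the ``quantile`` point
    of the pooled absolute differences of the pair at hand, and computes the
    four estimators at the given m.  (J,R) rates carry the concordant label;
    (R,S) and (J,S) the discordant one.  Undefined rates are dropped from
    the ROC with their counts reported.

    Returns (per-iteration estimates table, per-method ROC results,
    undefined-count table).
    """
    for s in (series_r, series_s):
        if s.n_subjects != series_j.n_subjects or s.n_times != series_j.n_times:
            raise EvaluationError("the three series must be aligned subject-wise")
    if n_iterations < 2:
        raise EvaluationError(
            "at least two resampling iterations are needed for an ROC"
        )
    rng = np.random.default_rng(seed)
    n = series_j.n_subjects
    pairs = [
        ("JR", series_j, series_r, True),
        ("RS", series_r, series_s, False),
        ("JS", series_j, series_s, False),
    ]
    records = []
    for it in range(n_iterations):
        idx = rng.integers(0, n, size=subjects_per_draw)
        for name, ref, tst, positive in pairs:
            rates = _pair_rates(
                ref.reference_values[idx],
                tst.reference_values[idx],
                m,
                quantile,
                qmc_options,
            )
            for method in ("proposal", "ccr", "control1", "control2"):
                records.append(
                    {
                        "iteration": it,
                        "pair": name,
                        "positive": positive,
                        "method": method,
                        "rate": rates[method],
                        "a": rates["a"],
                        "defined": not np.isnan(rates[method]),
                    }
                )
    table = pd.DataFrame.from_records(records)
    undefined = (
        table[~table["defined"]].groupby("method").size().rename("n_undefined")
    ).reset_index()
    rocs: dict[str, ROCResult] = {}
    for method in ("proposal", "ccr", "control1", "control2"):
        sub = table[(table["method"] == method) & table["defined"]]
        rocs[method] = roc_auc(
            sub["rate"].to_numpy(), sub["positive"].to_numpy(dtype=bool)
        )
    return table, rocs, undefined
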