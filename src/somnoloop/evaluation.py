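"""Agreement metrics and statistical utilities for scoring evaluation.

All functions here are pure: confusion-matrix agreement with Cohen's kappa
(UNSCORED epochs excluded from accuracy but reported as percent scorable),
Bland–Altman limits of agreement, MAE/MAPE for vitals, sleep-onset-latency
deviation summaries, and one-way ANOVA with Tukey post-hoc comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signal_io import STAGES, UNSCORED, Hypnogram

_LABELS = STAGES + (UNSCORED,)


@dataclass
class AgreementReport:
    confusion: pd.DataFrame          # 5x5 including the UNSCORED row/col
    accuracy: float
    kappa: float
    per_stage: pd.DataFrame          # precision/recall/F1 per stage
    percent_scorable: float


def agreement(est: Hypnogram, ref: Hypnogram) -> AgreementReport:
    """Epoch-wise agreement of an estimated hypnogram with a reference.

    UNSCORED estimated epochs are excluded from accuracy and kappa but
    counted in ``percent_scorable``.
    """
    if len(est) != len(ref):
        raise ValueError("hypnograms must have equal lengths")
    conf = pd.DataFrame(0, index=list(_LABELS), columns=list(_LABELS))
    for e, r in zip(est, ref):
        conf.loc[r, e] += 1
    scored = [(e, r) for e, r in zip(est, ref)
              if e != UNSCORED and r != UNSCORED]
    n = len(scored)
    percent_scorable = 100.0 * sum(e != UNSCORED for e in est) / len(est)
    if n == 0:
        return AgreementReport(conf, np.nan, np.nan,
                               pd.DataFrame(), percent_scorable)
    acc = sum(e == r for e, r in scored) / n
    # chance-corrected agreement over the scored epochs
    pe = 0.0
    for s in STAGES:
        p_est = sum(e == s for e, _ in scored) / n
        p_ref = sum(r == s for _, r in scored) / n
        pe += p_est * p_ref
    kappa = (acc - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    rows = []
    for s in STAGES:
        tp = sum(e == s and r == s for e, r in scored)
        fp = sum(e == s and r != s for e, r in scored)
        fn = sum(e != s and r == s for e, r in scored)
        prec = tp / (tp + fp) if tp + fp else np.nan
        rec = tp / (tp + fn) if tp + fn else np.nan
        f1 = (2 * prec * rec / (prec + rec)
              if prec + rec and not np.isnan(prec + rec) else np.nan)
        rows.append({"stage": s, "precision": prec, "recall": rec, "f1": f1})
    return AgreementReport(conf, float(acc), float(kappa),
                           pd.DataFrame(rows).set_index("stage"),
                           percent_scorable)


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    pairs: np.ndarray


def bland_altman(pairs: list[tuple[float, float]]) -> BlandAltmanResult:
    """Mean difference and 95% limits of agreement (mean ± 1.96 SD, n−1 SD)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or len(arr) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = arr[:, 0] - arr[:, 1]
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(mean_diff=m, sd_diff=sd,
                             loa_lower=m - 1.96 * sd, loa_upper=m + 1.96 * sd,
                             pairs=arr)


def mae_mape(est: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    """Mean absolute error and mean absolute percentage error (percent).

    NaN entries on either side are excluded pairwise; zero references are
    excluded from MAPE.  Raises when nothing remains.
    """
    e = np.asarray(est, dtype=float)
    r = np.asarray(ref, dtype=float)
    if e.shape != r.shape:
        raise ValueError("series must have equal lengths")
    ok = ~(np.isnan(e) | np.isnan(r))
    if not ok.any():
        raise ValueError("no valid pairs")
    err = np.abs(e[ok] - r[ok])
    mae = float(err.mean())
    nz = r[ok] != 0
    mape = float(100.0 * (err[nz] / np.abs(r[ok][nz])).mean()) if nz.any() else np.nan
    return mae, mape


def sol_deviation(est_sol: int | None, ref_sol: int | None) -> int | None:
    """Signed SOL difference in epochs (est − ref); None when undefined."""
    if est_sol is None or ref_sol is None:
        return None
    return int(est_sol) - int(ref_sol)


def sol_deviation_batch(pairs: list[tuple[int | None, int | None]],
                        tolerance_epochs: int = 5) -> dict:
    """Distribution of SOL deviations and the fraction within ±tolerance."""
    devs = [sol_deviation(e, r) for e, r in pairs]
    valid = [d for d in devs if d is not None]
    n_undefined = len(devs) - len(valid)
    if not valid:
        return {"deviations": [], "within_frac": np.nan,
                "n_undefined": n_undefined}
    within = sum(abs(d) <= tolerance_epochs for d in valid) / len(valid)
    return {"deviations": valid, "within_frac": float(within),
            "n_undefined": n_undefined}


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, p)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    f, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)


def tukey_posthoc(groups: list[np.ndarray]) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons with adjusted p-values."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    res = stats.tukey_hsd(*[np.asarray(g, dtype=float) for g in groups])
    rows = []
    k = len(groups)
    for i in range(k):
        for j in range(i + 1, k):
            rows.append({"group_a": i, "group_b": j,
                         "diff": float(res.statistic[i, j]),
                         "p_adj": float(res.pvalue[i, j])})
    return pd.DataFrame(rows)
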