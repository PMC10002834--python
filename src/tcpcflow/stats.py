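"""Method-agreement statistics between simulated and measured pressure losses.

Bland-Altman analysis quantifies agreement between two measurement methods
through the paired differences: the mean difference (bias) with its
t-based 95% confidence interval, and the 95% limits of agreement
mean +/- 1.96 SD, inside which ~95% of future differences are expected.
Pearson correlation complements the agreement view.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["PairedComparison", "BlandAltmanResult",
           "bland_altman", "pearson_r", "comparison_table"]


@dataclass
class PairedComparison:
    """Paired case-matched values (mmHg): a = simulated, b = measured."""

    labels: list
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, float)
        self.b = np.asarray(self.b, float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("paired series must be equal-length vectors")
        if len(self.labels) != self.a.size:
            raise ValueError("one label per pair required")
        if self.a.size < 2:
            raise ValueError("need at least 2 pairs")
        if np.any(~np.isfinite(self.a)) or np.any(~np.isfinite(self.b)):
            raise ValueError("missing or non-finite entries in paired data")

    @property
    def n(self) -> int:
        return self.a.size


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    ci95_mean_diff: tuple
    loa95: tuple
    n: int

    def summary(self) -> str:
        lo, hi = self.loa95
        cl, ch = self.ci95_mean_diff
        return (f"Bland-Altman (n={self.n}): mean difference "
                f"{self.mean_diff:+.3f} mmHg, 95% CI [{cl:.3f}, {ch:.3f}], "
                f"SD {self.sd_diff:.3f}, limits of agreement "
                f"[{lo:.3f}, {hi:.3f}] mmHg")


def bland_altman(pc: PairedComparison) -> BlandAltmanResult:
    """Agreement statistics on the paired differences a - b.

    The CI of the mean difference uses the t distribution with n-1 degrees
    of freedom; limits of agreement use the 1.96 normal quantile.
    """
    d = pc.a - pc.b
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd > 0:
        half = float(sps.t.ppf(0.975, pc.n - 1)) * sd / np.sqrt(pc.n)
    else:
        half = 0.0
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        ci95_mean_diff=(mean - half, mean + half),
        loa95=(mean - 1.96 * sd, mean + 1.96 * sd),
        n=pc.n,
    )


def pearson_r(pc: PairedComparison) -> float:
    """Sample Pearson correlation of the paired series."""
    if pc.n < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.std(pc.a) == 0 or np.std(pc.b) == 0:
        raise ValueError("zero variance in one series; correlation undefined")
    return float(sps.pearsonr(pc.a, pc.b).statistic)


def comparison_table(cfd: pd.DataFrame, mcl) -> tuple[pd.DataFrame, list]:
    """Join per-case simulated and measured pressure losses.

    ``cfd`` needs columns CO_L_min, model, dP_max_mmHg; ``mcl`` is an
    MCLDataset (or its table) with CO_L_min, model, dP_mmHg.  Returns the
    joined table (one row per matched case, columns dP_cfd, dP_mcl, diff)
    plus the list of unmatched (CO, model) keys.
    """
    mtab = mcl.table if hasattr(mcl, "table") else mcl
    for frame, cols in ((cfd, ("CO_L_min", "model", "dP_max_mmHg")),
                        (mtab, ("CO_L_min", "model", "dP_mmHg"))):
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise ValueError(f"missing columns {missing}")
    for name, frame in (("cfd", cfd), ("mcl", mtab)):
        if frame.duplicated(subset=["CO_L_min", "model"]).any():
            raise ValueError(f"duplicate (CO, model) keys in {name} table")
    joined = cfd.merge(mtab, on=["CO_L_min", "model"], how="outer",
                       suffixes=("_cfd", "_mcl"), indicator=True)
    unmatched = [tuple(r) for r in joined.loc[
        joined["_merge"] != "both", ["CO_L_min", "model"]].itertuples(index=False)]
    out = joined[joined["_merge"] == "both"].copy()
    out = out.rename(columns={"dP_max_mmHg": "dP_cfd_mmHg",
                              "dP_mmHg": "dP_mcl_mmHg"})
    out["diff_mmHg"] = out["dP_cfd_mmHg"] - out["dP_mcl_mmHg"]
    cols = ["CO_L_min", "model", "dP_cfd_mmHg", "dP_mcl_mmHg", "diff_mmHg"]
    return out[cols].reset_index(drop=True), unmatched
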