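"""Brain-behavior coupling: normalized ITPC and across-subject correlation.

The normalized ITPC (nITPC) of a subject is the evoked ITPC of the target
(attended low-frequency) condition minus the mean evoked ITPC over the other
cue conditions, averaged over a region of electrodes (typically the 2-electrode
cluster found by the spatial permutation test), at one frequency.  nITPC is
then correlated with the perceptual switch index (PSI) across subjects with a
Pearson r, two-tailed p from the t transform with df = n - 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrelationResult:
    r: float
    p: float
    df: int
    n: int

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.r)

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "df": self.df, "n": self.n}


def normalized_itpc(evoked_by_condition: Mapping[str, np.ndarray],
                    target: str, region: Sequence[int],
                    others: Sequence[str] | None = None) -> np.ndarray:
    """Per-subject nITPC over a region of electrodes.

    ``evoked_by_condition`` maps condition -> (n_subjects, n_channels) evoked
    ITPC at the frequency of interest.  ``others`` defaults to every
    non-target condition supplied (visual-only periods, which have no
    crossmodal onset to phase-lock to, are simply not passed in by default).
    """
    if target not in evoked_by_condition:
        raise ValueError(f"missing target condition {target!r}")
    if others is None:
        others = [k for k in evoked_by_condition if k != target]
    missing = [k for k in others if k not in evoked_by_condition]
    if missing:
        raise ValueError(f"missing conditions: {missing}")
    region = np.asarray(region, int)
    tgt = evoked_by_condition[target][:, region].mean(axis=1)
    oth = np.mean([evoked_by_condition[k][:, region].mean(axis=1)
                   for k in others], axis=0)
    return tgt - oth


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation reported in the r(df) convention.

    Returns NaN r and p (an explicit undefined flag) when n < 3 or either
    variable has zero variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y differ in length")
    n = x.size
    if n < 3 or x.std() == 0 or y.std() == 0:
        return CorrelationResult(r=np.nan, p=np.nan, df=max(n - 2, 0), n=n)
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue),
                             df=n - 2, n=n)


def brain_behavior_table(subjects: Sequence[int], nitpc: np.ndarray,
                         psi: np.ndarray, condition: str, region: Sequence[str],
                         freq: float) -> pd.DataFrame:
    return pd.DataFrame({"subject": list(subjects), "condition": condition,
                         "region": ",".join(region), "freq_hz": freq,
                         "nitpc": nitpc, "psi": psi})


def write_correlation_json(result: CorrelationResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=1))
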