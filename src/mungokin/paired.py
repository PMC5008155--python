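"""Paired comparison of guard-female vs extra-pair-male-female relatedness.

When a mate-guard loses paternity, is the male who sired the pups less
related to the female than the guard was? Each unsuccessful guard-female
pair with a single identified extra-pair (EPP) sire contributes one paired
difference d = r(guard, female) - r(EPP male, female), tested with a
classical paired t-test (two-tailed), overall and split by whether the EPP
male was within-group or extra-group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PairedTestResult", "paired_t", "epp_comparison"]


@dataclass
class PairedTestResult:
    n_pairs: int
    mean_difference: float
    t_statistic: float
    degrees_of_freedom: int
    p_two_tailed: float

    def to_json(self, path=None) -> str:
        s = json.dumps(self.__dict__, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def paired_t(differences) -> PairedTestResult:
    """One-sample t-test of the paired differences against zero.

    t = mean(d) / (sd(d) / sqrt(n)) with the n-1 sample standard deviation;
    two-tailed p from Student's t with n-1 degrees of freedom.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    sd = d.std(ddof=1)
    if np.ptp(d) == 0.0 or sd == 0.0:  # constant differences
        raise ValueError("paired differences have zero variance")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return PairedTestResult(
        n_pairs=int(n),
        mean_difference=float(d.mean()),
        t_statistic=float(t),
        degrees_of_freedom=int(df),
        p_two_tailed=float(p),
    )


def epp_comparison(epp_rows: pd.DataFrame, scope: str = "all") -> PairedTestResult:
    """Paired t-test of guard_r - epp_r for a given EPP scope.

    ``scope`` is ``"all"``, ``"within_group"`` or ``"extra_group"``;
    ``epp_rows`` comes from :func:`mungokin.filters.identify_epp`.
    """
    if scope not in ("all", "within_group", "extra_group"):
        raise ValueError(f"unknown scope {scope!r}")
    rows = epp_rows
    if scope != "all":
        rows = rows[rows["epp_scope"] == scope]
    if len(rows) < 2:
        raise ValueError(f"fewer than 2 EPP pairs in scope {scope!r}")
    return paired_t(rows["guard_r"].to_numpy() - rows["epp_r"].to_numpy())
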