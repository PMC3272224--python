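"""Descriptive mean ± SEM summaries for report tables.

Inferential statistics (ANOVA, post hoc tests) are out of scope by design:
results are emitted as tidy per-window values so any external tool can take
over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptyGroup


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and standard error of the mean for one variable."""

    variable: str
    n: int
    mean: float
    sem: float

    def to_dict(self) -> dict:
        return {"n": self.n, "mean": self.mean, "sem": self.sem}


def summarize(values, variable: str = "") -> GroupSummary:
    """Mean ± SEM with the n-1 (sample) standard deviation.

    SEM is undefined (NaN) for a single value; an empty group raises
    :class:`EmptyGroup`.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise EmptyGroup("cannot summarize an empty group")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else math.nan
    return GroupSummary(variable, int(v.size), mean, sem)
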