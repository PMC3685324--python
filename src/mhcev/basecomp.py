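"""GC content by codon position and Welch's unequal-variance t-test."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mhcev.errors import TestError
from mhcev.seqio import AlignedSequence, CodonAlignment


@dataclass(frozen=True)
class GCProfile:
    id: str
    gc1: float | None
    gc2: float | None
    gc3: float | None
    gc_all: float | None


def gc_profile(seq: AlignedSequence) -> GCProfile:
    """GC percentage at each codon position and overall (gaps and N excluded).

    A position with no non-gap bases yields None for that field.
    """
    gc_counts = [0, 0, 0]
    totals = [0, 0, 0]
    for i, ch in enumerate(seq.bases):
        if ch in "-N":
            continue
        pos = i % 3
        totals[pos] += 1
        if ch in "GC":
            gc_counts[pos] += 1
    per_pos = [
        100.0 * g / t if t else None for g, t in zip(gc_counts, totals)
    ]
    total = sum(totals)
    gc_all = 100.0 * sum(gc_counts) / total if total else None
    return GCProfile(id=seq.id, gc1=per_pos[0], gc2=per_pos[1], gc3=per_pos[2], gc_all=gc_all)


def gc_table(aln: CodonAlignment) -> pd.DataFrame:
    rows = []
    for seq in aln:
        p = gc_profile(seq)
        rows.append(
            {
                "id": p.id,
                "species": seq.species,
                "clade": seq.clade,
                "gc1": p.gc1,
                "gc2": p.gc2,
                "gc3": p.gc3,
                "gc_all": p.gc_all,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "t": self.t,
                    "df": self.df,
                    "p": self.p,
                    "mean_a": self.mean_a,
                    "mean_b": self.mean_b,
                },
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )


def welch_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's two-sample t-test with Satterthwaite degrees of freedom.

    t = (mean_a - mean_b) / sqrt(s2a/na + s2b/nb); two-sided p from the
    t distribution.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if len(xa) < 2 or len(xb) < 2:
        raise TestError("each group needs at least 2 values")
    va = xa.var(ddof=1)
    vb = xb.var(ddof=1)
    if va + vb == 0.0:
        if xa.mean() == xb.mean():
            return WelchResult(t=0.0, df=float(len(xa) + len(xb) - 2), p=1.0,
                               mean_a=float(xa.mean()), mean_b=float(xb.mean()))
        raise TestError("zero variance in both groups with unequal means")
    sa = va / len(xa)
    sb = vb / len(xb)
    t = (xa.mean() - xb.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        sa**2 / (len(xa) - 1) + sb**2 / (len(xb) - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(
        t=float(t), df=float(df), p=float(min(p, 1.0)),
        mean_a=float(xa.mean()), mean_b=float(xb.mean()),
    )


def clade_gc_tests(aln: CodonAlignment) -> dict[str, WelchResult]:
    """Welch tests (songbird vs nonpasserine) on per-sequence GC3 and overall GC.

    The outgroup is excluded; group a = songbirds.
    """
    table = gc_table(aln)
    table = table[table["clade"] != "outgroup"]
    a = table[table["clade"] == "songbird"]
    b = table[table["clade"] == "nonpasserine"]
    return {
        "gc3": welch_test(a["gc3"].dropna(), b["gc3"].dropna()),
        "gc_all": welch_test(a["gc_all"].dropna(), b["gc_all"].dropna()),
    }
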