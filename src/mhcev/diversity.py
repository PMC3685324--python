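"""Per-species polymorphism summaries: S, k and pi.

All statistics use pairwise deletion: alignment columns where either member
of a pair carries a gap or N are excluded from that pair's comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd

from mhcev.errors import SizeError
from mhcev.seqio import CodonAlignment


@dataclass(frozen=True)
class DiversityResult:
    species: str
    na: int
    s: int
    pi: float
    k: float


def polymorphic_sites(aln: CodonAlignment) -> int:
    """Number of columns with >= 2 distinct non-gap, non-N bases."""
    if len(aln) < 2:
        raise SizeError("polymorphic_sites needs at least 2 sequences")
    count = 0
    for col in range(aln.length):
        bases = {s.bases[col] for s in aln} - {"-", "N"}
        if len(bases) >= 2:
            count += 1
    return count


def pairwise_diff_stats(aln: CodonAlignment) -> tuple[float, float]:
    """Mean pairwise differences k and per-site diversity pi.

    k averages, over all unordered pairs, the count of differing columns
    (gap/N columns dropped pairwise); pi averages differences divided by the
    number of compared sites for each pair.
    """
    if len(aln) < 2:
        raise SizeError("pairwise_diff_stats needs at least 2 sequences")
    diffs_sum = 0.0
    prop_sum = 0.0
    n_pairs = 0
    for a, b in combinations(aln.sequences, 2):
        diffs = 0
        compared = 0
        for x, y in zip(a.bases, b.bases):
            if x in "-N" or y in "-N":
                continue
            compared += 1
            if x != y:
                diffs += 1
        n_pairs += 1
        diffs_sum += diffs
        if compared:
            prop_sum += diffs / compared
    return diffs_sum / n_pairs, prop_sum / n_pairs


def species_diversity_table(
    species_alignments: dict[str, CodonAlignment]
) -> pd.DataFrame:
    """One row per species with Na, S, pi, k (species with < 2 alleles get NA)."""
    rows = []
    for species, aln in species_alignments.items():
        if len(aln) >= 2:
            s = polymorphic_sites(aln)
            k, pi = pairwise_diff_stats(aln)
        else:
            s, k, pi = None, None, None
        rows.append(
            {"species": species, "Na": len(aln), "S": s, "pi": pi, "k": k}
        )
    return pd.DataFrame(rows, columns=["species", "Na", "S", "pi", "k"])


def write_diversity_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
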