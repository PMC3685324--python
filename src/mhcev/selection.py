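"""Counting-based dN/dS estimation partitioned into PBR and non-PBR codons.

Synonymous and nonsynonymous sites are counted per codon with a
transition/transversion weight R (R = 0.5 reduces to the unweighted classic
estimator, since each codon position offers one transition and two
transversions).  Differences between codons are averaged over all mutational
pathways, excluding pathways through stop codons.  Per-pair proportions are
corrected for multiple hits with the Jukes–Cantor formula and averaged over
pairs; bootstrap standard errors resample codon columns within a partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from mhcev.errors import SaturationError, SiteError, SizeError
from mhcev.seqio import AlignedSequence, CodonAlignment, STANDARD_STOPS, translate_codon

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
BASES = "ACGT"


def is_transition(x: str, y: str) -> bool:
    return (x in PURINES and y in PURINES) or (x in PYRIMIDINES and y in PYRIMIDINES)


@dataclass(frozen=True)
class PartitionScheme:
    """A-priori peptide-binding-region codons, in exon coordinates.

    `frame_offset` is the number of exon codons missing from the start of the
    alignment, so exon codon `c` maps to 1-based alignment codon
    ``c - frame_offset``.
    """

    pbr_exon_codons: frozenset[int]
    frame_offset: int = 4

    @classmethod
    def default_pbr(cls, frame_offset: int = 4) -> "PartitionScheme":
        """The a-priori avian class-I exon-3 PBR codon set."""
        return cls(
            pbr_exon_codons=frozenset(
                {5, 7, 8, 9, 23, 25, 38, 60, 61, 62, 65, 66, 68, 73}
            ),
            frame_offset=frame_offset,
        )

    @classmethod
    def from_file(cls, path: str | Path, frame_offset: int = 4) -> "PartitionScheme":
        """Read one exon codon number per line (blank lines and # comments ok)."""
        codons = set()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                codons.add(int(line))
        return cls(pbr_exon_codons=frozenset(codons), frame_offset=frame_offset)

    def alignment_codon_indices(self, n_codons: int) -> frozenset[int]:
        """0-based alignment codon indices of the PBR partition."""
        idx = set()
        for c in self.pbr_exon_codons:
            pos = c - self.frame_offset - 1
            if not 0 <= pos < n_codons:
                raise ValueError(
                    f"exon codon {c} maps outside the alignment "
                    f"(offset {self.frame_offset}, {n_codons} codons)"
                )
            idx.add(pos)
        return frozenset(idx)

    def partition_indices(self, n_codons: int) -> dict[str, frozenset[int]]:
        pbr = self.alignment_codon_indices(n_codons)
        non = frozenset(range(n_codons)) - pbr
        return {
            "PBR": pbr,
            "nonPBR": non,
            "all": frozenset(range(n_codons)),
        }


@dataclass(frozen=True)
class DnDsEstimate:
    partition: str
    group: str
    dn: float
    ds: float
    se_dn: float | None
    se_ds: float | None
    n_sites_syn: float
    n_sites_nonsyn: float
    n_pairs: int

    @property
    def omega(self) -> float | None:
        if self.ds is None or self.ds == 0.0 or math.isnan(self.ds):
            return None
        return self.dn / self.ds


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str, r: float = 0.5) -> tuple[float, float]:
    """Synonymous and nonsynonymous site fractions of one codon.

    Each of the nine single-nucleotide mutants is weighted 2R (transition) or
    1 (each transversion) and normalized per position, so each position
    contributes exactly one site and syn + nonsyn == 3.  Mutants to stop
    codons are dropped and the position weight renormalizes over the
    remaining mutants.
    """
    if set(codon) - set(BASES):
        raise SiteError(f"ambiguous or gapped codon {codon!r}")
    if codon in STANDARD_STOPS:
        raise SiteError(f"stop codon {codon!r} has no site decomposition")
    aa = translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        weights: list[float] = []
        syn_flags: list[bool] = []
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STANDARD_STOPS:
                continue
            weights.append(2.0 * r if is_transition(codon[pos], base) else 1.0)
            syn_flags.append(translate_codon(mutant) == aa)
        total = sum(weights)
        if total == 0.0:
            continue  # all mutants are stops: position contributes nothing
        syn += sum(w for w, f in zip(weights, syn_flags) if f) / total
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def ng86_codon_differences(c1: str, c2: str) -> tuple[float, float, bool]:
    """Pathway-averaged synonymous/nonsynonymous difference counts.

    Enumerates all orderings of the differing positions, drops pathways that
    pass through a stop codon, labels each remaining step syn/nonsyn and
    averages with equal pathway weight.  When every pathway passes through a
    stop, falls back to including stop pathways and sets the returned flag.

    Returns (syn_diffs, nonsyn_diffs, used_stop_pathways).
    """
    for c in (c1, c2):
        if set(c) - set(BASES):
            raise SiteError(f"ambiguous or gapped codon {c!r}")
        if c in STANDARD_STOPS:
            raise SiteError(f"stop codon {c!r} not allowed")
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return 0.0, 0.0, False

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        syn = nonsyn = 0.0
        current = c1
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STANDARD_STOPS and nxt != c2 and not allow_stops:
                return None
            if (
                nxt not in STANDARD_STOPS
                and current not in STANDARD_STOPS
                and translate_codon(nxt) == translate_codon(current)
            ):
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        return syn, nonsyn

    orders = list(permutations(diff_positions))
    results = [res for order in orders if (res := walk(order, False)) is not None]
    fallback = False
    if not results:
        fallback = True
        results = [walk(order, True) for order in orders]
    syn = sum(rs for rs, _ in results) / len(results)
    nonsyn = sum(rn for _, rn in results) / len(results)
    return syn, nonsyn, fallback


def jc69_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0.0:
        raise ValueError(f"negative proportion {p}")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} >= 0.75: distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _codon_ok(codon: str) -> bool:
    return not (set(codon) - set(BASES)) and codon not in STANDARD_STOPS


def _pair_dnds(
    codons1: Sequence[str],
    codons2: Sequence[str],
    indices: Iterable[int],
    r: float,
) -> tuple[float, float] | None:
    """JC-corrected (dN, dS) for one sequence pair over the given codon columns.

    Codons containing gaps/N or stops in either sequence are dropped pairwise;
    site counts are averaged over the two sequences.  Returns None when no
    codon is comparable or either proportion is saturated.
    """
    syn_sites = nonsyn_sites = 0.0
    syn_diffs = nonsyn_diffs = 0.0
    any_codon = False
    for idx in indices:
        ca, cb = codons1[idx], codons2[idx]
        if not (_codon_ok(ca) and _codon_ok(cb)):
            continue
        any_codon = True
        sa, na = ng86_site_counts(ca, r)
        sb, nb = ng86_site_counts(cb, r)
        syn_sites += (sa + sb) / 2.0
        nonsyn_sites += (na + nb) / 2.0
        sd, nd, _ = ng86_codon_differences(ca, cb)
        syn_diffs += sd
        nonsyn_diffs += nd
    if not any_codon:
        return None
    try:
        dn = jc69_correct(nonsyn_diffs / nonsyn_sites) if nonsyn_sites > 0 else math.nan
        ds = jc69_correct(syn_diffs / syn_sites) if syn_sites > 0 else math.nan
    except SaturationError:
        return None
    return dn, ds


def _group_dnds(
    codon_rows: list[list[str]], indices: Sequence[int], r: float
) -> tuple[float, float]:
    """Mean over sequence pairs of per-pair JC-corrected dN and dS."""
    dns: list[float] = []
    dss: list[float] = []
    for i, j in combinations(range(len(codon_rows)), 2):
        res = _pair_dnds(codon_rows[i], codon_rows[j], indices, r)
        if res is None:
            continue
        dn, ds = res
        if not math.isnan(dn):
            dns.append(dn)
        if not math.isnan(ds):
            dss.append(ds)
    dn = float(np.mean(dns)) if dns else math.nan
    ds = float(np.mean(dss)) if dss else math.nan
    return dn, ds


def partitioned_dnds(
    aln: CodonAlignment,
    scheme: PartitionScheme,
    group: str | Callable[[AlignedSequence], bool] | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    r: float = 0.5,
    partitions: Sequence[str] = ("PBR", "nonPBR", "all"),
) -> list[DnDsEstimate]:
    """Partitioned dN/dS for a group of sequences.

    `group` selects sequences: None (all), a clade name, or a predicate.
    Point estimates are means over sequence pairs of per-pair JC-corrected
    rates; standard errors come from `n_boot` bootstrap resamples of codon
    columns within each partition (`n_boot=0` reports SEs as None).
    """
    if group is None:
        members = list(aln.sequences)
        group_name = "all"
    elif callable(group):
        members = [s for s in aln.sequences if group(s)]
        group_name = getattr(group, "__name__", "custom")
    else:
        members = [s for s in aln.sequences if s.clade == group]
        group_name = group
    if len(members) < 2:
        raise SizeError(f"group {group_name!r} has fewer than 2 sequences")

    codon_rows = [s.codons() for s in members]
    index_map = scheme.partition_indices(aln.n_codons)
    rng = np.random.default_rng(seed)

    estimates: list[DnDsEstimate] = []
    for part in partitions:
        indices = sorted(index_map[part])
        if not indices:
            raise ValueError(f"partition {part!r} is empty")
        dn, ds = _group_dnds(codon_rows, indices, r)

        # average site counts over sequences for reporting site proportions
        syn_sites = nonsyn_sites = 0.0
        n_counted = 0
        for row in codon_rows:
            for idx in indices:
                if _codon_ok(row[idx]):
                    s, n = ng86_site_counts(row[idx], r)
                    syn_sites += s
                    nonsyn_sites += n
                    n_counted += 1
        se_dn = se_ds = None
        if n_boot > 0:
            boot_dn = []
            boot_ds = []
            for _ in range(n_boot):
                resampled = list(rng.choice(indices, size=len(indices), replace=True))
                bdn, bds = _group_dnds(codon_rows, resampled, r)
                boot_dn.append(bdn)
                boot_ds.append(bds)
            se_dn = float(np.nanstd(boot_dn, ddof=1))
            se_ds = float(np.nanstd(boot_ds, ddof=1))

        estimates.append(
            DnDsEstimate(
                partition=part,
                group=group_name,
                dn=dn,
                ds=ds,
                se_dn=se_dn,
                se_ds=se_ds,
                n_sites_syn=syn_sites / max(n_counted, 1) * len(indices) if n_counted else math.nan,
                n_sites_nonsyn=nonsyn_sites / max(n_counted, 1) * len(indices) if n_counted else math.nan,
                n_pairs=len(members) * (len(members) - 1) // 2,
            )
        )
    return estimates


def dnds_table(estimates: Iterable[DnDsEstimate]):
    """Long-format table of estimates (rows: partition x group)."""
    import pandas as pd

    rows = []
    for e in estimates:
        total = e.n_sites_syn + e.n_sites_nonsyn
        rows.append(
            {
                "partition": e.partition,
                "group": e.group,
                "dN": e.dn,
                "dS": e.ds,
                "se_dN": e.se_dn,
                "se_dS": e.se_ds,
                "omega": e.omega,
                "prop_nonsyn_sites": e.n_sites_nonsyn / total if total else math.nan,
                "prop_syn_sites": e.n_sites_syn / total if total else math.nan,
                "n_pairs": e.n_pairs,
            }
        )
    return pd.DataFrame(rows)
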