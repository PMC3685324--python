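"""End-to-end orchestration: from alignment + metadata to report tables.

Stages: read -> per-species allele filtering -> diversity table ->
pooled partitioned dN/dS per clade -> NJ tree with bootstrap -> per-clade
species-clustering permutation tests -> GC profiles and Welch tests ->
outgroup pruning, ultrametricization and Brownian-motion clade-model table.
Every stage writes its outputs before the next begins, so a failure leaves
partial results in place.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import mhcev
from mhcev import basecomp, bm_clades, diversity, parsimony_test, phylo, selection, seqio
from mhcev.errors import MhcevError
from mhcev.seqio import CodonAlignment


@dataclass
class RunConfig:
    alignment: Path
    metadata: Path
    outdir: Path
    partition_file: Path | None = None
    frame_offset: int = 4
    model: str = "TN93G"
    alpha: float = 0.78
    n_boot: int = 100
    n_rand: int = 1000
    stem_factors: tuple[float, ...] = (1.0, 0.5)
    seed: int = 0
    min_nt_diff: int = 3

    def scheme(self) -> selection.PartitionScheme:
        if self.partition_file is not None:
            return selection.PartitionScheme.from_file(
                self.partition_file, frame_offset=self.frame_offset
            )
        return selection.PartitionScheme.default_pbr(frame_offset=self.frame_offset)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Plain key=value config text; CLI overrides win."""
        kv: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                key, _, value = line.partition("=")
                kv[key.strip()] = value.strip()
        kwargs: dict = {}
        for key in ("alignment", "metadata", "outdir", "partition_file"):
            if key in kv:
                kwargs[key] = Path(kv[key])
        for key in ("frame_offset", "n_boot", "n_rand", "seed", "min_nt_diff"):
            if key in kv:
                kwargs[key] = int(kv[key])
        if "alpha" in kv:
            kwargs["alpha"] = float(kv["alpha"])
        if "model" in kv:
            kwargs["model"] = kv["model"]
        if "stem_factors" in kv:
            kwargs["stem_factors"] = tuple(
                float(x) for x in kv["stem_factors"].split(",")
            )
        kwargs.update(overrides)
        return cls(**kwargs)


class StageFailure(MhcevError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _log(msg: str) -> None:
    print(f"[{time.strftime('%H:%M:%S')}] {msg}", file=sys.stderr)


def filter_alignment(
    aln: CodonAlignment, min_nt_diff: int = 3
) -> tuple[CodonAlignment, list[seqio.SequenceClass]]:
    """Apply per-species allele filtering across the whole alignment.

    The outgroup is passed through unfiltered.
    """
    retained_ids: list[str] = []
    discarded: list[seqio.SequenceClass] = []
    for species, sub in aln.by_species().items():
        if sub.sequences[0].clade == "outgroup":
            retained_ids.extend(sub.ids())
            continue
        kept, dropped = seqio.filter_putative_alleles(sub.sequences, min_nt_diff)
        retained_ids.extend(s.id for s in kept)
        discarded.extend(dropped)
    return aln.subset(retained_ids), discarded


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the whole pipeline; returns the manifest dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": mhcev.__version__,
        "seed": cfg.seed,
        "config": {
            "alignment": str(cfg.alignment),
            "metadata": str(cfg.metadata),
            "model": cfg.model,
            "alpha": cfg.alpha,
            "frame_offset": cfg.frame_offset,
            "n_boot": cfg.n_boot,
            "n_rand": cfg.n_rand,
            "stem_factors": list(cfg.stem_factors),
            "min_nt_diff": cfg.min_nt_diff,
        },
        "stages": {},
    }
    scheme = cfg.scheme()
    stage = "read"
    try:
        t0 = time.time()
        aln = seqio.read_codon_alignment(cfg.alignment, cfg.metadata)
        manifest["stages"][stage] = {"seconds": time.time() - t0, "n_sequences": len(aln)}
        _log(f"read {len(aln)} sequences x {aln.n_codons} codons")

        stage = "filter"
        t0 = time.time()
        filtered, discarded = filter_alignment(aln, cfg.min_nt_diff)
        seqio.write_discard_report(discarded, outdir / "discarded.json")
        seqio.write_codon_alignment(
            filtered, outdir / "retained.fasta", outdir / "retained_metadata.tsv"
        )
        manifest["stages"][stage] = {
            "seconds": time.time() - t0,
            "n_retained": len(filtered),
            "n_discarded": len(discarded),
        }
        _log(f"retained {len(filtered)} putative alleles")

        stage = "diversity"
        t0 = time.time()
        by_species = {
            sp: sub
            for sp, sub in filtered.by_species().items()
            if sub.sequences[0].clade == "songbird"
        }
        div_table = diversity.species_diversity_table(by_species)
        omegas = {"omega_PBR": [], "omega_nonPBR": []}
        for sp in div_table["species"]:
            sub = by_species[sp]
            if len(sub) >= 2:
                ests = selection.partitioned_dnds(
                    sub, scheme, n_boot=0, partitions=("PBR", "nonPBR")
                )
                for est in ests:
                    omegas[f"omega_{est.partition}"].append(est.omega)
            else:
                omegas["omega_PBR"].append(None)
                omegas["omega_nonPBR"].append(None)
        for col, vals in omegas.items():
            div_table[col] = vals
        diversity.write_diversity_table(div_table, outdir / "table1_diversity.tsv")
        manifest["stages"][stage] = {"seconds": time.time() - t0, "n_species": len(div_table)}
        _log(f"diversity table for {len(div_table)} species")

        stage = "dnds"
        t0 = time.time()
        estimates = []
        for clade in ("songbird", "nonpasserine"):
            if len(filtered.by_clade(clade)) >= 2:
                estimates.extend(
                    selection.partitioned_dnds(
                        filtered, scheme, group=clade, n_boot=cfg.n_boot, seed=cfg.seed
                    )
                )
        selection.dnds_table(estimates).to_csv(
            outdir / "table2_dnds.tsv", sep="\t", index=False, float_format="%.4f"
        )
        manifest["stages"][stage] = {"seconds": time.time() - t0}
        _log("pooled partitioned dN/dS done")

        stage = "tree"
        t0 = time.time()
        tree = phylo.bootstrap_support(
            filtered, model=cfg.model, alpha=cfg.alpha, n=cfg.n_boot, seed=cfg.seed
        )
        phylo.write_newick(tree, outdir / "nj_tree.nwk")
        manifest["stages"][stage] = {
            "seconds": time.time() - t0,
            "n_bootstrap_used": getattr(tree, "n_bootstrap_used", 0),
        }
        _log("NJ tree + bootstrap done")

        stage = "permtest"
        t0 = time.time()
        perm_results = {}
        for clade in ("songbird", "nonpasserine"):
            sub = filtered.by_clade(clade)
            if len(sub) < 4:
                continue
            sub_tree = phylo.neighbor_joining(
                phylo.pairwise_distance(sub, model=cfg.model, alpha=cfg.alpha)
            )
            states = {s.id: s.species for s in sub}
            result = parsimony_test.species_clustering_test(
                sub_tree, states, n_rand=cfg.n_rand, seed=cfg.seed
            )
            result.to_json(outdir / f"permtest_{clade}.json")
            perm_results[clade] = {
                "observed": result.observed_steps,
                "null_min": result.null_min,
                "null_max": result.null_max,
                "p": result.p_value,
            }
        manifest["stages"][stage] = {"seconds": time.time() - t0, **perm_results}
        _log("permutation tests done")

        stage = "gc"
        t0 = time.time()
        gc = basecomp.gc_table(filtered)
        gc.to_csv(outdir / "gc_profiles.tsv", sep="\t", index=False, float_format="%.4f")
        tests = basecomp.clade_gc_tests(filtered)
        with (outdir / "gc_tests.json").open("w", encoding="utf-8") as fh:
            json.dump(
                {
                    name: {
                        "t": r.t, "df": r.df, "p": r.p,
                        "mean_songbird": r.mean_a, "mean_nonpasserine": r.mean_b,
                    }
                    for name, r in tests.items()
                },
                fh,
                indent=2,
            )
        manifest["stages"][stage] = {
            "seconds": time.time() - t0,
            "gc3_t": tests["gc3"].t,
            "gc3_p": tests["gc3"].p,
        }
        _log(f"GC tests done (gc3 t={tests['gc3'].t:.3f})")

        stage = "bmfit"
        t0 = time.time()
        outgroup_ids = [s.id for s in filtered if s.clade == "outgroup"]
        bm_input = tree
        if outgroup_ids:
            bm_input = phylo.prune_outgroup(tree, outgroup_ids[0])
            for extra in outgroup_ids[1:]:
                bm_input.prune_taxa_with_labels([extra], suppress_unifurcations=True)
        ultra = phylo.ultrametricize(bm_input)
        split = bm_clades.CladeSplit.from_iterables(
            (s.id for s in filtered if s.clade == "songbird"),
            (s.id for s in filtered if s.clade == "nonpasserine"),
        )
        gc_in = gc.set_index("id")
        for trait in ("gc3", "gc_all"):
            values = gc_in[trait].dropna().to_dict()
            rows = bm_clades.clade_model_table(
                ultra, values, split, stem_factors=cfg.stem_factors
            )
            bm_clades.clade_model_frame(rows).to_csv(
                outdir / f"table3_bm_{trait}.tsv", sep="\t", index=False,
                float_format="%.4f",
            )
        phylo.write_newick(ultra, outdir / "ultrametric_tree.nwk")
        manifest["stages"][stage] = {"seconds": time.time() - t0}
        _log("BM clade-model table done")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
        )
        raise StageFailure(stage, exc) from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return manifest
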