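"""End-to-end pipeline driver with a structured config and a run manifest.

Stages run in dependency order: simulate -> map -> trends -> lca ->
profile -> rarefy -> cazy.  All intermediates are files in the standard
formats of :mod:`rmorf.io_formats`; no stage mutates another stage's
outputs.  A single global seed is split deterministically per stage, so
rerunning an identical config reproduces identical outputs (checksummed
in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .errors import InputError
from . import cazy as cazy_mod
from . import io_formats as io
from . import mapping, profiles, simulate, taxonomy, trends

log = logging.getLogger(__name__)

STAGES = ("simulate", "map", "trends", "lca", "profile", "rarefy", "cazy")

_DEFAULTS: dict[str, dict[str, Any]] = {
    "simulate": {"preset": "fig1", "genome_length": 50_000, "gene_density": 0.5,
                 "error_rate": 0.002, "p_nohit": 0.128, "p_offtarget": 0.05},
    "map": {"max_mismatches": 2, "sam": None},
    "trends": {"read_length": 100, "k": "auto", "plot": None},
    "lca": {"min_score": 35.0, "top_percent": 10.0, "min_support": 5,
            "discard_rank": "root"},
    "profile": {"rank": "phylum"},
    "rarefy": {"reps": 100, "n_depths": 10},
    "cazy": {"evalue": 1e-4, "map": None},
}


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(source: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    """Load and validate a pipeline config (YAML file or mapping)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(source)
    if not isinstance(cfg, dict):
        raise InputError("config must be a mapping")
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", list(STAGES))
    if cfg["stages"] == "all":
        cfg["stages"] = list(STAGES)
    unknown = [s for s in cfg["stages"] if s not in STAGES]
    if unknown:
        raise InputError(f"unknown stages in config: {unknown}")
    cfg["stages"] = sorted(set(cfg["stages"]), key=STAGES.index)
    for stage in STAGES:
        merged = dict(_DEFAULTS[stage])
        user = cfg.get(stage) or {}
        if not isinstance(user, dict):
            raise InputError(f"config section {stage!r} must be a mapping")
        bad = set(user) - set(merged)
        if bad:
            raise InputError(f"unknown keys in config section {stage!r}: {sorted(bad)}")
        merged.update(user)
        cfg[stage] = merged
    return cfg


def _preflight(cfg: dict[str, Any]) -> None:
    """Validate every referenced input path before any stage runs."""
    for stage, key in (("map", "sam"), ("cazy", "map")):
        path = cfg[stage].get(key)
        if path is not None and not Path(path).exists():
            raise InputError(f"config {stage}.{key}: input path {path!r} does not exist")


def run_pipeline(config: str | Path | Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Run the configured stages, writing outputs and a manifest under ``outdir``.

    Returns the manifest dict (also written as manifest.json).
    """
    cfg = load_config(config)
    _preflight(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "config": {k: cfg[k] for k in ("seed", "stages", *STAGES)},
        "stages": {},
    }

    state: dict[str, Any] = {}

    def record(stage: str, outputs: dict[str, Path], params: Mapping[str, Any]) -> None:
        manifest["stages"][stage] = {
            "seed": _stage_seed(seed, stage),
            "params": dict(params),
            "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                        for name, p in outputs.items()},
        }

    for stage in cfg["stages"]:
        params = cfg[stage]
        if stage == "simulate":
            spec = simulate.fig1_preset(
                seed=_stage_seed(seed, stage),
                genome_length=int(params["genome_length"]),
                gene_density=float(params["gene_density"]),
                error_rate=float(params["error_rate"]),
                p_nohit=float(params["p_nohit"]),
                p_offtarget=float(params["p_offtarget"]),
            )
            comm = simulate.build_community(spec)
            r1, r2, read_truth = simulate.simulate_reads(comm)
            phits = simulate.simulate_protein_hits(comm)
            dmap = cazy_mod.load_cazy_map(params.get("map"))
            dhits, _dtruth = simulate.simulate_domain_hits(
                comm.orfs, dmap, seed=_stage_seed(seed, "simulate.domains"),
                family_weights={"GH9": 3, "CBM3": 3, "GH3": 2, "GH2": 2, "GH5": 1,
                                "GH10": 1, "GH48": 1, "CBM6": 1},
            )
            out = {
                "genomes": outdir / "genomes.fna",
                "orfs_gff": outdir / "orfs.gff3",
                "orfs_fna": outdir / "orfs.fna",
                "reads_1": outdir / "reads_1.fastq",
                "reads_2": outdir / "reads_2.fastq",
                "taxonomy": outdir / "taxonomy.tsv",
                "orf_truth": outdir / "orf_truth.tsv",
                "protein_hits": outdir / "protein_hits.tsv",
                "domain_hits": outdir / "domain_hits.tsv",
            }
            io.write_fasta(out["genomes"], sorted(comm.genomes.items()))
            io.write_gff3_orfs(out["orfs_gff"], comm.orfs)
            io.write_fasta(out["orfs_fna"], sorted(comm.orf_seqs.items()))
            io.write_fastq(out["reads_1"], r1)
            io.write_fastq(out["reads_2"], r2)
            io.write_taxonomy_table(out["taxonomy"], comm.tree)
            io.write_orf_taxa(out["orf_truth"], comm.truth)
            io.write_protein_hits(out["protein_hits"], phits)
            io.write_domain_hits(out["domain_hits"], dhits)
            state.update(community=comm, r1=r1, r2=r2)
            record(stage, out, params)

        elif stage == "map":
            comm = state.get("community")
            orf_gff = outdir / "orfs.gff3"
            if comm is None and not orf_gff.exists():
                raise InputError("map stage needs the simulate stage (or its outputs) first")
            orfs = comm.orfs if comm else io.read_gff3_orfs(orf_gff)
            orf_index = {o.orf_id: o for o in orfs}
            if params.get("sam"):
                alns = io.read_sam_alignments(params["sam"], orf_index,
                                              int(params["max_mismatches"]))
            else:
                orf_seqs = comm.orf_seqs if comm else dict(io.read_fasta(outdir / "orfs.fna"))
                reads = [(rid, seq) for rid, seq, _q in state.get("r1", [])] + \
                        [(rid, seq) for rid, seq, _q in state.get("r2", [])]
                if not reads:
                    reads = [(rid, seq) for rid, seq, _q in io.read_fastq(outdir / "reads_1.fastq")]
                    reads += [(rid, seq) for rid, seq, _q in io.read_fastq(outdir / "reads_2.fastq")]
                alns = mapping.align_reads(reads, orf_seqs, int(params["max_mismatches"]))
            counts = mapping.count_reads_per_orf(alns, orf_index)
            out = {"counts": outdir / "counts.tsv"}
            io.write_counts_table(out["counts"], counts, orf_index)
            state.update(counts=counts, orfs=orf_index)
            record(stage, out, params)

        elif stage == "trends":
            table = io.read_counts_table(outdir / "counts.tsv")
            r = int(params["read_length"])
            pts = [trends.OrfCoveragePoint.make(o, L, n, r) for o, (L, n) in table.items()]
            if params["k"] == "auto":
                model = trends.select_num_trends(pts, read_length=r,
                                                 seed=_stage_seed(seed, stage))
            else:
                model = trends.fit_trend_mixture(pts, int(params["k"]), read_length=r,
                                                 seed=_stage_seed(seed, stage))
            out = {"model": outdir / "trend_model.json"}
            model.to_json(out["model"])
            if params.get("plot"):
                plot_path = outdir / str(params["plot"])
                trends.plot_trends(pts, model, plot_path)
                out["plot"] = plot_path
            state.update(trend_model=model, points=pts)
            record(stage, out, params)

        elif stage == "lca":
            tree = io.read_taxonomy_table(outdir / "taxonomy.tsv")
            hits = io.read_tabular_hits(outdir / "protein_hits.tsv", "protein")
            lca_params = taxonomy.LcaParams(
                min_score=float(params["min_score"]),
                top_percent=float(params["top_percent"]),
                min_support=int(params["min_support"]),
                discard_rank=str(params["discard_rank"]),
            )
            assignments, _counts = taxonomy.assign_orf_taxonomy(hits, tree, lca_params)
            out = {"orf_taxa": outdir / "orf_taxa.tsv"}
            io.write_orf_taxa(out["orf_taxa"], assignments)
            state.update(tree=tree, orf_taxa=assignments)
            record(stage, out, params)

        elif stage == "profile":
            tree = state.get("tree") or io.read_taxonomy_table(outdir / "taxonomy.tsv")
            orf_taxa = state.get("orf_taxa") or io.read_orf_taxa(outdir / "orf_taxa.tsv")
            table = io.read_counts_table(outdir / "counts.tsv")
            counts = {o: n for o, (_L, n) in table.items()}
            rank = str(params["rank"])
            p_reads = profiles.read_weighted_profile(orf_taxa, counts, tree, rank)
            p_orfs = profiles.orf_count_profile(orf_taxa, tree, rank)
            out = {"profile_reads": outdir / "profile_reads.tsv",
                   "profile_orfs": outdir / "profile_orfs.tsv"}
            for path, prof in ((out["profile_reads"], p_reads), (out["profile_orfs"], p_orfs)):
                with open(path, "w") as fh:
                    fh.write(f"# rank={prof.rank}\tunit={prof.unit}\t"
                             f"assigned={prof.total_assigned:g}\tinput={prof.total_input:g}\n")
                    fh.write("# taxon\tweight\tproportion\n")
                    for t in sorted(prof.weights):
                        fh.write(f"{t}\t{prof.weights[t]:g}\t{prof.proportions[t]:.6f}\n")
            state.update(profile_reads=p_reads, profile_orfs=p_orfs)
            record(stage, out, params)

        elif stage == "rarefy":
            orf_taxa = state.get("orf_taxa") or io.read_orf_taxa(outdir / "orf_taxa.tsv")
            labels = [t for t in orf_taxa.values() if t != taxonomy.UNASSIGNED]
            if not labels:
                raise InputError("rarefy stage: no classified units")
            depths = profiles.default_depths(len(labels), int(params["n_depths"]))
            curve = profiles.rarefaction_curve(labels, depths, reps=int(params["reps"]),
                                               seed=_stage_seed(seed, stage))
            out = {"rarefaction": outdir / "rarefaction.tsv"}
            with open(out["rarefaction"], "w") as fh:
                fh.write("# depth\tmean_richness\tsd\texpected\n")
                for m in depths:
                    mean, sd = curve[m]
                    exp = profiles.expected_richness(labels, m)
                    fh.write(f"{m}\t{mean:.3f}\t{sd:.3f}\t{exp:.3f}\n")
            record(stage, out, params)

        elif stage == "cazy":
            cmap = cazy_mod.load_cazy_map(params.get("map"))
            dhits = io.read_tabular_hits(outdir / "domain_hits.tsv", "domain")
            anns, fam_counts = cazy_mod.screen_domain_hits(dhits, cmap,
                                                           float(params["evalue"]))
            out = {"annotations": outdir / "cazy_annotations.tsv",
                   "families": outdir / "cazy_families.tsv"}
            with open(out["annotations"], "w") as fh:
                fh.write("# orf_id\tn_modules\tfamilies\n")
                for ann in anns:
                    fams = ",".join(m[0] for m in ann.modules)
                    fh.write(f"{ann.orf_id}\t{len(ann.modules)}\t{fams}\n")
            cazy_mod.write_family_table(out["families"], fam_counts, anns, cmap)
            record(stage, out, params)

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    log.info("pipeline complete: %d stages, manifest at %s",
             len(manifest["stages"]), manifest_path)
    return manifest
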