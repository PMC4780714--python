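"""End-to-end workflow: run every analysis stage and emit TSV report tables.

Outputs (one directory): region_stats.tsv, class_stats.tsv, gene_census.tsv,
introns.tsv, junctions.tsv, ssrs.tsv, tandem_repeats.tsv,
dispersed_repeats.tsv, intron_survey.tsv, screen_coding.tsv,
screen_noncoding.tsv, tree.nwk and manifest.json.  Outputs carry no
timestamps, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import composition, intron_survey, repeats, structure, variability
from .parsimony import bootstrap, concatenate_genes, mp_search
from .plastome_io import AnnotatedPlastome, read_genbank

log = logging.getLogger(__name__)

ALL_STAGES = ("structure", "composition", "repeats", "intron_survey",
              "screen", "phylogeny")


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the study's stated parameterization
    (SSR thresholds 8/4/3/3/3, tandem score 50 / period <= 500, dispersed
    repeats >= 30 bp at Hamming <= 3, 1000/500 sliding windows, 200 bp
    minimum region length)."""

    input_paths: list = field(default_factory=list)
    stages: tuple = ALL_STAGES
    out_dir: str = "plastomekit_out"
    seed: int = 0
    min_ir_len: int = 10_000
    min_region_len: int = 200
    top_k: int = 10
    bootstrap_replicates: int = 0
    survey_gene: str = "rpl2"
    log_level: str = "INFO"


def _checksum(seq: str) -> str:
    return hashlib.md5(seq.encode()).hexdigest()


def _write(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig, genomes: dict[str, AnnotatedPlastome] | None = None):
    """Run the requested stages; returns a manifest dict (also written to disk).

    ``genomes`` may be passed directly (e.g. simulated); otherwise
    ``config.input_paths`` are read as GenBank flat files.  A failing stage is
    recorded in the manifest and the remaining stages still run.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if genomes is None:
        genomes = {}
        for p in config.input_paths:
            g = read_genbank(p)
            genomes[g.id] = g
    if not genomes:
        raise ValueError("no input genomes")

    manifest = {
        "parameters": asdict(config),
        "inputs": {name: {"length": len(g), "md5": _checksum(g.sequence)}
                   for name, g in genomes.items()},
        "stages": {},
    }

    rotated: dict[str, AnnotatedPlastome] = {}
    qmaps: dict[str, object] = {}

    def stage(name):
        return name in config.stages

    # ---------------- structure ----------------
    try:
        rows_r, rows_j = [], []
        for name, g in genomes.items():
            rg, qmap = structure.detect_inverted_repeat(g, config.min_ir_len)
            rotated[name] = rg
            qmaps[name] = qmap if isinstance(qmap, structure.QuadripartiteMap) else None
            if qmaps[name] and stage("structure"):
                q = qmaps[name]
                n = len(rg)
                rows_r.append({"genome": name, "LSC": q.lsc.length(n),
                               "SSC": q.ssc.length(n), "IR": q.ir_length,
                               "total": n})
                if rg.features:
                    for ev in structure.junction_report(rg, q):
                        rows_j.append({"genome": name, **asdict(ev)})
        if stage("structure"):
            _write(pd.DataFrame(rows_r), out / "quadripartite.tsv")
            _write(pd.DataFrame(rows_j), out / "junctions.tsv")
            manifest["stages"]["structure"] = "ok"
    except Exception as exc:  # noqa: BLE001 - partial-failure contract
        log.exception("structure stage failed")
        manifest["stages"]["structure"] = f"failed: {exc}"

    # ---------------- composition ----------------
    if stage("composition"):
        try:
            r1, r2, r3, r4 = [], [], [], []
            for name in genomes:
                g, q = rotated[name], qmaps[name]
                if q:
                    for rs in composition.region_stats(g, q):
                        r1.append({"genome": name, "region": rs.region,
                                   "length_bp": rs.length_bp,
                                   "gc_percent": round(rs.gc_percent, 2),
                                   "length_percent": round(rs.length_percent_of_total, 2)})
                if g.features:
                    for cs in composition.class_stats(g):
                        r2.append({"genome": name, "class": cs.cls,
                                   "length_bp": cs.length_bp,
                                   "gc_percent": round(cs.gc_percent, 2),
                                   "length_percent": round(cs.length_percent, 2)})
                    if q:
                        c = composition.gene_census(g, q)
                        r3.append({"genome": name, "total_genes": c.total_genes,
                                   "protein_coding": c.by_class.get("CDS", 0),
                                   "tRNA": c.by_class.get("tRNA", 0),
                                   "rRNA": c.by_class.get("rRNA", 0),
                                   "duplicated_in_IR": c.duplicated_in_IR,
                                   "unique_genes": c.unique_genes,
                                   "unique_LSC": c.unique_by_region["LSC"],
                                   "unique_SSC": c.unique_by_region["SSC"],
                                   "unique_IR": c.unique_by_region["IR"],
                                   "boundary_spanning": ",".join(c.boundary_spanning)})
                        for rec in composition.intron_inventory(g, q):
                            r4.append({"genome": name, "gene": rec.gene,
                                       "region": rec.region,
                                       "exon_lengths": ",".join(map(str, rec.exon_lengths)),
                                       "intron_lengths": ",".join(map(str, rec.intron_lengths)),
                                       "trans_spliced": rec.trans_spliced,
                                       "nested_genes": ",".join(rec.nested_genes)})
            _write(pd.DataFrame(r1), out / "region_stats.tsv")
            _write(pd.DataFrame(r2), out / "class_stats.tsv")
            _write(pd.DataFrame(r3), out / "gene_census.tsv")
            _write(pd.DataFrame(r4), out / "introns.tsv")
            manifest["stages"]["composition"] = "ok"
        except Exception as exc:  # noqa: BLE001
            log.exception("composition stage failed")
            manifest["stages"]["composition"] = f"failed: {exc}"

    # ---------------- repeats ----------------
    if stage("repeats"):
        try:
            rs_, rt_, rd_ = [], [], []
            for name in genomes:
                g, q = rotated[name], qmaps[name]
                seq, rmap = repeats.analysis_sequence(g, q)
                for h in repeats.find_ssrs(seq, features=g.features, region_map=rmap):
                    rs_.append({"genome": name, **asdict(h)})
                for h in repeats.find_tandem_repeats(seq, region_map=rmap):
                    d = asdict(h)
                    rt_.append({"genome": name, **d})
                for h in repeats.merge_overlapping(repeats.find_dispersed_repeats(seq)):
                    rd_.append({"genome": name, **asdict(h)})
            _write(pd.DataFrame(rs_), out / "ssrs.tsv")
            _write(pd.DataFrame(rt_), out / "tandem_repeats.tsv")
            _write(pd.DataFrame(rd_), out / "dispersed_repeats.tsv")
            manifest["stages"]["repeats"] = "ok"
        except Exception as exc:  # noqa: BLE001
            log.exception("repeats stage failed")
            manifest["stages"]["repeats"] = f"failed: {exc}"

    # ---------------- intron survey ----------------
    if stage("intron_survey"):
        try:
            rows = intron_survey.survey_genomes(
                {n: rotated[n] for n in genomes}, gene=config.survey_gene)
            _write(pd.DataFrame(rows), out / "intron_survey.tsv")
            manifest["stages"]["intron_survey"] = "ok"
        except Exception as exc:  # noqa: BLE001
            log.exception("intron survey stage failed")
            manifest["stages"]["intron_survey"] = f"failed: {exc}"

    # ---------------- marker screen ----------------
    if stage("screen"):
        if len(genomes) < 3:
            log.info("screen stage skipped: needs >= 3 genomes, got %d", len(genomes))
            manifest["stages"]["screen"] = "skipped: needs >= 3 genomes"
        else:
            try:
                stats, wstats, topc, topn = variability.screen_genomes(
                    {n: rotated[n] for n in genomes},
                    min_len=config.min_region_len, k=config.top_k,
                    seed=config.seed)
                cols = ["region_name", "region_class", "length_in_reference",
                        "aligned_length", "conserved_sites",
                        "parsimony_informative", "pic_percent", "retention_index"]
                for rows, fname in ((topc, "screen_coding.tsv"),
                                    (topn, "screen_noncoding.tsv")):
                    df = pd.DataFrame([{c: getattr(s, c) for c in cols} for s in rows])
                    df.insert(0, "No.", range(1, len(df) + 1))
                    _write(df, out / fname)
                _write(pd.DataFrame([{c: getattr(s, c) for c in cols}
                                     for s in stats + wstats]),
                       out / "screen_all.tsv")
                manifest["stages"]["screen"] = "ok"
            except Exception as exc:  # noqa: BLE001
                log.exception("screen stage failed")
                manifest["stages"]["screen"] = f"failed: {exc}"

    # ---------------- phylogeny ----------------
    if stage("phylogeny"):
        if len(genomes) < 4:
            manifest["stages"]["phylogeny"] = "skipped: needs >= 4 genomes"
        else:
            try:
                regions = variability.extract_shared_regions(
                    {n: rotated[n] for n in genomes}, min_len=config.min_region_len)
                per_gene = {}
                for reg in regions:
                    if reg.region_class != "CDS":
                        continue
                    aln = variability.align_region(reg.sequences, reg.name, "CDS")
                    per_gene[reg.name] = aln.sequences
                supermatrix, parts = concatenate_genes(per_gene)
                if config.bootstrap_replicates > 0:
                    tree = bootstrap(supermatrix, config.bootstrap_replicates,
                                     seed=config.seed)
                    score = mp_search(supermatrix, seed=config.seed).best_score
                else:
                    res = mp_search(supermatrix, seed=config.seed)
                    tree, score = res.best_trees[0], res.best_score
                with open(out / "tree.nwk", "w") as fh:
                    fh.write(tree.newick() + "\n")
                manifest["stages"]["phylogeny"] = "ok"
                manifest["phylogeny"] = {
                    "genes": len(per_gene),
                    "supermatrix_columns": sum(e - s for s, e in parts.values()),
                    "parsimony_score": score,
                }
            except Exception as exc:  # noqa: BLE001
                log.exception("phylogeny stage failed")
                manifest["stages"]["phylogeny"] = f"failed: {exc}"

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
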