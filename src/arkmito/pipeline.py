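"""End-to-end orchestration: io -> URs -> repeats -> ORFs -> screening ->
families -> Ka/Ks -> TPM -> ancestral states, with a JSON run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .expression import compute_tpm, read_counts_tsv, write_expression_tsv
from .genome_io import GenomeRecord, read_genbank, write_gff3
from .homology import cluster_families, presence_matrix, write_presence_matrix
from .orf_scan import LORF_THRESHOLD, find_orfs, write_orf_table
from .selection import align_cds_pair, batch_kaks, ng86, write_kaks_table
from .size_evolution import bm_ancestral, read_newick, size_trait_table, write_node_states
from .ur_analysis import (
    extract_urs,
    label_shared_urs,
    repeat_statistics,
    ur_report,
    write_repeats_bed,
    write_ur_report,
    find_tandem_repeats,
)

log = logging.getLogger("arkmito")


@dataclass
class RunConfig:
    """Stage parameters; defaults are the study conditions."""

    genbank_paths: list = field(default_factory=list)
    counts_path: str | None = None
    tree_path: str | None = None
    out_dir: str = "arkmito_out"
    seed: int = 0
    min_nt: int = 75
    starts: tuple = ("ATG", "ATA", "ATT", "GTG")
    lorf_threshold: int = LORF_THRESHOLD
    max_period: int = 300
    min_ident: float = 30.0
    complete_cov: float = 90.0
    partial_cov: float = 30.0
    family_min_ident: float = 28.0
    kaks_pair: tuple | None = None  # (genome_id_A, genome_id_B)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _ur_sequences(rec: GenomeRecord):
    urs = label_shared_urs(extract_urs(rec), rec)
    for ur in urs:
        seq = (rec.sequence[ur.start :] + rec.sequence[: ur.end]
               if ur.wraps else rec.sequence[ur.start : ur.end])
        yield ur, seq


def run_all(cfg: RunConfig) -> dict:
    """Run every applicable stage; returns a manifest of outputs."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg).items()
        },
        "inputs": {},
        "stages": [],
    }
    recs: list[GenomeRecord] = []
    for p in cfg.genbank_paths:
        manifest["inputs"][str(p)] = _sha256(Path(p))
        recs.extend(read_genbank(p))
    log.info("loaded %d genomes", len(recs))

    if recs:
        write_ur_report(ur_report(recs), out / "ur_report.tsv")
        manifest["stages"].append("urs")

        with open(out / "repeat_stats.tsv", "w") as fh:
            fh.write("genome_id\trepeat_count\trepeat_total_len\tpct_of_urs\n")
            for row in repeat_statistics(recs, max_period=cfg.max_period):
                fh.write("{genome_id}\t{repeat_count}\t{repeat_total_len}\t{pct_of_urs}\n".format(**row))
        for rec in recs:
            reps = find_tandem_repeats(rec.sequence, max_period=cfg.max_period)
            write_repeats_bed(reps, rec.id, out / f"repeats.{rec.id}.bed")
        manifest["stages"].append("repeats")

        all_orfs = []
        orf_proteins: dict[str, dict[str, str]] = {}
        for rec in recs:
            orf_proteins[rec.id] = {}
            for ur, seq in _ur_sequences(rec):
                if len(seq) < cfg.min_nt:
                    continue
                for orf in find_orfs(seq, min_nt=cfg.min_nt, starts=cfg.starts,
                                     lorf_threshold=cfg.lorf_threshold,
                                     genome_id=rec.id, region_label=ur.label,
                                     region_start=ur.start):
                    all_orfs.append(orf)
                    if orf.protein:
                        orf_proteins[rec.id][orf.name] = orf.protein
        write_orf_table(all_orfs, out / "orf_table.tsv")
        write_gff3(recs, out / "genomes.gff3")
        manifest["stages"].append("orfs")

        if len(recs) > 1 and orf_proteins.get(recs[0].id):
            queries = orf_proteins[recs[0].id]
            matrix = presence_matrix(queries, recs[1:], min_ident=cfg.min_ident,
                                     complete_cov=cfg.complete_cov,
                                     partial_cov=cfg.partial_cov)
            write_presence_matrix(matrix, out / "presence_matrix.tsv")
            manifest["stages"].append("screen")

        if orf_proteins.get(recs[0].id):
            fams = cluster_families(orf_proteins[recs[0].id],
                                    family_min_ident=cfg.family_min_ident)
            with open(out / "orf_families.tsv", "w") as fh:
                fh.write("family\tmembers\n")
                for i, f in enumerate(fams):
                    fh.write(f"F{i + 1}\t{','.join(f.members)}\n")
            manifest["stages"].append("families")

    if cfg.kaks_pair and len(recs) >= 2:
        by_id = {r.id: r for r in recs}
        a, b = by_id[cfg.kaks_pair[0]], by_id[cfg.kaks_pair[1]]
        pairs = []
        for f in a.features:
            if f.kind != "CDS":
                continue
            g = b.feature_by_name(f.name)
            if g is None:
                log.warning("ortholog %s missing in %s; skipped", f.name, b.id)
                continue
            from .genome_io import feature_sequence

            pairs.append((f.name, "PCG", feature_sequence(a, f), feature_sequence(b, g)))
        rows, summary = batch_kaks(pairs)
        write_kaks_table(rows, out / "kaks.tsv")
        (out / "kaks_summary.json").write_text(json.dumps(summary, indent=1))
        manifest["stages"].append("kaks")

    if cfg.counts_path:
        manifest["inputs"][cfg.counts_path] = _sha256(Path(cfg.counts_path))
        table = read_counts_tsv(cfg.counts_path)
        write_expression_tsv(compute_tpm(table), out / "tpm.tsv")
        manifest["stages"].append("tpm")
    else:
        log.info("no counts table given; TPM stage skipped")

    if cfg.tree_path and recs:
        manifest["inputs"][cfg.tree_path] = _sha256(Path(cfg.tree_path))
        tree = read_newick(cfg.tree_path)
        est = bm_ancestral(tree, size_trait_table(recs))
        write_node_states(est, out / "ancestral_states.tsv")
        manifest["stages"].append("anc")
    elif cfg.tree_path:
        log.info("tree given but no genomes; ancestral stage skipped")

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
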