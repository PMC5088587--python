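"""Stage orchestration: simulate -> identify -> phylo -> orthologs -> kaks
-> express, with a stable output layout and a run manifest.

Output layout under ``outdir``::

    inputs/       simulated or user-provided sequence/count inputs
    truth/        planted ground truth (when simulated)
    catalog/      family catalog and architecture report
    phylo/        NJ tree (Newick, bootstrap supports) and distance matrix
    homology/     orthologue and paralogue pair tables
    kaks/         Ka/Ks table and molecular-clock dating
    expression/   RPKM, log2-RPKM, calls, summary, qPCR folds
    manifest.json config hash, seed, version, stage timings
"""

from __future__ import annotations

import json
import logging
import math
import time
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import expression as expr
from . import homology, molevol, motifs, phylogeny, sequence_io
from .config import PipelineConfig
from .simulate import FamilySimConfig, simulate_three_genome_scenario

log = logging.getLogger("tifykit")


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _timed(stage: str):
    def decorator(fn):
        def wrapper(cfg: PipelineConfig, *args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(cfg, *args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # tag errors with the failing stage
                raise StageError(stage, str(exc)) from exc
            elapsed = time.perf_counter() - t0
            log.info("stage %-10s done in %.2f s", stage, elapsed)
            _TIMINGS[stage] = round(elapsed, 3)
            return result
        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper
    return decorator


_TIMINGS: dict[str, float] = {}


def _outdir(cfg: PipelineConfig, sub: str) -> Path:
    path = Path(cfg.outdir) / sub
    path.mkdir(parents=True, exist_ok=True)
    return path


def _input_path(cfg: PipelineConfig, key: str, default: str) -> Path:
    if key in cfg.inputs:
        return Path(cfg.inputs[key])
    return Path(cfg.outdir) / "inputs" / default


def _sim_config(cfg: PipelineConfig) -> FamilySimConfig:
    overrides = dict(cfg.sim)
    for key in ("background_length_aa", "genomes", "conditions", "timepoints",
                "baseline_rpkm_range", "est_identity_range"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    return FamilySimConfig(seed=cfg.seed, **overrides)


def _genomes(cfg: PipelineConfig) -> tuple[str, ...]:
    return _sim_config(cfg).genomes


def _fixed(x: float | None, nd: int = 6) -> str:
    return "NA" if x is None or (isinstance(x, float) and not math.isfinite(x)) else f"{x:.{nd}f}"


# ---------------------------------------------------------------------------


@_timed("simulate")
def run_simulate(cfg: PipelineConfig):
    """Generate the full synthetic scenario and write every pipeline input
    plus the planted truth tables."""
    scenario = simulate_three_genome_scenario(_sim_config(cfg))
    inputs = _outdir(cfg, "inputs")
    truth_dir = _outdir(cfg, "truth")
    for genome in scenario.config.genomes:
        sequence_io.write_fasta(scenario.proteins[genome], inputs / f"proteins_{genome}.fasta")
        sequence_io.write_fasta(scenario.cds[genome], inputs / f"cds_{genome}.fasta")
    if scenario.msa is not None:
        sequence_io.write_fasta(
            [sequence_io.SequenceRecord(i, r, "protein")
             for i, r in zip(scenario.msa.ids, scenario.msa.rows)],
            inputs / "msa.fasta",
        )
    sequence_io.write_counts(scenario.counts, inputs / "counts.tsv")
    sequence_io.write_fasta(scenario.ests, inputs / "ests.fasta")
    sequence_io.write_gene_models(scenario.gene_models, inputs / "gene_models.tsv")
    expr.write_qpcr(scenario.qpcr, inputs / "qpcr.tsv")

    truth = scenario.truth
    pd.DataFrame(
        sorted(truth.subfamily.items()), columns=["gene_id", "subfamily"]
    ).to_csv(truth_dir / "subfamilies.tsv", sep="\t", index=False)
    pd.DataFrame(truth.paralog_pairs, columns=["gene_a", "gene_b"]).to_csv(
        truth_dir / "paralog_pairs.tsv", sep="\t", index=False
    )
    for (ga, gb), pairs in truth.ortholog_pairs.items():
        pd.DataFrame(pairs, columns=[ga, gb]).to_csv(
            truth_dir / f"ortholog_pairs_{ga}-{gb}.tsv", sep="\t", index=False
        )
    rows = []
    for gene, by_cond in truth.response.items():
        for cond, call in by_cond.items():
            rows.append({"gene_id": gene, "condition": cond, "response": call})
    pd.DataFrame(rows).to_csv(truth_dir / "response.tsv", sep="\t", index=False)
    return scenario


@_timed("identify")
def run_identify(cfg: PipelineConfig):
    """Scan the focal genome's proteins, classify subfamilies, extract TIFY
    hexamers and attach expressed-sequence evidence; write the catalog."""
    focal = _genomes(cfg)[0]
    proteins_path = _input_path(cfg, "proteins", f"proteins_{focal}.fasta")
    proteins = sequence_io.read_fasta(proteins_path, "protein")
    ests_path = _input_path(cfg, "ests", "ests.fasta")
    ests = sequence_io.read_fasta(ests_path, "dna") if ests_path.exists() else []
    cds_path = _input_path(cfg, "cds", f"cds_{focal}.fasta")
    cds = {r.id: r for r in sequence_io.read_fasta(cds_path, "dna")} if cds_path.exists() else {}

    models = motifs.default_motif_models()
    entries: list[sequence_io.CatalogEntry] = []
    arch_rows = []
    for prot in proteins:
        arch = motifs.scan_motifs(prot, models)
        for hit in arch.hits:
            arch_rows.append(
                {"protein_id": prot.id, "motif": hit.motif, "start": hit.start,
                 "end": hit.end, "score": round(hit.score, 2)}
            )
        subfamily = motifs.classify_subfamily(arch)
        if subfamily == "unassigned":
            continue
        hexamer = motifs.extract_tify_hexamer(arch, prot)
        evidence = []
        query = cds.get(prot.id, prot)
        support = motifs.evidence_support(query, ests) if ests else None
        if motifs.is_supported(support, cfg.evidence_identity_floor):
            evidence.append(
                sequence_io.Evidence(support.evidence_id, round(support.identity_pct, 1))
            )
        entries.append(
            sequence_io.CatalogEntry(prot.id, subfamily, len(prot.residues),
                                     hexamer, evidence)
        )
    if not entries:
        log.warning("identify: no TIFY-domain proteins found; catalog is empty")
    catalog_dir = _outdir(cfg, "catalog")
    sequence_io.write_catalog(entries, catalog_dir / "catalog.tsv")
    pd.DataFrame(
        arch_rows, columns=["protein_id", "motif", "start", "end", "score"]
    ).to_csv(catalog_dir / "architectures.tsv", sep="\t", index=False)
    hexamers = [e.tify_hexamer for e in entries]
    if hexamers:
        pfm = motifs.position_frequency_matrix(hexamers)
        sequence_io.write_tsv_matrix(pfm, catalog_dir / "tify_hexamer_pfm.tsv")
    return entries


@_timed("phylo")
def run_phylo(cfg: PipelineConfig):
    """NJ tree with bootstrap supports from the aligned family proteins."""
    msa_path = _input_path(cfg, "msa", "msa.fasta")
    records = sequence_io.read_fasta(msa_path, "protein")
    if len(records) < 3:
        log.warning("phylo: fewer than 3 aligned sequences; tree skipped")
        return None
    msa = phylogeny.MultipleAlignment.from_records(records)
    dm = phylogeny.pairwise_distance(msa, cfg.distance_model)
    tree, supports, redraws = phylogeny.bootstrap_support(
        msa, cfg.distance_model, cfg.bootstrap_replicates, cfg.seed
    )
    if redraws:
        log.info("phylo: %d bootstrap replicates redrawn", redraws)
    phylo_dir = _outdir(cfg, "phylo")
    phylogeny.write_newick(tree, phylo_dir / "tree.nwk")
    sequence_io.write_tsv_matrix(
        pd.DataFrame(dm.d, index=dm.ids, columns=dm.ids),
        phylo_dir / "distances.tsv",
    )
    return tree


@_timed("orthologs")
def run_orthologs(cfg: PipelineConfig):
    """Reciprocal-best-hit orthologues between genome pairs and paralogues
    within the focal genome."""
    genomes = _genomes(cfg)
    proteins = {
        g: sequence_io.read_fasta(
            _input_path(cfg, f"proteins_{g}", f"proteins_{g}.fasta"), "protein"
        )
        for g in genomes
    }
    scheme = homology.ScoringScheme()
    out = _outdir(cfg, "homology")
    ortho = {}
    for ga, gb in combinations(genomes, 2):
        pairs = homology.reciprocal_best_hits(
            proteins[ga], proteins[gb], scheme, cfg.ortholog
        )
        ortho[(ga, gb)] = pairs
        pd.DataFrame(pairs, columns=[ga, gb]).to_csv(
            out / f"orthologs_{ga}-{gb}.tsv", sep="\t", index=False
        )
    paralogs = homology.find_paralogs(proteins[genomes[0]], scheme, cfg.paralog)
    pd.DataFrame(paralogs, columns=["gene_a", "gene_b"]).to_csv(
        out / "paralogs.tsv", sep="\t", index=False
    )
    return ortho, paralogs


@_timed("kaks")
def run_kaks(cfg: PipelineConfig):
    """NG86 Ka/Ks for every detected pair, with molecular-clock dating per
    pair class."""
    genomes = _genomes(cfg)
    out_h = Path(cfg.outdir) / "homology"
    cds = {}
    prot = {}
    for g in genomes:
        for rec in sequence_io.read_fasta(_input_path(cfg, f"cds_{g}", f"cds_{g}.fasta"), "dna"):
            cds[rec.id] = rec
        for rec in sequence_io.read_fasta(
            _input_path(cfg, f"proteins_{g}", f"proteins_{g}.fasta"), "protein"
        ):
            prot[rec.id] = rec
    pair_classes: dict[str, list[tuple[str, str]]] = {}
    for ga, gb in combinations(genomes, 2):
        path = out_h / f"orthologs_{ga}-{gb}.tsv"
        if path.exists():
            df = pd.read_csv(path, sep="\t")
            pair_classes[f"{ga}-{gb}"] = [tuple(r) for r in df.itertuples(index=False)]
    para_path = out_h / "paralogs.tsv"
    if para_path.exists():
        df = pd.read_csv(para_path, sep="\t")
        pair_classes[f"{genomes[0]}-{genomes[0]}"] = [
            tuple(r) for r in df.itertuples(index=False)
        ]
    scheme = homology.ScoringScheme()
    rows = []
    dating_rows = []
    for pclass, pairs in pair_classes.items():
        ks_values = []
        for id_a, id_b in pairs:
            row_a, row_b = homology.global_alignment(prot[id_a], prot[id_b], scheme)
            aln = molevol.thread_codon_alignment(
                row_a, row_b, cds[id_a].residues, cds[id_b].residues, id_a, id_b
            )
            res = molevol.kaks(aln)
            ks_values.append(res.Ks)
            rows.append(
                {
                    "pair_class": pclass, "gene_a": id_a, "gene_b": id_b,
                    "S": _fixed(res.S_sites, 2), "N": _fixed(res.N_sites, 2),
                    "Sd": _fixed(res.Sd, 2), "Nd": _fixed(res.Nd, 2),
                    "Ka": _fixed(res.Ka, 4), "Ks": _fixed(res.Ks, 4),
                    "Ka_Ks": _fixed(res.omega, 4),
                    "selection": molevol.selection_class(res.omega),
                    "method": res.method,
                    "flags": ";".join(res.flags),
                }
            )
        if any(k is not None for k in ks_values):
            est = molevol.divergence_time(ks_values, cfg.lam)
            dating_rows.append(
                {
                    "pair_class": pclass, "n_pairs": est.n_pairs,
                    "mean_Ks": _fixed(est.ks_mean, 4),
                    "T_mya": est.T_mya, "T_mya_nearest": est.T_mya_nearest,
                    "n_excluded": est.n_excluded,
                }
            )
    out = _outdir(cfg, "kaks")
    pd.DataFrame(rows).to_csv(out / "kaks.tsv", sep="\t", index=False)
    pd.DataFrame(dating_rows).to_csv(out / "dating.tsv", sep="\t", index=False)
    return rows, dating_rows


@_timed("express")
def run_expression(cfg: PipelineConfig):
    """RPKM quantification, level/response calls, family summary and qPCR
    cross-validation."""
    counts = sequence_io.read_counts(_input_path(cfg, "counts", "counts.tsv"))
    rpkm_df = expr.rpkm(counts)
    sim = _sim_config(cfg)
    control = [s for s in rpkm_df.columns if s.startswith("control")]
    treatments: dict[str, dict[str, list[str]]] = {}
    for s in rpkm_df.columns:
        if s.startswith("control"):
            continue
        cond, tp, _rep = s.rsplit("_", 2)
        treatments.setdefault(cond, {}).setdefault(tp, []).append(s)
    if not control or not treatments:
        raise ValueError("counts must include control_* and <condition>_<tp>_<rep> samples")
    calls = expr.call_expression(
        rpkm_df, control, treatments, cfg.fold_threshold, cfg.pseudocount
    )
    summary = expr.summarize_profile(calls)
    out = _outdir(cfg, "expression")
    sequence_io.write_tsv_matrix(rpkm_df, out / "rpkm.tsv")
    sequence_io.write_tsv_matrix(
        np.log2(rpkm_df + cfg.pseudocount), out / "log2_rpkm.tsv"
    )
    call_rows = []
    for c in calls:
        row = {"gene_id": c.gene_id, "level": c.level}
        for cond in sorted(c.response):
            row[f"{cond}_response"] = c.response[cond]
            for tp, fold in sorted(c.fold_changes[cond].items()):
                row[f"{cond}_{tp}_fold"] = f"{fold:.4f}"
        call_rows.append(row)
    pd.DataFrame(call_rows).to_csv(out / "calls.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                "n_genes": summary.n_genes,
                "level_counts": summary.level_counts,
                "level_percent": summary.level_percent,
                "response_counts": summary.response_counts,
                "up_overlap": {f"{a}&{b}": v for (a, b), v in summary.up_overlap.items()},
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")

    qpcr_path = _input_path(cfg, "qpcr", "qpcr.tsv")
    if qpcr_path.exists():
        records = expr.read_qpcr(qpcr_path)
        qrows = []
        for rec in records:
            for sample in rec.cq_target:
                if sample == "control":
                    continue
                fold = expr.ddct_fold(rec, "control", sample)
                qrows.append(
                    {"gene_id": rec.gene_id, "sample": sample, "fold": f"{fold:.4f}"}
                )
        pd.DataFrame(qrows).to_csv(out / "qpcr_folds.tsv", sep="\t", index=False)
    return calls, summary


def run_all(cfg: PipelineConfig) -> dict:
    """Run simulate -> identify -> phylo -> orthologs -> kaks -> express and
    write the run manifest."""
    _TIMINGS.clear()
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    run_simulate(cfg)
    run_identify(cfg)
    run_phylo(cfg)
    run_orthologs(cfg)
    run_kaks(cfg)
    run_expression(cfg)
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "stages": dict(_TIMINGS),
    }
    with open(Path(cfg.outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
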