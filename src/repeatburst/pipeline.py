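"""End-to-end orchestration: simulate -> assemble -> landscape -> tau -> miRNA -> size.

Each stage reads only files named in the manifest of upstream stages and
writes its artifacts plus SHA-256 checksums into ``manifest.json``. All
randomness flows from the config seed, so a rerun with the same config is
byte-identical (the manifest records no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import simulate as sim
from .assembler import assemble_consensus, classify_consensus, recover_copies
from .config import PipelineConfig
from .cytometry import VICIA_FABA_2C_PG, CytometryMeasurement, genome_size_report
from .errors import InsufficientDataError, RepeatburstError
from .expression import compare_tau_groups, tau_table
from .io import (
    newick_string,
    read_fasta,
    read_flat_config,
    write_bed6,
    write_fasta,
    write_flat_config,
)
from .kmers import count_kmers
from .landscape import detect_bursts, domain_retention, pairwise_distances
from .mirna import count_family_copies, scan_genome_for_copies
from .phylo import nj_tree

log = logging.getLogger("repeatburst")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class RunReport:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.manifest: dict = {"stages": {}}

    def record(self, stage: str, params: dict, inputs: list[str], outputs: list[Path],
               status: str = "complete") -> None:
        self.manifest["stages"][stage] = {
            "status": status,
            "params": params,
            "inputs": sorted(inputs),
            "outputs": {p.name: _sha256(p) for p in sorted(outputs) if p.exists()},
        }

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")
        return path


def _stage_simulate(cfg: PipelineConfig, out: Path, report: RunReport) -> None:
    ages = cfg.burst_ages()
    copies_per = cfg.copies_per_burst()
    fam_specs = [
        sim.TEFamilySpec(
            family_id="harbinger_like",
            master_length=cfg.te_master_length,
            burst_ages=ages,
            copies_per_burst=copies_per,
            per_site_rate=cfg.te_rate,
            has_domain=True,
            domain_peptide=sim.MYB_LIKE_PEPTIDE,
        )
    ]
    if cfg.continuous_family:
        n = cfg.continuous_copies
        fam_specs.append(
            sim.TEFamilySpec(
                family_id="gypsy_like",
                master_length=max(1000, cfg.te_master_length - 500),
                burst_ages=[0.05 + 0.55 * i / max(n - 1, 1) for i in range(n)],
                copies_per_burst=[1] * n,
                per_site_rate=cfg.te_rate,
                has_domain=True,
                domain_peptide=sim.RT_LIKE_PEPTIDE,
            )
        )
    all_copies: list[str] = []
    all_ids: list[str] = []
    all_ages: list[float] = []
    masters: dict[str, str] = {}
    for i, spec in enumerate(fam_specs):
        fam = sim.simulate_te_copies(spec, seed=cfg.seed + 11 * i + 1)
        masters[spec.family_id] = fam.master
        all_copies += fam.copies
        all_ids += [spec.family_id] * len(fam.copies)
        all_ages += fam.ages

    mirna = sim.simulate_mirna_families(seed=cfg.seed + 101)
    all_copies += [s for _, s in mirna.precursors]
    all_ids += [pid.rsplit("_copy", 1)[0] for pid, _ in mirna.precursors]
    all_ages += [0.0] * len(mirna.precursors)

    genome, truth = sim.plant_copies_in_genome(
        cfg.background_length, all_copies, seed=cfg.seed + 202,
        family_ids=all_ids, ages=all_ages,
    )

    expr = sim.simulate_expression_matrix(
        cfg.n_genes, cfg.n_tissues, cfg.frac_specific, cfg.fold_effect,
        cfg.dispersion, seed=cfg.seed + 303,
    )
    sample_peak, ref_peak = sim.simulate_cytometry(
        cfg.true_2c_pg, noise_sd=cfg.cytometry_noise_sd, seed=cfg.seed + 404
    )

    write_fasta(out / "genome.fa", genome)
    write_bed6(out / "truth.bed", [
        (c.contig, c.start, c.end, c.family_id, int(round(c.age * 1000)), c.strand)
        for c in truth.copy_coordinates
    ])
    write_fasta(out / "reference.fa", masters)
    write_fasta(out / "mirna_matures.fa", {k: v.replace("U", "T").replace("u", "t")
                                           for k, v in mirna.matures.items()})
    pd.Series(mirna.truth_counts, name="planted_copies").rename_axis("family").to_csv(
        out / "mirna_truth.tsv", sep="\t"
    )
    expr.matrix.rename_axis("gene_id").to_csv(out / "expression.tsv", sep="\t")
    labels = pd.Series(
        {g: "specific" for g in expr.specific_gene_ids}
        | {g: "broad" for g in expr.broad_gene_ids},
        name="label",
    ).rename_axis("gene_id").sort_index()
    labels.to_csv(out / "gene_labels.tsv", sep="\t")
    write_flat_config(out / "cytometry.cfg", {
        "ref_2c_pg": VICIA_FABA_2C_PG,
        "ref_peak": ref_peak,
        "sample_peak": sample_peak,
    })
    report.record(
        "simulate",
        {"seed": cfg.seed, "background_length": cfg.background_length,
         "burst_ages": cfg.te_burst_ages, "copies_per_burst": cfg.te_copies_per_burst,
         "rate": cfg.te_rate},
        [],
        [out / f for f in ("genome.fa", "truth.bed", "reference.fa", "mirna_matures.fa",
                            "mirna_truth.tsv", "expression.tsv", "gene_labels.tsv",
                            "cytometry.cfg")],
    )


def _stage_assemble(cfg: PipelineConfig, out: Path, report: RunReport) -> list:
    genome_path = Path(cfg.genome) if cfg.genome else out / "genome.fa"
    genome = read_fasta(genome_path)
    table = count_kmers(genome, k=cfg.k)
    consensuses = assemble_consensus(
        table, min_count=cfg.min_count, min_length=cfg.min_length, max_length=cfg.max_length
    )
    with open(out / "consensus.fa", "w") as fh:
        for c in consensuses:
            fh.write(f">{c.consensus_id} depth={c.mean_depth:.1f} seed={c.seed_kmer}\n")
            for i in range(0, len(c.sequence), 60):
                fh.write(c.sequence[i : i + 60] + "\n")

    ref_path = Path(cfg.reference_library) if cfg.reference_library else out / "reference.fa"
    rows = []
    if ref_path.is_file():
        library = read_fasta(ref_path)
        for c in consensuses:
            label, stats = classify_consensus(c, library)
            rows.append({
                "consensus_id": c.consensus_id,
                "label": label,
                "align_length": stats.columns if stats else 0,
                "identity": round(stats.identity, 4) if stats else 0.0,
            })
    pd.DataFrame(rows).to_csv(out / "classification.tsv", sep="\t", index=False)
    report.record(
        "assemble",
        {"k": cfg.k, "min_count": cfg.min_count, "min_length": cfg.min_length,
         "max_length": cfg.max_length},
        [genome_path.name, ref_path.name],
        [out / "consensus.fa", out / "classification.tsv"],
    )
    return consensuses


def _stage_landscape(cfg: PipelineConfig, out: Path, report: RunReport, consensuses) -> None:
    genome_path = Path(cfg.genome) if cfg.genome else out / "genome.fa"
    genome = read_fasta(genome_path)
    burst_rows = []
    domain_rows = []
    bed_rows = []
    copy_records = []
    for c in consensuses[:2]:
        copies = recover_copies(
            genome, c, min_identity=cfg.min_identity, min_length=cfg.min_length
        )
        for cp in copies:
            bed_rows.append((cp.contig, cp.start, cp.end, c.consensus_id,
                             int(round(cp.identity_to_consensus * 1000)), cp.strand))
            copy_records.append((f"{c.consensus_id}_{cp.contig}_{cp.start}", cp.sequence))
        if len(copies) < 3:
            continue
        dm = pairwise_distances(copies, min_mutual_coverage=cfg.min_mutual_coverage)
        (out / f"distances_{c.consensus_id}.phy").write_text(dm.to_phylip())
        tree = nj_tree(dm)
        (out / f"tree_{c.consensus_id}.nwk").write_text(newick_string(tree) + "\n")
        try:
            rep = detect_bursts(dm.condensed(), margin=cfg.mixture_margin, seed=cfg.seed)
            burst_rows.append({
                "consensus_id": c.consensus_id,
                "n_modes": rep.n_modes,
                "mode_means": ";".join(f"{m:.4f}" for m in rep.mode_means),
                "mode_weights": ";".join(f"{w:.4f}" for w in rep.mode_weights),
            })
        except InsufficientDataError:
            pass
        ret = domain_retention(
            [cp.sequence for cp in copies],
            [("Myb_like", sim.MYB_LIKE_PEPTIDE), ("RT_like", sim.RT_LIKE_PEPTIDE)],
        )
        for label, frac in sorted(ret.items()):
            domain_rows.append({
                "consensus_id": c.consensus_id, "domain": label, "fraction_retained": round(frac, 4)
            })
    write_bed6(out / "copies.bed", bed_rows)
    write_fasta(out / "copies.fa", copy_records)
    pd.DataFrame(burst_rows).to_csv(out / "bursts.tsv", sep="\t", index=False)
    pd.DataFrame(domain_rows).to_csv(out / "domains.tsv", sep="\t", index=False)
    report.record(
        "landscape",
        {"min_identity": cfg.min_identity, "min_mutual_coverage": cfg.min_mutual_coverage,
         "mixture_margin": cfg.mixture_margin},
        [genome_path.name, "consensus.fa"],
        [out / "copies.bed", out / "copies.fa", out / "bursts.tsv", out / "domains.tsv"]
        + sorted(out.glob("distances_*.phy")) + sorted(out.glob("tree_*.nwk")),
    )


def _stage_tau(cfg: PipelineConfig, out: Path, report: RunReport) -> None:
    expr_path = Path(cfg.expression) if cfg.expression else out / "expression.tsv"
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    result = tau_table(expr, min_tpm=cfg.tau_floor)
    table = pd.DataFrame({"tau": result.tau.round(6), "max_tissue": result.max_tissue})
    table.rename_axis("gene_id").to_csv(out / "tau.tsv", sep="\t")
    rows = []
    labels_path = out / "gene_labels.tsv"
    if labels_path.is_file():
        labels = pd.read_csv(labels_path, sep="\t", index_col=0)["label"]
        spec = result.tau[labels.reindex(result.tau.index) == "specific"]
        broad = result.tau[labels.reindex(result.tau.index) == "broad"]
        if len(spec) >= 5 and len(broad) >= 5:
            cmp = compare_tau_groups(spec, broad)
            rows.append({k: round(v, 6) for k, v in cmp.items()})
    pd.DataFrame(rows).to_csv(out / "tau_compare.tsv", sep="\t", index=False)
    report.record(
        "tau", {"tau_floor": cfg.tau_floor}, [expr_path.name],
        [out / "tau.tsv", out / "tau_compare.tsv"],
    )


def _stage_mirna(cfg: PipelineConfig, out: Path, report: RunReport) -> None:
    genome_path = Path(cfg.genome) if cfg.genome else out / "genome.fa"
    genome = read_fasta(genome_path)
    matures = read_fasta(out / "mirna_matures.fa")
    counts = count_family_copies(genome, matures, max_mismatches=cfg.max_mismatches)
    bed_rows = []
    for fam, mat in matures.items():
        for h in scan_genome_for_copies(genome, mat, cfg.max_mismatches):
            bed_rows.append((h.contig, h.start, h.end, fam, h.mismatches, h.strand))
    bed_rows.sort(key=lambda r: (r[0], r[1]))
    write_bed6(out / "mirna_hits.bed", bed_rows)
    pd.Series(counts, name="copy_count").rename_axis("family").to_csv(
        out / "mirna_counts.tsv", sep="\t"
    )
    report.record(
        "mirna", {"max_mismatches": cfg.max_mismatches},
        [genome_path.name, "mirna_matures.fa"],
        [out / "mirna_hits.bed", out / "mirna_counts.tsv"],
    )


def _stage_genomesize(cfg: PipelineConfig, out: Path, report: RunReport) -> None:
    cyto_path = out / "cytometry.cfg"
    if cyto_path.is_file():
        raw = read_flat_config(cyto_path)
        m = CytometryMeasurement(
            ref_2c_pg=float(raw["ref_2c_pg"]),
            ref_peak=float(raw["ref_peak"]),
            sample_peak=float(raw["sample_peak"]),
        )
    else:
        m = CytometryMeasurement(26.9, 13746.0, 20255.0)
    rep = genome_size_report(m)
    pd.DataFrame([rep]).to_csv(out / "genome_size.tsv", sep="\t", index=False)
    report.record(
        "genomesize",
        {"ref_2c_pg": m.ref_2c_pg, "ref_peak": m.ref_peak, "sample_peak": m.sample_peak},
        [cyto_path.name if cyto_path.is_file() else ""],
        [out / "genome_size.tsv"],
    )


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the enabled stages in dependency order; halts on failure."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(out)
    stages = [
        ("simulate", cfg.run_simulate, lambda: _stage_simulate(cfg, out, report)),
    ]
    consensuses: list = []

    def do_assemble():
        consensuses.extend(_stage_assemble(cfg, out, report))

    stages += [
        ("assemble", cfg.run_assemble, do_assemble),
        ("landscape", cfg.run_landscape,
         lambda: _stage_landscape(cfg, out, report, consensuses)),
        ("tau", cfg.run_tau, lambda: _stage_tau(cfg, out, report)),
        ("mirna", cfg.run_mirna, lambda: _stage_mirna(cfg, out, report)),
        ("genomesize", cfg.run_genomesize, lambda: _stage_genomesize(cfg, out, report)),
    ]
    for name, enabled, fn in stages:
        if not enabled:
            report.manifest["stages"][name] = {"status": "skipped"}
            continue
        t0 = time.monotonic()
        try:
            fn()
        except RepeatburstError as exc:
            report.manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            report.write()
            log.error("stage %s failed: %s", name, exc)
            raise
        log.info("stage %s finished in %.1fs", name, time.monotonic() - t0)
    report.write()
    return report
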