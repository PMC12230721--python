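"""End-to-end pipeline: from a folder of genome FASTAs to the numbered
output layout.

Stages (output folder numbering):
  1   ANI matrix and closest relatives (adapter-fed)
  2a-c  ORFs, ORF statistics, translated ORFs
  3   genome completeness (adapter-fed profile hits)
  4   orphan genes
  5a-b  orthogroup tables (plain, annotated, OrthoXML), size histogram,
        phyletic pattern, numeric representation, consensus sequences
  6a-d  per-orthogroup unaligned/aligned DNA and protein FASTAs
  7a-b  concatenated core proteome and core genome with manifests
  8   species tree
  9   codon-bias products (W vectors, per-orthogroup mean CAI)

Every machine-readable artifact is deterministic under a fixed seed and
fixed adapter binaries; images are rendered best-effort and never carry
information absent from their machine-readable twins.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import __version__, annotation_qc, codon_bias, core_alignment, og_products
from .genome_io import (
    Genome,
    SequenceRecord,
    genome_orf_stats,
    load_genome_dir,
    naive_orf_finder,
    parse_fasta,
    translate,
    write_fasta,
)
from .orthogroups import (
    OrthogroupTable,
    OrthoParams,
    infer_orthogroups,
    infer_orthogroups_batched,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    input_kind: str = "orfs"  # "orfs" | "assemblies"
    filter_plasmids: bool = False
    min_identity_pct: float = 40.0
    min_coverage_pct: float = 70.0
    inflation: float = 1.5
    core_threshold_pct: float = 100.0
    batch_size: int = 250
    max_core_ogs_for_tree: int = 1000
    outgroup: str | None = None
    seed: int = 0
    # adapters / optional inputs
    gene_caller_cmd: str | None = None  # "{input}" and "{output}" placeholders
    use_external_msa: bool | None = None  # None = auto-detect mafft
    tree_cmd: str | None = None  # None = auto-detect fasttree, else NJ fallback
    ani_pairs_tsv: str | None = None
    profile_hits_dir: str | None = None
    n_profiles: int = annotation_qc.DEFAULT_PANEL_SIZE
    completeness_evalue: float = annotation_qc.DEFAULT_COMPLETENESS_EVALUE
    ko_catalog_tsv: str | None = None
    ko_hits_tsv: str | None = None
    heg_fasta: str | None = None
    make_plots: bool = False

    def validate(self) -> None:
        for name in ("min_identity_pct", "min_coverage_pct", "core_threshold_pct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.input_kind not in ("orfs", "assemblies"):
            raise ValueError("input_kind must be 'orfs' or 'assemblies'")
        if not os.path.isdir(self.input_dir):
            raise FileNotFoundError(f"input directory not found: {self.input_dir}")


@dataclass
class PipelineResult:
    output_dir: str
    table: OrthogroupTable
    manifest: dict


def _dir(base: str, name: str) -> str:
    path = os.path.join(base, name)
    os.makedirs(path, exist_ok=True)
    return path


def _maybe_plot(fn, path: str, enabled: bool):
    if not enabled:
        return
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig = fn(plt)
        fig.savefig(path)
        plt.close(fig)
    except Exception as exc:  # pragma: no cover - plotting is best-effort
        log.warning("plot %s skipped: %s", path, exc)


def run_gene_caller(cmd_template: str, assembly_path: str, out_path: str) -> None:
    """Adapter contract: the command reads an assembly FASTA and writes a DNA
    ORF FASTA whose record order follows genomic coordinates."""
    cmd = cmd_template.format(input=assembly_path, output=out_path)
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode != 0 or not os.path.exists(out_path):
        raise RuntimeError(f"gene caller failed: {cmd}\n{proc.stderr[-2000:]}")


def extract_orfs(genomes: list[Genome], config: PipelineConfig) -> list[Genome]:
    if config.input_kind == "orfs":
        return genomes
    out = []
    for g in genomes:
        if config.gene_caller_cmd:
            with tempfile.TemporaryDirectory() as tmp:
                inp = os.path.join(tmp, g.name + ".fna")
                outp = os.path.join(tmp, g.name + ".orfs.fna")
                write_fasta(g.records, inp)
                run_gene_caller(config.gene_caller_cmd, inp, outp)
                records = parse_fasta(outp)
        else:
            records = naive_orf_finder(g)
        out.append(Genome(name=g.name, records=records, kind="orf_set"))
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the numbered output folder layout."""
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    manifest: dict = {
        "tool": "panforge",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "output_dir"
        },
        "stages": {},
    }
    genomes = load_genome_dir(
        config.input_dir,
        kind="assembly" if config.input_kind == "assemblies" else "orf_set",
        drop_plasmids=config.filter_plasmids,
    )
    genome_names = [g.name for g in genomes]

    # --- 2: ORFs, stats, translations --------------------------------------
    orf_genomes = extract_orfs(genomes, config)
    d2a = _dir(config.output_dir, "02a_orfs")
    d2b = _dir(config.output_dir, "02b_orf_statistics")
    d2c = _dir(config.output_dir, "02c_translated_orfs")
    stats_rows = []
    proteins: dict[str, dict[str, str]] = {}
    dna: dict[str, str] = {}
    orf_order: dict[str, list[str]] = {}
    for g in orf_genomes:
        write_fasta(g.records, os.path.join(d2a, g.name + ".fna"))
        st = genome_orf_stats(g.records)
        stats_rows.append({"genome": g.name, "orf_count": st.orf_count, "gc_percent": round(st.gc_percent, 4)})
        prots = {}
        for r in g.records:
            prots[r.id] = translate(r.seq, r.id)
            dna[r.id] = r.seq
        proteins[g.name] = prots
        orf_order[g.name] = [r.id for r in g.records]
        write_fasta(
            [SequenceRecord(rid, rid, p) for rid, p in prots.items()],
            os.path.join(d2c, g.name + ".faa"),
        )
    stats_df = pd.DataFrame(stats_rows).set_index("genome")
    stats_df.to_csv(os.path.join(d2b, "orf_stats.csv"))
    _maybe_plot(
        lambda plt: _hist_fig(plt, stats_df["orf_count"], "ORF count"),
        os.path.join(d2b, "orf_count_histogram.png"),
        config.make_plots,
    )
    manifest["stages"]["02_orfs"] = {"genomes": len(orf_genomes), "orfs": int(stats_df["orf_count"].sum())}

    # --- 1: ANI -------------------------------------------------------------
    d1 = _dir(config.output_dir, "01_ani")
    if config.ani_pairs_tsv:
        pairs = []
        with open(config.ani_pairs_tsv) as fh:
            for line in fh:
                if line.strip() and not line.startswith("#"):
                    a, b, v = line.rstrip("\n").split("\t")[:3]
                    pairs.append((a, b, float(v)))
        ani = annotation_qc.build_ani_matrix(pairs, genomes=genome_names)
        ani.to_csv(os.path.join(d1, "ani_matrix.csv"))
        rel = annotation_qc.closest_relatives(ani)
        with open(os.path.join(d1, "closest_relatives.csv"), "w") as fh:
            fh.write("genome,closest_relative,ani\n")
            for g in sorted(rel):
                if rel[g] is None:
                    fh.write(f"{g},none,\n")
                else:
                    fh.write(f"{g},{rel[g][0]},{rel[g][1]:.4f}\n")
        _maybe_plot(lambda plt: _heatmap_fig(plt, ani), os.path.join(d1, "ani_heatmap.png"), config.make_plots)
        manifest["stages"]["01_ani"] = {
            "pairs": len(pairs),
            "complete": bool(annotation_qc.ani_is_complete(ani)),
        }
    else:
        _note(d1, "No ANI adapter input supplied (ani_pairs_tsv); stage skipped.")
        manifest["stages"]["01_ani"] = {"skipped": True}

    # --- 3: completeness ----------------------------------------------------
    d3 = _dir(config.output_dir, "03_completeness")
    if config.profile_hits_dir:
        rows = []
        for g in genome_names:
            path = os.path.join(config.profile_hits_dir, g + ".tblout")
            hits = []
            if os.path.exists(path):
                with open(path) as fh:
                    hits = annotation_qc.parse_hmmer_tblout(fh)
            frac = annotation_qc.completeness(hits, config.n_profiles, config.completeness_evalue)
            rows.append({"genome": g, "completeness": round(frac, 6)})
        comp_df = pd.DataFrame(rows).set_index("genome")
        comp_df.to_csv(os.path.join(d3, "completeness.csv"))
        _maybe_plot(
            lambda plt: _hist_fig(plt, comp_df["completeness"], "completeness"),
            os.path.join(d3, "completeness_histogram.png"),
            config.make_plots,
        )
        manifest["stages"]["03_completeness"] = {"genomes": len(rows)}
    else:
        _note(d3, "No profile-search adapter input supplied (profile_hits_dir); stage skipped.")
        manifest["stages"]["03_completeness"] = {"skipped": True}

    # --- 5: orthogroups -----------------------------------------------------
    params = OrthoParams(
        min_identity_pct=config.min_identity_pct,
        min_coverage_pct=config.min_coverage_pct,
        inflation=config.inflation,
    )
    if len(genome_names) > config.batch_size:
        table = infer_orthogroups_batched(proteins, params, config.batch_size, config.seed)
    else:
        table = infer_orthogroups(proteins, params)
    d5a = _dir(config.output_dir, "05a_orthogroups")
    d5b = _dir(config.output_dir, "05b_orthogroup_products")
    table.to_csv(os.path.join(d5a, "orthogroups.csv"))
    with open(os.path.join(d5a, "orthogroups.orthoxml"), "w") as fh:
        fh.write(og_products.write_orthoxml(table, origin="panforge", version=__version__))
    pattern = og_products.phyletic_pattern(table)
    og_products.write_phyletic_fasta(pattern, os.path.join(d5b, "phyletic_pattern.fasta"))
    numerics = [
        og_products.numeric_representation(g, orf_order[g], table) for g in genome_names
    ]
    og_products.write_numeric_representations(
        numerics, os.path.join(d5b, "numeric_representation.txt")
    )
    hist = og_products.og_size_histogram(table)
    pd.Series(hist, name="count").rename_axis("n_genomes").to_csv(
        os.path.join(d5b, "og_size_histogram.csv")
    )
    _maybe_plot(
        lambda plt: _bar_fig(plt, hist, "orthogroup size (genomes)"),
        os.path.join(d5b, "og_size_histogram.png"),
        config.make_plots,
    )
    manifest["stages"]["05_orthogroups"] = {
        "orthogroups": len(table),
        "genes": len(table.all_genes()),
    }

    # --- 4: orphans ---------------------------------------------------------
    d4 = _dir(config.output_dir, "04_orphans")
    orphans = og_products.find_orphans(table)
    by_id = {og.og_id: og for og in table}
    for g in genome_names:
        with open(os.path.join(d4, g + "_orphans.txt"), "w") as fh:
            for og_id in orphans.orphan_orthogroups.get(g, []):
                fh.write(f"orphan_orthogroup\tOG{og_id}\t" + ";".join(by_id[og_id].all_genes()) + "\n")
            for gene in orphans.orphan_single_genes.get(g, []):
                fh.write(f"orphan_single_gene\t{gene}\n")
    counts = orphans.counts()
    pd.DataFrame(counts).T.rename_axis("genome").to_csv(os.path.join(d4, "orphan_counts.csv"))
    manifest["stages"]["04_orphans"] = {
        "orphan_genes_total": orphans.total_orphan_genes(table)
    }

    # --- 6: per-OG FASTAs and alignments ------------------------------------
    d6a = _dir(config.output_dir, "06a_og_dna")
    d6b = _dir(config.output_dir, "06b_og_aa")
    d6c = _dir(config.output_dir, "06c_og_aa_aligned")
    d6d = _dir(config.output_dir, "06d_og_codon_aligned")
    use_mafft = config.use_external_msa
    if use_mafft is None:
        use_mafft = shutil.which("mafft") is not None
    genome_of_gene = {gid: g for g, d in proteins.items() for gid in d}
    aa_msas: dict[int, core_alignment.MSA] = {}
    codon_msas: dict[int, core_alignment.MSA] = {}
    consensus: dict[int, str] = {}
    for og in table:
        genes = og.all_genes()
        seqs = {gid: proteins[genome_of_gene[gid]][gid] for gid in genes}
        write_fasta(
            [SequenceRecord(g_, g_, dna[g_]) for g_ in genes],
            os.path.join(d6a, f"OG{og.og_id}.fna"),
        )
        write_fasta(
            [SequenceRecord(g_, g_, seqs[g_]) for g_ in genes],
            os.path.join(d6b, f"OG{og.og_id}.faa"),
        )
        if len(genes) == 1:
            msa = core_alignment.MSA([(genes[0], seqs[genes[0]])])
        elif use_mafft:
            msa = core_alignment.mafft_adapter(seqs)
        else:
            msa = core_alignment.align_protein_og(seqs)
        aa_msas[og.og_id] = msa
        codon_msas[og.og_id] = core_alignment.reverse_translate(msa, dna)
        consensus[og.og_id] = og_products.consensus_sequence([s for _, s in msa.rows])
        write_fasta(
            [SequenceRecord(n, n, s) for n, s in msa.rows],
            os.path.join(d6c, f"OG{og.og_id}.faa"),
        )
        write_fasta(
            [SequenceRecord(n, n, s) for n, s in codon_msas[og.og_id].rows],
            os.path.join(d6d, f"OG{og.og_id}.fna"),
        )
    write_fasta(
        [SequenceRecord(f"OG{i}", f"OG{i}", consensus[i]) for i in sorted(consensus)],
        os.path.join(d5b, "og_consensus.faa"),
    )
    manifest["stages"]["06_og_fastas"] = {"aligner": "mafft" if use_mafft else "builtin"}

    # --- 7: core proteome / genome ------------------------------------------
    d7a = _dir(config.output_dir, "07a_core_proteome")
    d7b = _dir(config.output_dir, "07b_core_genome")
    core = core_alignment.select_core(table, config.core_threshold_pct, config.seed)
    prot_by_og: dict[int, dict[str, str]] = {}
    codon_by_og: dict[int, dict[str, str]] = {}
    for og_id in core.og_ids:
        reps = {
            genome: core.representative[(og_id, genome)]
            for genome in genome_names
            if (og_id, genome) in core.representative
        }
        rep_seqs = {genome: proteins[genome][gid] for genome, gid in reps.items()}
        if len(rep_seqs) == 1:
            (genome, seq), = rep_seqs.items()
            sub = core_alignment.MSA([(genome, seq)])
        elif use_mafft:
            sub = core_alignment.mafft_adapter(rep_seqs)
        else:
            sub = core_alignment.align_protein_og(rep_seqs)
        rep_dna = {genome: dna[gid] for genome, gid in reps.items()}
        codon_sub = core_alignment.reverse_translate(sub, rep_dna)
        prot_by_og[og_id] = sub.as_dict()
        codon_by_og[og_id] = codon_sub.as_dict()
    tree_ogs = core_alignment.sample_core_for_tree(
        core.og_ids, config.max_core_ogs_for_tree, config.seed
    )
    proteome, core_genome, man = core_alignment.concatenate_core(
        core_alignment.CoreSet(core.threshold_pct, tree_ogs, core.representative),
        prot_by_og,
        codon_by_og,
        genome_names,
    )
    write_fasta(
        [SequenceRecord(n, n, s) for n, s in proteome.rows],
        os.path.join(d7a, "core_proteome.faa"),
    )
    write_fasta(
        [SequenceRecord(n, n, s) for n, s in core_genome.rows],
        os.path.join(d7b, "core_genome.fna"),
    )
    for d in (d7a, d7b):
        with open(os.path.join(d, "core_orthogroups.csv"), "w") as fh:
            fh.write("og_id\n")
            for og_id in man:
                fh.write(f"OG{og_id}\n")
    manifest["stages"]["07_core"] = {
        "core_orthogroups": len(core.og_ids),
        "sampled_for_tree": len(tree_ogs),
        "core_proteome_length": proteome.length,
    }

    # --- 8: species tree -----------------------------------------------------
    d8 = _dir(config.output_dir, "08_species_tree")
    if config.tree_cmd:
        tree = core_alignment.tree_adapter(proteome, binary=config.tree_cmd)
    else:
        tree = core_alignment.tree_adapter(proteome)
    if config.outgroup:
        tree = core_alignment.outgroup_root(tree, config.outgroup)
    with open(os.path.join(d8, "species_tree.newick"), "w") as fh:
        fh.write(tree.as_string(schema="newick"))
    display = tree if config.outgroup else core_alignment.midpoint_root(tree)
    _maybe_plot(lambda plt: _tree_fig(plt, display), os.path.join(d8, "species_tree.png"), config.make_plots)
    _maybe_plot(lambda plt: _tree_fig(plt, display), os.path.join(d8, "species_tree.svg"), config.make_plots)
    manifest["stages"]["08_tree"] = {"leaves": len(genome_names), "rooted": bool(config.outgroup)}

    # --- 9: codon bias --------------------------------------------------------
    d9 = _dir(config.output_dir, "09_codon_bias")
    mean_cai: dict[int, float] = {}
    if config.heg_fasta:
        heg_recs = parse_fasta(config.heg_fasta)
        wvecs = []
        gene_cai: dict[str, float] = {}
        for g in orf_genomes:
            wv = codon_bias.genome_w_vector(g, heg_recs)
            wvecs.append(wv)
            for r in g.records:
                try:
                    gene_cai[r.id] = codon_bias.cai(r.seq, wv)
                except ValueError:
                    pass
        codon_bias.w_vectors_to_dataframe(wvecs).to_csv(os.path.join(d9, "w_vectors.csv"))
        ann = codon_bias.annotate_og_cai(table, gene_cai)
        mean_cai = ann.og_mean_cai
        pd.Series(mean_cai, name="mean_cai").rename_axis("og_id").to_csv(
            os.path.join(d9, "og_mean_cai.csv")
        )
        _maybe_plot(
            lambda plt: _hist_fig(plt, pd.Series(list(mean_cai.values())), "mean CAI"),
            os.path.join(d9, "mean_cai_histogram.png"),
            config.make_plots,
        )
        manifest["stages"]["09_codon_bias"] = {"genomes_with_w": len(wvecs)}
    else:
        _note(d9, "No HEG protein FASTA supplied (heg_fasta); stage skipped.")
        manifest["stages"]["09_codon_bias"] = {"skipped": True}

    # --- KO annotation + annotated orthogroup table (5a) ----------------------
    ko_assign: dict[int, list[tuple[str, float]]] = {}
    if config.ko_catalog_tsv and config.ko_hits_tsv:
        with open(config.ko_catalog_tsv) as fh:
            catalog = annotation_qc.KoCatalog.from_tsv(fh)
        with open(config.ko_hits_tsv) as fh:
            hits = annotation_qc.parse_hmmer_tblout(fh)
        per_og: dict[int, list] = {}
        for h in hits:
            if h.sequence_id.startswith("OG"):
                per_og.setdefault(int(h.sequence_id[2:]), []).append(h)
        ko_assign = annotation_qc.assign_ko(per_og, catalog)
    annotated = table.to_dataframe()
    annotated.insert(0, "n_genomes", [og.n_genomes() for og in table])
    annotated.insert(1, "n_genes", [og.size() for og in table])
    annotated.insert(
        2,
        "ko",
        [";".join(k for k, _ in ko_assign.get(og.og_id, [])) for og in table],
    )
    annotated.insert(
        3,
        "mean_cai",
        [round(mean_cai[og.og_id], 6) if og.og_id in mean_cai else "" for og in table],
    )
    annotated.to_csv(os.path.join(d5a, "orthogroups_annotated.csv"))

    with open(os.path.join(config.output_dir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(config.output_dir, table, manifest)


def _note(folder: str, text: str) -> None:
    with open(os.path.join(folder, "README.txt"), "w") as fh:
        fh.write(text + "\n")


def _hist_fig(plt, series, label):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(series.values, bins=20, color="#4477aa")
    ax.set_xlabel(label)
    ax.set_ylabel("genomes")
    fig.tight_layout()
    return fig


def _bar_fig(plt, mapping, label):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(list(mapping.keys()), list(mapping.values()), color="#4477aa")
    ax.set_xlabel(label)
    ax.set_ylabel("orthogroups")
    fig.tight_layout()
    return fig


def _heatmap_fig(plt, df):
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(df.values, cmap="RdYlGn_r")
    ax.set_xticks(range(len(df.columns)), df.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(df.index)), df.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="ANI")
    fig.tight_layout()
    return fig


def _tree_fig(plt, tree):
    # minimal unrooted-to-ladder rendering: leaf names vs root distance
    fig, ax = plt.subplots(figsize=(5, 4))
    leaves = list(tree.leaf_node_iter())
    dists = [l.distance_from_root() for l in leaves]
    ax.barh(range(len(leaves)), dists, color="#cccccc")
    ax.set_yticks(range(len(leaves)), [l.taxon.label for l in leaves], fontsize=7)
    ax.set_xlabel("distance from root")
    fig.tight_layout()
    return fig
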