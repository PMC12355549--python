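"""End-to-end orchestration: simulate → authenticate → screen → panel → proteoqc.

One hierarchical configuration drives every stage; a single global seed is
fanned out to per-stage named substreams, so toggling one stage never
perturbs another's randomness.  Every run writes a manifest of produced
files with content checksums; identical config + seed reproduces identical
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import authenticate as auth
from . import io as pio
from . import proteomics as pqc
from . import screen as scr
from . import snp_panel as panel
from ._rng import substream
from .errors import ParameterError
from .simulate import (
    CommunityProfile,
    DamageModelParams,
    PeptideSimParams,
    StrainSimConfig,
    default_species_pools,
    simulate_damaged_reads,
    simulate_peptide_table,
    simulate_sample_calls,
    simulate_strain_set,
    simulate_taxon_report,
)

__all__ = ["STAGES", "run_pipeline"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "authenticate", "screen", "panel", "proteoqc")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    return int(substream(seed, f"pipeline/{stage}").integers(0, 2**31))


def run_pipeline(config: dict, seed: int = 0, outdir=None) -> dict:
    """Run the enabled stages in dependency order; return the manifest.

    ``config`` keys: ``stages`` (list of stage names), ``outdir``, and one
    optional parameter block per stage.  Later stages read the files earlier
    stages wrote under ``outdir`` (or explicit ``*_path`` entries in their
    blocks).  Missing inputs for an enabled stage raise
    :class:`ParameterError` before any stage runs.
    """
    stages = list(config.get("stages", []))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ParameterError(f"unknown stage(s): {sorted(unknown)}")
    outdir = Path(outdir or config.get("outdir", "paleokit_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    # upfront input validation: every enabled non-simulate stage needs its
    # inputs either from an enabled simulate stage or from explicit paths
    def _input(stage: str, key: str, default_name: str) -> Path:
        block = config.get(stage, {}) or {}
        if key in block:
            return Path(block[key])
        return outdir / default_name

    if "simulate" not in stages:
        needs = {
            "authenticate": ["reads_path", "reference_path"],
            "screen": ["reports_dir"],
            "panel": ["vcf_dir"],
            "proteoqc": ["peptides_path", "blank_path"],
        }
        for stage in stages:
            for key in needs.get(stage, []):
                p = _input(stage, key, "__missing__")
                if not p.exists():
                    raise ParameterError(
                        f"stage {stage!r} enabled without 'simulate': missing input {key}={p}"
                    )

    produced: list = []

    def emit(path: Path) -> Path:
        produced.append(path)
        return path

    if "simulate" in stages:
        _run_simulate(config.get("simulate", {}) or {}, _stage_seed(seed, "simulate"),
                      outdir, emit)
    if "authenticate" in stages:
        _run_authenticate(config.get("authenticate", {}) or {},
                          _stage_seed(seed, "authenticate"), outdir, emit, _input)
    if "screen" in stages:
        _run_screen(config.get("screen", {}) or {}, _stage_seed(seed, "screen"),
                    outdir, emit, _input)
    if "panel" in stages:
        _run_panel(config.get("panel", {}) or {}, outdir, emit, _input)
    if "proteoqc" in stages:
        _run_proteoqc(config.get("proteoqc", {}) or {}, outdir, emit, _input)

    manifest = {str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(produced))}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_simulate(cfg: dict, seed: int, outdir: Path, emit) -> None:
    strain_cfg = StrainSimConfig(
        n_strains=cfg.get("n_strains", 6),
        genome_length=cfg.get("genome_length", 20_000),
        tree=cfg.get("tree", "random"),
        subs_per_branch=cfg.get("subs_per_branch", 40.0),
        seed=seed,
    )
    ss = simulate_strain_set(strain_cfg)
    pio.write_fasta({"ancestor": ss.ancestor, **ss.genomes}, emit(outdir / "genomes.fasta"))
    pio.write_newick(ss.tree_newick, emit(outdir / "true_tree.nwk"))

    calls = simulate_sample_calls(
        ss,
        coverage_mean=cfg.get("coverage_mean", 30.0),
        emit_all_sites=cfg.get("emit_all_sites", False),
        noise=cfg.get("noise", 0.0),
        seed=seed,
    )
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for name, recs in calls.items():
        pio.write_vcf(recs, [name], emit(vcf_dir / f"{name}.vcf"),
                      contig_lengths={ss.contig: strain_cfg.genome_length})

    dmg = DamageModelParams(
        d5=cfg.get("d5", 0.3), d3=cfg.get("d3", 0.3), decay=cfg.get("decay", 0.5),
        frag_median=cfg.get("frag_median", 60.0), frag_sd=cfg.get("frag_sd", 0.3),
        n_reads=cfg.get("n_reads", 5000), seq_error=cfg.get("seq_error", 0.0), seed=seed,
    )
    reads, truth = simulate_damaged_reads(ss.ancestor, dmg, contig=ss.contig)
    pio.write_reads_tsv(reads, emit(outdir / "reads.tsv"))
    pio.write_fasta({"reference": ss.ancestor}, emit(outdir / "reference.fasta"))

    pools = default_species_pools(
        spurious_fraction=cfg.get("spurious_fraction", 0.25), seed=seed
    )
    reports_dir = outdir / "reports"
    reports_dir.mkdir(exist_ok=True)
    weights_by_sample = cfg.get(
        "sample_weights",
        {
            "calc_1": {"oral": 0.85, "gut": 0.05, "skin": 0.05, "soil": 0.05},
            "calc_2": {"oral": 0.7, "gut": 0.1, "skin": 0.1, "soil": 0.1},
            "soil_1": {"oral": 0.02, "gut": 0.03, "skin": 0.05, "soil": 0.9},
        },
    )
    for i, (sid, w) in enumerate(weights_by_sample.items()):
        community = CommunityProfile(
            source_weights=w, species_pools=pools,
            library_size=cfg.get("library_size", 50_000), seed=seed + i + 1,
        )
        recs, _ = simulate_taxon_report(community)
        pio.write_taxon_report(recs, emit(reports_dir / f"{sid}.report.tsv"))

    pep_params = PeptideSimParams(
        n_peptides=cfg.get("n_peptides", 1500),
        deamidation_rate=cfg.get("deamidation_rate", 0.25),
        contaminant_fraction=cfg.get("contaminant_fraction", 0.1),
        seed=seed,
    )
    peptides, blanks, contaminants, _ = simulate_peptide_table(pep_params)
    pio.write_peptide_table(peptides, emit(outdir / "peptides.tsv"))
    pio.write_peptide_table(blanks, emit(outdir / "blank.tsv"))
    with open(emit(outdir / "contaminants.txt"), "w") as fh:
        fh.write("\n".join(sorted(contaminants)) + "\n")


def _run_authenticate(cfg: dict, seed: int, outdir: Path, emit, _input) -> None:
    reads = pio.read_reads_tsv(_input("authenticate", "reads_path", "reads.tsv"))
    reference = next(iter(pio.read_fasta(
        _input("authenticate", "reference_path", "reference.fasta")).values()))
    profile = auth.compute_damage_profile(
        reads, reference,
        n_positions=cfg.get("n_positions", 25),
        min_mapq=cfg.get("min_mapping_quality", 30),
    )
    auth.damage_profile_frame(profile).to_csv(emit(outdir / "damage_profile.tsv"),
                                              sep="\t", index=False)
    summary = auth.fragment_length_summary(reads)
    mapp = auth.compute_mappability(
        reference[: cfg.get("mappability_span", 5000)],
        auth.AuthParams(
            mappability_read_length=cfg.get("mappability_read_length", 50),
            mappability_depth=cfg.get("mappability_depth", 30),
        ),
        seed=seed,
    )
    with open(emit(outdir / "authentication.json"), "w") as fh:
        json.dump(
            {
                "fragment_median": summary["median"],
                "fragment_mean": summary["mean"],
                "n_reads": summary["n"],
                "mappability": mapp,
                "ct_offset0": float(profile.ct_5prime[0]),
                "ga_offset0": float(profile.ga_3prime[0]),
            },
            fh, indent=2,
        )


def _run_screen(cfg: dict, seed: int, outdir: Path, emit, _input) -> None:
    reports_dir = Path(_input("screen", "reports_dir", "reports"))
    params = scr.EscoreParams(
        min_escore=cfg.get("min_escore", 7.0), min_reads=cfg.get("min_reads", 10)
    )
    per_sample = {
        p.name.replace(".report.tsv", ""): scr.filter_taxa(pio.read_taxon_report(p), params)
        for p in sorted(reports_dir.glob("*.report.tsv"))
    }
    matrix = scr.records_to_matrix(per_sample)
    matrix.to_frame().to_csv(emit(outdir / "filtered_matrix.tsv"), sep="\t")
    if matrix.counts.size and matrix.counts.shape[0] >= 2:
        clr = scr.clr_transform(matrix.counts, pseudocount=cfg.get("pseudocount", 1.0))
        np.savetxt(emit(outdir / "clr_matrix.tsv"), clr, delimiter="\t")
        scores, loadings, explained = scr.pca_embed(
            clr, n_components=cfg.get("n_components", 2)
        )
        np.savetxt(emit(outdir / "pca_scores.tsv"), scores, delimiter="\t")
        np.savetxt(emit(outdir / "pca_loadings.tsv"), loadings, delimiter="\t")
        np.savetxt(emit(outdir / "pca_explained.tsv"), explained, delimiter="\t")


def _run_panel(cfg: dict, outdir: Path, emit, _input) -> None:
    vcf_dir = Path(_input("panel", "vcf_dir", "vcf"))
    per_sample = {}
    for p in sorted(vcf_dir.glob("*.vcf")):
        recs = pio.read_variant_calls(p)
        per_sample[p.stem] = recs
    params = panel.SnpPanelParams(
        het_ratio=cfg.get("het_ratio", 0.9),
        min_gq=cfg.get("min_gq", 30),
        min_depth=cfg.get("min_depth", 3),
        min_presence=cfg.get("min_presence", 0.75),
        min_spacing=cfg.get("min_spacing", 3),
    )
    aln, table, retained = panel.build_panel(per_sample, params)
    pio.write_alignment_fasta(aln, emit(outdir / "snp_alignment.fasta"))
    with open(emit(outdir / "snp_sites.tsv"), "w") as fh:
        fh.write("contig\tpos\tref\talts\n")
        for j in retained:
            s = table.sites[j]
            fh.write(f"{s.contig}\t{s.pos}\t{s.ref}\t{','.join(s.alts)}\n")
    if aln.n_sites > 0 and aln.n_samples >= 3:
        D, _ = panel.pairwise_p_distance(aln)
        if not np.isnan(D).any():
            np.savetxt(emit(outdir / "p_distances.tsv"), D, delimiter="\t")
            nwk = panel.neighbor_joining(D, aln.sample_ids)
            pio.write_newick(nwk, emit(outdir / "nj_tree.nwk"))


def _run_proteoqc(cfg: dict, outdir: Path, emit, _input) -> None:
    peptides = pio.read_peptide_table(_input("proteoqc", "peptides_path", "peptides.tsv"))
    blanks = pio.read_peptide_table(_input("proteoqc", "blank_path", "blank.tsv"))
    cpath = _input("proteoqc", "contaminants_path", "contaminants.txt")
    contaminants = set()
    if Path(cpath).exists():
        contaminants = {l.strip() for l in open(cpath) if l.strip()}
    params = pqc.ProteoFilterParams(
        max_peptide_score=cfg.get("max_peptide_score", 0.01),
        min_psms_per_protein=cfg.get("min_psms_per_protein", 2),
        keep_human_collagen=cfg.get("keep_human_collagen", True),
    )
    kept = pqc.filter_peptides(peptides, params)
    kept, drop_log = pqc.remove_contaminants(kept, blanks, contaminants, params)
    pio.write_peptide_table(kept, emit(outdir / "peptides_filtered.tsv"))
    groups = pqc.aggregate_protein_groups(kept, params)
    with open(emit(outdir / "protein_groups.tsv"), "w") as fh:
        fh.write("accession\tprotein_name\tunique_peptides\ttotal_psms\n")
        for acc in sorted(groups):
            g = groups[acc]
            fh.write(f"{acc}\t{g['protein_name']}\t{g['unique_peptides']}\t{g['total_psms']}\n")
    stats = pqc.deamidation_stats(kept)
    with open(emit(outdir / "proteomics_stats.json"), "w") as fh:
        json.dump(
            {
                "n_input": len(peptides),
                "n_after_filters": len(kept),
                "dropped": dict(drop_log),
                "n_protein_groups": len(groups),
                "per_sample": {
                    sid: {k: v for k, v in s.items() if k != "length_histogram"}
                    for sid, s in stats.items()
                },
            },
            fh, indent=2,
        )
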