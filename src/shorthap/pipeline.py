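"""End-to-end orchestration: simulate (optional) → frames → variants →
haplotyping → popgen + relatedness → trees, with a machine-readable manifest.

Every stage threshold lives in :class:`PipelineConfig` with the standard
defaults (40 bp frames, 8 spanning reads, >90% completeness and correctness,
mapq 30, frequency bounds 15/15/85/85, 50 kb pi windows, 200 bootstrap
replicates), so one config record reproduces the whole analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
import yaml

from shorthap import frames as frames_mod
from shorthap import haplotyping, popgen, relatedness, simdata, trees, variants

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths.

    When ``simulate`` is set, the synthetic generator produces the reference,
    alignments, and VCF under ``out_dir`` and the path fields are ignored.
    """

    out_dir: str = "shorthap_run"
    reference: str | None = None
    alignments_dir: str | None = None
    vcf: str | None = None
    population_file: str | None = None
    simulate: simdata.SimulationConfig | None = None

    frame_size: int = 40
    frame_distance: int = 40
    min_depth: int = 8
    completeness: float = 0.9
    min_mapq: int = 30
    min_read_count: int = 8
    min_freq_pct: float = 10.0
    bounds: tuple[float, float, float, float] = (15, 15, 85, 85)
    ploidy: int = 2
    correctness: float = 0.9
    window_size: int = 50_000
    n_bootstrap: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("completeness", "correctness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.window_size <= 0:
            raise ValueError(f"window_size must be positive, got {self.window_size}")
        if self.n_bootstrap < 1:
            raise ValueError(f"n_bootstrap must be >= 1, got {self.n_bootstrap}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: tuple(v) if k == "bounds" else v for k, v in raw.items()})
        if sim is not None:
            cfg.simulate = simdata.SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bounds"] = list(self.bounds)
        return d


def _load_assignment(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                sample, pop = line.split()[:2]
                out[sample] = pop
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest dict (also written as
    ``manifest.json`` under the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": config.to_dict(), "stages": {}}

    if config.simulate is not None:
        sim = simdata.simulate_all(config.simulate, out / "simulated")
        reference = sim["reference"]
        sam_paths = {s: str(p) for s, p in sim["sam"].items()}
        vcf_path = sim["vcf"]
        assignment = {s: sub for s, (_sp, sub) in sim["truth"].population_labels.items()}
        species_of = {s: sp for s, (sp, _sub) in sim["truth"].population_labels.items()}
        manifest["stages"]["simulate"] = {
            "n_samples": len(sam_paths),
            "n_variant_sites": len(sim["truth"].variant_sites),
        }
    else:
        for name in ("reference", "alignments_dir", "vcf", "population_file"):
            p = getattr(config, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"missing input path for {name}: {p}")
        import pyfaidx
        fa = pyfaidx.Fasta(config.reference)
        reference = {name: str(fa[name][:]) for name in fa.keys()}
        sam_paths = {p.stem: str(p) for p in sorted(Path(config.alignments_dir).glob("*.sam"))}
        sam_paths.update({p.stem: str(p) for p in sorted(Path(config.alignments_dir).glob("*.bam"))})
        vcf_path = config.vcf
        assignment = _load_assignment(config.population_file)
        species_of = None

    # frames
    lengths = {c: len(s) for c, s in reference.items()}
    all_frames = frames_mod.define_frames(lengths, config.frame_size, config.frame_distance)
    depths = frames_mod.depth_matrix(all_frames, sam_paths, min_mapq=config.min_mapq)
    selected = frames_mod.select_loci(all_frames, depths, config.min_depth,
                                      config.completeness)
    frames_mod.write_bed(selected, out / "selected_loci.bed")
    depths.to_csv(out / "frame_depths.tsv", sep="\t")
    manifest["stages"]["frames"] = {"n_frames": len(all_frames),
                                    "n_selected": len(selected)}

    # variants
    records, samples = variants.read_vcf(vcf_path)
    retained, fail_reasons = variants.apply_hard_filters(records)
    on_loci = variants.subset_to_loci(retained, selected)
    singles = variants.find_singletons(on_loci)
    variants.write_vcf(retained, samples, lengths, out / "filtered_snps.vcf")
    manifest["stages"]["variants"] = {
        "n_input": len(records), "n_pass_hard_filters": len(retained),
        "n_failed": len(fail_reasons), "n_on_selected_loci": len(on_loci),
        "n_singletons": len(singles),
        "n_non_singleton": len(on_loci) - len(singles),
    }

    # haplotyping
    snps_per_locus = variants.snps_by_locus(on_loci, selected)
    counts, dosage = haplotyping.build_dosage_matrix(
        selected, snps_per_locus, sam_paths, min_mapq=config.min_mapq,
        min_read_count=config.min_read_count, min_freq_pct=config.min_freq_pct,
        bounds=config.bounds, ploidy=config.ploidy)
    retained_loci, dosage_f = haplotyping.filter_loci(
        dosage, config.completeness, config.correctness)
    dosage_f.write_tsv(out / "haplotype_dosage.tsv")
    het = {s: haplotyping.het_fraction(dosage_f, s) for s in dosage_f.samples}
    manifest["stages"]["haplotyping"] = {
        "n_loci_called": len(dosage.loci), "n_loci_retained": len(retained_loci),
        "n_haplotypes": dosage_f.n_haplotypes(),
        "het_fraction": het,
    }

    # popgen on SNPs restricted to retained loci
    final_frames = [f for f in selected if f.locus_id in set(retained_loci)]
    final_snps = variants.subset_to_loci(on_loci, final_frames)
    geno = popgen.genotype_matrix(final_snps)
    het_df = popgen.het_stats(geno, samples, assignment)
    fst = popgen.pairwise_neifst(geno, samples, assignment)
    pi_pop = popgen.pi_by_population(final_snps, samples, assignment,
                                     config.window_size)
    pca = popgen.genotype_pca(geno, samples) if geno.size else None
    het_df.to_csv(out / "het_stats.tsv", sep="\t")
    fst.to_csv(out / "fst.tsv", sep="\t")
    manifest["stages"]["popgen"] = {
        "n_snps": len(final_snps),
        "het_stats": {p: {k: _j(v) for k, v in row.items()}
                      for p, row in het_df.iterrows()},
        "pi_by_population": {k: _j(v) for k, v in pi_pop.items()},
        "fst": {a: {b: _j(fst.loc[a, b]) for b in fst.columns} for a in fst.index},
        "pca_explained": [float(x) for x in pca.explained_variance_ratio[:5]] if pca else [],
    }
    if pca is not None:
        np.savetxt(out / "pca_coordinates.tsv", pca.coordinates, delimiter="\t",
                   header="\t".join(pca.samples), comments="")

    # relatedness + tree
    dm = relatedness.jid_matrix(dosage_f)
    dm.write_tsv(out / "jid_matrix.tsv")
    reps = relatedness.bootstrap_jid(dosage_f, config.n_bootstrap, seed=config.seed)
    tree = trees.nj(dm)
    rep_trees = [trees.nj(r) for r in reps]
    tree = trees.bootstrap_support(tree, rep_trees)
    (out / "nj_tree.nwk").write_text(trees.write_newick(tree) + "\n")
    manifest["stages"]["relatedness"] = {"n_bootstrap": config.n_bootstrap}
    if species_of is not None:
        labels = {s: (species_of[s], assignment[s]) for s in dm.samples}
        manifest["stages"]["relatedness"]["jid_summary"] = {
            k: _j(v) for k, v in relatedness.group_jid_summary(dm, labels).items()}
        group_a = {s for s, sp in species_of.items() if sp == "A"}
        manifest["stages"]["relatedness"]["species_split_support"] = _j(
            trees.species_split_support(tree, group_a))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_j)
    return manifest


def _j(v):
    if v is None:
        return None
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float) and not np.isfinite(v):
        return None
    return v
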