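"""Synthetic cohort generator: reference contigs, a hierarchically structured
diploid cohort, aligned reads, and a truth VCF.

The generator emulates the sampling design of a two-species comparison with
nested subpopulations: a fraction of polymorphic sites is fixed-different
between the two species (``species_divergence``), the remainder segregates at
a shared intermediate frequency; each subpopulation's allele frequency is the
species frequency perturbed by drift; individual diploid genotypes are drawn
binomially from the subpopulation frequency, phased onto two chromosome
copies. Reads are emitted as already-aligned single-end records with exact
positions and full-length match CIGARs, so downstream stages test haplotype
and genotype calling, never alignment.

All randomness flows from ``config.seed`` through one root generator;
sub-stages (reference, cohort, per-sample reads, annotations) derive child
seeds deterministically, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

BASES = np.frombuffer(b"ACGT", dtype="S1")

# Annotation mixtures for the truth VCF: pass-like values sit comfortably
# inside the GATK hard-filter thresholds, fail-like values violate at least
# one of them. (key, pass (mean, sd), fail (mean, sd))
_ANNOTATION_MIXTURES = {
    "QD": ((20.0, 5.0), (1.0, 0.5)),
    "FS": ((2.0, 1.5), (80.0, 10.0)),
    "SOR": ((1.0, 0.5), (4.0, 0.5)),
    "MQ": ((60.0, 2.0), (25.0, 5.0)),
    "MQRankSum": ((0.0, 1.0), (-10.0, 1.0)),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the cohort and read generator.

    Defaults give the standard study design: 2 species x 2 subpopulations
    x 5 samples = 20 diploids, 150 bp reads at 30x depth.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 50_000
    snp_density: float = 0.02
    species_divergence: float = 0.3
    n_subpops_per_species: int = 2
    subpop_drift: float = 0.08
    admixture_fraction: float = 0.0
    samples_per_subpop: int = 5
    read_length: int = 150
    mean_depth: float = 30.0
    error_rate: float = 0.001
    mapq: int = 60
    annotation_fail_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_contigs", "contig_length", "n_subpops_per_species",
                     "samples_per_subpop", "read_length"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer, got {getattr(self, name)}")
        for name in ("snp_density", "species_divergence", "subpop_drift",
                     "admixture_fraction", "annotation_fail_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ValueError(f"mean_depth must be positive, got {self.mean_depth}")
        if self.mapq < 0:
            raise ValueError(f"mapq must be non-negative, got {self.mapq}")

    @property
    def samples(self) -> list[str]:
        """Sample names, ordered species A then B, subpop-major."""
        out = []
        for sp in "AB":
            for sub in range(self.n_subpops_per_species):
                for i in range(self.samples_per_subpop):
                    out.append(f"{sp}{sub}-{i:02d}")
        return out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TruthSet:
    """Ground truth for one simulated cohort.

    ``genotypes[(sample, contig, pos0)]`` is the ordered (phased) pair of
    allele characters on the two chromosome copies; ``pos0`` is 0-based.
    """

    genotypes: dict[tuple[str, str, int], tuple[str, str]]
    population_labels: dict[str, tuple[str, str]]
    variant_sites: list[tuple[str, int, str, str]]  # (contig, pos0, ref, alt)
    subpop_freqs: dict[str, np.ndarray] = field(default_factory=dict)

    def alleles(self, sample: str, contig: str, pos0: int) -> tuple[str, str]:
        return self.genotypes[(sample, contig, pos0)]


def _child_rng(seed: int, *tokens) -> np.random.Generator:
    """Deterministic child generator keyed on the root seed plus stage tokens.

    Tokens are hashed with crc32 (stable across processes, unlike ``hash``).
    """
    keys = [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + keys))


def simulate_reference(config: SimulationConfig) -> dict[str, str]:
    """Generate ``n_contigs`` uniform-random sequences of ``contig_length``."""
    rng = _child_rng(config.seed, "reference")
    ref = {}
    for i in range(config.n_contigs):
        seq = BASES[rng.integers(0, 4, size=config.contig_length)]
        ref[f"contig_{i + 1}"] = seq.tobytes().decode()
    return ref


def simulate_cohort(config: SimulationConfig, reference: dict[str, str]) -> TruthSet:
    """Draw variant sites and phased diploid genotypes for the whole cohort.

    Per contig, each position is polymorphic with probability ``snp_density``.
    A ``species_divergence`` fraction of polymorphic sites is fixed-different:
    alt frequency 1 in species A and 0 in species B. The rest share a common
    alt frequency drawn Uniform(0.1, 0.9). Subpopulation frequencies are the
    species frequency plus Normal(0, subpop_drift) noise, clamped to [0, 1].
    With ``admixture_fraction`` > 0, species-B subpopulations draw that
    fraction of sites from the species-A frequency instead.
    """
    rng = _child_rng(config.seed, "cohort")
    labels = {}
    for s in config.samples:
        labels[s] = (s[0], s.split("-")[0])

    variant_sites: list[tuple[str, int, str, str]] = []
    site_subpop_freq: dict[str, list[float]] = {lab: [] for lab in
                                               {v[1] for v in labels.values()}}
    genotypes: dict[tuple[str, str, int], tuple[str, str]] = {}

    subpops = sorted(site_subpop_freq)
    for contig, seq in reference.items():
        L = len(seq)
        is_var = rng.random(L) < config.snp_density
        positions = np.flatnonzero(is_var)
        for pos in positions:
            ref_base = seq[pos]
            alt_base = rng.choice([b for b in "ACGT" if b != ref_base])
            if rng.random() < config.species_divergence:
                f_species = {"A": 1.0, "B": 0.0}
            else:
                f = rng.uniform(0.1, 0.9)
                f_species = {"A": f, "B": f}
            site_freqs = {}
            for sub in subpops:
                species = sub[0]
                base_f = f_species[species]
                if species == "B" and config.admixture_fraction > 0 and \
                        rng.random() < config.admixture_fraction:
                    base_f = f_species["A"]
                fs = base_f + rng.normal(0.0, config.subpop_drift) if config.subpop_drift > 0 else base_f
                site_freqs[sub] = float(np.clip(fs, 0.0, 1.0))
                site_subpop_freq[sub].append(site_freqs[sub])
            variant_sites.append((contig, int(pos), ref_base, alt_base))
            for sample in config.samples:
                f = site_freqs[labels[sample][1]]
                pair = tuple(alt_base if rng.random() < f else ref_base for _ in range(2))
                genotypes[(sample, contig, int(pos))] = pair  # phased order kept

    freqs = {sub: np.asarray(v) for sub, v in site_subpop_freq.items()}
    return TruthSet(genotypes=genotypes, population_labels=labels,
                    variant_sites=variant_sites, subpop_freqs=freqs)


def write_reference_fasta(reference: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def _sam_header(reference: dict[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in reference.items()],
    })


def _simulate_sample_reads(sample: str, truth: TruthSet, reference: dict[str, str],
                           config: SimulationConfig, rng: np.random.Generator):
    """Yield (contig, start, qseq) for one sample, sorted by coordinate."""
    rl = config.read_length
    for contig, seq in reference.items():
        L = len(seq)
        if rl > L:
            raise ValueError(f"read_length {rl} exceeds contig_length {L}")
        n_reads = rng.poisson(config.mean_depth * L / rl)
        starts = np.sort(rng.integers(0, L - rl + 1, size=n_reads))
        hap_choice = rng.integers(0, 2, size=n_reads)
        # per-contig variant lookup for this sample
        sites = [(p, truth.genotypes[(sample, contig, p)])
                 for (c, p, _r, _a) in truth.variant_sites if c == contig]
        site_pos = np.asarray([p for p, _ in sites], dtype=int)
        for ridx in range(n_reads):
            start = int(starts[ridx])
            read = bytearray(seq[start:start + rl], "ascii")
            if site_pos.size:
                lo = np.searchsorted(site_pos, start)
                hi = np.searchsorted(site_pos, start + rl)
                for k in range(lo, hi):
                    pos, pair = sites[k]
                    read[pos - start] = ord(pair[hap_choice[ridx]])
            if config.error_rate > 0:
                err = np.flatnonzero(rng.random(rl) < config.error_rate)
                for e in err:
                    cur = chr(read[e])
                    read[e] = ord(rng.choice([b for b in "ACGT" if b != cur]))
            yield contig, start, read.decode()


def simulate_reads(truth: TruthSet, reference: dict[str, str], config: SimulationConfig,
                   out_dir: str | Path) -> dict[str, Path]:
    """Write one coordinate-sorted SAM per sample plus the truth VCF.

    Returns a dict with per-sample SAM paths under key ``sam`` and the truth
    VCF path under ``vcf``.
    """
    if config.read_length > config.contig_length:
        raise ValueError(
            f"read_length {config.read_length} exceeds contig_length {config.contig_length}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = _sam_header(reference)
    sam_paths = {}
    for sample in sorted(truth.population_labels):
        rng = _child_rng(config.seed, "reads", sample)
        path = out_dir / f"{sample}.sam"
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            n = 0
            for contig, start, qseq in _simulate_sample_reads(
                    sample, truth, reference, config, rng):
                a = pysam.AlignedSegment(header)
                a.query_name = f"{sample}.r{n}"
                a.query_sequence = qseq
                a.flag = 0
                a.reference_id = header.get_tid(contig)
                a.reference_start = start
                a.mapping_quality = config.mapq
                a.cigarstring = f"{config.read_length}M"
                a.query_qualities = pysam.qualitystring_to_array("I" * config.read_length)
                out.write(a)
                n += 1
        sam_paths[sample] = path
    vcf_path = out_dir / "truth.vcf"
    write_truth_vcf(truth, reference, config, vcf_path)
    return {"sam": sam_paths, "vcf": vcf_path}


def write_truth_vcf(truth: TruthSet, reference: dict[str, str],
                    config: SimulationConfig, path: str | Path) -> None:
    """Truth variant sites with phased genotypes and synthetic annotations.

    A record's annotation block is drawn from the pass-like mixture with
    probability ``1 - annotation_fail_rate``, else from the fail-like mixture
    (which violates at least one hard-filter threshold).
    """
    rng = _child_rng(config.seed, "annotations")
    header = pysam.VariantHeader()
    for name, seq in reference.items():
        header.contigs.add(name, length=len(seq))
    for key in _ANNOTATION_MIXTURES:
        header.info.add(key, 1, "Float", f"Synthetic {key} site annotation")
    header.formats.add("GT", 1, "String", "Genotype")
    samples = sorted(truth.population_labels)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for contig, pos0, ref_a, alt_a in truth.variant_sites:
            rec = vcf.new_record(contig=contig, start=pos0, alleles=(ref_a, alt_a))
            failing = rng.random() < config.annotation_fail_rate
            fail_key = rng.choice(list(_ANNOTATION_MIXTURES)) if failing else None
            for key, (pass_ms, fail_ms) in _ANNOTATION_MIXTURES.items():
                mean, sd = fail_ms if key == fail_key else pass_ms
                rec.info[key] = round(float(rng.normal(mean, sd)), 3)
            for s in samples:
                pair = truth.genotypes[(s, contig, pos0)]
                gt = tuple(0 if a == ref_a else 1 for a in pair)
                rec.samples[s]["GT"] = gt
                rec.samples[s].phased = True
            vcf.write(rec)


def simulate_all(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Run the full generator: FASTA + per-sample SAMs + truth VCF.

    Returns ``{"reference", "truth", "fasta", "sam", "vcf"}``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference = simulate_reference(config)
    truth = simulate_cohort(config, reference)
    fasta = out_dir / "reference.fasta"
    write_reference_fasta(reference, fasta)
    paths = simulate_reads(truth, reference, config, out_dir)
    return {"reference": reference, "truth": truth, "fasta": fasta,
            "sam": paths["sam"], "vcf": paths["vcf"]}
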