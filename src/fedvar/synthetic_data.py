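"""Synthetic inputs: cohort VCFs, random sample splits, annotation tables.

Everything the query layers consume can be generated here without any
download.  Cohorts are diploid with genotypes drawn under Hardy-Weinberg
equilibrium at a known per-variant allele frequency, so the true AF is a
simulation parameter and federated estimates have an exact pooled oracle.
``split_cohort`` partitions the *sample columns* of a VCF at random into two
halves that both retain every site row — the structure of a cohort whose
genotype matrix is sharded across two storage platforms — so per-site
(AC, AN) of the halves sum exactly to the original.

A fixed four-variant fixture (well-known GWAS loci identified by rsID) with
hand-set genotypes gives rsID lookups a canonical answer in tests and
examples.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np

DEFAULT_CHROMOSOMES = (("1", 10_000_000), ("2", 10_000_000))

_BASES = np.array(["A", "C", "G", "T"])


class SimSpec:
    """Parameters of one simulated cohort.

    ``af_distribution`` is either ("uniform", low, high) — the default
    uniform(0.01, 0.5), common variants, the regime where split-cohort
    frequency estimation is informative — or an explicit list of per-variant
    frequencies in (0, 1).
    """

    def __init__(self, n_samples, n_variants, chromosomes=DEFAULT_CHROMOSOMES,
                 af_distribution=("uniform", 0.01, 0.5), rsid_prefix="rs",
                 seed=0):
        if n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if n_variants <= 0:
            raise ValueError("n_variants must be positive")
        for _name, length in chromosomes:
            if length <= 0:
                raise ValueError("chromosome lengths must be positive")
        if not isinstance(af_distribution, tuple) or af_distribution[0] != "uniform":
            freqs = list(af_distribution)
            if len(freqs) != n_variants:
                raise ValueError("explicit AF list must have n_variants entries")
            if any(not (0.0 < f < 1.0) for f in freqs):
                raise ValueError("allele frequencies must lie in (0, 1)")
        self.n_samples = n_samples
        self.n_variants = n_variants
        self.chromosomes = tuple((str(n), int(l)) for n, l in chromosomes)
        self.af_distribution = af_distribution
        self.rsid_prefix = rsid_prefix
        self.seed = seed


def _unique_positions(rng, length: int, n: int) -> np.ndarray:
    """n distinct 1-based positions on a chromosome, sorted, O(n) memory."""
    if n > length:
        raise ValueError(
            f"cannot place {n} variants on a {length} bp chromosome"
        )
    chosen: set = set()
    while len(chosen) < n:
        draw = rng.integers(1, length + 1, size=int((n - len(chosen)) * 1.2) + 8)
        chosen.update(draw.tolist())
        if len(chosen) > n:
            chosen = set(sorted(chosen)[:n])
    return np.array(sorted(chosen), dtype=np.int64)


def simulate_cohort(spec: SimSpec, out_dir, stem: str = "cohort") -> tuple:
    """Write a diploid HWE cohort VCF plus its truth table.

    Returns (vcf_path, truth_path).  Genotypes at a variant with true
    frequency p are two independent Bernoulli(p) alleles per sample
    (Hardy-Weinberg).  Positions are unique and sorted per chromosome;
    output is byte-identical for a given spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    os.makedirs(out_dir, exist_ok=True)

    # allocate variants across chromosomes proportionally to length
    lengths = np.array([l for _n, l in spec.chromosomes], dtype=float)
    counts = np.floor(spec.n_variants * lengths / lengths.sum()).astype(int)
    for i in range(spec.n_variants - counts.sum()):
        counts[i % len(counts)] += 1

    if isinstance(spec.af_distribution, tuple):
        _u, low, high = spec.af_distribution
        freqs = rng.uniform(low, high, size=spec.n_variants)
    else:
        freqs = np.asarray(list(spec.af_distribution), dtype=float)

    ref_idx = rng.integers(0, 4, size=spec.n_variants)
    alt_idx = (ref_idx + rng.integers(1, 4, size=spec.n_variants)) % 4

    # HWE diploid genotypes: two Bernoulli(p) alleles per sample
    alleles = rng.random((spec.n_variants, spec.n_samples, 2)) < freqs[:, None, None]
    dosage = alleles.sum(axis=2).astype(np.int8)
    gt_text = np.array(["0/0", "0/1", "1/1"])[dosage]

    sample_names = [f"S{i+1:05d}" for i in range(spec.n_samples)]
    vcf_path = os.path.join(out_dir, f"{stem}.vcf")
    truth_path = os.path.join(out_dir, f"{stem}.truth.tsv")
    k = 0
    with open(vcf_path, "w", encoding="utf-8") as vcf, \
            open(truth_path, "w", encoding="utf-8") as truth:
        vcf.write("##fileformat=VCFv4.2\n")
        vcf.write(f"##source=fedvar-simulate seed={spec.seed}\n")
        for name, length in spec.chromosomes:
            vcf.write(f"##contig=<ID={name},length={length}>\n")
        vcf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        vcf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(sample_names) + "\n")
        truth.write("rsid\tchromosome_name\tpos\treference_bases\t"
                    "alternate_bases\ttrue_af\n")
        for (chrom, length), n_c in zip(spec.chromosomes, counts):
            positions = _unique_positions(rng, length, int(n_c))
            for pos in positions:
                rsid = f"{spec.rsid_prefix}{k + 1:07d}"
                ref = _BASES[ref_idx[k]]
                alt = _BASES[alt_idx[k]]
                vcf.write(
                    f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                    + "\t".join(gt_text[k]) + "\n"
                )
                truth.write(
                    f"{rsid}\t{chrom}\t{pos}\t{ref}\t{alt}\t{freqs[k]:.8f}\n"
                )
                k += 1
    return vcf_path, truth_path


def split_cohort(vcf_path, fraction: float = 0.5, seed: int = 0,
                 out_prefix: Optional[str] = None) -> tuple:
    """Randomly partition a VCF's sample columns into two half-cohorts.

    Both halves retain ALL site rows; the two sample sets are disjoint and
    exhaustive, so per-site AC/AN of the halves sum to the original's.
    Returns (half1_path, half2_path).
    """
    rng = np.random.default_rng(seed)
    with open(vcf_path, "r", encoding="utf-8") as handle:
        lines = handle.read().splitlines()
    header_at = next(
        i for i, line in enumerate(lines) if line.startswith("#CHROM")
    )
    header = lines[header_at].split("\t")
    samples = header[9:]
    if len(samples) < 2:
        raise ValueError("splitting needs a VCF with at least 2 samples")
    n_first = int(round(fraction * len(samples)))
    if n_first == 0 or n_first == len(samples):
        raise ValueError(
            f"fraction {fraction} yields an empty half for {len(samples)} samples"
        )
    perm = rng.permutation(len(samples))
    first = np.sort(perm[:n_first])
    second = np.sort(perm[n_first:])

    prefix = out_prefix or os.path.splitext(vcf_path)[0]
    paths = (f"{prefix}.half1.vcf", f"{prefix}.half2.vcf")
    for path, picked in zip(paths, (first, second)):
        with open(path, "w", encoding="utf-8") as out:
            for line in lines[:header_at]:
                out.write(line + "\n")
            out.write("\t".join(header[:9] + [samples[i] for i in picked]) + "\n")
            for line in lines[header_at + 1:]:
                if not line:
                    continue
                cols = line.split("\t")
                out.write("\t".join(cols[:9] + [cols[9 + i] for i in picked]) + "\n")
    return paths


def simulate_annotation(gene_count: int, records_per_gene: int,
                        chromosomes: Sequence = DEFAULT_CHROMOSOMES,
                        seed: int = 0, out_dir=".",
                        ensure_symbols: Sequence[str] = (),
                        stem: str = "annotation") -> tuple:
    """Write an annotation TSV and matching gene-model TSV.

    Every synthetic gene receives a region and ``records_per_gene``
    annotation intervals guaranteed to overlap it, each carrying a gene
    symbol, a score and a database identifier.  ``ensure_symbols`` names
    genes that must be present (e.g. "TP53" for the worked annotation
    scenario); remaining genes are GENE0001, GENE0002, ...
    Returns (annotation_path, gene_model_path).
    """
    if gene_count <= 0 or records_per_gene <= 0:
        raise ValueError("gene_count and records_per_gene must be positive")
    if len(ensure_symbols) > gene_count:
        raise ValueError("more ensured symbols than genes")
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    chroms = [(str(n), int(l)) for n, l in chromosomes]

    symbols = list(ensure_symbols) + [
        f"GENE{i + 1:04d}" for i in range(gene_count - len(ensure_symbols))
    ]
    annotation_path = os.path.join(out_dir, f"{stem}.tsv")
    gene_model_path = os.path.join(out_dir, f"{stem}.genes.tsv")
    with open(annotation_path, "w", encoding="utf-8") as ann, \
            open(gene_model_path, "w", encoding="utf-8") as genes:
        ann.write("chromosome_name\tstart_position\tend_position\t"
                  "gene\tscore\tdb_id\n")
        genes.write("symbol\tchromosome_name\tstart_position\tend_position\n")
        record_id = 0
        for symbol in symbols:
            chrom, length = chroms[int(rng.integers(0, len(chroms)))]
            gene_len = int(rng.integers(20_000, 120_000))
            g_start = int(rng.integers(0, max(1, length - gene_len)))
            g_end = g_start + gene_len
            genes.write(f"{symbol}\t{chrom}\t{g_start}\t{g_end}\n")
            for _ in range(records_per_gene):
                s = int(rng.integers(max(0, g_start - 2_000), g_end))
                e = int(rng.integers(max(s, g_start) + 1,
                                     max(s, g_start) + 5_000))
                score = float(rng.random())
                record_id += 1
                ann.write(f"{chrom}\t{s}\t{e}\t{symbol}\t{score:.4f}\t"
                          f"DB{record_id:06d}\n")
    return annotation_path, gene_model_path


# ---------------------------------------------------------------------------
# Fixed four-variant fixture
# ---------------------------------------------------------------------------

#: (description, rsid, chromosome, 1-based position, REF, ALT)
FIXTURE_VARIANTS = (
    ("Attention-deficit/hyperactivity disorder (ADHD)",
     "rs671", "12", 112241766, "G", "A"),
    ("Blue Eye Color (BEC)", "rs12913832", "15", 28365618, "A", "G"),
    ("Coronary Heart Disease (CHD)", "rs1333049", "9", 22125503, "G", "C"),
    ("Lactose Intolerance", "rs4988235", "2", 136608646, "G", "A"),
)

#: Hand-set diploid genotypes for six samples; one "./." half-missing call
#: exercises the AN bookkeeping.  Expected counts:
#: rs671 AC=4 AN=12, rs12913832 AC=10 AN=12, rs1333049 AC=3 AN=10,
#: rs4988235 AC=1 AN=12.
FIXTURE_GENOTYPES = {
    "rs671": ("0/1", "1/1", "0/0", "0/0", "0/1", "0/0"),
    "rs12913832": ("1/1", "1/1", "0/1", "1/1", "0/1", "1/1"),
    "rs1333049": ("0/1", "0/0", "0/1", "0/0", "./.", "0/1"),
    "rs4988235": ("0/0", "0/1", "0/0", "0/0", "0/0", "0/0"),
}

FIXTURE_EXPECTED_COUNTS = {
    "rs671": (4, 12),
    "rs12913832": (10, 12),
    "rs1333049": (3, 10),
    "rs4988235": (1, 12),
}


def write_fixture_vcf(path) -> str:
    """Write the four-variant fixture VCF (six samples, genotypes above)."""
    n = len(next(iter(FIXTURE_GENOTYPES.values())))
    sample_names = [f"F{i+1:02d}" for i in range(n)]
    with open(path, "w", encoding="utf-8") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=fedvar-fixture\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(sample_names) + "\n")
        for _desc, rsid, chrom, pos, ref, alt in FIXTURE_VARIANTS:
            out.write(f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                      + "\t".join(FIXTURE_GENOTYPES[rsid]) + "\n")
    return str(path)
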