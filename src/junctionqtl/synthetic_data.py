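"""Synthetic cohort generator for splicing-QTL analysis.

Emulates a bovine mammary RNA-seq study design: ~375 animals genotyped at a
biallelic causal MNP (an AA>GC dinucleotide substitution) plus LD neighbours
in a 1 Mbp interval, with genotype-dependent per-junction splicing
efficiency, genotype-dependent alternative-donor usage, genotype-dependent
total expression, and triplicate mini-gene qPCR plates for the two plasmid
alleles.  Every sub-simulation draws from a named generator seeded from one
master seed, and emits a truth table alongside its output so downstream
estimates can be checked against the generating parameters.

Default parameter values are the study's printed population conditions:
causal (K) allele frequency 0.51; intron-8 read percentages 1.94 / 1.53 /
1.16 for the AA / AK / KK classes; reference-donor PSI 96.4 / 94.5 / 94.1;
normalised expression 9.244 / 9.436 / 9.628; mini-gene splicing ratios per
junction as printed for the two alleles.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from junctionqtl.io_core import (
    AlignedRead,
    GeneModel,
    GenotypeMatrix,
    add_alternative_donor,
)

GENO_CLASSES = ("AA", "AK", "KK")  # dosage 0, 1, 2 copies of the K (alt) allele


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class QPCRConfig:
    """Mini-gene qPCR plate layout and generating quantities.

    ``true_unspliced`` holds per-junction true relative quantities of the
    unspliced (intron-containing) transcript per allele; the spliced
    quantity is ``true_ratio x true_unspliced``.  Defaults are the printed
    in-vitro measurements for the four assayed junctions.
    """

    junctions: tuple[int, ...] = (3, 5, 7, 13)
    true_ratio: dict = field(
        default_factory=lambda: {
            "K": {3: 0.253, 5: 143.18, 7: 28.49, 13: 92.90},
            "A": {3: 0.173, 5: 133.52, 7: 5.55, 13: 90.92},
        }
    )
    true_unspliced: dict = field(
        default_factory=lambda: {
            "K": {3: 0.092, 5: 0.286, 7: 0.216, 13: 0.821},
            "A": {3: 0.0842, 5: 0.180, 7: 0.234, 13: 0.503},
        }
    )
    n_samples_per_allele: int = 3  # independent cell preparations
    n_wells: int = 3  # technical replicate wells per sample x assay
    n_curve_dilutions: int = 5  # serial 5x dilutions for the standard curve
    dilution_step: float = 5.0
    amplification_efficiency: float = 0.95
    cq_noise_sd: float = 0.15  # cycles, per well
    # biological lognormal CV per sample x assay; together with the well
    # noise this yields ~10% between-sample spread of the splicing ratio,
    # matching the printed in-vitro dispersion
    sample_noise_cv: float = 0.05
    loading_cv: float = 0.20  # per-sample loading factor, cancelled by references
    reference_assays: tuple[str, ...] = ("EIF3K", "GFP")


@dataclass
class SimulationConfig:
    """All generating parameters for the synthetic cohort.

    Per-genotype triples are ordered (AA, AK, KK), i.e. by dosage of the
    causal K allele.  ``ld_decay`` is the per-marker-step haplotype flip
    probability: the marker ``d`` index steps away from the causal marker
    copies each causal haplotype allele and flips it with probability
    ``min(0.5, ld_decay x d)``, so the nearest neighbours are strong but
    imperfect proxies and distant markers are unlinked.
    """

    n_animals: int = 375
    causal_allele_freq: float = 0.51
    n_markers: int = 200
    ld_decay: float = 0.03
    chrom: str = "chr14"
    region_span: int = 1_000_000
    # splicing phenotypes -------------------------------------------------
    intron_pct_by_genotype: dict = field(
        default_factory=lambda: {8: (1.94, 1.53, 1.16), 2: (1.90, 1.45, 1.10), 7: (1.80, 1.45, 1.15)}
    )
    default_intron_pct: float = 1.5  # junctions without a genotype effect
    boundary_share: float = 0.5  # fraction of intron-touching reads crossing the donor boundary
    spliced_read_fraction: float = 0.02  # junction-bridging reads per junction
    retention_sd_logit: float = 0.15  # animal-level biological spread
    psi_by_genotype: tuple = (96.4, 94.5, 94.1)
    psi_sd_logit: float = 0.25
    # expression ----------------------------------------------------------
    expression_by_genotype: tuple = (9.244, 9.436, 9.628)
    expression_sd: float = 0.25
    cohort_effects: tuple = (0.0, 0.05, -0.05)  # additive cohort shifts on expression
    # cohort-genotype assortment: 0 = cohorts sampled independently of
    # genotype; > 0 skews cohort membership with causal dosage (structured
    # sampling across collection waves), confounding cohort with genotype
    cohort_assortment: float = 0.0
    # sequencing ----------------------------------------------------------
    read_depth: int = 5000  # mean gene-overlapping reads per animal
    nb_dispersion: float = 50.0  # negative-binomial size; larger = closer to Poisson
    read_length: int = 100
    # sub-experiments -----------------------------------------------------
    qpcr: QPCRConfig = field(default_factory=QPCRConfig)
    seed: int = 0

    def rng(self, name: str) -> np.random.Generator:
        """A named, reproducible generator derived from the master seed."""
        return np.random.default_rng([self.seed, zlib.crc32(name.encode())])

    def intron_pct_triple(self, junction: int) -> tuple[float, float, float]:
        trip = self.intron_pct_by_genotype.get(junction)
        return trip if trip is not None else (self.default_intron_pct,) * 3

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qp = QPCRConfig(**raw.pop("qpcr", {}))
        raw.pop("junctions", None)
        # YAML keys for per-junction dicts arrive as strings
        if "intron_pct_by_genotype" in raw:
            raw["intron_pct_by_genotype"] = {
                int(k): tuple(v) for k, v in raw["intron_pct_by_genotype"].items()
            }
        return cls(qpcr=qp, **raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# gene model fixtures


def toy_gene_model(read_length: int = 100) -> GeneModel:
    """A 15-exon plus-strand gene on a small toy contig.

    Exon 8 mirrors the real alternative-donor geometry: a 75 bp exon whose
    alternative 5' donor truncates it to 9 bp, splicing out a 66 bp
    (22-codon) span.  All other exons are >= ``read_length`` + 2 bp and all
    introns >= ``read_length`` + 50 bp so that single-block reads fit inside
    any feature.
    """
    exon_lengths = [150, 120, 130, 110, 140, 125, 160, 75, 135, 120, 115, 150, 130, 140, 180]
    intron_lengths = [800, 1200, 400, 350, 500, 300, 250, 220, 380, 420, 600, 450, 350, 280]
    exons = []
    pos = 1001  # 1-based start of exon 1
    for i, elen in enumerate(exon_lengths):
        exons.append((pos, pos + elen - 1))
        if i < len(intron_lengths):
            pos = pos + elen + intron_lengths[i]
    model = GeneModel.from_1based("DGAT1_toy", "chr14", "+", exons)
    e8s, e8e = model.exons_1based[7]
    assert e8e - e8s + 1 == 75
    return add_alternative_donor(model, (e8s, e8s + 8), (e8s + 9, e8e))


def dgat1_exon8_geometry() -> dict:
    """The exon-8 alternative-donor geometry and causal variant.

    1-based genomic intervals of the alternative and reference forms of the
    exon, and the AA>GC dinucleotide substitution.  The 23-nt K-allele
    context is a synthetic reconstruction: it places the two enhancer
    hexamers AAGAAG / AGAAGG at their reported positions (1802262 and
    1802263) around the variant, with neutral flanking bases — it does not
    claim the true genomic flanks.
    """
    return {
        "chrom": "chr14",
        "alt_exon": (1_802_251, 1_802_259),
        "ref_exon": (1_802_260, 1_802_325),
        "variant_pos": 1_802_265,
        "variant_ref": "AA",
        "variant_alt": "GC",
        "context_offset": 1_802_260,  # 1-based genomic position of context[0]
        "k_allele_context_23nt": "CTAAGAAGGCTTCCAGCTGGCCT",
    }


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Causal marker at Hardy-Weinberg plus LD neighbours by haplotype copy.

    Two causal haplotypes per animal are drawn as Bernoulli(freq); each
    non-causal marker copies them with a per-site flip probability growing
    with marker distance (see :class:`SimulationConfig`).  The causal marker
    is named ``K232A`` with REF=AA, ALT=GC.
    """
    rng = config.rng("genotypes")
    n, m = config.n_animals, config.n_markers
    causal_idx = m // 2
    hap = rng.random((2, n)) < config.causal_allele_freq  # K-allele indicator
    causal_pos = 1_802_265
    positions = np.linspace(
        causal_pos - config.region_span // 2,
        causal_pos + config.region_span // 2,
        m,
        dtype=int,
    )
    positions[causal_idx] = causal_pos  # interval is centred on the causal MNP
    dosage = np.empty((n, m))
    markers = []
    for j in range(m):
        d = abs(j - causal_idx)
        if d == 0:
            alleles = hap
            markers.append(("K232A", config.chrom, int(positions[j]), "AA", "GC"))
        else:
            flip_p = min(0.5, config.ld_decay * d)
            flips = rng.random((2, n)) < flip_p
            alleles = hap ^ flips
            markers.append((f"rs_sim_{j:04d}", config.chrom, int(positions[j]), "A", "G"))
        dosage[:, j] = alleles.sum(axis=0)
    sample_ids = [f"animal_{i:04d}" for i in range(n)]
    return GenotypeMatrix(sample_ids=sample_ids, markers=markers, dosage=dosage)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write the dosage matrix as a minimal genotype-only VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({m[1] for m in genotypes.markers})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        order = sorted(
            range(len(genotypes.markers)),
            key=lambda j: (genotypes.markers[j][1], genotypes.markers[j][2]),
        )
        for j in order:
            mid, chrom, pos, ref, alt = genotypes.markers[j]
            gts = []
            for d in genotypes.dosage[:, j]:
                if np.isnan(d):
                    gts.append("./.")
                else:
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
            fh.write(f"{chrom}\t{pos}\t{mid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# covariates


def simulate_covariates(
    config: SimulationConfig, genotypes: GenotypeMatrix | None = None
) -> pd.DataFrame:
    """Cohort labels, ancestry proportions (Dirichlet, summing to 1) and a
    heterosis fraction per animal, indexed by sample id.

    With ``cohort_assortment`` > 0 (and genotypes supplied), cohort
    membership probabilities shift with the causal dosage, creating genuine
    cohort-genotype confounding for covariate-adjustment checks.
    """
    rng = config.rng("covariates")
    n = config.n_animals
    base = np.array([0.056, 0.488, 0.456])
    if config.cohort_assortment > 0 and genotypes is not None:
        dos = genotypes.dosages_of("K232A")
        cohorts = np.empty(n, dtype=object)
        for i in range(n):
            shift = config.cohort_assortment * (dos[i] - 1.0)
            p = base + np.array([0.0, shift, -shift])
            p = np.clip(p, 0.01, None)
            p /= p.sum()
            cohorts[i] = rng.choice(["cohort_A", "cohort_B", "cohort_C"], p=p)
    else:
        cohorts = rng.choice(["cohort_A", "cohort_B", "cohort_C"], size=n, p=base)
    ancestry = rng.dirichlet([6.0, 2.0, 2.0], size=n)
    heterosis = rng.beta(2.0, 5.0, size=n)
    df = pd.DataFrame(
        {
            "cohort": cohorts,
            "anc_nz_hf": ancestry[:, 0],
            "anc_us_hf": ancestry[:, 1],
            "anc_jersey": ancestry[:, 2],
            "heterosis": heterosis,
        },
        index=[f"animal_{i:04d}" for i in range(n)],
    )
    df.index.name = "sample"
    return df


def covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    """Numeric design for the association model: cohort indicators (first
    level dropped) + ancestry proportions (last dropped) + heterosis."""
    cohorts = pd.get_dummies(covariates["cohort"], drop_first=True).to_numpy(dtype=float)
    return np.column_stack(
        [cohorts, covariates[["anc_nz_hf", "anc_us_hf", "heterosis"]].to_numpy(dtype=float)]
    )


# ---------------------------------------------------------------------------
# per-animal truth


def simulate_truth(config: SimulationConfig, genotypes: GenotypeMatrix,
                   covariates: pd.DataFrame | None = None,
                   n_junctions: int = 14) -> pd.DataFrame:
    """Latent per-animal truth: retention probability per junction, PSI
    probability, expected expression, and realised read depth.

    Genotype class means are mapped to animal-level probabilities on the
    logit scale with biological spread ``retention_sd_logit`` /
    ``psi_sd_logit``; expression is Gaussian around the class mean (plus the
    cohort effect when covariates are supplied) and scales expected depth.
    """
    rng = config.rng("truth")
    dos = genotypes.dosages_of("K232A").astype(int)
    n = dos.size
    rows: dict[str, np.ndarray] = {}
    for j in range(1, n_junctions + 1):
        trip = config.intron_pct_triple(j)
        # degenerate class means (0 or 100%) bypass the logit map exactly
        probs = np.array([min(max(t / 100.0, 0.0), 1.0) for t in trip])
        if (probs <= 0).any() or (probs >= 1).any():
            rows[f"retention_prob_{j}"] = probs[dos]
            continue
        mu = np.log(probs / (1 - probs))[dos]
        rows[f"retention_prob_{j}"] = _inv_logit(mu + rng.normal(0, config.retention_sd_logit, n))
    psi_mu = np.array([_logit(p / 100.0) for p in config.psi_by_genotype])[dos]
    rows["psi_prob"] = _inv_logit(psi_mu + rng.normal(0, config.psi_sd_logit, n))
    expr = np.asarray(config.expression_by_genotype)[dos] + rng.normal(0, config.expression_sd, n)
    if covariates is not None:
        eff = dict(zip(["cohort_A", "cohort_B", "cohort_C"], config.cohort_effects))
        expr = expr + covariates["cohort"].map(eff).to_numpy()
    rows["expression"] = expr
    mean_expr = float(np.mean(config.expression_by_genotype))
    mu_depth = config.read_depth * np.exp2(expr - mean_expr)
    k = config.nb_dispersion
    rows["depth"] = rng.negative_binomial(k, k / (k + mu_depth)).astype(float)
    truth = pd.DataFrame(rows, index=genotypes.sample_ids)
    truth.insert(0, "dosage", dos)
    truth.insert(1, "genotype", [GENO_CLASSES[d] for d in dos])
    truth.index.name = "sample"
    return truth


# ---------------------------------------------------------------------------
# fast path: junction count tables without per-read simulation


def simulate_junction_counts(
    config: SimulationConfig, truth: pd.DataFrame, n_junctions: int = 14
) -> pd.DataFrame:
    """Per-animal junction count table drawn directly from the truth model.

    For each junction: spliced reads ~ Binomial(depth, spliced fraction);
    intron-touching reads ~ Binomial(depth, retention probability), split
    into donor-boundary-crossing (unspliced) and fully intronic reads.
    Statistically matched to the read-level simulator, without materialising
    alignments.
    """
    rng = config.rng("junction_counts")
    depth = truth["depth"].to_numpy(int)
    out = {"depth": depth}
    for j in range(1, n_junctions + 1):
        rho = truth[f"retention_prob_{j}"].to_numpy()
        n_intron = rng.binomial(depth, rho)
        n_unspliced = rng.binomial(n_intron, config.boundary_share)
        n_spliced = rng.binomial(depth, config.spliced_read_fraction)
        out[f"n_spliced_{j}"] = n_spliced
        out[f"n_unspliced_{j}"] = n_unspliced
        out[f"n_intronic_{j}"] = n_intron - n_unspliced
    # alternative-donor usage at the exon-8 junction
    n_donor = rng.binomial(depth, config.spliced_read_fraction)
    n_ref = rng.binomial(n_donor, truth["psi_prob"].to_numpy())
    out["n_ref_spliced"] = n_ref
    out["n_alt_spliced"] = n_donor - n_ref
    df = pd.DataFrame(out, index=truth.index)
    return df


def phenotypes_from_counts(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Phenotype table (psi, eff_j, intronpct_j) from a fast-path count table."""
    from junctionqtl.junction_phenotypes import compute_psi, efficiency_ratio

    depth = counts["depth"].to_numpy(float)
    out = {}
    junctions = sorted(
        int(c.split("_")[-1]) for c in counts.columns if c.startswith("n_spliced_")
    )
    out["psi"] = [
        compute_psi(r, a) for r, a in zip(counts["n_ref_spliced"], counts["n_alt_spliced"])
    ]
    for j in junctions:
        out[f"eff_{j}"] = [
            efficiency_ratio(s, u, pseudocount)
            for s, u in zip(counts[f"n_spliced_{j}"], counts[f"n_unspliced_{j}"])
        ]
        n_intron = counts[f"n_unspliced_{j}"] + counts[f"n_intronic_{j}"]
        out[f"intronpct_{j}"] = 100.0 * n_intron.to_numpy(float) / depth
    return pd.DataFrame(out, index=counts.index)


# ---------------------------------------------------------------------------
# read-level simulation


def _exon_flanks(model: GeneModel, intron: tuple[int, int]) -> tuple[tuple[int, int], tuple[int, int]]:
    left = next(e for e in model.exons if e[1] == intron[0])
    right = next(e for e in model.exons if e[0] == intron[1])
    return left, right


def _spliced_read(rng, model, intron, read_len, sample, min_anchor=1) -> AlignedRead:
    left, right = _exon_flanks(model, intron)
    lo = max(min_anchor, read_len - (right[1] - right[0]))
    hi = min(read_len - min_anchor, left[1] - left[0])
    a = int(rng.integers(lo, hi + 1)) if hi > lo else lo
    return AlignedRead(
        sample, model.chrom,
        ((intron[0] - a, intron[0]), (intron[1], intron[1] + read_len - a)),
    )


def _alt_spliced_read(rng, model, read_len, sample, min_anchor=1) -> AlignedRead:
    alt_j = model.alt_donor_junction()
    s, e = alt_j.intron
    if model.strand == "+":
        left_len = model.alt_donor.alt_exon[1] - model.alt_donor.alt_exon[0]
        _, right = _exon_flanks(model, model.reference_donor_junction().intron)
        lo = max(min_anchor, read_len - (right[1] - right[0]))
        hi = min(read_len - min_anchor, left_len)
        a = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        return AlignedRead(sample, model.chrom, ((s - a, s), (e, e + read_len - a)))
    left, _ = _exon_flanks(model, model.reference_donor_junction().intron)
    right_len = model.alt_donor.alt_exon[1] - model.alt_donor.alt_exon[0]
    lo = max(min_anchor, read_len - right_len)
    hi = min(read_len - min_anchor, left[1] - left[0])
    a = int(rng.integers(lo, hi + 1)) if hi > lo else lo
    return AlignedRead(sample, model.chrom, ((s - a, s), (e, e + read_len - a)))


def _unspliced_read(rng, junction, read_len, sample, min_anchor=1) -> AlignedRead:
    b = junction.donor_boundary
    # exonic-side anchor: stay within [min_anchor, read_len - min_anchor]
    a = int(rng.integers(min_anchor, read_len - min_anchor + 1))
    if junction.strand == "+":
        start = b - a
    else:
        start = b + a - read_len
    return AlignedRead(sample, "", ((start, start + read_len),))


def _intronic_read(rng, intron, read_len, sample) -> AlignedRead:
    s, e = intron
    start = int(rng.integers(s, e - read_len + 1))
    return AlignedRead(sample, "", ((start, start + read_len),))


def _exonic_read(rng, exons, read_len, sample) -> AlignedRead | None:
    fits = [(s, e) for s, e in exons if (e - 1) - (s + 1) >= read_len]
    if not fits:
        return None
    s, e = fits[int(rng.integers(len(fits)))]
    start = int(rng.integers(s + 1, e - 1 - read_len + 1))
    return AlignedRead(sample, "", ((start, start + read_len),))


def simulate_reads(
    config: SimulationConfig,
    model: GeneModel,
    truth: pd.DataFrame,
    samples: list[str] | None = None,
) -> tuple[list[AlignedRead], pd.DataFrame]:
    """Materialise aligned reads per animal, with a per-read truth table.

    Per animal the total read count is the truth table's negative-binomial
    depth; junction-local spliced / unspliced / intronic reads are drawn per
    junction from the same probabilities as the fast path, reference vs
    alternative donor usage follows the animal's PSI probability, and the
    remainder are exonic background reads.  The returned truth table has one
    row per junction-local read: (sample, read index, junction, true class,
    donor) where ``true class`` is the classification at that junction.
    """
    rng = config.rng("reads")
    junctions = model.junctions()
    L = config.read_length
    samples = list(truth.index) if samples is None else samples
    reads: list[AlignedRead] = []
    truth_rows = []
    ref_j = model.reference_donor_junction() if model.alt_donor is not None else None
    for sample in samples:
        trow = truth.loc[sample]
        depth = int(trow["depth"])
        n_junction_reads = 0
        for junction in junctions:
            rho = float(trow[f"retention_prob_{junction.index}"])
            n_intron = rng.binomial(depth, rho)
            n_unspliced = rng.binomial(n_intron, config.boundary_share)
            n_intronic = n_intron - n_unspliced
            if ref_j is not None and junction.index == ref_j.index:
                n_donor = rng.binomial(depth, config.spliced_read_fraction)
                n_ref = rng.binomial(n_donor, float(trow["psi_prob"]))
                n_alt = n_donor - n_ref
                n_spliced, n_alt_spliced = n_ref, n_alt
            else:
                n_spliced = rng.binomial(depth, config.spliced_read_fraction)
                n_alt_spliced = 0
            for _ in range(n_spliced):
                r = _spliced_read(rng, model, junction.intron, L, sample)
                reads.append(r)
                truth_rows.append((sample, len(reads) - 1, junction.index, "spliced", "ref"))
            for _ in range(n_alt_spliced):
                r = _alt_spliced_read(rng, model, L, sample)
                reads.append(r)
                # at the reference junction this read matches neither rule
                truth_rows.append((sample, len(reads) - 1, junction.index, "other", "alt"))
            for _ in range(n_unspliced):
                r = _unspliced_read(rng, junction, L, sample)
                reads.append(AlignedRead(sample, model.chrom, r.blocks))
                truth_rows.append((sample, len(reads) - 1, junction.index, "unspliced", ""))
            for _ in range(n_intronic):
                r = _intronic_read(rng, junction.intron, L, sample)
                reads.append(AlignedRead(sample, model.chrom, r.blocks))
                truth_rows.append((sample, len(reads) - 1, junction.index, "other", ""))
            n_junction_reads += n_spliced + n_alt_spliced + n_unspliced + n_intronic
        for _ in range(max(0, depth - n_junction_reads)):
            r = _exonic_read(rng, model.exons, L, sample)
            if r is not None:
                reads.append(AlignedRead(sample, model.chrom, r.blocks))
    truth_table = pd.DataFrame(
        truth_rows, columns=["sample", "read", "junction", "true_class", "donor"]
    )
    return reads, truth_table


def write_sam(reads: list[AlignedRead], model: GeneModel, path,
              contig_length: int | None = None) -> None:
    """Write reads as a coordinate-sorted SAM file (CIGAR M/N blocks)."""
    import pysam

    length = contig_length or model.span[1] + 1000
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": model.chrom, "LN": length}],
        "RG": [{"ID": s} for s in sorted({r.sample_id for r in reads})],
    }
    ordered = sorted(enumerate(reads), key=lambda ir: ir[1].blocks[0][0])
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, read in ordered:
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read_{i:07d}"
            a.reference_name = model.chrom
            a.reference_start = read.blocks[0][0]
            a.mapping_quality = 60
            cigar = []
            for k, (s, e) in enumerate(read.blocks):
                if k:
                    cigar.append((3, s - read.blocks[k - 1][1]))  # N
                cigar.append((0, e - s))  # M
            a.cigartuples = cigar
            a.query_sequence = "A" * read.aligned_length
            a.set_tag("RG", read.sample_id)
            out.write(a)


def write_genome_fasta(model: GeneModel, path, seed: int = 0,
                       embed: dict | None = None) -> None:
    """Random toy contig covering the gene span (plus 1 kb), optionally
    embedding a given sequence at a 1-based position (``embed`` maps
    position -> sequence)."""
    rng = np.random.default_rng([seed, zlib.crc32(b"genome")])
    length = model.span[1] + 1000
    seq = rng.choice(list("ACGT"), size=length)
    if embed:
        for pos, s in embed.items():
            seq[pos - 1 : pos - 1 + len(s)] = list(s)
    with open(path, "w") as fh:
        fh.write(f">{model.chrom}\n")
        s = "".join(seq)
        for i in range(0, length, 60):
            fh.write(s[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# qPCR plates


def simulate_qpcr_plate(config: SimulationConfig) -> pd.DataFrame:
    """Triplicate mini-gene qPCR plate for the two plasmid alleles.

    Emits standard-curve wells (serial 5x dilutions of a pooled template)
    and experimental wells for every junction x {spliced, unspliced} assay
    plus the reference assays.  Cq values follow the standard-curve model
    ``cq = intercept + slope x log10(quantity)`` with the configured
    amplification efficiency and Gaussian well noise; per-sample loading
    factors apply to all assays of a sample and are cancelled by
    reference-gene normalisation.
    """
    qp = config.qpcr
    rng = config.rng("qpcr")
    slope = -1.0 / math.log10(1.0 + qp.amplification_efficiency)
    rows = []
    assays = []
    for j in qp.junctions:
        assays.append((f"spliced_{j}", "spliced", j))
        assays.append((f"unspliced_{j}", "unspliced", j))
    for ref in qp.reference_assays:
        assays.append((ref, "reference", None))
    intercepts = {aid: 22.0 + float(rng.normal(0, 1.0)) for aid, _, _ in assays}

    def true_quantity(role, j, allele):
        if role == "reference":
            return 1.0
        unspliced = qp.true_unspliced[allele][j]
        return qp.true_ratio[allele][j] * unspliced if role == "spliced" else unspliced

    # standard curves from pooled template (quantity 1 at dilution 1)
    for aid, role, j in assays:
        for d in range(qp.n_curve_dilutions):
            dilution = qp.dilution_step ** (-d)
            cq = intercepts[aid] + slope * math.log10(dilution) + float(
                rng.normal(0, qp.cq_noise_sd)
            )
            rows.append(("pool", "", aid, role, j, f"curve_{d}", cq, dilution))
    # experimental wells
    for allele in ("K", "A"):
        for s in range(qp.n_samples_per_allele):
            sample = f"{allele}_prep{s + 1}"
            loading = float(np.exp(rng.normal(0, qp.loading_cv)))
            for aid, role, j in assays:
                q = true_quantity(role, j, allele) * loading
                if role != "reference" and qp.sample_noise_cv > 0:
                    q *= float(np.exp(rng.normal(0, qp.sample_noise_cv)))
                for w in range(qp.n_wells):
                    cq = intercepts[aid] + slope * math.log10(q) + float(
                        rng.normal(0, qp.cq_noise_sd)
                    )
                    rows.append((sample, allele, aid, role, j, f"w{w + 1}", cq, None))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "allele", "assay_id", "assay_role", "junction", "well", "cq", "dilution"],
    )
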