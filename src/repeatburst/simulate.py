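"""Synthetic data generator.

Builds the inputs the analysis stages consume — genomes seeded with
transposon families, miRNA precursor clusters carrying the ESCC seed,
noisy expression matrices, and flow-cytometry peak positions — together
with the ground truth needed to test recovery.

Transposon copies are simulated under a master-lineage model: the active
element lineage accumulates substitutions through time, and each genomic
copy branches off the lineage at its insertion age and then evolves
independently at the same per-site rate. Copies from one burst therefore
diverge from each other by roughly ``2 * rate * age``, while any pair
spanning two bursts diverges by roughly ``2 * rate * max(age)`` — which is
what makes a two-burst family's pairwise-distance landscape bimodal rather
than trimodal, matching what divergence landscapes of real repeat
families look like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import BASE_BYTES, CODE, decode, encode, random_sequence, revcomp, to_dna
from .errors import InputError, PlacementError, SaturationError

SATURATION_BOUND = 0.75

# fixed reverse-translation table (one codon per residue) for embedding ORFs
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

# Synthetic stand-ins for the Myb-like and reverse-transcriptase domains
# carried by Harbinger and Gypsy elements. These are invented peptides with
# domain-like residue composition, not database profiles.
MYB_LIKE_PEPTIDE = (
    "MKGPWTREEDELLRELVNKHGTENWSLISSHMEGRTGKQCRERWHNQLDPN"
    "IKKDAWTEEEDRILIEAHKELGNRWAEIAKRLPGRTDNAIKNHWNSTIKRK"
)
RT_LIKE_PEPTIDE = (
    "MTPVFLVKKKDGSWRLVQDLRAINEVIEPMGALQPGLPSPAMIPKDWPLII"
    "IDLKDCFFTIPLHPDDRERFAFSVPSINNQEPMKRYQWKVLPQGMKNSPTL"
)

ESCC_SEED_RNA = "AAGUGC"

# miR-427-like and miR-93b-like mature sequences (ESCC-seed families whose
# copy-number expansion the generator plants by default: 155 and 66 loci).
MIR427_LIKE_MATURE = "AAAGUGCUUUCUGUUUUGGGCG"
MIR93B_LIKE_MATURE = "CAAAGUGCUGUUCGUGCAGGUAG"


@dataclass
class TEFamilySpec:
    """Parameters of one simulated transposon family.

    ``burst_ages`` are relative ages in [0, 1] (0 = now); a "continuous"
    family is expressed as many ages spread over the interval.
    ``per_site_rate`` is the substitution probability per site per unit
    age. ``burst_age_spread`` optionally smears each burst's branch ages
    uniformly by +/- that half-width (default 0: copies of a burst share
    an age exactly).
    """

    family_id: str
    master_length: int = 2000
    burst_ages: list[float] = field(default_factory=lambda: [0.1, 0.6])
    copies_per_burst: list[int] = field(default_factory=lambda: [50, 50])
    per_site_rate: float = 0.3
    has_domain: bool = False
    domain_peptide: str = MYB_LIKE_PEPTIDE
    burst_age_spread: float = 0.0
    model: str = "lineage"  # "lineage" (evolving source) or "star" (frozen master)

    def validate(self) -> None:
        if self.master_length < 1000:
            raise InputError("master_length must be >= 1000")
        if len(self.burst_ages) != len(self.copies_per_burst):
            raise InputError("burst_ages and copies_per_burst must have equal length")
        if not self.burst_ages:
            raise InputError("at least one burst is required")
        if any(a < 0 for a in self.burst_ages):
            raise InputError("burst ages must be non-negative")
        max_age = max(self.burst_ages) + self.burst_age_spread
        if self.per_site_rate * max_age >= SATURATION_BOUND:
            raise SaturationError(
                f"per_site_rate * max(age) = {self.per_site_rate * max_age:.3f} "
                f"exceeds the sub-saturation bound {SATURATION_BOUND}"
            )
        if self.has_domain and len(self.domain_peptide) < 20:
            raise InputError("domain_peptide must be at least 20 aa")
        if self.model not in ("lineage", "star"):
            raise InputError(f"unknown evolution model '{self.model}'")


@dataclass(frozen=True)
class CopyPlacement:
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    family_id: str
    age: float


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside every simulated dataset."""

    copy_coordinates: list[CopyPlacement] = field(default_factory=list)
    mirna_copy_counts: dict[str, int] = field(default_factory=dict)
    specific_gene_ids: list[str] = field(default_factory=list)
    broad_gene_ids: list[str] = field(default_factory=list)
    true_2c_pg: float | None = None

    def bed_lines(self) -> list[str]:
        """BED6 records: name = family_id, score = age * 1000."""
        return [
            f"{c.contig}\t{c.start}\t{c.end}\t{c.family_id}\t{int(round(c.age * 1000))}\t{c.strand}"
            for c in self.copy_coordinates
        ]


@dataclass
class SimulatedFamily:
    spec: TEFamilySpec
    master: str
    copies: list[str]
    ages: list[float]


def _mutate(arr: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Independent per-site substitution to a uniformly chosen other base."""
    out = arr.copy()
    idx = np.where(rng.random(arr.size) < p)[0]
    if idx.size:
        out[idx] = BASE_BYTES[(CODE[out[idx]] + rng.integers(1, 4, idx.size)) % 4]
    return out


def embed_orf(master: str, peptide: str) -> tuple[str, int]:
    """Splice an intact ORF encoding ``peptide`` into the middle of a master.

    Returns the modified master and the 0-based ORF start.
    """
    orf = "ATG" + "".join(_CODON[aa] for aa in peptide.upper().lstrip("M")) + "TAA"
    if len(orf) > len(master):
        raise InputError("domain ORF longer than master sequence")
    start = (len(master) - len(orf)) // 2
    return master[:start] + orf + master[start + len(orf):], start


def simulate_te_copies(
    spec: TEFamilySpec, seed: int = 0, master: str | None = None
) -> SimulatedFamily:
    """Simulate genomic copies of one transposon family.

    Under the default ``lineage`` model the active element itself evolves
    and copies branch off it at their burst age (pairwise distances within
    a burst ~ 2*rate*age; across bursts ~ 2*rate*max(age), the bimodal
    landscape of a two-burst family). Under the ``star`` model every copy
    derives independently from the frozen master with per-site
    substitution probability rate*age. Copies are returned grouped by
    burst in the order the bursts are listed; ``ages`` gives each copy's
    branch age.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    if master is None:
        master = random_sequence(spec.master_length, rng)
        if spec.has_domain:
            master, _ = embed_orf(master, spec.domain_peptide)
    elif len(master) != spec.master_length:
        raise InputError("provided master length does not match spec.master_length")

    branch: list[tuple[float, int, int]] = []  # (age, burst index, copy index)
    for b, (age, n) in enumerate(zip(spec.burst_ages, spec.copies_per_burst)):
        for c in range(n):
            a = age
            if spec.burst_age_spread > 0:
                a = rng.uniform(max(age - spec.burst_age_spread, 0.0), age + spec.burst_age_spread)
            branch.append((a, b, c))

    copies_by_key: dict[tuple[int, int], tuple[str, float]] = {}
    if spec.model == "star":
        for age, b, c in branch:
            copy = _mutate(encode(master), spec.per_site_rate * age, rng)
            copies_by_key[(b, c)] = (decode(copy), age)
    else:
        # evolve the lineage backwards in time, branching copies off as reached
        order = sorted(range(len(branch)), key=lambda i: branch[i][0])
        lineage = encode(master)
        prev_age = 0.0
        for i in order:
            age, b, c = branch[i]
            if age > prev_age:
                lineage = _mutate(lineage, spec.per_site_rate * (age - prev_age), rng)
                prev_age = age
            copy = _mutate(lineage, spec.per_site_rate * age, rng)
            copies_by_key[(b, c)] = (decode(copy), age)

    copies, ages = [], []
    for b, n in enumerate(spec.copies_per_burst):
        for c in range(n):
            s, a = copies_by_key[(b, c)]
            copies.append(s)
            ages.append(a)
    return SimulatedFamily(spec=spec, master=master, copies=copies, ages=ages)


def plant_copies_in_genome(
    background_length: int,
    copies: list[str],
    seed: int = 0,
    family_ids: list[str] | None = None,
    ages: list[float] | None = None,
    contig: str = "contig_1",
    max_tries: int = 500,
) -> tuple[dict[str, str], SimulationTruth]:
    """Insert copies at non-overlapping uniform-random positions.

    The emitted contig has exactly ``background_length`` bases: copies
    occupy disjoint intervals and i.i.d. uniform ACGT background fills the
    rest. Each copy lands on a random strand and is reverse-complemented
    into the genome when '-'; the truth records every placement in 0-based
    half-open coordinates, so extracting a truth interval (and reverse
    complementing '-' entries) reproduces the input copy exactly.
    """
    total = sum(len(c) for c in copies)
    if total > 0.5 * background_length:
        raise PlacementError(
            f"total copy length {total} exceeds half the background ({background_length})"
        )
    if family_ids is None:
        family_ids = [f"copy_{i}" for i in range(len(copies))]
    if ages is None:
        ages = [0.0] * len(copies)
    if not (len(copies) == len(family_ids) == len(ages)):
        raise InputError("copies, family_ids and ages must have equal length")

    rng = np.random.default_rng(seed)
    genome = encode(random_sequence(background_length, rng))
    placed: list[tuple[int, int]] = []
    placements: list[CopyPlacement] = []
    for copy, fam, age in zip(copies, family_ids, ages):
        L = len(copy)
        if L > background_length:
            raise PlacementError(f"copy of length {L} longer than the genome")
        for _ in range(max_tries):
            start = int(rng.integers(0, background_length - L + 1))
            end = start + L
            if all(end <= s or start >= e for s, e in placed):
                break
        else:
            raise PlacementError(f"could not place copy '{fam}' after {max_tries} tries")
        strand = "+" if rng.random() < 0.5 else "-"
        oriented = copy if strand == "+" else revcomp(copy)
        genome[start:end] = encode(oriented)
        placed.append((start, end))
        placements.append(CopyPlacement(contig, start, end, strand, fam, age))

    placements.sort(key=lambda p: p.start)
    truth = SimulationTruth(copy_coordinates=placements)
    return {contig: decode(genome)}, truth


@dataclass
class MirnaFamilyDef:
    """One planted miRNA family: a mature sequence expanded to many loci."""

    family_id: str
    mature: str
    n_copies: int
    hairpin_template: str | None = None  # must carry an N-run the size of the mature
    per_copy_mutations: int = 1
    escc: bool = True


def default_mirna_families() -> list[MirnaFamilyDef]:
    """The two ESCC-seed expansions planted by default: 155 + 66 loci."""
    return [
        MirnaFamilyDef("mir-427-like", MIR427_LIKE_MATURE, 155),
        MirnaFamilyDef("mir-93b-like", MIR93B_LIKE_MATURE, 66),
    ]


@dataclass
class MirnaSimulation:
    precursors: list[tuple[str, str]]  # (precursor id, DNA sequence)
    matures: dict[str, str]  # family_id -> mature as given (RNA preserved)
    truth_counts: dict[str, int]


def _seed_span(mature_dna: str) -> tuple[int, int]:
    """Span of the ESCC seed hexamer within the first eight nucleotides.

    Falls back to the canonical miRNA seed (positions 2-7) when absent.
    """
    pos = mature_dna[:8].find("AAGTGC")
    if 0 <= pos <= 2:
        return pos, pos + 6
    return 1, 7


def simulate_mirna_families(
    family_defs: list[MirnaFamilyDef] | None = None, seed: int = 0
) -> MirnaSimulation:
    """Generate precursor loci for each family with mutations sparing the seed."""
    if family_defs is None:
        family_defs = default_mirna_families()
    rng = np.random.default_rng(seed)
    precursors: list[tuple[str, str]] = []
    matures: dict[str, str] = {}
    counts: dict[str, int] = {}
    for fam in family_defs:
        mature_dna = to_dna(fam.mature)
        if len(mature_dna) < 18:
            raise InputError(f"mature sequence of '{fam.family_id}' shorter than 18 nt")
        if fam.escc and not 0 <= mature_dna[:8].find("AAGTGC") <= 2:
            raise InputError(
                f"family '{fam.family_id}' flagged ESCC but mature lacks AAGUGC "
                "within its first eight nucleotides"
            )
        template = fam.hairpin_template
        if template is None:
            template = (
                random_sequence(30, rng) + "N" * len(mature_dna) + random_sequence(30, rng)
            )
        template = to_dna(template)
        n_pos = template.find("N")
        if n_pos < 0 or template[n_pos : n_pos + len(mature_dna)] != "N" * len(mature_dna):
            raise InputError(
                f"hairpin template of '{fam.family_id}' lacks an N-run matching the mature length"
            )
        s0, s1 = _seed_span(mature_dna)
        mutable = [i for i in range(len(mature_dna)) if not s0 <= i < s1]
        for i in range(fam.n_copies):
            m = encode(mature_dna)
            if fam.per_copy_mutations:
                k = min(fam.per_copy_mutations, len(mutable))
                for p in rng.choice(mutable, size=k, replace=False):
                    m[p] = BASE_BYTES[(CODE[m[p]] + rng.integers(1, 4)) % 4]
            prec = template[:n_pos] + decode(m) + template[n_pos + len(mature_dna):]
            precursors.append((f"{fam.family_id}_copy{i + 1}", prec))
        matures[fam.family_id] = fam.mature
        counts[fam.family_id] = fam.n_copies
    return MirnaSimulation(precursors=precursors, matures=matures, truth_counts=counts)


@dataclass
class ExpressionSimulation:
    matrix: "object"  # pandas DataFrame, genes x tissues
    specific_gene_ids: list[str]
    broad_gene_ids: list[str]
    specific_tissue: dict[str, str]


def simulate_expression_matrix(
    n_genes: int,
    n_tissues: int,
    frac_specific: float = 0.2,
    fold_effect: float = 8.0,
    dispersion: float = 0.3,
    seed: int = 0,
    base_mean: float = 100.0,
    base_sigma: float = 1.0,
) -> ExpressionSimulation:
    """Noisy expression matrix with planted tissue-specific genes.

    Broad genes draw a per-gene log-normal baseline shared across tissues
    (log-normal multiplicative noise of width ``dispersion`` per value);
    specific genes receive baseline * fold_effect in one random tissue and
    baseline / fold_effect elsewhere. The number of specific genes is
    ``round(frac_specific * n_genes)`` exactly.
    """
    import pandas as pd

    if n_tissues < 2:
        raise InputError("n_tissues must be >= 2")
    if not 0.0 <= frac_specific <= 1.0:
        raise InputError("frac_specific must be within [0, 1]")
    if fold_effect < 1.0:
        raise InputError("fold_effect must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i + 1}" for i in range(n_genes)]
    tissues = [f"tissue_{j + 1}" for j in range(n_tissues)]
    n_spec = int(round(frac_specific * n_genes))
    spec_idx = rng.choice(n_genes, size=n_spec, replace=False) if n_spec else np.array([], int)
    is_spec = np.zeros(n_genes, bool)
    is_spec[spec_idx] = True

    baseline = base_mean * np.exp(rng.normal(0.0, base_sigma, n_genes))
    mean = np.repeat(baseline[:, None], n_tissues, axis=1)
    spec_tissue = {}
    for g in spec_idx:
        t = int(rng.integers(n_tissues))
        mean[g, :] = baseline[g] / fold_effect
        mean[g, t] = baseline[g] * fold_effect
        spec_tissue[genes[g]] = tissues[t]
    noise = np.exp(rng.normal(0.0, dispersion, (n_genes, n_tissues))) if dispersion > 0 else 1.0
    values = mean * noise
    df = pd.DataFrame(values, index=genes, columns=tissues)
    return ExpressionSimulation(
        matrix=df,
        specific_gene_ids=[genes[i] for i in np.where(is_spec)[0]],
        broad_gene_ids=[genes[i] for i in np.where(~is_spec)[0]],
        specific_tissue=spec_tissue,
    )


def simulate_cytometry(
    true_2c_pg: float,
    ref_2c_pg: float = 26.9,
    ref_peak: float = 13746.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[float, float]:
    """Fluorescence peak positions for a sample/reference pair.

    sample_peak = ref_peak * (true_2c / ref_2c) * (1 + eps), eps ~ N(0, noise_sd).
    """
    if min(true_2c_pg, ref_2c_pg, ref_peak) <= 0 or noise_sd < 0:
        raise InputError("cytometry parameters must be positive (noise_sd non-negative)")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    return ref_peak * (true_2c_pg / ref_2c_pg) * (1.0 + eps), ref_peak
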