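"""Synthetic inputs with a ground-truth answer key for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:
replicated mutant/wild-type log2 expression with a shared (core) set of
planted up/down genes plus genotype-private changes; a 23-tissue
expression atlas with planted tissue-biased gene groups and an elevated
inflorescence signal for core genes; a genome carrying planted fold-back
precursor loci that emit 20-21 nt mature miRNAs; per-genotype sRNA read
libraries with genotype-dependent presence/absence of those matures;
a conserved-20mer set (true 20mers plus decoys); and multi-category
GO-SLIM annotation tables with a planted transcription-factor excess
among the up-regulated core genes.

Every generator is a pure function of its configuration and seed:
identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import dna_to_rna, revcomp, rna_to_dna
from .io import (
    GeneModel,
    write_annotations,
    write_design,
    write_expression,
    write_fasta,
    write_gff3,
)
from .mirna_discovery import Locus

#: the 15 GO-SLIM molecular-function categories used throughout
GO_SLIM_MF_CATEGORIES: tuple[str, ...] = (
    "DNA or RNA binding",
    "hydrolase activity",
    "kinase activity",
    "nucleic acid binding",
    "nucleotide binding",
    "other binding",
    "other enzyme activity",
    "other molecular functions",
    "protein binding",
    "receptor binding or activity",
    "structural molecule activity",
    "transcription factor activity",
    "transferase activity",
    "transporter activity",
    "unknown molecular functions",
)

#: genome-scale relative frequencies of the categories above (background)
_CATEGORY_WEIGHTS = np.array(
    [1479, 2107, 1174, 431, 1000, 2127, 2225, 699, 1775, 181, 385, 1358, 1664, 1028, 5635],
    dtype=float,
)

CANONICAL_MUTANTS: tuple[str, ...] = ("dcl1-7", "hen1-1", "hyl1-2", "hst15")
WT_GROUP = "WT"

#: 23 tissue codes: three inflorescence stages plus the atlas panel
TISSUES: tuple[str, ...] = (
    "FL1", "FL2", "FL3",
    "RT1", "RT2", "RT3",
    "MS1", "MS2", "MS3", "MS4",
    "RL1", "RL2", "RL3", "RL4", "CL",
    "MP",
    "SL1", "SL2", "SL3",
    "SD1", "SD2", "SD3", "SD4",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: valid pairing partners (WC + G.U) per base, DNA alphabet
_PARTNERS = {"A": "T", "C": "G", "G": "CT", "T": "AG"}


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic data generators.

    Defaults follow the design of the emulated experiments: three
    replicate arrays per genotype, four canonical miRNA-pathway mutants,
    a 23-tissue atlas, and sRNA library depths matching the published
    454 library totals.
    """

    seed: int = 0
    n_genes: int = 8000
    n_mutants: int = 4
    n_reps: int = 3
    n_tissues: int = 23
    frac_shared_up: float = 0.015
    frac_shared_down: float = 0.0125
    frac_private: float = 0.03
    frac_cross_hyb: float = 0.03
    effect_lfc: float = 2.0
    noise_sd: float = 0.35
    n_hairpins: int = 10
    n_novel: int = 5
    n_decoy_kmers: int = 50
    library_sizes: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {
            "rdr2-1": 4573,
            "rdr6-15": 6441,
            "Col-0": 7488,
            "dcl1-7": 8663,
            "dcl234": 6214,
        }
    )
    genome_len: int = 200_000
    n_chromosomes: int = 2
    gene_len: int = 400
    n_unique_background: int = 2000
    site_mismatches: int = 2
    hairpin_mismatches: int = 1
    #: inflorescence elevation of core genes in the atlas: a ~1 sd tendency,
    #: so core genes are enriched toward high inflorescence ranks without
    #: exhausting the top rank bins (the rank-matched null needs non-core
    #: genes at every inflorescence rank a core gene can take)
    infl_effect_lfc: float = 0.35
    targets_per_mature: int = 2
    inflorescence_tissue: str = "FL1"

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        fr = (self.frac_shared_up, self.frac_shared_down)
        if any(f < 0 for f in fr) or sum(fr) > 1:
            raise ValueError("shared fractions must be >= 0 and sum to <= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for name in ("n_genes", "n_mutants", "n_tissues", "n_hairpins", "n_decoy_kmers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_novel > self.n_hairpins:
            raise ValueError("n_novel cannot exceed n_hairpins")

    @property
    def mutants(self) -> tuple[str, ...]:
        extra = tuple(f"mut{i}" for i in range(5, self.n_mutants + 1))
        return CANONICAL_MUTANTS[: self.n_mutants] + extra

    @property
    def tissues(self) -> tuple[str, ...]:
        extra = tuple(f"T{i}" for i in range(24, self.n_tissues + 1))
        return TISSUES[: self.n_tissues] + extra


@dataclasses.dataclass(frozen=True)
class PlantedMature:
    name: str
    mature: str  # RNA alphabet, 5'->3'
    locus: Locus  # genomic span of the mature itself
    precursor: Locus  # genomic span of the whole stem-loop insert
    arm: str  # "5'" | "3'"
    is_novel: bool


@dataclasses.dataclass
class GroundTruth:
    """Answer key for a simulated study (plus the simulated genome itself)."""

    planted_up: frozenset[str]
    planted_down: frozenset[str]
    #: genes that carry the shared effect but are cross-hybridization-flagged
    #: (they change in every mutant yet are excluded from the answer key,
    #: mirroring the probe-set filter applied to the observed core sets)
    planted_up_flagged: frozenset[str]
    planted_down_flagged: frozenset[str]
    cross_hyb: frozenset[str]
    private_up: dict[str, frozenset[str]]
    private_down: dict[str, frozenset[str]]
    planted_bias: dict[str, tuple[frozenset[str], frozenset[str]]]
    planted_matures: list[PlantedMature]
    planted_targets: dict[str, tuple[str, ...]]
    genotype_presence: dict[str, dict[str, int]]
    known_matures: dict[str, str]
    genome: dict[str, str]
    gene_models: list[GeneModel]
    mrna_to_gene: dict[str, str]
    universe: tuple[str, ...]


@dataclasses.dataclass(frozen=True)
class HairpinLocus:
    """A constructed stem-loop precursor (DNA, transcript sense)."""

    seq: str
    mature_start: int  # 0-based half-open span of the mature on seq
    mature_end: int
    arm: str


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _mutate_star(star: str, mature: str, k: int, rng: np.random.Generator) -> str:
    """Introduce exactly k substitutions into the star arm.

    Substituted bases are interior (never the two terminal stem pairs),
    non-adjacent, and chosen so the new base cannot pair (WC or wobble)
    with the opposing mature base — each substitution yields a symmetric
    1x1 internal loop, never a bulge.
    """
    L = len(mature)
    interior = list(range(2, L - 2))
    if k > (len(interior) + 1) // 2:
        raise ValueError(f"{k} mismatches do not fit a {L} nt stem")
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out = list(star)
    pos: list[int] = []
    order = rng.permutation(interior)
    for p in order:
        if len(pos) == k:
            break
        if any(abs(p - q) <= 1 for q in pos):
            continue
        # a register-shifted co-optimal fold exists if the mismatched mature
        # base can pair (incl. wobble) the star partner of a neighbour
        if comp[mature[p - 1]] in _PARTNERS[mature[p]]:
            continue
        if comp[mature[p + 1]] in _PARTNERS[mature[p]]:
            continue
        # the substitute must pair neither the opposing mature base nor its
        # neighbours (same register-shift argument from the star side)
        forbidden = (
            set(_PARTNERS[mature[p]])
            | set(_PARTNERS[mature[p - 1]])
            | set(_PARTNERS[mature[p + 1]])
            | {out[L - 1 - p]}
        )
        choices = [b for b in "ACGT" if b not in forbidden]
        if not choices:
            continue
        pos.append(int(p))
        out[L - 1 - p] = choices[rng.integers(0, len(choices))]
    if len(pos) < k:
        raise ValueError(f"could not place {k} clean mismatches in a {L} nt stem")
    return "".join(out)


def build_hairpin_locus(
    mature: str,
    arm_gap: int = 8,
    loop_len: int = 4,
    n_mismatches: int = 0,
    seed: int = 0,
    arm: str = "5'",
    lower_stem: int = 12,
    upper_stem: int = 8,
) -> HairpinLocus:
    """Construct a DNA precursor whose transcript folds into a stem-loop.

    The mature sits on one arm, its near-complement (exactly
    ``n_mismatches`` substitutions, none creating an asymmetric bulge) on
    the other, separated by a terminal loop of ``loop_len`` C residues.
    As in real pre-miRNAs the pairing extends beyond the miRNA/miRNA*
    duplex: a perfectly paired lower stem (``lower_stem`` nt) below the
    duplex and an upper stem (``upper_stem`` nt) between the duplex and
    the loop keep the mature in the helix interior.  ``arm_gap`` unpaired
    A spacers flank the stem; the spacer and the all-C loop cannot pair
    with each other, keeping the planted duplex the dominant structure.
    """
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 to close a hairpin")
    mature = mature.upper()
    if any(b not in "ACGU" for b in mature):
        raise ValueError("mature must be RNA over {A,C,G,U}")
    if n_mismatches >= len(mature):
        raise ValueError("mature would be fully unpaired")
    rng = np.random.default_rng(seed)
    m_dna = rna_to_dna(mature)
    star = _mutate_star(revcomp(m_dna), m_dna, n_mismatches, rng)
    lower = _random_seq(rng, lower_stem)
    upper = _random_seq(rng, upper_stem)
    flank = "A" * arm_gap
    loop = "C" * loop_len
    if arm == "5'":
        arm5, arm3 = m_dna, star
    elif arm == "3'":
        arm5, arm3 = star, m_dna
    else:
        raise ValueError("arm must be \"5'\" or \"3'\"")
    seq = (
        flank + lower + arm5 + upper + loop + revcomp(upper) + arm3 + revcomp(lower) + flank
    )
    if arm == "5'":
        m0 = arm_gap + lower_stem
    else:
        m0 = arm_gap + lower_stem + len(star) + upper_stem + loop_len + upper_stem
    return HairpinLocus(seq=seq, mature_start=m0, mature_end=m0 + len(m_dna), arm=arm)


def _transcript_write(
    chrom: np.ndarray, start0: int, end0: int, strand: str, offset: int, payload: str
) -> None:
    """Write ``payload`` at transcript offset ``offset`` of a gene interval.

    ``start0:end0`` is the 0-based half-open genomic interval; on the
    minus strand the payload is reverse-complemented and placed so the
    transcript (5'->3') reads the payload at ``offset``.
    """
    if strand == "+":
        g0 = start0 + offset
        chrom[g0 : g0 + len(payload)] = np.frombuffer(payload.encode(), dtype=np.uint8)
    else:
        g1 = end0 - offset
        rc = revcomp(payload)
        chrom[g1 - len(payload) : g1] = np.frombuffer(rc.encode(), dtype=np.uint8)


def make_ground_truth(cfg: SimConfig) -> GroundTruth:
    """Build the genome, planted loci and the full answer key."""
    rng = np.random.default_rng([1, cfg.seed])
    universe = tuple(f"At1g{(i + 1) * 10:05d}" for i in range(cfg.n_genes))
    genes = np.array(universe)

    n_up = round(cfg.frac_shared_up * cfg.n_genes)
    n_down = round(cfg.frac_shared_down * cfg.n_genes)
    perm = rng.permutation(cfg.n_genes)
    shared_up = set(map(str, genes[perm[:n_up]]))
    shared_down = set(map(str, genes[perm[n_up : n_up + n_down]]))
    rest = genes[perm[n_up + n_down :]]

    cross_hyb = set(map(str, genes[rng.random(cfg.n_genes) < cfg.frac_cross_hyb]))
    planted_up = frozenset(shared_up - cross_hyb)
    planted_down = frozenset(shared_down - cross_hyb)
    planted_up_flagged = frozenset(shared_up & cross_hyb)
    planted_down_flagged = frozenset(shared_down & cross_hyb)

    n_priv = round(cfg.frac_private * cfg.n_genes)
    private_up: dict[str, frozenset[str]] = {}
    private_down: dict[str, frozenset[str]] = {}
    for mut in cfg.mutants:
        pick = rng.choice(rest, size=min(2 * n_priv, len(rest)), replace=False)
        private_up[mut] = frozenset(map(str, pick[:n_priv]))
        private_down[mut] = frozenset(map(str, pick[n_priv:]))

    # --- mature miRNAs: novel ones are far from every known mature
    known_matures = {
        f"ath-miR-known-{i + 1}": dna_to_rna(_random_seq(rng, int(rng.integers(20, 22))))
        for i in range(3)
    }
    from .mirna_discovery import _shifted_hamming  # avoid cycle at module load

    matures: list[tuple[str, str, bool]] = []  # (name, rna, is_novel)
    hairpins: dict[str, HairpinLocus] = {}
    for i in range(cfg.n_hairpins):
        is_novel = i < cfg.n_novel
        arm = "5'" if i % 2 == 0 else "3'"
        while True:
            seq = dna_to_rna(_random_seq(rng, int(rng.integers(20, 22))))
            dists = [
                _shifted_hamming(seq, k) for k in known_matures.values()
            ]
            if is_novel and not all(d > 3 for d in dists):
                continue
            try:
                hp = build_hairpin_locus(
                    seq,
                    arm_gap=8,
                    loop_len=4,
                    n_mismatches=cfg.hairpin_mismatches,
                    seed=int(rng.integers(0, 2**31)),
                    arm=arm,
                )
            except ValueError:
                continue  # no clean mismatch placement; draw another mature
            break
        name = f"mir-sim-{i + 1}"
        matures.append((name, seq, is_novel))
        hairpins[name] = hp
        if not is_novel:
            known_matures[f"ath-{name}"] = seq

    # --- genome layout: modeled genes then precursors, sequential with gaps
    chrom_len = cfg.genome_len // cfg.n_chromosomes
    chrom_ids = [f"Chr{i + 1}" for i in range(cfg.n_chromosomes)]
    chroms = {
        cid: np.frombuffer(_random_seq(rng, chrom_len).encode(), dtype=np.uint8).copy()
        for cid in chrom_ids
    }

    extra_models = [str(g) for g in genes[perm[n_up + n_down : n_up + n_down + 20]]]
    modeled = sorted(shared_up | shared_down) + extra_models
    gene_models: list[GeneModel] = []
    cursors = {cid: 0 for cid in chrom_ids}
    placements: dict[str, GeneModel] = {}
    ci = 0
    for g in modeled:
        cid = chrom_ids[ci % len(chrom_ids)]
        ci += 1
        gap = int(rng.integers(50, 200))
        start0 = cursors[cid] + gap
        end0 = start0 + cfg.gene_len
        if end0 > chrom_len:
            raise ValueError("genome_len too small for the requested gene models")
        strand = "+" if rng.random() < 0.5 else "-"
        model = GeneModel(g, cid, start0 + 1, end0, strand)
        gene_models.append(model)
        placements[g] = model
        cursors[cid] = end0

    planted_list: list[PlantedMature] = []
    precursor_spans: list[tuple[str, int, int]] = []
    for idx, (name, rna, is_novel) in enumerate(matures):
        hp = hairpins[name]
        arm = hp.arm
        cid = chrom_ids[idx % len(chrom_ids)]
        gap = int(rng.integers(50, 200))
        start0 = cursors[cid] + gap
        end0 = start0 + len(hp.seq)
        if end0 > chrom_len:
            raise ValueError("genome_len too small for the planted precursors")
        strand = "+" if rng.random() < 0.5 else "-"
        payload = hp.seq if strand == "+" else revcomp(hp.seq)
        chroms[cid][start0:end0] = np.frombuffer(payload.encode(), dtype=np.uint8)
        cursors[cid] = end0
        if strand == "+":
            m_start0 = start0 + hp.mature_start
            m_end0 = start0 + hp.mature_end
        else:
            m_end0 = end0 - hp.mature_start
            m_start0 = end0 - hp.mature_end
        planted_list.append(
            PlantedMature(
                name=name,
                mature=rna,
                locus=Locus(cid, strand, m_start0 + 1, m_end0),
                precursor=Locus(cid, strand, start0 + 1, end0),
                arm=arm,
            is_novel=is_novel,
            )
        )
        precursor_spans.append((cid, start0, end0))

    # --- target sites inside planted-up gene transcripts
    up_modeled = sorted(planted_up & set(placements))
    planted_targets: dict[str, tuple[str, ...]] = {}
    target_pool = rng.permutation(up_modeled)
    pool_idx = 0
    sites_in_gene: dict[str, int] = {}
    for name, rna, _ in matures:
        chosen: list[str] = []
        for _ in range(min(cfg.targets_per_mature, len(up_modeled))):
            g = str(target_pool[pool_idx % len(target_pool)])
            pool_idx += 1
            if g not in chosen:
                chosen.append(g)
        L = len(rna)
        site = list(revcomp(rna_to_dna(rna)))
        allowed = [1] + list(range(13, L + 1))  # 1-based sRNA positions
        mm_pos = rng.choice(allowed, size=cfg.site_mismatches, replace=False)
        for p in mm_pos:
            c = L - int(p)  # window column for sRNA position p
            options = [b for b in "ACGT" if b != site[c]]
            site[c] = options[rng.integers(0, len(options))]
        site_seq = "".join(site)
        for g in chosen:
            model = placements[g]
            slot = sites_in_gene.get(g, 0)
            sites_in_gene[g] = slot + 1
            off = 20 + slot * (L + 10)  # non-overlapping slots per gene
            if off + L + 20 > cfg.gene_len:
                raise ValueError("gene_len too small for the planted target sites")
            _transcript_write(
                chroms[model.seqid],
                model.start - 1,
                model.end,
                model.strand,
                off,
                site_seq,
            )
        planted_targets[name] = tuple(chosen)

    genome = {cid: arr.tobytes().decode() for cid, arr in chroms.items()}

    # --- genotype-dependent sRNA library presence
    genotype_presence: dict[str, dict[str, int]] = {}
    for i, (name, _, _) in enumerate(matures):
        counts = {"rdr2-1": int(rng.integers(1, 4))}
        if i == 1:  # one mature also detectable outside the enriched library
            counts["Col-0"] = 2
            counts["dcl234"] = 3
        genotype_presence[name] = counts

    # --- planted tissue bias (meristem-high/pollen-low for up, mirrored down)
    planted_bias = {
        "MS2": (planted_up, planted_down),
        "MP": (planted_down, planted_up),
    }

    mrna_to_gene = {f"{m.gene_id}.1": m.gene_id for m in gene_models}
    return GroundTruth(
        planted_up=planted_up,
        planted_down=planted_down,
        planted_up_flagged=planted_up_flagged,
        planted_down_flagged=planted_down_flagged,
        cross_hyb=frozenset(cross_hyb),
        private_up=private_up,
        private_down=private_down,
        planted_bias=planted_bias,
        planted_matures=planted_list,
        planted_targets=planted_targets,
        genotype_presence=genotype_presence,
        known_matures=known_matures,
        genome=genome,
        gene_models=gene_models,
        mrna_to_gene=mrna_to_gene,
        universe=universe,
    )


def mrna_sequences(truth: GroundTruth, genes: Sequence[str] | None = None) -> dict[str, str]:
    """Transcript-sense DNA sequences for modeled genes (mRNA id -> seq)."""
    wanted = set(genes) if genes is not None else None
    out = {}
    for m in truth.gene_models:
        if wanted is not None and m.gene_id not in wanted:
            continue
        seq = truth.genome[m.seqid][m.start - 1 : m.end]
        if m.strand == "-":
            seq = revcomp(seq)
        out[f"{m.gene_id}.1"] = seq
    return out


def simulate_expression(
    cfg: SimConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.Series]:
    """Replicated log2 expression for WT plus each mutant, with design labels.

    Planted shared genes shift by +/- ``effect_lfc`` in every mutant;
    genotype-private genes shift only in their own mutant; i.i.d. Gaussian
    noise with sd ``noise_sd`` on the log2 scale.
    """
    rng = np.random.default_rng([2, cfg.seed])
    genes = list(truth.universe)
    gi = {g: k for k, g in enumerate(genes)}
    mu = rng.normal(8.0, 1.5, len(genes))

    groups = [WT_GROUP] + list(cfg.mutants)
    samples, labels, cols = [], [], []
    shared_up = truth.planted_up | truth.planted_up_flagged
    shared_down = truth.planted_down | truth.planted_down_flagged
    for grp in groups:
        effect = np.zeros(len(genes))
        if grp != WT_GROUP:
            for g in shared_up:
                effect[gi[g]] += cfg.effect_lfc
            for g in shared_down:
                effect[gi[g]] -= cfg.effect_lfc
            for g in truth.private_up.get(grp, ()):
                effect[gi[g]] += cfg.effect_lfc
            for g in truth.private_down.get(grp, ()):
                effect[gi[g]] -= cfg.effect_lfc
        for r in range(cfg.n_reps):
            samples.append(mu + effect + rng.normal(0, cfg.noise_sd, len(genes)))
            labels.append(grp)
            cols.append(f"{grp}_r{r + 1}")
    matrix = pd.DataFrame(np.column_stack(samples), index=genes, columns=cols)
    design = pd.Series(labels, index=cols, name="group")
    return matrix, design


def simulate_tissue_atlas(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Genes x 23-tissue log2 atlas with planted tissue-biased groups.

    Background genes are exchangeable across tissues.  Genes in a planted
    high-set gain ``effect_lfc`` in their tissue, low-set genes lose it,
    and all core-set genes are additionally elevated in the designated
    inflorescence tissue (emulating inflorescence-derived material).
    """
    rng = np.random.default_rng([3, cfg.seed])
    genes = list(truth.universe)
    gi = {g: k for k, g in enumerate(genes)}
    tissues = list(cfg.tissues)
    if cfg.inflorescence_tissue not in tissues:
        raise ValueError("inflorescence tissue not in the atlas panel")
    base = rng.normal(8.0, 1.5, len(genes))
    mat = base[:, None] + rng.normal(0, cfg.noise_sd, (len(genes), len(tissues)))

    core = truth.planted_up | truth.planted_down
    j = tissues.index(cfg.inflorescence_tissue)
    for g in core:
        mat[gi[g], j] += cfg.infl_effect_lfc
    for t, (high, low) in truth.planted_bias.items():
        if t not in tissues:
            continue
        j = tissues.index(t)
        for g in high:
            mat[gi[g], j] += cfg.effect_lfc
        for g in low:
            mat[gi[g], j] -= cfg.effect_lfc
    return pd.DataFrame(mat, index=genes, columns=tissues)


def simulate_srna_libraries(
    cfg: SimConfig, truth: GroundTruth
) -> tuple[dict[str, dict[str, str]], pd.DataFrame]:
    """Per-genotype sRNA read libraries (FASTA-shaped) plus a count table.

    Planted matures are emitted only in the libraries named by the answer
    key's presence map; the remaining reads are random genome substrings
    of 20-24 nt drawn from a fixed pool of distinct background species
    (sampled with replacement, as resequencing does), excluding the
    planted precursor loci.  Per-library totals equal
    ``cfg.library_sizes`` exactly.
    """
    rng = np.random.default_rng([4, cfg.seed])
    forbidden = [
        (m.precursor.seqid, m.precursor.start - 1, m.precursor.end)
        for m in truth.planted_matures
    ]
    chrom_ids = list(truth.genome)
    pool: list[str] = []
    seen: set[str] = set()
    guard = 0
    while len(pool) < cfg.n_unique_background and guard < 50 * cfg.n_unique_background:
        guard += 1
        cid = chrom_ids[int(rng.integers(0, len(chrom_ids)))]
        L = int(rng.integers(20, 25))
        chrom = truth.genome[cid]
        if len(chrom) <= L:
            continue
        p = int(rng.integers(0, len(chrom) - L))
        if any(c == cid and p < e and p + L > s for c, s, e in forbidden):
            continue
        seq = chrom[p : p + L]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        if seq in seen:
            continue
        seen.add(seq)
        pool.append(seq)
    if len(pool) < cfg.n_unique_background:
        raise ValueError("genome too small to draw the background sRNA pool")

    libraries: dict[str, dict[str, str]] = {}
    rows = []
    for lib, total in cfg.library_sizes.items():
        planted = [
            (m.name, rna_to_dna(m.mature), truth.genotype_presence[m.name].get(lib, 0))
            for m in truth.planted_matures
        ]
        n_planted = sum(c for _, _, c in planted)
        if n_planted > total:
            raise ValueError(f"library {lib}: planted counts exceed library size")
        reads: dict[str, str] = {}
        k = 0
        for name, seq, count in planted:
            for _ in range(count):
                k += 1
                reads[f"{lib}_r{k:06d}"] = seq
        idx = rng.integers(0, len(pool), total - n_planted)
        for i in idx:
            k += 1
            reads[f"{lib}_r{k:06d}"] = pool[int(i)]
        libraries[lib] = reads
        for name, _, count in planted:
            rows.append({"library": lib, "mature": name, "count": count})
        rows.append({"library": lib, "mature": "TOTAL", "count": total})
    counts = pd.DataFrame(rows, columns=["library", "mature", "count"])
    return libraries, counts


def simulate_conserved_kmers(
    truth: GroundTruth, n_decoys: int = 50, seed: int = 0, kmer_len: int = 20
) -> dict[str, str]:
    """Conserved-kmer set: one exact substring per planted mature + decoys.

    Decoys are rejection-sampled so that none occurs in any planted
    mature; duplicates are removed.
    """
    rng = np.random.default_rng([5, seed])
    kmers: dict[str, str] = {}
    seen: set[str] = set()
    mature_dnas = [rna_to_dna(m.mature) for m in truth.planted_matures]
    for m, dna in zip(truth.planted_matures, mature_dnas):
        off = int(rng.integers(0, len(dna) - kmer_len + 1))
        k = dna[off : off + kmer_len]
        if k not in seen:
            seen.add(k)
            kmers[f"kmer-{m.name}"] = k
    d = 0
    while d < n_decoys:
        k = _random_seq(rng, kmer_len)
        if k in seen or any(k in dna for dna in mature_dnas):
            continue
        seen.add(k)
        d += 1
        kmers[f"decoy-{d}"] = k
    return kmers


def simulate_go_annotations(
    cfg: SimConfig,
    truth: GroundTruth,
    categories: Sequence[str] = GO_SLIM_MF_CATEGORIES,
    tf_up_rate: float = 0.25,
    extra_rate: float = 0.13,
) -> dict[str, list[str]]:
    """Multi-category GO-SLIM annotations with a planted TF excess.

    Every gene carries one or more categories (annotation counts can
    exceed gene counts).  Planted-up genes draw "transcription factor
    activity" as their primary category at rate ``tf_up_rate`` instead of
    the background frequency.
    """
    if not categories:
        raise ValueError("at least one category is required")
    rng = np.random.default_rng([6, cfg.seed])
    cats = list(categories)
    if len(cats) == len(GO_SLIM_MF_CATEGORIES):
        weights = _CATEGORY_WEIGHTS / _CATEGORY_WEIGHTS.sum()
    else:
        weights = np.full(len(cats), 1 / len(cats))
    tf = "transcription factor activity"
    out: dict[str, list[str]] = {}
    for g in truth.universe:
        if g in truth.planted_up and tf in cats and rng.random() < tf_up_rate:
            primary = tf
        else:
            primary = cats[int(rng.choice(len(cats), p=weights))]
        assigned = [primary]
        while rng.random() < extra_rate:
            extra = cats[int(rng.choice(len(cats), p=weights))]
            if extra not in assigned:
                assigned.append(extra)
        out[g] = assigned
    return out


# ---------------------------------------------------------------------------
# Bundle


@dataclasses.dataclass
class SimBundle:
    cfg: SimConfig
    truth: GroundTruth
    expression: pd.DataFrame
    design: pd.Series
    atlas: pd.DataFrame
    libraries: dict[str, dict[str, str]]
    library_counts: pd.DataFrame
    kmers: dict[str, str]
    annotations: dict[str, list[str]]


def simulate_all(cfg: SimConfig) -> SimBundle:
    """Generate every pipeline input from one configuration."""
    truth = make_ground_truth(cfg)
    expression, design = simulate_expression(cfg, truth)
    atlas = simulate_tissue_atlas(cfg, truth)
    libraries, counts = simulate_srna_libraries(cfg, truth)
    kmers = simulate_conserved_kmers(truth, cfg.n_decoy_kmers, cfg.seed)
    annotations = simulate_go_annotations(cfg, truth)
    return SimBundle(
        cfg=cfg,
        truth=truth,
        expression=expression,
        design=design,
        atlas=atlas,
        libraries=libraries,
        library_counts=counts,
        kmers=kmers,
        annotations=annotations,
    )


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write all bundle inputs as deterministic plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["expression"] = out / "expression.tsv"
    write_expression(paths["expression"], bundle.expression)
    paths["design"] = out / "design.tsv"
    write_design(paths["design"], bundle.design)
    paths["atlas"] = out / "atlas.tsv"
    write_expression(paths["atlas"], bundle.atlas)
    paths["genome"] = out / "genome.fasta"
    write_fasta(paths["genome"], bundle.truth.genome)
    paths["genes"] = out / "genes.gff3"
    write_gff3(paths["genes"], bundle.truth.gene_models)
    paths["kmers"] = out / "conserved_20mers.fasta"
    write_fasta(paths["kmers"], bundle.kmers)
    paths["known_matures"] = out / "known_matures.fasta"
    write_fasta(
        paths["known_matures"],
        {k: rna_to_dna(v) for k, v in bundle.truth.known_matures.items()},
    )
    for lib, reads in bundle.libraries.items():
        p = out / f"srna_{lib}.fasta"
        write_fasta(p, reads)
        paths[f"library:{lib}"] = p
    paths["library_counts"] = out / "library_counts.tsv"
    bundle.library_counts.to_csv(paths["library_counts"], sep="\t", index=False)
    paths["annotations"] = out / "go_annotations.tsv"
    write_annotations(paths["annotations"], bundle.annotations)
    return paths
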