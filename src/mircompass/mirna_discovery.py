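"""Novel-miRNA discovery cascade.

Candidate small RNAs are matched antisense against the mRNAs of the
up-regulated core set (gapless, mismatch-tolerant), filtered for perfect
matches to a set of conserved 20mers, located in the genome, folded inside
a ~500 nt window centred on the locus, screened as hairpins by explicit
duplex-geometry criteria, and finally checked for valid target sites,
similarity to known mature miRNAs, and genotype-dependent expression
across the sRNA libraries.

Coordinate conventions: genomic loci are 1-based inclusive and
strand-tagged; spans inside an extracted window are 0-based half-open in
transcript (5'->3') sense.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import dna_to_rna, encode, revcomp, rna_to_dna
from .folding import fold, pair_table

__all__ = [
    "SiteRule",
    "DiscoveryConfig",
    "TargetHit",
    "Locus",
    "HairpinCandidate",
    "DiscoveryReport",
    "antisense_match",
    "antisense_match_all",
    "match_conserved_kmers",
    "locate_in_genome",
    "extract_window",
    "fold",
    "mircheck_evaluate",
    "validate_target_site",
    "hamming_to_known",
    "count_library_occurrences",
    "discover",
]


# ---------------------------------------------------------------------------
# Configuration


@dataclasses.dataclass(frozen=True)
class SiteRule:
    """Empirical miRNA:target pairing constraints (Schwab-style).

    Positions are 1-based from the sRNA's 5' end.  A site fails if it has
    a mismatch at any forbidden position or more than ``window_max_mismatch``
    mismatches inside the ``window`` (inclusive).
    """

    forbidden_positions: frozenset[int] = frozenset({10, 11})
    window: tuple[int, int] = (2, 12)
    window_max_mismatch: int = 1


@dataclasses.dataclass(frozen=True)
class DiscoveryConfig:
    max_mismatch: int = 3
    kmer_len: int = 20
    window_nt: int = 500
    mature_len_range: tuple[int, int] = (20, 21)
    min_loop: int = 3
    max_unpaired_mature: int = 4
    max_asym_bulge: int = 0
    site_rule: SiteRule = SiteRule()
    hamming_known_max: int = 2
    #: sRNA library providing candidate sequences (miRNA-enriched background)
    source_library: str = "rdr2-1"
    #: library in which a true miRNA must be absent (miRNA-depleted)
    absent_library: str = "dcl1-7"

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.window_nt < 2 * self.mature_len_range[1] + self.min_loop:
            raise ValueError("window_nt too small to hold a hairpin")


# ---------------------------------------------------------------------------
# Domain types


@dataclasses.dataclass(frozen=True)
class TargetHit:
    """A gapless antisense match of an sRNA on an mRNA."""

    srna_id: str
    mrna_id: str
    site_start: int  # 1-based inclusive on the mRNA
    site_end: int
    mismatch_positions: frozenset[int]  # 1-based from the sRNA 5' end
    passes_site_rule: bool | None = None

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatch_positions)


@dataclasses.dataclass(frozen=True)
class Locus:
    seqid: str
    strand: str
    start: int  # 1-based inclusive
    end: int


@dataclasses.dataclass(frozen=True)
class HairpinCandidate:
    locus: Locus | None
    window_seq: str
    dotbracket: str
    mature_span: tuple[int, int]  # 0-based half-open on the window
    arm: str | None  # "5'" | "3'" | None on failure
    n_unpaired_mature: int
    n_asym_bulge: int
    star_span: tuple[int, int] | None
    verdict: str  # "pass" | "fail"
    reason: str


# ---------------------------------------------------------------------------
# Stage operations


def _hamming_hits(
    mrna_codes: np.ndarray, srna: str, max_mismatch: int
) -> tuple[np.ndarray, np.ndarray]:
    """Offsets and mismatch matrix of gapless antisense matches.

    Returns (offsets into the mRNA, boolean mismatch matrix rows aligned
    with offsets, columns in window orientation).
    """
    query = encode(rna_to_dna(revcomp(srna)))
    L = query.shape[0]
    if L > mrna_codes.shape[0]:
        return np.empty(0, dtype=np.int64), np.empty((0, L), dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(mrna_codes, L)
    mism = (windows != query) | (windows == 4) | (query == 4)
    counts = mism.sum(axis=1)
    offsets = np.nonzero(counts <= max_mismatch)[0]
    return offsets, mism[offsets]


def antisense_match(srna: str, mrna: str, max_mismatch: int = 3) -> list[TargetHit]:
    """Slide the reverse complement of ``srna`` along ``mrna`` (gapless).

    Every offset with Hamming distance <= ``max_mismatch`` is a hit.
    Ambiguous bases (N) always count as mismatches.  Mismatch positions
    are 1-based from the sRNA's 5' end (which aligns with the 3' end of
    the site on the mRNA).
    """
    if not srna or not mrna:
        raise ValueError("empty sequence")
    if len(srna) > len(mrna):
        raise ValueError("sRNA longer than mRNA")
    codes = encode(rna_to_dna(mrna))
    offsets, mism = _hamming_hits(codes, srna, max_mismatch)
    L = len(srna)
    hits = []
    for off, row in zip(offsets, mism):
        # window column c corresponds to sRNA position L - c (1-based, 5')
        positions = frozenset(int(L - c) for c in np.nonzero(row)[0])
        hits.append(
            TargetHit(
                srna_id="srna",
                mrna_id="mrna",
                site_start=int(off) + 1,
                site_end=int(off) + L,
                mismatch_positions=positions,
            )
        )
    return hits


def antisense_match_all(
    srnas: Mapping[str, str], mrnas: Mapping[str, str], max_mismatch: int = 3
) -> dict[str, list[TargetHit]]:
    """Batch antisense matching of many sRNAs against many mRNAs.

    The mRNAs are concatenated with N spacers so each sRNA is scanned in a
    single vectorised pass; hits spanning two mRNAs are impossible because
    the spacer is longer than any sRNA and N always mismatches.
    """
    if not mrnas:
        return {sid: [] for sid in srnas}
    max_len = max((len(s) for s in srnas.values()), default=0)
    spacer = "N" * (max_len + 1)
    ids = list(mrnas)
    concat = spacer.join(mrnas[i] for i in ids)
    codes = encode(rna_to_dna(concat))
    starts = np.empty(len(ids), dtype=np.int64)
    pos = 0
    for k, i in enumerate(ids):
        starts[k] = pos
        pos += len(mrnas[i]) + len(spacer)
    lengths = np.array([len(mrnas[i]) for i in ids], dtype=np.int64)

    out: dict[str, list[TargetHit]] = {}
    for sid, seq in srnas.items():
        L = len(seq)
        offsets, mism = _hamming_hits(codes, seq, max_mismatch)
        hits = []
        for off, row in zip(offsets, mism):
            k = int(np.searchsorted(starts, off, side="right")) - 1
            local = int(off) - int(starts[k])
            if local + L > lengths[k]:
                continue  # spans a spacer
            positions = frozenset(int(L - c) for c in np.nonzero(row)[0])
            hits.append(
                TargetHit(
                    srna_id=sid,
                    mrna_id=ids[k],
                    site_start=local + 1,
                    site_end=local + L,
                    mismatch_positions=positions,
                )
            )
        out[sid] = hits
    return out


def extract_mrnas(
    genome: Mapping[str, str],
    gene_models: Sequence,
    genes: Iterable[str] | None = None,
) -> dict[str, str]:
    """Transcript-sense mRNA sequences from genome + gene models.

    Returns ``{"<gene>.1": sequence}`` for the requested genes (all
    modeled genes when ``genes`` is None); minus-strand models are
    reverse-complemented so every sequence reads 5'->3'.
    """
    wanted = set(genes) if genes is not None else None
    out = {}
    for m in gene_models:
        if wanted is not None and m.gene_id not in wanted:
            continue
        seq = genome[m.seqid][m.start - 1 : m.end]
        if m.strand == "-":
            seq = revcomp(seq)
        out[f"{m.gene_id}.1"] = seq
    return out


def match_conserved_kmers(
    srna: str, kmer_set: Iterable[str], kmer_len: int = 20
) -> set[str]:
    """Conserved kmers equal to a same-strand substring of the sRNA."""
    s = rna_to_dna(srna).upper()
    subs = {s[i : i + kmer_len] for i in range(len(s) - kmer_len + 1)}
    return {k for k in kmer_set if rna_to_dna(k).upper() in subs}


def locate_in_genome(srna: str, genome: Mapping[str, str]) -> list[Locus]:
    """Exact full-length matches of the sRNA on both genome strands."""
    query = rna_to_dna(srna).upper()
    rc = revcomp(query)
    loci = []
    for seqid in genome:
        chrom = genome[seqid].upper()
        for pattern, strand in ((query, "+"), (rc, "-")):
            idx = chrom.find(pattern)
            while idx != -1:
                loci.append(Locus(seqid, strand, idx + 1, idx + len(pattern)))
                idx = chrom.find(pattern, idx + 1)
    return loci


def extract_window(
    genome: Mapping[str, str], locus: Locus, window_nt: int = 500
) -> tuple[str, tuple[int, int]]:
    """Extract a transcript-sense RNA window centred on a genomic locus.

    Returns (window RNA 5'->3' in transcript sense, 0-based half-open
    mature span inside the window).  The window is truncated at chromosome
    ends; for windows that cannot be centred exactly the extra base goes
    3' of centre.
    """
    chrom = genome[locus.seqid]
    L = locus.end - locus.start + 1
    flank_total = max(window_nt - L, 0)
    flank5 = flank_total // 2
    flank3 = flank_total - flank5
    if locus.strand == "+":
        gstart = max(locus.start - flank5, 1)
        gend = min(locus.end + flank3, len(chrom))
        window = chrom[gstart - 1 : gend]
        m0 = locus.start - gstart
    else:
        gstart = max(locus.start - flank3, 1)
        gend = min(locus.end + flank5, len(chrom))
        window = revcomp(chrom[gstart - 1 : gend])
        m0 = gend - locus.end
    return dna_to_rna(window.upper()), (m0, m0 + L)


def _terminal_loops(partners: np.ndarray) -> list[tuple[int, int]]:
    """Intervals strictly inside pairs that enclose no further pairs."""
    loops = []
    for i in np.nonzero(partners >= 0)[0]:
        j = partners[i]
        if j > i and not (partners[i + 1 : j] >= 0).any():
            loops.append((i + 1, j))  # half-open interior
    return loops


def mircheck_evaluate(
    window_seq: str,
    dotbracket: str,
    mature_span: tuple[int, int],
    cfg: DiscoveryConfig = DiscoveryConfig(),
    locus: Locus | None = None,
) -> HairpinCandidate:
    """Screen a folded window for a plant-miRNA-style hairpin duplex.

    Along the mature the function counts unpaired bases and asymmetric
    bulges (a gap between consecutive paired mature bases whose opposite
    arm gap has a different length), infers the star span from the
    partners of the paired mature bases, and rejects matures that are not
    in a stem, that overlap a terminal loop, or whose duplex geometry
    exceeds the configured thresholds.
    """
    m0, m1 = mature_span
    if not (0 <= m0 < m1 <= len(window_seq)):
        raise ValueError("mature span outside window")
    if len(dotbracket) != len(window_seq):
        raise ValueError("structure/sequence length mismatch")
    partners = pair_table(dotbracket)

    def fail(reason: str, **kw) -> HairpinCandidate:
        return HairpinCandidate(
            locus=locus,
            window_seq=window_seq,
            dotbracket=dotbracket,
            mature_span=mature_span,
            arm=kw.get("arm"),
            n_unpaired_mature=kw.get("n_unpaired", m1 - m0),
            n_asym_bulge=kw.get("n_asym", 0),
            star_span=kw.get("star_span"),
            verdict="fail",
            reason=reason,
        )

    paired = [p for p in range(m0, m1) if partners[p] >= 0]
    n_unpaired = (m1 - m0) - len(paired)
    if not paired:
        return fail("not in stem")

    mates = partners[paired]
    self_paired = (mates >= m0) & (mates < m1)
    if self_paired.any() or ((mates >= m1).any() and (mates < m0).any()):
        return fail("mature spans terminal loop", n_unpaired=n_unpaired)
    arm = "5'" if mates[0] >= m1 else "3'"

    for lo, hi in _terminal_loops(partners):
        if max(m0, lo) < min(m1, hi):
            return fail("mature overlaps terminal loop", n_unpaired=n_unpaired, arm=arm)

    n_asym = 0
    for a, b in zip(paired[:-1], paired[1:]):
        gap_m = b - a - 1
        gap_s = abs(int(partners[a]) - int(partners[b])) - 1
        if gap_m != gap_s:
            n_asym += 1
    star_span = (int(mates.min()), int(mates.max()) + 1)

    reasons = []
    if n_unpaired > cfg.max_unpaired_mature:
        reasons.append(f"{n_unpaired} unpaired mature bases")
    if n_asym > cfg.max_asym_bulge:
        reasons.append(f"{n_asym} asymmetric bulges")
    return HairpinCandidate(
        locus=locus,
        window_seq=window_seq,
        dotbracket=dotbracket,
        mature_span=mature_span,
        arm=arm,
        n_unpaired_mature=n_unpaired,
        n_asym_bulge=n_asym,
        star_span=star_span,
        verdict="fail" if reasons else "pass",
        reason="; ".join(reasons) if reasons else "ok",
    )


def validate_target_site(hit: TargetHit, rule: SiteRule = SiteRule()) -> bool:
    """Apply the empirical pairing constraints to an antisense hit."""
    if hit.mismatch_positions & rule.forbidden_positions:
        return False
    lo, hi = rule.window
    in_window = sum(1 for p in hit.mismatch_positions if lo <= p <= hi)
    return in_window <= rule.window_max_mismatch


def _shifted_hamming(a: str, b: str) -> int:
    """Hamming distance for equal lengths; otherwise minimal-shift distance.

    The shorter sequence slides along the longer; distance is the minimum
    substitution count over shifts plus the length difference.
    """
    if len(a) > len(b):
        a, b = b, a
    diff = len(b) - len(a)
    best = len(a)
    for off in range(diff + 1):
        d = sum(1 for x, y in zip(a, b[off : off + len(a)]) if x != y)
        best = min(best, d)
    return best + diff


def hamming_to_known(
    mature: str, known_matures: Mapping[str, str]
) -> tuple[str | None, int]:
    """Closest known mature miRNA and its (shift-aware) Hamming distance."""
    if not known_matures:
        return None, len(mature)
    q = dna_to_rna(mature).upper()
    best = min(
        ((_shifted_hamming(q, dna_to_rna(s).upper()), kid) for kid, s in known_matures.items()),
    )
    return best[1], best[0]


def count_library_occurrences(
    mature: str, libraries: Mapping[str, Mapping[str, str] | Sequence[str]]
) -> dict[str, int]:
    """Exact same-strand read counts of a mature sequence per sRNA library."""
    q = rna_to_dna(mature).upper()
    counts = {}
    for lib, reads in libraries.items():
        seqs = reads.values() if isinstance(reads, Mapping) else reads
        counts[lib] = sum(1 for s in seqs if rna_to_dna(s).upper() == q)
    return counts


# ---------------------------------------------------------------------------
# Pipeline composition


@dataclasses.dataclass
class CandidateRow:
    srna_id: str
    mature: str  # RNA alphabet
    status: str  # "novel" | "known" | "variant_of_known"
    closest_known: str | None
    hamming_to_known: int
    loci: list[Locus]
    arms: list[str]
    target_mrnas: list[str]
    target_genes: list[str]
    library_counts: dict[str, int]


@dataclasses.dataclass
class DiscoveryReport:
    funnel: dict[str, int]
    candidates: list[CandidateRow]
    hairpins: list[HairpinCandidate]

    @property
    def novel(self) -> list[CandidateRow]:
        return [c for c in self.candidates if c.status == "novel"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            rows.append(
                {
                    "srna_id": c.srna_id,
                    "mature_miRNA": c.mature,
                    "status": c.status,
                    "closest_known": c.closest_known or "",
                    "hamming_to_known": c.hamming_to_known,
                    "loci": ";".join(
                        f"{l.seqid}:{l.strand}:{l.start}-{l.end}" for l in c.loci
                    ),
                    "arms": ";".join(c.arms),
                    "target_mrnas": ";".join(c.target_mrnas),
                    "target_genes": ";".join(c.target_genes),
                    **{f"count_{k}": v for k, v in c.library_counts.items()},
                }
            )
        return pd.DataFrame(rows)

    def funnel_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(self.funnel), "count": list(self.funnel.values())}
        )


def _unique_srnas(reads: Mapping[str, str]) -> dict[str, str]:
    """Collapse reads to unique sequences; id = first read id carrying it."""
    seen: dict[str, str] = {}
    for rid, seq in reads.items():
        key = rna_to_dna(seq).upper()
        if key not in seen:
            seen[key] = rid
    return {rid: seq for seq, rid in seen.items()}


def discover(
    core_up_mrnas: Mapping[str, str],
    srna_libraries: Mapping[str, Mapping[str, str]],
    kmer_set: Iterable[str],
    genome: Mapping[str, str],
    known_matures: Mapping[str, str],
    cfg: DiscoveryConfig = DiscoveryConfig(),
    mrna_to_gene: Mapping[str, str] | None = None,
) -> DiscoveryReport:
    """Run the full discovery cascade and report survivors per stage.

    Candidate sRNAs are the unique read sequences of the miRNA-enriched
    source library.  A candidate is reported as a novel mature miRNA when
    it (1) matches a core-set mRNA antisense with at most
    ``cfg.max_mismatch`` mismatches, (2) contains a conserved kmer as an
    exact substring, (3) has length inside ``cfg.mature_len_range``,
    (4) is farther than ``cfg.hamming_known_max`` from every known mature,
    (5) folds into a passing hairpin at one of its genomic loci, (6) has a
    target site satisfying the pairing rule, and (7) is expressed in the
    source library but absent from the miRNA-depleted library.
    """
    kmers = list(kmer_set)
    funnel: dict[str, int] = {}
    source_reads = srna_libraries.get(cfg.source_library, {})
    srnas = _unique_srnas(source_reads)
    funnel["unique_srnas"] = len(srnas)

    hits_by_srna = antisense_match_all(srnas, core_up_mrnas, cfg.max_mismatch)
    matched = {sid: s for sid, s in srnas.items() if hits_by_srna[sid]}
    funnel["antisense_matched"] = len(matched)

    kmer_ok = {
        sid: s
        for sid, s in matched.items()
        if match_conserved_kmers(s, kmers, cfg.kmer_len)
    }
    funnel["kmer_matched"] = len(kmer_ok)

    lo, hi = cfg.mature_len_range
    sized = {sid: s for sid, s in kmer_ok.items() if lo <= len(s) <= hi}
    funnel["mature_length"] = len(sized)

    known_ids, variant_ids, novel_cand = {}, {}, {}
    for sid, s in sized.items():
        closest, dist = hamming_to_known(s, known_matures)
        if dist == 0:
            known_ids[sid] = (closest, dist)
        elif dist <= cfg.hamming_known_max:
            variant_ids[sid] = (closest, dist)
        else:
            novel_cand[sid] = (closest, dist)
    funnel["known"] = len(known_ids)
    funnel["variant_of_known"] = len(variant_ids)
    funnel["novel_candidates"] = len(novel_cand)

    hairpins: list[HairpinCandidate] = []
    candidates: list[CandidateRow] = []
    n_hairpin = n_site = n_expressed = 0
    for sid, (closest, dist) in sorted(novel_cand.items()):
        seq = sized[sid]
        passing_loci, arms = [], []
        for locus in locate_in_genome(seq, genome):
            window, span = extract_window(genome, locus, cfg.window_nt)
            structure, _ = fold(window, cfg.min_loop)
            hp = mircheck_evaluate(window, structure, span, cfg, locus=locus)
            hairpins.append(hp)
            if hp.verdict == "pass":
                passing_loci.append(locus)
                arms.append(hp.arm or "")
        if not passing_loci:
            continue
        n_hairpin += 1

        good_hits = [
            dataclasses.replace(h, passes_site_rule=True)
            for h in hits_by_srna[sid]
            if validate_target_site(h, cfg.site_rule)
        ]
        if not good_hits:
            continue
        n_site += 1

        counts = count_library_occurrences(seq, srna_libraries)
        if counts.get(cfg.source_library, 0) <= 0 or counts.get(cfg.absent_library, 0) != 0:
            continue
        n_expressed += 1

        mrna_ids = sorted({h.mrna_id for h in good_hits})
        genes = sorted(
            {mrna_to_gene.get(m, m) for m in mrna_ids}
        ) if mrna_to_gene else mrna_ids
        candidates.append(
            CandidateRow(
                srna_id=sid,
                mature=dna_to_rna(seq).upper(),
                status="novel",
                closest_known=closest,
                hamming_to_known=dist,
                loci=passing_loci,
                arms=arms,
                target_mrnas=mrna_ids,
                target_genes=genes,
                library_counts=counts,
            )
        )
    funnel["hairpin_pass"] = n_hairpin
    funnel["target_site_pass"] = n_site
    funnel["expressed_novel"] = n_expressed
    return DiscoveryReport(funnel=funnel, candidates=candidates, hairpins=hairpins)
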