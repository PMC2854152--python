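"""Discovery cascade operations: matchers, windows, hairpin screen, pipeline."""

import numpy as np
import pytest

from mircompass._seq import dna_to_rna, revcomp, rna_to_dna
from mircompass.folding import fold
from mircompass.mirna_discovery import (
    DiscoveryConfig,
    Locus,
    SiteRule,
    TargetHit,
    antisense_match,
    antisense_match_all,
    count_library_occurrences,
    discover,
    extract_window,
    hamming_to_known,
    locate_in_genome,
    match_conserved_kmers,
    mircheck_evaluate,
    validate_target_site,
)
from mircompass.synthetic_data import build_hairpin_locus


def oracle_antisense(srna, mrna, max_mm):
    """O(n*m) nested-loop scan used as the independent reference."""
    q = rna_to_dna(revcomp(srna)).upper()
    m = rna_to_dna(mrna).upper()
    L = len(q)
    hits = []
    for off in range(len(m) - L + 1):
        mism = [
            L - c
            for c in range(L)
            if m[off + c] != q[c] or m[off + c] == "N" or q[c] == "N"
        ]
        if len(mism) <= max_mm:
            hits.append((off + 1, frozenset(mism)))
    return hits


class TestAntisenseMatch:
    def test_exact_interior_match(self):
        rng = np.random.default_rng(0)
        mrna = "".join(rng.choice(list("ACGT"), 200))
        srna = dna_to_rna(revcomp(mrna[80:101]))
        hits = antisense_match(srna, mrna, 3)
        exact = [h for h in hits if h.n_mismatch == 0]
        assert len(exact) == 1
        assert (exact[0].site_start, exact[0].site_end) == (81, 101)

    def test_threshold_boundary(self):
        mrna = "A" * 30 + "GGGGGGGGGGGGGGGGGGGGG" + "A" * 30
        srna = dna_to_rna(revcomp("GGGGGGGGGGGGGGGGGGGGG"))
        # four substitutions at the site: no hit at max_mismatch=3
        broken = mrna[:30] + "TTTT" + mrna[34:]
        assert antisense_match(srna, mrna, 3)
        assert not [
            h for h in antisense_match(srna, broken, 3) if h.site_start == 31
        ]

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(1)
        mrna = "".join(rng.choice(list("ACGT"), 500))
        for _ in range(25):
            L = int(rng.integers(20, 25))
            if rng.random() < 0.5:
                srna = dna_to_rna("".join(rng.choice(list("ACGT"), L)))
            else:  # planted near-site so hits actually occur
                off = int(rng.integers(0, 500 - L))
                site = list(mrna[off : off + L])
                for p in rng.choice(L, 2, replace=False):
                    site[p] = rng.choice([b for b in "ACGT" if b != site[p]])
                srna = dna_to_rna(revcomp("".join(site)))
            got = [
                (h.site_start, h.mismatch_positions)
                for h in antisense_match(srna, mrna, 3)
            ]
            assert got == oracle_antisense(srna, mrna, 3)

    def test_batch_agrees_with_single(self):
        rng = np.random.default_rng(2)
        mrnas = {
            f"m{i}": "".join(rng.choice(list("ACGT"), 120)) for i in range(4)
        }
        srnas = {}
        for i in range(6):
            src = mrnas[f"m{i % 4}"]
            srnas[f"s{i}"] = dna_to_rna(revcomp(src[10 : 10 + 21]))
        batch = antisense_match_all(srnas, mrnas, 3)
        for sid, seq in srnas.items():
            singles = [
                (mid, h.site_start, h.mismatch_positions)
                for mid, mseq in mrnas.items()
                for h in antisense_match(seq, mseq, 3)
            ]
            got = [(h.mrna_id, h.site_start, h.mismatch_positions) for h in batch[sid]]
            assert sorted(got) == sorted(singles)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            antisense_match("", "ACGT", 3)


class TestKmersAndGenome:
    def test_kmer_prefix_of_longer_srna_matches(self):
        srna = "ACGUACGUACGUACGUACGUA"  # 21 nt
        kmer = rna_to_dna(srna[:20])
        assert match_conserved_kmers(srna, [kmer]) == {kmer}

    def test_central_substitution_breaks_match(self):
        srna = "ACGUACGUACGUACGUACGUA"
        kmer = list(rna_to_dna(srna[:20]))
        kmer[10] = "A" if kmer[10] != "A" else "C"
        assert match_conserved_kmers(srna, ["".join(kmer)]) == set()

    def test_kmer_batch_matches_substring_oracle(self):
        rng = np.random.default_rng(3)
        srnas = ["".join(rng.choice(list("ACGT"), 22)) for _ in range(20)]
        kmers = [s[1:21] for s in srnas[:10]] + [
            "".join(rng.choice(list("ACGT"), 20)) for _ in range(10)
        ]
        for s in srnas:
            expect = {k for k in kmers if k in s}
            assert match_conserved_kmers(s, kmers) == expect

    def test_locate_minus_strand_and_multicopy(self):
        rng = np.random.default_rng(4)
        mature = "".join(rng.choice(list("ACGT"), 21))
        chrom = (
            "".join(rng.choice(list("ACGT"), 100))
            + revcomp(mature)
            + "".join(rng.choice(list("ACGT"), 50))
            + mature
            + "".join(rng.choice(list("ACGT"), 30))
        )
        loci = locate_in_genome(dna_to_rna(mature), {"Chr1": chrom})
        strands = sorted((l.strand, l.start) for l in loci)
        assert len(loci) == 2
        assert strands[0] == ("+", 172)
        assert strands[1] == ("-", 101)
        assert locate_in_genome("UUUUUUUUUUUUUUUUUUUUU", {"Chr1": chrom}) == []

    def test_extract_window_centering_and_truncation(self):
        rng = np.random.default_rng(5)
        chrom = "".join(rng.choice(list("ACGT"), 1000))
        mature = chrom[500:521]
        win, span = extract_window({"Chr1": chrom}, Locus("Chr1", "+", 501, 521), 100)
        assert len(win) == 100
        assert rna_to_dna(win[span[0] : span[1]]) == mature
        # locus near the chromosome start: left-truncated, span still correct
        near = chrom[5:26]
        win2, span2 = extract_window({"Chr1": chrom}, Locus("Chr1", "+", 6, 26), 100)
        assert len(win2) < 100
        assert rna_to_dna(win2[span2[0] : span2[1]]) == near

    def test_extract_window_minus_strand_reads_transcript_sense(self):
        rng = np.random.default_rng(6)
        chrom = "".join(rng.choice(list("ACGT"), 400))
        mature_rc = chrom[200:221]
        win, span = extract_window({"Chr1": chrom}, Locus("Chr1", "-", 201, 221), 80)
        assert rna_to_dna(win[span[0] : span[1]]) == revcomp(mature_rc)


class TestHairpinScreen:
    def _eval(self, hp, cfg=DiscoveryConfig()):
        structure, _ = fold(hp.seq)
        return mircheck_evaluate(
            hp.seq, structure, (hp.mature_start, hp.mature_end), cfg
        )

    def test_clean_hairpin_passes_with_star_span(self):
        hp = build_hairpin_locus("ACGUACGUACGUACGUACGUA", n_mismatches=0, seed=1)
        cand = self._eval(hp)
        assert cand.verdict == "pass"
        assert cand.star_span is not None
        s0, s1 = cand.star_span
        assert s1 - s0 == 21  # perfect duplex star mirrors the mature

    def test_mature_across_terminal_loop_fails(self):
        hp = build_hairpin_locus("ACGUACGUACGUACGUACGUA", n_mismatches=0, seed=1)
        structure, _ = fold(hp.seq)
        # shift the claimed mature span onto the loop
        centre = len(hp.seq) // 2
        cand = mircheck_evaluate(
            hp.seq, structure, (centre - 10, centre + 11), DiscoveryConfig()
        )
        assert cand.verdict == "fail"
        assert "loop" in cand.reason

    def test_unstructured_region_fails_not_in_stem(self):
        window = "A" * 60 + "GGGGG" + "CCCC" + "CCCCC" + "A" * 60
        structure, _ = fold(window)
        cand = mircheck_evaluate(window, structure, (10, 31), DiscoveryConfig())
        assert cand.verdict == "fail"
        assert cand.reason == "not in stem"

    def test_asymmetric_bulge_fails_when_disallowed(self):
        """A 2 nt insertion under the mature (no opposing bases) must be
        counted as an asymmetric bulge and rejected at the default of 0."""
        mature = "GCAGCCAAGGAUGACUUGCCG"
        m = rna_to_dna(mature)
        bulged = m[:10] + "TT" + m[10:]  # mature arm carries 2 extra bases
        star = revcomp(m)
        seq = "A" * 8 + bulged + "CCCC" + star + "A" * 8
        structure, _ = fold(seq)
        cand = mircheck_evaluate(seq, structure, (8, 8 + len(bulged)), DiscoveryConfig())
        assert cand.verdict == "fail"
        assert cand.n_asym_bulge >= 1

    def test_too_many_unpaired_mature_bases_fail(self):
        import dataclasses

        hp = build_hairpin_locus("ACGUACGUACGUACGUACGUA", n_mismatches=3, seed=3)
        cfg = dataclasses.replace(DiscoveryConfig(), max_unpaired_mature=2)
        cand = self._eval(hp, cfg)
        assert cand.verdict == "fail"
        assert "unpaired" in cand.reason


class TestSiteRuleAndKnown:
    @pytest.mark.parametrize(
        "positions,ok",
        [
            (set(), True),
            ({10}, False),
            ({11}, False),
            ({2, 5}, False),
            ({5}, True),
            ({1, 13, 21}, True),
            ({12, 13}, True),
            ({2, 13, 21}, True),
        ],
    )
    def test_pairing_rule(self, positions, ok):
        hit = TargetHit("s", "m", 1, 21, frozenset(positions))
        assert validate_target_site(hit, SiteRule()) is ok

    def test_hamming_identical_and_substituted(self):
        known = {"k1": "ACGUACGUACGUACGUACGUA", "k2": "UUUUUUUUUUUUUUUUUUUUU"}
        assert hamming_to_known("ACGUACGUACGUACGUACGUA", known) == ("k1", 0)
        two_off = "ACGUACGUACGUACGUACGAC"
        assert hamming_to_known(two_off, known) == ("k1", 2)

    def test_hamming_length_difference_uses_minimal_shift(self):
        known = {"k": "ACGUACGUACGUACGUACGUA"}  # 21 nt
        sub = "CGUACGUACGUACGUACGUA"  # 20 nt suffix: distance = 1 length diff
        assert hamming_to_known(sub, known) == ("k", 1)

    def test_hamming_batch_matches_pairwise_oracle(self):
        rng = np.random.default_rng(7)
        known = {
            f"k{i}": dna_to_rna("".join(rng.choice(list("ACGT"), 21)))
            for i in range(8)
        }
        for _ in range(10):
            q = dna_to_rna("".join(rng.choice(list("ACGT"), int(rng.integers(20, 22)))))
            _, dist = hamming_to_known(q, known)
            def pair_dist(a, b):
                if len(a) > len(b):
                    a, b = b, a
                d = len(b) - len(a)
                return d + min(
                    sum(x != y for x, y in zip(a, b[o : o + len(a)]))
                    for o in range(d + 1)
                )
            assert dist == min(pair_dist(q, s) for s in known.values())

    def test_count_occurrences_matches_grep_oracle(self):
        rng = np.random.default_rng(8)
        mature = "".join(rng.choice(list("ACGT"), 21))
        libs = {}
        for lib, n_cp in (("rdr2-1", 2), ("dcl1-7", 0), ("Col-0", 1)):
            reads = {
                f"{lib}_r{i}": "".join(rng.choice(list("ACGT"), 21)) for i in range(30)
            }
            for i in range(n_cp):
                reads[f"{lib}_p{i}"] = mature
            libs[lib] = reads
        counts = count_library_occurrences(dna_to_rna(mature), libs)
        for lib, reads in libs.items():
            assert counts[lib] == sum(1 for s in reads.values() if s == mature)


class TestDiscoverPipeline:
    def test_empty_srna_input_gives_empty_report(self, truth, bundle):
        report = discover(
            {}, {"rdr2-1": {}, "dcl1-7": {}}, bundle.kmers.values(), truth.genome, {}
        )
        assert report.candidates == []
        assert report.funnel["unique_srnas"] == 0

    def test_variant_of_known_not_reported_novel(self, truth, bundle):
        from mircompass.synthetic_data import mrna_sequences

        m = truth.planted_matures[0]
        # register the planted novel as a 1-substitution variant of a known
        variant = list(m.mature)
        variant[5] = "A" if variant[5] != "A" else "C"
        known = dict(truth.known_matures)
        known["near-variant"] = "".join(variant)
        mrnas = mrna_sequences(truth, truth.planted_targets[m.name])
        libs = {
            "rdr2-1": {"r1": rna_to_dna(m.mature)},
            "dcl1-7": {},
        }
        report = discover(mrnas, libs, bundle.kmers.values(), truth.genome, known)
        assert report.funnel["variant_of_known"] == 1
        assert all(c.mature != m.mature for c in report.novel)

    def test_funnel_is_monotone_and_recovers_planted(self, bundle, truth):
        from mircompass.synthetic_data import mrna_sequences

        mrnas = mrna_sequences(truth, truth.planted_up)
        report = discover(
            mrnas,
            bundle.libraries,
            bundle.kmers.values(),
            truth.genome,
            truth.known_matures,
            DiscoveryConfig(),
            truth.mrna_to_gene,
        )
        f = report.funnel
        chain = ["unique_srnas", "antisense_matched", "kmer_matched", "mature_length"]
        for a, b in zip(chain, chain[1:]):
            assert f[a] >= f[b]
        assert f["known"] + f["variant_of_known"] + f["novel_candidates"] == f["mature_length"]
        assert f["novel_candidates"] >= f["hairpin_pass"] >= f["target_site_pass"] >= f["expressed_novel"]
        novel_truth = {m.mature for m in truth.planted_matures if m.is_novel}
        assert {c.mature for c in report.novel} == novel_truth
        # reported targets and counts agree with the answer key
        by_mature = {c.mature: c for c in report.novel}
        for m in truth.planted_matures:
            if not m.is_novel:
                continue
            cand = by_mature[m.mature]
            assert set(truth.planted_targets[m.name]) <= set(cand.target_genes)
            assert cand.library_counts["rdr2-1"] == truth.genotype_presence[m.name]["rdr2-1"]
            assert cand.library_counts["dcl1-7"] == 0

    def test_complementary_pair_on_one_precursor(self):
        """One stem-loop can emit passing matures from both arms that target
        different mRNAs (the two-miRNAs-one-gene configuration)."""
        rng = np.random.default_rng(9)
        mature_a = "GCAGCCAAGGAUGACUUGCCG"
        hp = build_hairpin_locus(mature_a, n_mismatches=2, seed=12)
        # the opposite arm, read 5'->3', is itself a candidate mature
        arm3_start = hp.mature_end + 8 + 4 + 8  # upper stem + loop + upper stem
        mature_b = dna_to_rna(hp.seq[arm3_start : arm3_start + 21])
        genome = {
            "Chr1": "".join(rng.choice(list("ACGT"), 300))
            + hp.seq
            + "".join(rng.choice(list("ACGT"), 300))
        }
        def mk_mrna(mat):
            site = revcomp(rna_to_dna(mat))
            return (
                "".join(rng.choice(list("ACGT"), 50))
                + site
                + "".join(rng.choice(list("ACGT"), 50))
            )
        mrnas = {"tA.1": mk_mrna(mature_a), "tB.1": mk_mrna(mature_b)}
        libs = {
            "rdr2-1": {"r1": rna_to_dna(mature_a), "r2": rna_to_dna(mature_b)},
            "dcl1-7": {},
        }
        kmers = [rna_to_dna(mature_a)[:20], rna_to_dna(mature_b)[:20]]
        report = discover(mrnas, libs, kmers, genome, {}, DiscoveryConfig())
        found = {c.mature for c in report.novel}
        assert found == {mature_a, mature_b}
        arms = {c.mature: c.arms for c in report.novel}
        assert arms[mature_a] == ["5'"]
        assert arms[mature_b] == ["3'"]

    def test_strand_coherence(self):
        """Recovery of a planted mature does not depend on the precursor's
        genomic strand."""
        rng = np.random.default_rng(10)
        mature = "GCAGCCAAGGAUGACUUGCCG"
        hp = build_hairpin_locus(mature, n_mismatches=1, seed=4)
        flank1 = "".join(rng.choice(list("ACGT"), 300))
        flank2 = "".join(rng.choice(list("ACGT"), 300))
        site = revcomp(rna_to_dna(mature))
        mrna = {"t.1": "A" * 30 + site + "A" * 30}
        libs = {"rdr2-1": {"r1": rna_to_dna(mature)}, "dcl1-7": {}}
        kmers = [rna_to_dna(mature)[:20]]
        for payload in (hp.seq, revcomp(hp.seq)):
            genome = {"Chr1": flank1 + payload + flank2}
            report = discover(mrna, libs, kmers, genome, {}, DiscoveryConfig())
            assert [c.mature for c in report.novel] == [mature]
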