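import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from triframe.alphabet import AMINO_ACIDS
from triframe.encoding import reverse_complement, translate_frame
from triframe.simulate import (
    OUTLIER,
    FamilySpec,
    ReadSimConfig,
    generate_families,
    generate_outliers,
    inject_errors,
    make_references,
    reverse_translate,
    simulate_reads,
    split_members,
)

proteins = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=60)


class TestGenerateFamilies:
    def test_zero_noise_members_identical(self):
        spec = FamilySpec(
            n_families=2, within_family_substitution_rate=0.0, seed=0
        )
        fams = generate_families(spec)
        for cons, members in zip(fams.consensus, fams.members):
            assert all(m == cons for m in members)

    def test_motifs_invariant_and_substitution_rate_calibrated(self):
        rate = 0.15
        spec = FamilySpec(
            n_families=2,
            motifs_per_family=2,
            motif_length=10,
            motif_margin=10,
            within_family_substitution_rate=rate,
            members_per_family=1000,
            seed=3,
        )
        fams = generate_families(spec)
        mismatches = 0
        n_free = 0
        for fam_i in range(2):
            cons = fams.consensus[fam_i]
            in_motif = np.zeros(len(cons), dtype=bool)
            for start, motif in fams.motifs[fam_i]:
                in_motif[start : start + len(motif)] = True
                for m in fams.members[fam_i]:
                    assert m[start : start + len(motif)] == motif
            free = np.flatnonzero(~in_motif)
            for m in fams.members[fam_i]:
                mismatches += sum(m[p] != cons[p] for p in free)
                n_free += len(free)
        # binomial(n_free, rate) within 3 standard deviations
        sd = np.sqrt(n_free * rate * (1 - rate))
        assert abs(mismatches - n_free * rate) < 3 * sd

    def test_determinism_and_seed_sensitivity(self):
        a = generate_families(FamilySpec(seed=1))
        b = generate_families(FamilySpec(seed=1))
        c = generate_families(FamilySpec(seed=2))
        assert a.members == b.members and a.motifs == b.motifs
        assert a.motif_strings() != c.motif_strings()

    def test_overlapping_motifs_rejected(self):
        with pytest.raises(ValueError, match="motif"):
            FamilySpec(
                n_families=2,
                protein_length=30,
                motifs_per_family=3,
                motif_length=10,
                motif_margin=5,
            )

    def test_shared_background_differs_only_at_motif_sites(self):
        spec = FamilySpec(
            n_families=3, within_family_substitution_rate=0.0, seed=4
        )
        fams = generate_families(spec)
        motif_sites = set()
        for fam in fams.motifs:
            for start, motif in fam:
                motif_sites.update(range(start, start + len(motif)))
        for a in range(3):
            for b in range(a + 1, 3):
                diff = {
                    p
                    for p in range(spec.protein_length)
                    if fams.consensus[a][p] != fams.consensus[b][p]
                }
                assert diff <= motif_sites


class TestReverseTranslate:
    @pytest.mark.parametrize("protein,cds", [("M", "ATG"), ("MW", "ATGTGG")])
    def test_single_codon_residues(self, protein, cds):
        assert reverse_translate(protein, 0) == cds

    @given(proteins, st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_translation(self, protein, seed):
        cds = reverse_translate(protein, seed)
        assert len(cds) == 3 * len(protein)
        assert translate_frame(cds, 0) == protein

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="residue"):
            reverse_translate("MXW", 0)


class TestInjectErrors:
    def test_zero_rate_is_identity(self):
        cfg = ReadSimConfig(error_rate=0.0)
        assert inject_errors("ACGTACGT", cfg, np.random.default_rng(0)) == "ACGTACGT"

    def test_substitution_only_rate_calibrated(self, rng):
        n = 100_000
        seq = "".join(rng.choice(list("ACGT"), size=n))
        cfg = ReadSimConfig(error_rate=0.10, error_ratio=(1.0, 0.0, 0.0))
        out, counts = inject_errors(seq, cfg, rng, return_counts=True)
        assert len(out) == n
        hamming = sum(a != b for a, b in zip(seq, out))
        assert hamming == counts["sub"]
        sd = np.sqrt(n * 0.1 * 0.9)
        assert abs(hamming - n * 0.1) < 3 * sd

    def test_deletion_only_shrinks_by_rate(self, rng):
        n = 100_000
        seq = "".join(rng.choice(list("ACGT"), size=n))
        cfg = ReadSimConfig(error_rate=0.05, error_ratio=(0.0, 0.0, 1.0))
        out = inject_errors(seq, cfg, rng)
        assert set(out) <= set("ACGT")
        sd = np.sqrt(n * 0.05 * 0.95)
        assert abs(len(out) - 0.95 * n) < 3 * sd

    def test_mixed_ratio_counts_calibrated(self, rng):
        """Each error type's empirical rate is within 3 binomial SD."""
        n = 100_000
        seq = "".join(rng.choice(list("ACGT"), size=n))
        cfg = ReadSimConfig(error_rate=0.10)  # default ratio 10:60:30
        _, counts = inject_errors(seq, cfg, rng, return_counts=True)
        for kind, frac in (("sub", 0.01), ("ins", 0.06), ("del", 0.03)):
            sd = np.sqrt(n * frac * (1 - frac))
            assert abs(counts[kind] - n * frac) < 3 * sd, kind


class TestSimulateReads:
    @pytest.fixture()
    def refs(self):
        fams = generate_families(
            FamilySpec(n_families=2, members_per_family=2, seed=7)
        )
        return make_references(fams, seed=8)

    def test_full_length_coverage_arithmetic(self, refs):
        ds = simulate_reads(refs, ReadSimConfig(0.0, coverage=10, seed=1))
        assert len(ds) == 10 * len(refs.sequences)
        for read, (ref_i, ref) in zip(
            ds.reads,
            [(i, s) for i, s in enumerate(refs.sequences) for _ in range(10)],
        ):
            assert read.sequence == ref  # error-free full-length copies
            assert read.true_label == refs.labels[ref_i]

    def test_coverage_contract(self, refs):
        ds = simulate_reads(refs, ReadSimConfig(0.05, coverage=30, seed=2))
        per_ref_bases = {}
        # read ids encode the source reference index
        for r in ds.reads:
            ref_i = int(r.read_id.split(".")[1][3:])
            per_ref_bases.setdefault(ref_i, 0)
            per_ref_bases[ref_i] += len(r.sequence)
        for ref_i, ref in enumerate(refs.sequences):
            assert per_ref_bases[ref_i] >= 0.9 * 30 * len(ref)

    def test_both_strands_half_reverse_complemented(self, refs):
        ds = simulate_reads(
            refs, ReadSimConfig(0.0, coverage=10, strand="both", seed=3)
        )
        minus = [r for r in ds.reads if r.read_id.endswith("-")]
        assert len(minus) == len(ds.reads) // 2
        ref0 = refs.sequences[0]
        first_minus = next(
            r for r in minus if r.read_id.startswith("fam00.ref0")
        )
        assert reverse_complement(first_minus.sequence) == ref0

    def test_determinism(self, refs):
        cfg = ReadSimConfig(0.10, coverage=5, seed=42)
        a = simulate_reads(refs, cfg)
        b = simulate_reads(refs, cfg)
        assert [r.sequence for r in a.reads] == [r.sequence for r in b.reads]

    def test_length_model_clamped_with_warning(self, refs):
        cfg = ReadSimConfig(
            0.0, coverage=2, read_length_model=(10_000.0, 1.0), seed=1
        )
        with pytest.warns(UserWarning, match="clamp"):
            ds = simulate_reads(refs, cfg)
        assert max(len(r.sequence) for r in ds.reads) <= max(
            len(s) for s in refs.sequences
        )

    def test_empty_references_rejected(self):
        from triframe.simulate import ReferenceSet

        with pytest.raises(ValueError):
            simulate_reads(ReferenceSet([], [], []), ReadSimConfig())


class TestSplit:
    def test_split_is_disjoint_and_covers(self):
        fams = generate_families(FamilySpec(seed=9))
        train, test = split_members(fams, seed=9)
        for fam_i in range(len(fams.members)):
            assert len(train[fam_i]) + len(test[fam_i]) == len(
                fams.members[fam_i]
            )
            assert len(train[fam_i]) >= 1 and len(test[fam_i]) >= 1


class TestOutliers:
    def test_zero_is_empty(self):
        assert len(generate_outliers(0)) == 0

    def test_uniform_mode_has_no_planted_motifs(self):
        fams = generate_families(FamilySpec(seed=10))
        motif_dna = [
            reverse_translate(m, 0) for m in fams.motif_strings()
        ]
        ds = generate_outliers(1000, seed=11, mode="uniform")
        assert all(r.true_label == OUTLIER for r in ds.reads)
        # expected random hits ~ n*L/4^30 << 1; assert exactly zero
        for r in ds.reads:
            for m in motif_dna:
                assert m not in r.sequence

    def test_decoy_mode_motif_disjoint_proteins(self):
        spec = FamilySpec(seed=12)
        fams = generate_families(spec)
        motifs = fams.motif_strings()
        ds = generate_outliers(
            200, seed=13, avoid_motifs=motifs, family_spec=spec
        )
        assert len(ds) == 200
        for r in ds.reads:
            assert r.true_label == OUTLIER
            for j in range(3):
                pep = translate_frame(r.sequence, j)
                for m in motifs:
                    assert m not in pep

    def test_determinism(self):
        a = generate_outliers(50, seed=14)
        b = generate_outliers(50, seed=14)
        assert [r.sequence for r in a.reads] == [r.sequence for r in b.reads]
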