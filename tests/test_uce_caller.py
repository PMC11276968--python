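import random

import pytest

from helpers import base_set
from ucekit.genome_io import GenomeSet, Interval
from ucekit.kmer_core import KmerHit, revcomp, build_index, map_core_kmers, select_core_kmers
from ucekit.simulate import oracle_find_uces
from ucekit.uce_caller import (
    CoreKmer,
    UCEParams,
    apply_multimap_cap,
    build_candidates,
    cumulative_scan,
    extend_and_call,
    find_uces,
    pigeonhole_seed_length,
    uces_to_bed,
)


def _rand(rng, n):
    return "".join(rng.choices("ACGT", k=n))


def _three_species(rng, seg_by_species, total=2400):
    """Each species gets the given segment inside independent background."""
    seqs = {}
    for sp, seg in seg_by_species.items():
        pad = (total - len(seg)) // 2
        left = _rand(rng, pad - 1) + "A"
        right = "A" + _rand(rng, total - len(seg) - pad - 1)
        # force flanking bases to differ between species at the junctions
        if sp != "ref":
            left = left[:-1] + "C"
            right = "G" + right[1:]
        seqs[sp] = {"chr1": left + seg + right}
    return GenomeSet(
        species_ids=list(seqs), sequences=seqs, reference_id="ref"
    ), pad


class TestUCEParams:
    def test_defaults_are_the_standard_setting(self):
        p = UCEParams()
        assert (p.min_length, p.min_identity, p.min_species_fraction) == (100, 0.97, 0.5)
        assert (p.core_k, p.kmer_map_limit, p.multimap_cap) == (50, 1000, 100)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_identity": 0.0},
            {"min_identity": 1.5},
            {"min_species_fraction": 0.0},
            {"min_length": 40},  # below core_k
            {"multimap_cap": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            UCEParams(**kwargs)

    def test_quorum_arithmetic(self):
        p = UCEParams(min_species_fraction=0.5)
        assert p.quorum(20) == 10
        assert p.quorum(3) == 2
        assert UCEParams(min_species_fraction=0.8).quorum(20) == 16

    def test_pigeonhole_seed_length(self):
        # w=100 at 95%: 5 mismatches -> guaranteed run ceil(95/6)=16
        assert pigeonhole_seed_length(0.95, 100, 1000) == 16
        assert pigeonhole_seed_length(1.0, 100, 1000) == 16  # capped
        with pytest.raises(ValueError, match="too low"):
            pigeonhole_seed_length(0.5, 100, 1000)


class TestBuildCandidates:
    def test_overlapping_reference_hits_merge(self):
        ks = [
            CoreKmer("A" * 50, 2, {"ref": [KmerHit("chr1", 0, "+", 0)],
                                   "sp01": [KmerHit("chr1", 10, "+", 0)]}),
            CoreKmer("C" * 50, 2, {"ref": [KmerHit("chr1", 40, "+", 0)]}),
        ]
        cands = build_candidates(ks, "ref")
        assert len(cands) == 1
        assert cands[0].interval == Interval("chr1", 0, 90)
        assert cands[0].species_support["sp01"] == [Interval("chr1", 10, 60)]

    def test_hits_on_different_sequences_stay_separate(self):
        ks = [
            CoreKmer("A" * 50, 2, {"ref": [KmerHit("chr1", 0, "+", 0)]}),
            CoreKmer("C" * 50, 2, {"ref": [KmerHit("chr2", 0, "+", 0)]}),
        ]
        cands = build_candidates(ks, "ref")
        assert [c.interval.seq_name for c in cands] == ["chr1", "chr2"]


class TestExtendAndCall:
    def test_identical_150bp_segment_called_at_exact_length(self):
        rng = random.Random(21)
        seg = _rand(rng, 150)
        gs, pad = _three_species(rng, {"ref": seg, "sp01": seg, "sp02": seg})
        params = UCEParams(min_identity=1.0, min_species_fraction=0.5,
                           cumulative_identities=(1.0,))
        uces = find_uces(gs, params)
        assert [(u.interval.start, u.interval.end) for u in uces] == [(pad, pad + 150)]
        assert uces[0].n_species_passing == 3

    def test_90bp_identical_segment_below_min_length_not_called(self):
        rng = random.Random(22)
        seg = _rand(rng, 90)
        gs, _ = _three_species(rng, {"ref": seg, "sp01": seg, "sp02": seg})
        params = UCEParams(min_identity=1.0, min_species_fraction=0.5,
                           cumulative_identities=(1.0,))
        assert find_uces(gs, params) == []

    def test_200bp_segment_with_three_substitutions_called_maximally(self):
        rng = random.Random(23)
        seg = _rand(rng, 200)
        mutated = list(seg)
        for pos in (40, 100, 160):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        gs, pad = _three_species(
            rng, {"ref": seg, "sp01": seg, "sp02": "".join(mutated)}
        )
        params = UCEParams(min_identity=0.97, min_species_fraction=1.0)
        uces = find_uces(gs, params)
        assert len(uces) == 1
        iv = uces[0].interval
        assert iv.start <= pad and iv.end >= pad + 150 + 50
        # the emitted interval is exactly the oracle's maximal window set
        oracle = oracle_find_uces(gs, params)
        assert [(o.start, o.end) for o in oracle] == [(iv.start, iv.end)]
        assert uces[0].species_hits["sp02"].identity >= 0.97

    def test_single_candidate_extension_matches_full_pipeline(self):
        rng = random.Random(24)
        seg = _rand(rng, 150)
        gs, pad = _three_species(rng, {"ref": seg, "sp01": seg, "sp02": seg})
        params = UCEParams(min_identity=1.0, cumulative_identities=(1.0,))
        idx = build_index(gs, params.core_k)
        core = select_core_kmers(idx, gs.n_species, params.core_fraction,
                                 params.kmer_map_limit)
        mapped = map_core_kmers(core, gs, params.min_identity)
        cands = build_candidates(mapped, "ref")
        assert len(cands) == 1
        uces = extend_and_call(cands[0], gs, params)
        assert [(u.interval.start, u.interval.end) for u in uces] == [(pad, pad + 150)]


class TestMultimapCap:
    def _repeat_genomes(self, rng, n_copies):
        # junction bases are pinned (A/C/T) so no species can extend a
        # window past the segment boundary by chance
        seg = _rand(rng, 120)
        ref = _rand(rng, 399) + "A" + seg + "A" + _rand(rng, 399)
        sp01 = _rand(rng, 399) + "C" + seg + "C" + _rand(rng, 399)
        chunks = [_rand(rng, 79) + "T"]
        for _ in range(n_copies):
            chunks.append(seg)
            chunks.append("T" + _rand(rng, 78) + "T")
        sp02 = "".join(chunks)
        return GenomeSet(
            ["ref", "sp01", "sp02"],
            {sp: {"chr1": s} for sp, s in
             {"ref": ref, "sp01": sp01, "sp02": sp02}.items()},
            "ref",
        )

    def test_cap_excludes_and_readmits_high_copy_element(self):
        rng = random.Random(31)
        gs = self._repeat_genomes(rng, n_copies=12)
        base = dict(min_identity=1.0, min_species_fraction=0.5,
                    cumulative_identities=(1.0,))
        capped = find_uces(gs, UCEParams(multimap_cap=11, **base))
        assert capped == []
        kept = find_uces(gs, UCEParams(multimap_cap=12, **base))
        assert len(kept) == 1 and len(kept[0].interval) == 120

    def test_infinite_cap_is_identity_transformation(self):
        rng = random.Random(32)
        gs = self._repeat_genomes(rng, n_copies=5)
        params = UCEParams(multimap_cap=10**6, min_identity=1.0,
                           cumulative_identities=(1.0,))
        uces = find_uces(gs, params)
        assert apply_multimap_cap(uces, gs, params) == uces


class TestCumulativeScan:
    def test_single_identity_ladder_equals_plain_run(self, small_sim):
        gs, _ = small_sim
        params = UCEParams(min_identity=1.0, cumulative_identities=(1.0,))
        scan = cumulative_scan(gs, params)
        single = [u.interval for u in find_uces(gs, params)]
        assert scan == single

    def test_ladder_must_end_at_min_identity(self):
        with pytest.raises(ValueError, match="min_identity"):
            cumulative_scan(
                GenomeSet(["a", "b"], {"a": {"c": "ACGT" * 30},
                                       "b": {"c": "ACGT" * 30}}, "a"),
                UCEParams(min_identity=0.95),
            )


class TestPipelineProperties:
    def test_deterministic_byte_identical_output(self, small_sim, tmp_path):
        from ucekit.genome_io import write_bed

        gs, _ = small_sim
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        for p in (p1, p2):
            write_bed(p, uces_to_bed(find_uces(gs, UCEParams())))
        assert p1.read_bytes() == p2.read_bytes()

    def test_monotone_in_identity_fraction_and_length(self, small_sim):
        gs, _ = small_sim
        def bases(**kw):
            return base_set(u.interval for u in find_uces(gs, UCEParams(**kw)))

        loose = bases(min_identity=0.95)
        mid = bases(min_identity=0.97)
        strict = bases(min_identity=1.0)
        assert strict <= mid <= loose
        assert bases(min_species_fraction=1.0) <= bases(min_species_fraction=0.5)
        assert bases(min_length=120) <= bases(min_length=100)

    def test_reported_identities_and_lengths_within_contract(self, small_sim):
        gs, _ = small_sim
        params = UCEParams()
        for u in find_uces(gs, params):
            assert len(u.interval) >= params.min_length
            assert u.n_species_passing >= params.quorum(gs.n_species)
            for hit in u.species_hits.values():
                assert 0.0 <= hit.identity <= 1.0

    def test_quorum_below_two_rejected(self):
        rng = random.Random(41)
        seq = _rand(rng, 1000)
        gs = GenomeSet(["a", "b"], {"a": {"c": seq}, "b": {"c": seq}}, "a")
        with pytest.raises(ValueError, match="quorum"):
            find_uces(gs, UCEParams(min_species_fraction=0.5))

    def test_bed_scores_are_per_mille_identity(self, small_sim):
        gs, _ = small_sim
        uces = find_uces(gs, UCEParams())
        for iv in uces_to_bed(uces):
            assert 900 <= iv.score <= 1000
            assert iv.strand == "+" and iv.name.startswith("UCE_")
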