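import math
import random

import pytest

from ucekit.genome_io import GeneModel, Interval
from ucekit.kmer_core import revcomp
from ucekit.simulate import SimConfig, simulate_genomes
from ucekit.tracer import (
    AlignmentHit,
    KarlinAltschul,
    ScoringScheme,
    align_glocal,
    count_detected,
    filter_hits,
    flank_profile,
    sample_control_cds,
    trace,
)


class TestKarlinAltschul:
    @pytest.mark.parametrize(
        "match,mismatch,lam,K",
        [
            # published ungapped nucleotide values (uniform composition)
            (1, -2, 1.33, 0.62),
            (1, -3, 1.37, 0.71),
            (5, -4, 0.192, 0.176),
        ],
    )
    def test_matches_published_ungapped_values(self, match, mismatch, lam, K):
        ka = KarlinAltschul.from_scores(match, mismatch)
        assert ka.lam == pytest.approx(lam, rel=0.01)
        assert ka.K == pytest.approx(K, rel=0.02)

    def test_evalue_monotone_in_target_length_and_score(self):
        ka = KarlinAltschul.from_scores(5, -4)
        assert ka.evalue(100, 100, 20_000) > ka.evalue(100, 100, 10_000)
        assert ka.evalue(120, 100, 10_000) < ka.evalue(100, 100, 10_000)
        assert ka.evalue(100, 100, 10_000) > 0

    def test_non_negative_expectation_rejected(self):
        with pytest.raises(ValueError):
            KarlinAltschul.from_scores(5, -1)


def _rand(rng, n):
    return "".join(rng.choices("ACGT", k=n))


class TestAlignGlocal:
    def setup_method(self):
        rng = random.Random(51)
        self.target = _rand(rng, 4000)
        self.query = self.target[1500:1650]

    def test_verbatim_embedding_found_at_full_identity(self):
        hit = align_glocal(self.query, {"chr1": self.target})
        assert (hit.start, hit.end, hit.strand) == (1500, 1650, "+")
        assert hit.identity == 1.0 and hit.aligned_length == 150
        assert hit.evalue < 1e-10

    def test_reverse_complement_query_maps_on_minus_strand(self):
        hit = align_glocal(revcomp(self.query), {"chr1": self.target})
        assert (hit.start, hit.end, hit.strand) == (1500, 1650, "-")
        assert hit.identity == 1.0

    def test_identity_counts_gap_columns_in_denominator(self):
        rng = random.Random(52)
        core = _rand(rng, 100)
        target = _rand(rng, 500) + core + _rand(rng, 500)
        query = core[:50] + core[53:]  # 3 bp deletion relative to target
        hit = align_glocal(query, {"chr1": target})
        assert hit.aligned_length == 100  # 97 aligned + 3 gap columns
        assert hit.identity == pytest.approx(97 / 100)

    def test_empty_target_returns_none(self):
        assert align_glocal(self.query, {}) is None
        assert align_glocal(self.query, {"chr1": ""}) is None


class TestFilters:
    def _hit(self, aligned_length=100, evalue=1e-20, matches=None, species="sp"):
        matches = aligned_length if matches is None else matches
        return AlignmentHit(
            query_id="q", species=species, seq_name="c", start=0,
            end=aligned_length, strand="+", aligned_length=aligned_length,
            matches=matches, score=500, bit_score=100, evalue=evalue,
        )

    def test_short_and_weak_hits_removed(self):
        hits = [
            self._hit(aligned_length=25),
            self._hit(evalue=0.5),
            self._hit(aligned_length=100, evalue=1e-20),
        ]
        kept = filter_hits(hits)
        assert len(kept) == 1 and kept[0].aligned_length == 100

    def test_boundary_values_kept(self):
        kept = filter_hits([self._hit(aligned_length=30, evalue=0.01)])
        assert len(kept) == 1

    def test_detection_cutoff_and_separate_identity_summary(self):
        hits = [
            self._hit(matches=65),   # identity 0.65: retained, not detected
            self._hit(matches=75),
            self._hit(matches=98),
        ]
        summary = count_detected(hits, n_queries=3)["sp"]
        assert summary.n_detected == 2
        # the 0.65 hit still contributes to the identity summary
        assert summary.mean_identity == pytest.approx((0.65 + 0.75 + 0.98) / 3)
        assert summary.min_identity == 0.65 and summary.max_identity == 0.98

    def test_no_hits_reports_na(self):
        assert count_detected([], n_queries=5) == {}


class TestSelfMapping:
    def test_uce_set_traced_onto_its_own_reference_is_perfect(self, small_sim):
        gs, truth = small_sim
        queries = {
            f"e{e.element_id}": gs.fetch("ref", e.ref_interval)
            for e in truth.elements[:5]
        }
        hits = filter_hits(trace(queries, {"ref": gs.sequences["ref"]}))
        summary = count_detected(hits, n_queries=len(queries))["ref"]
        assert summary.n_detected == len(queries)
        assert summary.mean_identity == 1.0


class TestControlCds:
    def _models(self):
        mk = lambda gid, ivs, bio="protein_coding": GeneModel(
            gene_id=gid, gene_name=gid, biotype=bio, strand="+",
            interval=Interval("chr1", min(s for s, _ in ivs),
                              max(e for _, e in ivs)),
            exons=[Interval("chr1", s, e) for s, e in ivs],
            cds=[Interval("chr1", s, e) for s, e in ivs] if bio == "protein_coding" else [],
        )
        return [
            mk("g1", [(0, 50)]),            # too short
            mk("g2", [(100, 300)]),         # eligible
            mk("g3", [(400, 1800)]),        # too long
            mk("g4", [(2000, 2400)]),       # eligible
            mk("lnc", [(3000, 3300)], bio="lncRNA"),  # wrong biotype
        ]

    def test_length_and_biotype_eligibility(self):
        rng = random.Random(53)
        ref = {"chr1": _rand(rng, 4000)}
        sample = sample_control_cds(self._models(), ref, n=2, seed=0)
        assert set(sample) == {"cds_g2_100", "cds_g4_2000"}
        assert len(sample["cds_g2_100"]) == 200

    def test_same_seed_same_sample_and_shortage_raises(self):
        rng = random.Random(54)
        ref = {"chr1": _rand(rng, 4000)}
        a = sample_control_cds(self._models(), ref, n=1, seed=7)
        b = sample_control_cds(self._models(), ref, n=1, seed=7)
        assert a == b
        with pytest.raises(ValueError, match="eligible"):
            sample_control_cds(self._models(), ref, n=3, seed=0)


class TestFlankProfile:
    def test_identical_species_give_flat_profile_at_100_percent(self):
        gs, truth = simulate_genomes(
            SimConfig(seed=61, n_species=3, genome_length=20_000, n_elements=5,
                      substitution_rates=(0.0,), flank_divergence=0.0,
                      n_repeat_copies=1)
        )
        prof = flank_profile(
            [e.ref_interval for e in truth.elements], gs, flank_bp=20
        )
        assert all(v == 1.0 for v in prof.values())

    def test_core_flank_divergence_step_matches_simulated_rates(self):
        core_rate, flank_rate = 0.0, 0.10
        gs, truth = simulate_genomes(
            SimConfig(seed=62, n_species=4, genome_length=60_000, n_elements=40,
                      element_length_range=(200, 200),
                      substitution_rates=(core_rate,),
                      flank_divergence=flank_rate, flank_length=40,
                      n_repeat_copies=1)
        )
        prof = flank_profile(
            [e.ref_interval for e in truth.elements], gs, flank_bp=30
        )
        core_vals = [v for o, v in prof.items() if 0 <= o < 200]
        flank_vals = [v for o, v in prof.items() if o < 0 or o >= 200]
        # 40 elements x 3 species per offset: binomial sigma ~ 0.027
        assert min(core_vals) > 0.99
        assert abs(sum(flank_vals) / len(flank_vals) - (1 - flank_rate)) < 0.03

    def test_zero_flank_covers_core_only(self):
        gs, truth = simulate_genomes(
            SimConfig(seed=63, n_species=3, genome_length=20_000, n_elements=5,
                      element_length_range=(150, 150),
                      substitution_rates=(0.0,), n_repeat_copies=1)
        )
        prof = flank_profile([e.ref_interval for e in truth.elements], gs, 0)
        assert min(prof) == 0 and max(prof) == 149
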