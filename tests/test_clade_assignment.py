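"""Clade assignment: local alignment vs full-DP oracle, best-hit rules,
relaxed/conservative filter semantics, census bookkeeping."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bahdscape.clade_assignment import (
    AlignmentScoring,
    AssignmentThresholds,
    CladeCall,
    ReferencePanel,
    SimilarityHit,
    assign_clades,
    best_hits,
    clade_census,
    local_align,
)
from conftest import random_protein
from _oracles import sw_affine_score

SCORING = AlignmentScoring()


def raw_score(hit):
    # invert the Karlin-Altschul bit scaling back to the raw DP score
    return (hit.bit_score * math.log(2) + math.log(SCORING.ka_k)) \
        / SCORING.ka_lambda


def make_hit(query="q1", target="r1", identity=50.0, length=250,
             bits=100.0, evalue=1e-60, engine="alignment"):
    return SimilarityHit(query, target, identity, length, bits, evalue,
                         engine)


class TestLocalAlign:
    def test_self_alignment_full_identity(self):
        hit = local_align("MKV", "MKV")
        assert hit.pct_identity == 100.0
        assert hit.match_length == 3

    def test_score_matches_dp_oracle(self, rng):
        for _ in range(40):
            a = random_protein(rng, int(rng.integers(15, 31)))
            b = random_protein(rng, int(rng.integers(15, 31)))
            hit = local_align(a, b)
            expected = sw_affine_score(a, b)
            if hit.match_length == 0:
                assert expected <= 0
            else:
                assert raw_score(hit) == pytest.approx(expected, abs=1e-6)

    def test_no_positive_alignment_gives_zero_hit(self):
        # A/C mismatches score negative under BLOSUM62 everywhere
        hit = local_align("AAAA", "CCCC")
        assert hit.match_length == 0 and hit.bit_score == 0.0
        assert sw_affine_score("AAAA", "CCCC") == 0.0

    def test_non_amino_acid_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            local_align("MK1V", "MKV")


class TestBestHits:
    def test_tie_breaks_lexicographically(self):
        hits = [make_hit(target="r3", bits=50), make_hit(target="r1", bits=80),
                make_hit(target="r2", bits=80)]
        assert best_hits(hits)["q1"].target_id == "r1"

    def test_single_hit_returned(self):
        (hit,) = [make_hit()]
        assert best_hits([hit])["q1"] is hit

    def test_matches_linear_scan_oracle(self, rng):
        hits = [
            make_hit(query=f"q{rng.integers(0, 20)}",
                     target=f"r{i}", bits=float(rng.integers(20, 500)),
                     identity=float(rng.uniform(10, 100)),
                     length=int(rng.integers(50, 450)))
            for i in range(1000)
        ]
        best = best_hits(hits)
        for q in {h.query_id for h in hits}:
            mine = [h for h in hits if h.query_id == q]
            top = max(h.bit_score for h in mine)
            winners = [h for h in mine if h.bit_score == top]
            winners.sort(key=lambda h: (-h.pct_identity, -h.match_length,
                                        h.target_id))
            assert best[q] == winners[0]

    def test_profile_engine_uses_min_evalue(self):
        hits = [make_hit(engine="profile", evalue=1e-40, target="rA"),
                make_hit(engine="profile", evalue=1e-80, target="rB")]
        assert best_hits(hits)["q1"].target_id == "rB"

    def test_mixed_engines_rejected(self):
        with pytest.raises(ValueError, match="mixed engines"):
            best_hits([make_hit(), make_hit(engine="profile")])


@pytest.fixture
def panel():
    return ReferencePanel([
        ("r1", "5", "MKVLAATGHKW" * 20),
        ("r2", "1a/b", "MDEFGWGHQRS" * 20),
    ])


class TestAssignClades:
    def get(self, calls, mode):
        return {c.query_id: c for c in calls if c.mode == mode}

    def test_passing_hit_assigned_in_both_modes(self, panel):
        best = {"q1": make_hit(identity=45.0, length=250)}
        calls = assign_clades(best, panel)
        assert self.get(calls, "relaxed")["q1"].clade == "5"
        assert self.get(calls, "conservative")["q1"].clade == "5"

    @pytest.mark.parametrize(
        "identity, length, conservative",
        [
            (39.0, 250, "unassigned"),  # below identity cutoff
            (40.0, 200, "5"),           # boundary values pass
            (45.0, 199, "unassigned"),  # below length cutoff
        ],
    )
    def test_identity_length_filter(self, panel, identity, length,
                                    conservative):
        best = {"q1": make_hit(identity=identity, length=length)}
        calls = assign_clades(best, panel)
        assert self.get(calls, "relaxed")["q1"].clade == "5"
        assert self.get(calls, "conservative")["q1"].clade == conservative

    @pytest.mark.parametrize("evalue, conservative",
                             [(1e-49, "unassigned"), (1e-50, "5"),
                              (1e-51, "5")])
    def test_profile_evalue_filter(self, panel, evalue, conservative):
        best = {"q1": make_hit(engine="profile", evalue=evalue)}
        calls = assign_clades(best, panel)
        assert self.get(calls, "conservative")["q1"].clade == conservative

    def test_unknown_target_named_in_error(self, panel):
        with pytest.raises(KeyError, match="rX"):
            assign_clades({"q1": make_hit(target="rX")}, panel)

    @given(identity=st.floats(10, 100), length=st.integers(30, 450))
    @settings(max_examples=50, deadline=None)
    def test_conservative_subset_of_relaxed(self, identity, length):
        panel = ReferencePanel([("r1", "5", "MKVLAATGHKW" * 20)])
        best = {"q1": make_hit(identity=identity, length=length)}
        calls = assign_clades(best, panel)
        relaxed = self.get(calls, "relaxed")["q1"].clade
        conservative = self.get(calls, "conservative")["q1"].clade
        assert relaxed != "unassigned"
        assert conservative in (relaxed, "unassigned")

    @given(identity=st.floats(10, 100), length=st.integers(30, 450),
           bump_identity=st.floats(0, 30), bump_length=st.integers(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_raising_thresholds_is_monotone(self, identity, length,
                                            bump_identity, bump_length):
        panel = ReferencePanel([("r1", "5", "MKVLAATGHKW" * 20)])
        best = {"q1": make_hit(identity=identity, length=length)}

        def conservative(th):
            calls = assign_clades(best, panel, th)
            return self.get(calls, "conservative")["q1"].clade

        loose = conservative(AssignmentThresholds())
        strict = conservative(AssignmentThresholds(
            min_identity=40.0 + bump_identity,
            min_match_length=200 + bump_length))
        if loose == "unassigned":
            assert strict == "unassigned"


class TestCladeCensus:
    def test_counts_and_row_sum(self):
        calls = [CladeCall("q1", "5", "conservative"),
                 CladeCall("q2", "5", "conservative"),
                 CladeCall("q3", "unassigned", "conservative")]
        table = clade_census(calls, {q: "sp1" for q in ("q1", "q2", "q3")})
        assert table.loc["sp1", "5"] == 2
        assert table.loc["sp1", "unassigned"] == 1
        assert table.sum(axis=1).loc["sp1"] == 3

    def test_relaxed_census_has_no_unassigned(self, panel):
        best = {f"q{i}": make_hit(identity=30.0, length=100)
                for i in range(5)}
        calls = [c for c in assign_clades(best, panel)
                 if c.mode == "relaxed"]
        table = clade_census(calls, {c.query_id: "sp1" for c in calls})
        assert "unassigned" not in table.columns

    def test_matches_groupby_oracle(self, rng):
        clades = ["1", "4", "5", "unassigned"]
        calls = [CladeCall(f"q{i}", clades[rng.integers(0, 4)], "relaxed")
                 for i in range(500)]
        species = {c.query_id: f"sp{rng.integers(1, 5)}" for c in calls}
        table = clade_census(calls, species)
        for call in calls:
            naive = sum(1 for c in calls
                        if species[c.query_id] == species[call.query_id]
                        and c.clade == call.clade)
            assert table.loc[species[call.query_id], call.clade] == naive

    def test_mixed_modes_rejected(self):
        calls = [CladeCall("q1", "5", "relaxed"),
                 CladeCall("q1", "5", "conservative")]
        with pytest.raises(ValueError, match="single mode"):
            clade_census(calls, {"q1": "sp1"})
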