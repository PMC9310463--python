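import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zetascreen import offtarget as ot
from zetascreen import screen_strength as ss
from zetascreen import zeta_core as zc

from conftest import brute_force_lcs


def _zm(rows: dict, cols=None):
    df = pd.DataFrame(rows).T
    if cols is not None:
        df.columns = cols
    return zc.ZMatrix(
        z=df, mu=pd.Series(0.0, index=df.columns), sigma=pd.Series(1.0, index=df.columns)
    )


class TestResponseSimilarity:
    def test_identical_rows_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=20)
        zm = _zm({"a": row, "b": row.copy()})
        assert ot.response_similarity(zm, "a", "b") == pytest.approx(1.0)

    def test_negated_row_anticorrelates(self):
        rng = np.random.default_rng(1)
        row = rng.normal(size=20)
        zm = _zm({"a": row, "b": -row})
        assert ot.response_similarity(zm, "a", "b") == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 1.0, 0.0, 2.0, 4.0, 3.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 0.0, 1.0, 2.0, 5.0, 2.0])
        zm = _zm({"a": a, "b": b})
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        want = cov / (a.std() * b.std())
        assert ot.response_similarity(zm, "a", "b") == pytest.approx(want, abs=1e-12)

    def test_zero_variance_errors(self):
        zm = _zm({"a": np.ones(12), "b": np.arange(12.0)})
        with pytest.raises(ValueError, match="variance"):
            ot.response_similarity(zm, "a", "b")


def _embed(transcript: str, guide_rc: str, pos: int) -> str:
    return transcript[:pos] + guide_rc + transcript[pos + len(guide_rc):]


class TestComplementarityScan:
    def test_perfect_complement_single_full_match(self):
        rng = np.random.default_rng(2)
        transcript = "".join(rng.choice(list("ACGT"), 200))
        site = transcript[50:69]  # 19-mer
        guide = ot.reverse_complement(site).replace("T", "U")  # guide in RNA
        matches = ot.complementarity_scan(guide, transcript)
        assert matches[0].length >= 19
        assert matches[0].t_start <= 51 <= matches[0].t_end

    def test_planted_11nt_island_found_at_coordinates(self):
        rng = np.random.default_rng(3)
        transcript = list("".join(rng.choice(list("ACGT"), 300)))
        guide = "".join(rng.choice(list("ACGU"), 21))
        rc = ot.reverse_complement(guide)
        island = rc[4:15]  # 11 nt of the guide's reverse complement
        # flanking bases must not extend the planted run by chance
        transcript[99] = next(b for b in "ACGT" if b != rc[3])
        transcript[111] = next(b for b in "ACGT" if b != rc[15])
        t2 = _embed("".join(transcript), island, 100)
        matches = [m for m in ot.complementarity_scan(guide, t2) if m.length >= 11]
        assert len(matches) == 1
        m = matches[0]
        assert (m.t_start, m.t_end) == (101, 111)
        assert m.length == 11

    def test_random_pairs_rarely_reach_11nt(self):
        rng = np.random.default_rng(4)
        n_flagged = 0
        for _ in range(50):
            guide = "".join(rng.choice(list("ACGU"), 21))
            transcript = "".join(rng.choice(list("ACGT"), 1000))
            n_flagged += bool(ot.complementarity_scan(guide, transcript))
        assert n_flagged <= 2

    def test_agrees_with_quadratic_lcs_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            # small alphabet sequences produce plenty of borderline runs
            guide = "".join(rng.choice(list("ACGU"), 21))
            transcript = "".join(rng.choice(list("ACGT"), rng.integers(30, 120)))
            matches = ot.complementarity_scan(guide, transcript, min_len=1)
            got = matches[0].length if matches else 0
            want = brute_force_lcs(
                ot.reverse_complement(guide), transcript.replace("U", "T")
            )
            assert got == want

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        guide=st.text(alphabet="ACGU", min_size=12, max_size=23),
        transcript=st.text(alphabet="ACGT", min_size=12, max_size=200),
        min_len=st.integers(min_value=1, max_value=12),
    )
    def test_longest_match_equals_lcs_oracle_property(self, guide, transcript, min_len):
        matches = ot.complementarity_scan(guide, transcript, min_len=min_len)
        lcs = brute_force_lcs(ot.reverse_complement(guide), transcript)
        if lcs >= min_len:
            assert matches and matches[0].length == lcs
        else:
            assert matches == []

    def test_short_sequence_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="min_len"):
            assert ot.complementarity_scan("ACGUACG", "ACGTACGTACGTACGT") == []

    def test_invalid_alphabet_errors(self):
        with pytest.raises(ValueError, match="invalid"):
            ot.complementarity_scan("ACGTN" * 4, "ACGT" * 30)


class TestAttribution:
    @staticmethod
    def _setup(n_passing, seed=0):
        rng = np.random.default_rng(seed)
        profile = rng.normal(0, 3, size=50)
        primary = _zm({"poolB": profile + rng.normal(0, 0.5, 50)})
        singles = {}
        for i in range(4):
            if i < n_passing:
                singles[f"s{i}"] = profile + rng.normal(0, 0.5, 50)
            else:
                singles[f"s{i}"] = rng.normal(0, 1, 50)
        secondary = _zm(singles)
        return primary, secondary

    def test_multiple_passing_singles_mean_related_function(self):
        primary, secondary = self._setup(3)
        out = ot.attribute_to_single_sirna(primary, secondary, "poolA", "poolB",
                                           singles=list("s0 s1 s2 s3".split()))
        assert out["status"] == "related_function"

    def test_single_passing_sirna_is_offtarget_candidate(self):
        primary, secondary = self._setup(1)
        out = ot.attribute_to_single_sirna(primary, secondary, "poolA", "poolB",
                                           singles=list("s0 s1 s2 s3".split()))
        assert out["status"] == "off_target_candidate"
        assert out["passing"] == ["s0"]

    def test_no_passing_single_no_flag(self):
        primary, secondary = self._setup(0)
        out = ot.attribute_to_single_sirna(primary, secondary, "poolA", "poolB",
                                           singles=list("s0 s1 s2 s3".split()))
        assert out["status"] == "no_flag"

    def test_no_singles_unattributable(self):
        primary, secondary = self._setup(0)
        out = ot.attribute_to_single_sirna(primary, secondary, "poolA", "poolB", singles=[])
        assert out["status"] == "unattributable"


class TestFlagOfftargets:
    @staticmethod
    def _fixture(corr: bool, complement: bool, seed=0):
        rng = np.random.default_rng(seed)
        profile = rng.normal(0, 3, size=40)
        rows = {
            "REG": profile,
            "NE": 0.9 * profile + rng.normal(0, 0.3, 40) if corr else rng.normal(0, 1, 40),
        }
        zm = _zm(rows)
        transcript = "".join(rng.choice(list("ACGT"), 300))
        guide = "".join(rng.choice(list("ACGU"), 21))
        if complement:
            island = ot.reverse_complement(guide)[3:17]
            transcript = _embed(transcript, island, 120)
        lib = ot.SirnaLibrary(
            pools={"REG": "REG", "NE": "NE"},
            guides={"NE_s1": ("NE", guide)},
            transcripts={"REG": transcript, "NE": "".join(rng.choice(list("ACGT"), 300))},
        )
        return zm, lib

    def test_both_criteria_flags_pool(self):
        zm, lib = self._fixture(corr=True, complement=True)
        rep = ot.flag_offtargets(zm, lib, hits=["REG", "NE"])
        assert set(rep["pool_id"]) == {"NE"}
        assert rep.iloc[0]["offended_gene"] == "REG"
        assert rep.iloc[0]["match_length"] >= 11

    def test_correlation_without_complementarity_not_flagged(self):
        zm, lib = self._fixture(corr=True, complement=False)
        rep = ot.flag_offtargets(zm, lib, hits=["REG", "NE"])
        assert rep.empty

    def test_complementarity_without_correlation_not_flagged(self):
        zm, lib = self._fixture(corr=False, complement=True)
        rep = ot.flag_offtargets(zm, lib, hits=["REG", "NE"])
        assert rep.empty

    def test_planted_guides_flagged_uniquely_on_synthetic_screen(self, offtarget_screen):
        sim = offtarget_screen
        zm = zc.z_transform(sim.matrix, sim.annotation)
        scores, _ = zc.compute_zeta_scores(zm, sim.annotation, seed=3)
        cuts = ss.fpl_cutoffs(scores, sim.annotation)
        classes = sim.annotation.loc[scores.index]
        screened = scores[classes.isin(("sample", "non_expressor"))]
        hits = screened.index[screened >= cuts[0.05]].tolist()
        sec_zm = zm.transform(sim.secondary)
        rep = ot.flag_offtargets(zm, sim.library, hits, secondary_zm=sec_zm)
        planted = set(sim.truth.loc[sim.truth["planted_offtarget"], "planted_sirna"])
        assert set(rep["suspect_sirna_id"]) == planted

    def test_removing_flagged_pools_never_decreases_ss(self, offtarget_screen):
        sim = offtarget_screen
        zm = zc.z_transform(sim.matrix, sim.annotation)
        scores, _ = zc.compute_zeta_scores(zm, sim.annotation, seed=3)
        flagged = sim.truth.index[sim.truth["planted_offtarget"]]
        before = ss.screen_strength_curve(scores, sim.annotation)
        keep = scores.index.difference(flagged)
        after = ss.screen_strength_curve(scores.loc[keep], sim.annotation.loc[keep])
        ss_after = np.interp(before.cutoffs, after.cutoffs, after.ss)
        assert (ss_after + 1e-9 >= before.ss).all()

    def test_flagging_directional_does_not_alter_target(self):
        zm, lib = self._fixture(corr=True, complement=True)
        rep = ot.flag_offtargets(zm, lib, hits=["REG", "NE"])
        assert "REG" not in set(rep["pool_id"])
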