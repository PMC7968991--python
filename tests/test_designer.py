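"""OFF/ON targets, DU+ notation, prevented patterns and the design loop."""
import numpy as np
import pytest

from grnaswitch import (
    EngineParams,
    NucSeq,
    ReferenceEngine,
    SecondaryStructure,
    SwitchArchitecture,
    build_off_structure,
    build_on_structure,
    check_prevented,
    design_switch,
    ensemble_defect,
    from_du_plus,
    revcomp,
    to_du_plus,
)
from grnaswitch.designer import (
    DEFAULT_PREVENTED_PATTERNS,
    IUPAC,
    PreventedPatternSet,
    TargetState,
)

from conftest import random_rna


class TestOffStructure:
    def test_default_dotbracket(self, default_arch):
        off = build_off_structure(default_arch)
        expected = "." * 15 + "(" * 13 + "." * 15 + ")" * 13 + "." * 6 + "." * 24
        assert off.to_dotbracket() == expected

    def test_linker_enlarges_enclosed_loop(self, default_guide):
        arch = SwitchArchitecture(guide=default_guide, linker_len=5)
        off = build_off_structure(arch)
        expected = "." * 15 + "(" * 13 + "." * 20 + ")" * 13 + "." * 6 + "." * 24
        assert off.to_dotbracket() == expected

    def test_clamp_register_pairs_repeat_prefix(self, default_arch):
        off = build_off_structure(default_arch)
        # clamp position k pairs repeat position clamp_len-1-k
        for k in range(13):
            assert off.pairs[15 + k] == 43 + (12 - k)

    def test_too_small_loop_rejected(self, default_guide):
        with pytest.raises(ValueError):
            SwitchArchitecture(guide=default_guide, loop_len=2)


class TestOnStructure:
    def test_geometry(self, default_arch, engine):
        on = build_on_structure(default_arch, engine=engine)
        S = default_arch.switch_length
        # toehold position 0 pairs the trigger's last position
        assert on.pairs[0] == S + 42
        for i in range(15):
            assert on.pairs[i] == S + 42 - i
        # loop pairs the trigger 5' segment
        for k in range(15):
            assert on.pairs[28 + k] == S + 14 - k
        # clamp and trigger middle unpaired (symmetric internal loop)
        assert all(on.pairs[15 + k] == -1 for k in range(13))
        assert all(on.pairs[S + 15 + k] == -1 for k in range(13))
        # guide unpaired
        assert all(on.pairs[62 + k] == -1 for k in range(24))

    def test_handle_hairpin_from_engine_mfe(self, default_arch, engine):
        folded, _ = engine.mfe_fold(default_arch.repeat)
        on = build_on_structure(default_arch, engine=engine)
        for a, b in folded.pair_map().items():
            assert on.pairs[43 + a] == 43 + b

    def test_explicit_handle_hairpin(self, default_arch):
        on = build_on_structure(default_arch, handle_hairpin={4: 17, 5: 16, 6: 15, 7: 14, 8: 13})
        assert on.pairs[43 + 4] == 43 + 17

    def test_invalid_handle_hairpin_rejected(self, default_arch):
        with pytest.raises(ValueError):
            build_on_structure(default_arch, handle_hairpin={4: 25})

    def test_clamp_middle_pairing_option(self, default_arch, engine):
        on = build_on_structure(default_arch, engine=engine, pair_clamp_middle=True)
        S = default_arch.switch_length
        for k in range(13):
            assert on.pairs[15 + k] == S + 15 + (12 - k)


class TestDuPlus:
    def test_all_unpaired(self):
        assert to_du_plus(SecondaryStructure.from_dotbracket("....")) == "U4"

    def test_default_off_target(self, default_arch):
        assert to_du_plus(build_off_structure(default_arch)) == "U15 D13(U15) U30"

    def test_strand_break_token(self):
        s = SecondaryStructure.from_dotbracket("((((....&....))))")
        assert to_du_plus(s) == "D4(U4 + U4)"

    def test_blunt_duplex(self):
        s = SecondaryStructure.from_dotbracket("(((&)))")
        assert to_du_plus(s) == "D3(+)"

    def test_parse_rejects_malformed(self):
        with pytest.raises(ValueError):
            from_du_plus("U4 D2(U3")
        with pytest.raises(ValueError):
            from_du_plus("U4)")
        with pytest.raises(ValueError):
            from_du_plus("U4 Q3")
        with pytest.raises(ValueError):
            from_du_plus("U4", [5])

    def test_roundtrip_on_engine_folds(self, engine):
        """DU+ round-trips through parse(format(s)) for MFE structures of
        random single sequences and random duplexes."""
        rng = np.random.default_rng(17)
        for trial in range(30):
            if trial % 2:
                strands = random_rna(rng, int(rng.integers(10, 40)))
            else:
                strands = [
                    random_rna(rng, int(rng.integers(5, 25))),
                    random_rna(rng, int(rng.integers(5, 25))),
                ]
            s, _ = engine.mfe_fold(strands)
            text = to_du_plus(s)
            back = from_du_plus(text, s.lengths)
            assert back == s, (text, s.to_dotbracket())

    def test_parse_infers_strands(self):
        s = from_du_plus("D4(U4 + U4)")
        assert s.lengths == [8, 8]
        assert s.to_dotbracket() == "((((....&....))))"


class TestPreventedPatterns:
    def test_homopolymer_hit(self):
        assert check_prevented("AAAA") == [("AAAA", 0)]

    def test_keto_run_hit(self):
        hits = check_prevented("GUGUGU")
        assert ("KKKKKK", 0) in hits

    def test_clean_sequence(self):
        assert check_prevented("ACGACG") == []

    def test_overlapping_occurrences_reported(self):
        hits = [h for h in check_prevented("AAAAA") if h[0] == "AAAA"]
        assert hits == [("AAAA", 0), ("AAAA", 1)]

    def test_brute_force_cross_check(self):
        """Pattern scan agrees with direct set-membership checks."""
        rng = np.random.default_rng(23)
        classes = {p: set(IUPAC[p[0]]) for p in DEFAULT_PREVENTED_PATTERNS}
        for _ in range(50):
            seq = random_rna(rng, 25)
            expected = []
            for pat, allowed in classes.items():
                m = len(pat)
                for s in range(25 - m + 1):
                    if set(seq[s : s + m]) <= allowed:
                        expected.append((pat, s))
            assert sorted(check_prevented(seq)) == sorted(expected)

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            PreventedPatternSet(("XXXX",))
        with pytest.raises(ValueError):
            PreventedPatternSet(())


class TestTargetState:
    def test_stop_condition_bounds(self, default_arch):
        off = build_off_structure(default_arch)
        TargetState("OFF", (86,), off, 0.01)
        with pytest.raises(ValueError):
            TargetState("OFF", (86,), off, 0.0)
        with pytest.raises(ValueError):
            TargetState("LIMBO", (86,), off, 0.01)
        with pytest.raises(ValueError):
            TargetState("ON", (86,), off, 0.05)


@pytest.fixture(scope="module")
def quick_result(default_arch):
    return design_switch(default_arch, seed=5, max_iters=120)


class TestDesignLoop:
    def test_determinism_same_seed(self, default_arch, quick_result):
        again = design_switch(default_arch, seed=5, max_iters=120)
        assert again.switch.sequence.residues == quick_result.switch.sequence.residues
        assert again.trigger.sequence.residues == quick_result.trigger.sequence.residues
        assert again.defect_off == quick_result.defect_off
        assert again.defect_on == quick_result.defect_on

    def test_objective_never_increases_with_budget(self, default_arch):
        start = design_switch(default_arch, seed=5, max_iters=0)
        more = design_switch(default_arch, seed=5, max_iters=120)
        assert (
            more.defect_off + more.defect_on <= start.defect_off + start.defect_on
        )

    def test_result_revalidates_with_independent_defect(
        self, quick_result, engine
    ):
        """The defects recorded in the result must equal a from-scratch
        ensemble_defect evaluation of the designed sequences."""
        r = quick_result
        d_off = ensemble_defect(r.switch.sequence, r.off_target, engine=engine)
        d_on = ensemble_defect(
            [r.switch.sequence, r.trigger.sequence], r.on_target, engine=engine
        )
        assert d_off == pytest.approx(r.defect_off, abs=1e-12)
        assert d_on == pytest.approx(r.defect_on, abs=1e-12)

    def test_no_prevented_patterns_in_designed_regions(self, quick_result):
        r = quick_result
        t, c, l = 15, 13, 15
        free_sw = np.zeros(86, dtype=bool)
        free_sw[:t] = True
        free_sw[t + c : t + c + l] = True
        for pat, start in check_prevented(r.switch.sequence):
            assert not free_sw[start : start + len(pat)].any(), (pat, start)
        for pat, start in check_prevented(r.trigger.sequence):
            assert start >= 43, (pat, start)  # trigger is fully designable

    def test_trigger_complementarity_maintained(self, quick_result):
        r = quick_result
        assert (
            r.trigger.sequence.residues
            == revcomp(r.switch.loop).residues
            + r.trigger.segment("middle")
            + revcomp(r.switch.toehold).residues
        )

    def test_natural_mode_fixes_sensor_from_window(self, default_arch):
        rng = np.random.default_rng(9)
        window = NucSeq("w", random_rna(rng, 43))
        arch = default_arch.with_(linker_len=5)
        r = design_switch(
            arch, mode="natural", natural_window=window, seed=3, max_iters=40
        )
        assert r.switch.toehold == revcomp(window.residues[28:]).residues
        assert r.switch.loop == revcomp(window.residues[:15]).residues
        # the designed trigger is the window itself
        assert r.trigger.sequence.residues == window.residues

    def test_natural_mode_requires_window(self, default_arch):
        with pytest.raises(ValueError):
            design_switch(default_arch, mode="natural", seed=0, max_iters=10)

    def test_ambiguous_guide_rejected(self, default_arch):
        with pytest.raises(ValueError):
            design_switch(
                default_arch,
                guide=NucSeq("g", "ACGUNACGUACGUACGUACGUACG", allow_n=True),
                max_iters=5,
            )

    def test_invalid_mode(self, default_arch):
        with pytest.raises(ValueError):
            design_switch(default_arch, mode="bogus", max_iters=5)
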