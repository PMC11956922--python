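import numpy as np
import pytest
from conftest import mutate_seq, random_seq
from oracles import fisher_exact_enumeration

from sdparalog.caller import (
    ABSENT,
    CANONICAL_POSITIONS,
    DEFAULT_CATALOG,
    HYBRID,
    NOTCH2TV,
    ConfigCatalog,
    EvidenceTriplet,
    HaplotypeConfiguration,
    ParalogCall,
    call_paralog,
    classify_haplotype,
    cohort_summary,
    converted_state,
    deleted_call,
    delineate_tract,
    enrichment_test,
    inverted_state,
)
from sdparalog.evidence import CladeAssignment, TranscriptMatch
from sdparalog.formats import SdparalogError
from sdparalog.synteny import window_identity

N2, NLR, NLA, NLB, NLC = CANONICAL_POSITIONS


def triplet(t, c, loc, tied=(), locus="L"):
    return EvidenceTriplet(
        locus,
        TranscriptMatch(locus, t, 0, 0 if t == "ambiguous" else 5, tied),
        CladeAssignment(locus, c, 0.0 if c == "ambiguous" else 0.01, True),
        (loc, 2),
    )


class TestCallParalog:
    def test_full_agreement_is_clean(self):
        call = call_paralog(triplet(NLA, NLA, NLA))
        assert (call.status, call.consensus_label, call.igc) == ("clean", NLA, False)

    def test_transcript_and_clade_against_location_is_igc(self):
        call = call_paralog(triplet(NLA, NLA, NLB))
        assert call.status == "igc"
        assert (call.donor_label, call.acceptor_label) == (NLA, NLB)
        assert call.consensus_label == converted_state(NLA, NLB)

    def test_ancestral_donor_at_pseudogene_position_is_notch2tv(self):
        call = call_paralog(triplet(N2, N2, NLR))
        assert call.consensus_label == NOTCH2TV
        assert (call.donor_label, call.acceptor_label) == (N2, NLR)

    def test_tied_a_b_transcript_at_nlc_is_hybrid(self):
        call = call_paralog(triplet("ambiguous", NLC, NLC, tied=(NLA, NLB)))
        assert call.consensus_label == HYBRID
        assert call.position_label == NLC

    def test_transcript_clade_conflict_is_ambiguous(self):
        call = call_paralog(triplet(NLA, NLB, NLA))
        assert call.status == "ambiguous"
        assert call.consensus_label is None

    def test_ambiguous_location_is_ambiguous(self):
        call = call_paralog(triplet(NLA, NLA, "ambiguous"))
        assert call.status == "ambiguous"
        assert call.position_label is None


class TestDelineateTract:
    def _profile(self, rng, tract=(5000, 13000)):
        location_ref = random_seq(rng, 20_000)
        donor = mutate_seq(location_ref, 200, rng)  # 1% diverged pair
        acceptor = (
            location_ref[: tract[0]] + donor[tract[0] : tract[1]] + location_ref[tract[1] :]
        )
        return window_identity(
            acceptor, {"donor": donor, "loc": location_ref}, window_size=1000
        )

    def test_simulated_8kb_tract_recovered_within_one_window(self, rng):
        profile = self._profile(rng)
        tract = delineate_tract(profile, "donor", "loc")
        assert tract is not None
        start, end = tract
        assert abs(start - 5000) <= 1000 and abs(end - 13_000) <= 1000

    def test_no_donor_favoring_windows_gives_none(self, rng):
        seq = random_seq(rng, 10_000)
        profile = window_identity(
            seq, {"donor": mutate_seq(seq, 300, rng), "loc": seq}, window_size=1000
        )
        assert delineate_tract(profile, "donor", "loc") is None

    def test_run_shorter_than_min_run_gives_none(self, rng):
        profile = self._profile(rng, tract=(5000, 7000))  # 2 windows
        assert delineate_tract(profile, "donor", "loc", min_run=3) is None


def _calls_from_states(states, hap="hap"):
    calls = []
    for pos, state in zip(CANONICAL_POSITIONS, states):
        if state == ABSENT:
            calls.append(deleted_call(pos, hap))
        elif state == NOTCH2TV:
            calls.append(
                ParalogCall(f"{hap}:{pos}", pos, NOTCH2TV, "igc", True, N2, pos,
                            haplotype_id=hap)
            )
        elif state == HYBRID:
            calls.append(
                ParalogCall(f"{hap}:{pos}", pos, HYBRID, "igc", True,
                            "NOTCH2NLA/B", pos, haplotype_id=hap)
            )
        elif "@" in state:
            donor = state.split("@")[0]
            calls.append(
                ParalogCall(f"{hap}:{pos}", pos, state, "igc", True, donor, pos,
                            haplotype_id=hap)
            )
        elif state.endswith("(inv)"):
            calls.append(
                ParalogCall(f"{hap}:{pos}", pos, state.removesuffix("(inv)"),
                            "clean", orientation="-", haplotype_id=hap)
            )
        else:
            calls.append(
                ParalogCall(f"{hap}:{pos}", pos, state, "clean", haplotype_id=hap)
            )
    return calls


class TestClassify:
    def test_canonical_vector_is_h1(self):
        cfg = classify_haplotype(_calls_from_states((N2, NLR, NLA, NLB, NLC)))
        assert cfg.config_label == "H1"

    def test_nlr_absent_is_h2(self):
        cfg = classify_haplotype(_calls_from_states((N2, ABSENT, NLA, NLB, NLC)))
        assert cfg.config_label == "H2"

    def test_tv_plus_b_to_a_is_h6(self):
        states = (N2, NOTCH2TV, NLA, converted_state(NLA, NLB), NLC)
        assert classify_haplotype(_calls_from_states(states)).config_label == "H6"

    def test_inverted_nlb_distinguishes_h9(self):
        states = (N2, ABSENT, NLA, inverted_state(NLB), NLC)
        assert classify_haplotype(_calls_from_states(states)).config_label == "H9"

    def test_unknown_vector_is_novel(self):
        states = (N2, NLR, NLA, ABSENT, NLC)  # NLB deleted alone: not cataloged
        assert classify_haplotype(_calls_from_states(states)).config_label == "novel"

    def test_two_calls_at_one_position_rejected(self):
        calls = _calls_from_states((N2, NLR, NLA, NLB, NLC))
        with pytest.raises(SdparalogError):
            classify_haplotype(calls + [calls[0]])


def _cohort_configs(counts):
    configs = []
    i = 0
    for label, n in counts.items():
        template = DEFAULT_CATALOG.templates[label]
        for _ in range(n):
            configs.append(
                HaplotypeConfiguration(
                    f"hap{i:03d}",
                    dict(zip(CANONICAL_POSITIONS, template)),
                    label,
                )
            )
            i += 1
    return configs


class TestCohortSummary:
    COUNTS = {
        "H1": 30, "H2": 10, "H3": 5, "H4": 4, "H5": 8,
        "H6": 2, "H7": 2, "H8": 2, "H9": 5, "H10": 1,
    }

    def test_designed_69_haplotype_percentages(self):
        summary = cohort_summary(_cohort_configs(self.COUNTS))
        assert summary.n_haplotypes == 69
        assert summary.percent_igc_union == 28
        assert summary.percent_lacking_nlr == 43
        assert summary.percent_deletion_class == 30
        assert summary.percent_b_to_a == 20
        assert summary.percent_notch2tv == 10
        assert summary.sum_ab_flags == []

    def test_all_h1_cohort_is_quiet(self):
        summary = cohort_summary(_cohort_configs({"H1": 10}))
        assert summary.percent_igc_union == 0
        assert summary.sum_ab_flags == []
        assert summary.copy_numbers[NLA] == 1.0
        assert summary.copy_numbers[NLB] == 1.0

    def test_b_to_a_doubles_nla_copy_number(self):
        summary = cohort_summary(_cohort_configs({"H5": 4}))
        assert summary.copy_numbers[NLA] == 2.0
        assert NLB not in summary.copy_numbers

    def test_order_permutation_invariant(self, rng):
        configs = _cohort_configs(self.COUNTS)
        shuffled = [configs[i] for i in rng.permutation(len(configs))]
        a, b = cohort_summary(configs), cohort_summary(shuffled)
        assert a.config_percent == b.config_percent
        assert a.percent_igc_union == b.percent_igc_union

    def test_deletion_and_non_deletion_partition(self):
        summary = cohort_summary(_cohort_configs(self.COUNTS))
        assert summary.fraction_deletion_class + (
            1 - summary.fraction_deletion_class
        ) == pytest.approx(1.0)

    def test_sum_violation_flagged(self):
        bad = HaplotypeConfiguration(
            "hapX",
            dict(zip(CANONICAL_POSITIONS, (N2, NLR, NLA, ABSENT, NLC))),
            "novel",
        )
        summary = cohort_summary([bad])
        assert summary.sum_ab_flags == ["hapX"]

    def test_empty_rejected(self):
        with pytest.raises(SdparalogError):
            cohort_summary([])


class TestEnrichment:
    def test_perfect_association(self):
        odds, p = enrichment_test([[0, 10], [10, 0]])
        assert odds == 0.0
        assert p == pytest.approx(fisher_exact_enumeration([[0, 10], [10, 0]]))

    def test_identical_rows_p_one(self):
        _, p = enrichment_test([[4, 6], [4, 6]])
        assert p == pytest.approx(1.0)

    def test_balanced_table_odds_one(self):
        odds, _ = enrichment_test([[5, 5], [5, 5]])
        assert odds == 1.0

    @pytest.mark.parametrize(
        "table", [[[3, 7], [9, 2]], [[1, 12], [8, 4]], [[6, 1], [2, 9]]]
    )
    def test_matches_hypergeometric_enumeration(self, table):
        _, p = enrichment_test(table)
        assert p == pytest.approx(fisher_exact_enumeration(table), rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(SdparalogError):
            enrichment_test([[0, 0], [3, 4]])


def test_catalog_tsv_round_trip(tmp_path):
    path = tmp_path / "catalog.tsv"
    DEFAULT_CATALOG.to_tsv(path)
    back = ConfigCatalog.from_tsv(path)
    assert back.positions == DEFAULT_CATALOG.positions
    assert back.templates == DEFAULT_CATALOG.templates
    assert back.deletion_class == DEFAULT_CATALOG.deletion_class
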