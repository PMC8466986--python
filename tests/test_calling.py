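"""MSI and LOH calling: the de novo allele rule, the >35% loss rule,
MSI precedence, and the caller's invariance properties."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msatprof.calling import call_loh, call_locus, call_msi
from msatprof.catalog import LocusDef
from msatprof.fragments import (
    CallingParams,
    GenotypeCall,
    Peak,
    PeakSet,
    bin_peaks,
    call_genotype,
)

DI = LocusDef("L1", "G1", "TS", "INTRON", "CA", 2, False, 100, 200)


def _ps(tissue, peaks, sample="S1", locus="L1"):
    return PeakSet(sample, locus, tissue, peaks=[Peak(s, h) for s, h in peaks])


def _gt(alleles, heights):
    het = len(alleles) == 2
    return GenotypeCall(tuple(alleles), tuple(heights), het, het, "PASS")


class TestCallMsi:
    def test_de_novo_allele_detected(self, params):
        msi, novel = call_msi(
            _gt([150, 154], [1000, 900]),
            _ps("TUMOR", [(150, 950), (154, 900), (158, 700)]),
            DI,
            params,
        )
        assert msi and novel == [158]

    def test_identical_profile_is_stable(self, params):
        msi, novel = call_msi(
            _gt([150, 154], [1000, 900]),
            _ps("TUMOR", [(150, 950), (154, 900)]),
            DI,
            params,
        )
        assert not msi and novel == []

    def test_stutter_not_called_as_novel(self, params):
        # 148 at 12% of the 150 anchor is within the 15% stutter envelope
        msi, novel = call_msi(
            _gt([150], [1900]),
            _ps("TUMOR", [(148, 120), (150, 1000)]),
            DI,
            params,
        )
        assert not msi and novel == []

    def test_slipped_allele_is_novel(self, params):
        # the 154 germline allele slipped to 156; its old position is empty
        msi, novel = call_msi(
            _gt([150, 154], [1000, 900]),
            _ps("TUMOR", [(150, 950), (156, 880)]),
            DI,
            params,
        )
        assert msi and novel == [156]

    def test_stutter_of_diminished_allele_not_msi(self, params):
        # LOH shrank 154 to 20%; its stutter at 152 must anchor on the
        # (noise-filtered) 154 peak and not surface as a novel allele
        msi, novel = call_msi(
            _gt([150, 154], [1000, 1000]),
            _ps("TUMOR", [(150, 1000), (152, 20), (154, 200)]),
            DI,
            params,
        )
        assert not msi


class TestCallLoh:
    def test_just_past_threshold_is_loh(self, params):
        loh, r = call_loh(
            _gt([150, 154], [1000, 1000]),
            _ps("TUMOR", [(150, 1000), (154, 640)]),
            params,
        )
        assert loh == "TRUE" and r == pytest.approx(0.64)

    def test_boundary_retention_is_not_loh(self, params):
        # exactly 35% loss: the rule requires strictly more
        loh, r = call_loh(
            _gt([150, 154], [1000, 1000]),
            _ps("TUMOR", [(150, 1000), (154, 650)]),
            params,
        )
        assert loh == "FALSE" and r == pytest.approx(0.65)

    def test_complete_allele_loss(self, params):
        loh, r = call_loh(
            _gt([150, 154], [800, 1000]),
            _ps("TUMOR", [(154, 900)]),
            params,
        )
        assert loh == "TRUE" and r == 0.0

    def test_homozygous_normal_not_informative(self, params):
        loh, r = call_loh(
            GenotypeCall((150,), (1900.0,), False, False, "PASS"),
            _ps("TUMOR", [(150, 1800)]),
            params,
        )
        assert loh == "NON_INFORMATIVE" and r is None

    def test_no_tumor_signal_at_either_allele(self, params):
        loh, r = call_loh(
            _gt([150, 154], [1000, 1000]),
            _ps("TUMOR", [(170, 900)]),
            params,
        )
        assert loh == "NON_INFORMATIVE"

    def test_imbalance_corrects_for_normal_skew(self, params):
        # normal already skewed 2:1; same skew in tumor is no loss
        loh, r = call_loh(
            _gt([150, 154], [1000, 500]),
            _ps("TUMOR", [(150, 800), (154, 400)]),
            params,
        )
        assert loh == "FALSE" and r == pytest.approx(1.0)

    @given(
        n1=st.floats(min_value=100, max_value=2000),
        n2=st.floats(min_value=100, max_value=2000),
        t1=st.floats(min_value=1, max_value=2000),
        t2=st.floats(min_value=1, max_value=2000),
        scale=st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=150, deadline=None)
    def test_symmetry_and_scale_invariance(self, n1, n2, t1, t2, scale, params):
        verdict, r = call_loh(
            _gt([150, 154], [n1, n2]), _ps("TUMOR", [(150, t1), (154, t2)]), params
        )
        # swapping the two allele labels leaves the folded ratio unchanged
        swapped, r_sw = call_loh(
            _gt([154, 150], [n2, n1]), _ps("TUMOR", [(150, t1), (154, t2)]), params
        )
        assert swapped == verdict and r_sw == pytest.approx(r)
        # rescaling all tumor heights leaves R unchanged
        _, r_sc = call_loh(
            _gt([150, 154], [n1, n2]),
            _ps("TUMOR", [(150, t1 * scale), (154, t2 * scale)]),
            params,
        )
        assert r_sc == pytest.approx(r)

    @given(
        t1=st.floats(min_value=100, max_value=1000),
        drop=st.floats(min_value=0.05, max_value=0.95),
    )
    @settings(max_examples=100, deadline=None)
    def test_lowering_one_allele_never_rescues_loh(self, t1, drop, params):
        gt = _gt([150, 154], [1000.0, 1000.0])
        before, _ = call_loh(gt, _ps("TUMOR", [(150, 1000), (154, t1)]), params)
        after, _ = call_loh(
            gt, _ps("TUMOR", [(150, 1000), (154, t1 * drop)]), params
        )
        if before == "TRUE":
            assert after == "TRUE"


class TestCallLocus:
    def test_stable_pair(self, params):
        call = call_locus(
            _ps("NORMAL", [(150, 1000), (154, 900)]),
            _ps("TUMOR", [(150, 950), (154, 880)]),
            DI,
            params,
        )
        assert call.status == "STABLE" and not call.msi and call.loh == "FALSE"

    def test_msi_takes_precedence_over_loh(self, params):
        # novel allele and a diminished one: one event per locus, MSI wins
        call = call_locus(
            _ps("NORMAL", [(150, 1000), (154, 900)]),
            _ps("TUMOR", [(150, 1000), (154, 300), (158, 700)]),
            DI,
            params,
        )
        assert call.status == "MSI" and call.loh == "NON_INFORMATIVE"
        assert call.novel_alleles == [158]

    def test_half_retained_is_loh(self, params):
        call = call_locus(
            _ps("NORMAL", [(150, 1000), (154, 1000)]),
            _ps("TUMOR", [(150, 1000), (154, 500)]),
            DI,
            params,
        )
        assert call.status == "LOH"
        assert call.imbalance_ratio == pytest.approx(0.5)

    def test_failed_normal_genotyping(self, params):
        call = call_locus(
            _ps("NORMAL", [(150, 1000), (153, 950), (157, 900)]),
            _ps("TUMOR", [(150, 950)]),
            DI,
            params,
        )
        assert call.status == "FAILED"

    def test_homozygous_quiet_pair_is_non_informative(self, params):
        call = call_locus(
            _ps("NORMAL", [(150, 1900)]),
            _ps("TUMOR", [(150, 1800)]),
            DI,
            params,
        )
        assert call.status == "NON_INFORMATIVE" and not call.msi

    def test_mismatched_pair_rejected(self, params):
        with pytest.raises(ValueError, match="mismatched"):
            call_locus(
                _ps("NORMAL", [(150, 1000)], sample="S1"),
                _ps("TUMOR", [(150, 1000)], sample="S2"),
                DI,
                params,
            )

    @given(
        normal_peaks=st.lists(
            st.tuples(
                st.sampled_from([146, 148, 150, 152, 154, 156]),
                st.floats(min_value=10, max_value=2000),
            ),
            min_size=1,
            max_size=4,
            unique_by=lambda t: t[0],
        ),
        tumor_peaks=st.lists(
            st.tuples(
                st.sampled_from([146, 148, 150, 152, 154, 156]),
                st.floats(min_value=10, max_value=2000),
            ),
            min_size=1,
            max_size=4,
            unique_by=lambda t: t[0],
        ),
    )
    @settings(max_examples=200, deadline=None)
    def test_every_pair_gets_exactly_one_defined_status(
        self, normal_peaks, tumor_peaks, params
    ):
        call = call_locus(
            _ps("NORMAL", normal_peaks), _ps("TUMOR", tumor_peaks), DI, params
        )
        assert call.status in ("MSI", "LOH", "STABLE", "NON_INFORMATIVE", "FAILED")
        assert call.msi == (call.status == "MSI")

    @given(
        normal_peaks=st.lists(
            st.tuples(
                st.sampled_from([144, 146, 148, 150, 152, 154]),
                st.floats(min_value=10, max_value=2000),
            ),
            min_size=1,
            max_size=6,
            unique_by=lambda t: t[0],
        ),
        tumor_peaks=st.lists(
            st.tuples(
                st.sampled_from([144, 146, 148, 150, 152, 154]),
                st.floats(min_value=10, max_value=2000),
            ),
            min_size=1,
            max_size=6,
            unique_by=lambda t: t[0],
        ),
    )
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_brute_force_reference(
        self, normal_peaks, tumor_peaks, params
    ):
        """The caller must match an independently coded reference that
        applies the noise/stutter/novel-allele rules by exhaustive lookup."""
        call = call_locus(
            _ps("NORMAL", normal_peaks), _ps("TUMOR", tumor_peaks), DI, params
        )
        ref = _reference_call(dict(normal_peaks), dict(tumor_peaks), 2, params)
        assert call.status == ref


def _reference_filter(heights: dict, motif: int, p: CallingParams, anchors=None):
    """Set-based re-statement of the noise + stutter rules."""
    if not heights:
        return {}
    floor = p.min_rel_height * max(heights.values())
    kept = {s: h for s, h in heights.items() if h >= floor}
    anchor_pool = dict(kept)
    for s, h in (anchors or {}).items():
        anchor_pool[s] = max(anchor_pool.get(s, 0.0), h)
    out = {}
    for s, h in kept.items():
        a = anchor_pool.get(s + motif)
        if a is not None and a > h and h <= p.stutter_ratio * a:
            continue
        out[s] = h
    return out


def _reference_call(normal, tumor, motif, p):
    surv = _reference_filter(normal, motif, p)
    if len(surv) == 0 or len(surv) > 2:
        return "FAILED"
    alleles = sorted(surv)
    floor = p.min_rel_height * max(tumor.values())
    tumor_kept = {s: h for s, h in tumor.items() if h >= floor}
    anchors = {s: h for s, h in tumor.items() if s in surv}
    tumor_surv = _reference_filter(tumor, motif, p, anchors)
    if any(s not in surv for s in tumor_surv):
        return "MSI"
    if len(alleles) != 2:
        return "NON_INFORMATIVE"
    t = [tumor_kept.get(a, 0.0) for a in alleles]
    n = [surv[a] for a in alleles]
    if t[0] == 0 and t[1] == 0:
        return "NON_INFORMATIVE"
    if not tumor_kept:
        return "NON_INFORMATIVE"
    if t[0] == 0 or t[1] == 0:
        r = 0.0
    else:
        big = (t[0] / t[1]) / (n[0] / n[1])
        r = min(big, 1 / big)
    return "LOH" if r < 1 - p.loh_loss_threshold else "STABLE"
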