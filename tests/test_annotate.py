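"""Filtering, frequency binning, suspicious-VUS rule, P/LP summary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import sdyburden as s
from sdyburden.annotate import (
    OVERFLOW_LABEL,
    FrequencyBins,
    assign_bin,
    filter_nonsynonymous,
    flag_suspicious_vus,
    summarize_plp,
    suspicious_vus_mask,
)
from sdyburden.datatypes import variants_to_frame
from sdyburden.examples import example_panels


def _record(**kwargs) -> s.VariantRecord:
    base = dict(
        sample_id="s1",
        gene="GENE1",
        contig="1",
        position=100,
        ref="A",
        alt="G",
        consequence_class="nonsynonymous",
        af_global=1e-5,
    )
    base.update(kwargs)
    return s.VariantRecord(**base)


class TestBins:
    @pytest.mark.parametrize(
        "af,label",
        [
            (0.0, "<0.001"),
            (0.0009999, "<0.001"),
            (0.001, "0.001–0.01"),
            (0.01, "0.01–0.1"),
            (0.0999, "0.01–0.1"),
            (0.1, "0.1–0.25"),
            (0.25, "0.25–0.5"),
            (0.5, "0.25–0.5"),  # final bin closed
            (0.50001, OVERFLOW_LABEL),
            (1.0, OVERFLOW_LABEL),
        ],
    )
    def test_edge_convention(self, af, label):
        assert assign_bin(af) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_bin(1.5)
        with pytest.raises(ValueError):
            assign_bin(-0.1)

    def test_labels(self):
        assert FrequencyBins().labels == [
            "<0.001",
            "0.001–0.01",
            "0.01–0.1",
            "0.1–0.25",
            "0.25–0.5",
        ]

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            FrequencyBins(edges=(0.01, 0.001))
        with pytest.raises(ValueError):
            FrequencyBins(edges=(0.0, 0.5))

    @given(st.floats(min_value=0.0, max_value=0.5, allow_nan=False))
    def test_partition_every_af_maps_to_one_bin(self, af):
        bins = FrequencyBins()
        label = assign_bin(af, bins)
        assert label in bins.labels
        assert bins.labels.count(label) == 1

    def test_vectorised_matches_scalar(self):
        bins = FrequencyBins()
        afs = np.concatenate(
            [np.array([0.0, 0.001, 0.01, 0.1, 0.25, 0.5, 0.7]),
             np.random.default_rng(0).random(200)]
        )
        vec = bins.assign_many(afs).tolist()
        assert vec == [assign_bin(a, bins) for a in afs]

    def test_counts_partition_totals(self, small_study):
        bins = FrequencyBins()
        labels = bins.assign_many(small_study.variants["af_global"].to_numpy())
        analysed = labels[labels != OVERFLOW_LABEL]
        assert labels.value_counts().sum() == len(small_study.variants)
        assert analysed.value_counts().sum() == len(analysed)


class TestNonsynonymousFilter:
    def test_counts(self):
        records = [
            _record(),
            _record(alt="T", consequence_class="synonymous"),
            _record(alt="C"),
            _record(position=200, consequence_class="synonymous"),
            _record(position=300, consequence_class="synonymous"),
        ]
        kept = filter_nonsynonymous(records)
        assert len(kept) == 2
        assert (kept["consequence_class"] == "nonsynonymous").all()

    def test_all_synonymous_warns(self, caplog):
        records = [_record(consequence_class="synonymous")]
        with caplog.at_level("WARNING", logger="sdyburden.annotate"):
            kept = filter_nonsynonymous(records)
        assert kept.empty
        assert any("no nonsynonymous" in r.message for r in caplog.records)

    def test_missing_consequence_fails_listing_offenders(self):
        frame = variants_to_frame([_record(), _record(alt="T")])
        frame.loc[1, "consequence_class"] = ""
        with pytest.raises(ValueError, match="s1:GENE1"):
            filter_nonsynonymous(frame)


class TestSuspiciousVus:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(mcap_score=0.3), True),
            (dict(mcap_score=0.3, clinvar_class="B"), False),
            (dict(mcap_score=0.3, clinvar_class="LP"), False),
            (dict(mcap_score=0.3, clinvar_class="VUS"), True),
            (dict(mcap_score=0.025), False),  # strict inequality at cutoff
            (dict(mcap_score=0.0251), True),
            (dict(mcap_score=None), False),
            (dict(mcap_score=0.3, af_global=0.001), False),  # rarity is strict <
            (dict(mcap_score=0.3, af_global=0.0009), True),
            (dict(mcap_score=0.3, consequence_class="synonymous"), False),
        ],
    )
    def test_rule(self, kwargs, expected):
        assert flag_suspicious_vus(_record(**kwargs)) is expected

    @given(
        mcap=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        thr_lo=st.floats(min_value=0.0, max_value=0.5),
        thr_hi=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_monotone_in_threshold(self, mcap, thr_lo, thr_hi):
        """Lowering the M-CAP cutoff never unflags a variant."""
        lo, hi = sorted([thr_lo, thr_hi])
        record = _record(mcap_score=mcap)
        if flag_suspicious_vus(record, mcap_threshold=hi):
            assert flag_suspicious_vus(record, mcap_threshold=lo)

    def test_vectorised_matches_scalar(self, plp_example):
        from sdyburden.datatypes import frame_to_variants

        mask = suspicious_vus_mask(plp_example)
        records = frame_to_variants(plp_example)
        assert mask.tolist() == [flag_suspicious_vus(r) for r in records]


class TestPlpSummary:
    def test_worked_example_counts(self, plp_example):
        summary = summarize_plp(plp_example, example_panels())
        assert summary.n_decedents == 11
        assert summary.recurrence_count("TTR", "p.Val142Ile") == 4

    def test_recessive_heterozygotes_flagged_but_kept(self, plp_example):
        summary = summarize_plp(plp_example, example_panels())
        flagged = set(
            summary.per_variant.loc[
                summary.per_variant["recessive_incidental"], "gene"
            ]
        )
        assert flagged == {"QARS", "CLN8", "PPT1", "CSTB", "FKRP"}

    def test_duplicated_rows_do_not_inflate_counts(self, plp_example):
        doubled = pd.concat([plp_example, plp_example], ignore_index=True)
        summary = summarize_plp(doubled, example_panels())
        assert summary.n_decedents == 11
        assert summary.recurrence_count("TTR", "p.Val142Ile") == 4

    def test_empty_input(self):
        summary = summarize_plp([], example_panels())
        assert summary.n_decedents == 0
        assert summary.recurrence.empty

    def test_panel_memberships_annotated(self, plp_example):
        summary = summarize_plp(plp_example, example_panels())
        kcnh2 = summary.per_variant[summary.per_variant["gene"] == "KCNH2"]
        assert kcnh2["panel_memberships"].iloc[0] == "cmar1,epilepsy"
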