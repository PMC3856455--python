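import pandas as pd
import pytest

from ricecnv.call import CnvCall
from ricecnv.cnvr import (
    GenotypeMatrix,
    ProbeValidationTable,
    genotype,
    merge_calls,
    unique_cnvrs,
    validate_cnvrs,
)


def _call(sample, chrom, start, end, type_="loss"):
    return CnvCall(sample, chrom, start, end, type_, -2.5 if type_ == "loss" else 1.2, 6)


class TestMergeCalls:
    def test_overlapping_calls_merge(self):
        cnvrs = merge_calls(
            [_call("A", "chr1", 100, 1199), _call("B", "chr1", 600, 1700)]
        )
        assert len(cnvrs) == 1
        r = cnvrs[0]
        assert (r.start, r.end) == (100, 1700)
        assert r.type == "loss"
        assert r.carrier_samples == {"A", "B"}

    def test_disjoint_calls_stay_separate(self):
        cnvrs = merge_calls(
            [_call("A", "chr1", 100, 1199), _call("A", "chr1", 5000, 6100)]
        )
        assert len(cnvrs) == 2

    def test_loss_plus_gain_makes_both(self):
        cnvrs = merge_calls(
            [_call("A", "chr1", 100, 1199, "loss"), _call("B", "chr1", 600, 1700, "gain")]
        )
        assert len(cnvrs) == 1
        assert cnvrs[0].type == "both"

    def test_transitive_chaining(self):
        cnvrs = merge_calls(
            [
                _call("A", "chr1", 100, 1000),
                _call("B", "chr1", 900, 2000),
                _call("C", "chr1", 1900, 3000),
            ]
        )
        assert len(cnvrs) == 1
        assert cnvrs[0].carrier_samples == {"A", "B", "C"}

    def test_chromosomes_independent(self):
        cnvrs = merge_calls([_call("A", "chr1", 100, 1199), _call("A", "chr2", 100, 1199)])
        assert len(cnvrs) == 2

    def test_order_invariance(self):
        calls = [
            _call("A", "chr1", 5000, 6000),
            _call("B", "chr1", 100, 1199),
            _call("C", "chr1", 900, 1500),
        ]
        a = merge_calls(calls)
        b = merge_calls(list(reversed(calls)))
        assert [(r.chrom, r.start, r.end, r.carrier_samples) for r in a] == [
            (r.chrom, r.start, r.end, r.carrier_samples) for r in b
        ]

    def test_merge_idempotence(self):
        calls = [
            _call("A", "chr1", 100, 1199),
            _call("B", "chr1", 600, 1700),
            _call("A", "chr2", 50, 2000),
        ]
        once = merge_calls(calls)
        spans = [(r.chrom, r.start, r.end) for r in once]
        again = merge_calls(
            [_call("X", c, s, e) for c, s, e in spans]
        )
        assert [(r.chrom, r.start, r.end) for r in again] == spans

    def test_every_call_maps_to_one_cnvr(self):
        calls = [
            _call("A", "chr1", 100, 1199),
            _call("B", "chr1", 600, 1700),
            _call("C", "chr2", 100, 1500),
        ]
        cnvrs = merge_calls(calls)
        assert sum(len(r.calls) for r in cnvrs) == len(calls)


class TestValidateCnvrs:
    def _validation(self, layout, multi_ids=()):
        df = pd.DataFrame(
            {
                "probe_id": layout.probes["probe_id"],
                "n_perfect_matches": [
                    3 if pid in multi_ids else 1 for pid in layout.probes["probe_id"]
                ],
            }
        )
        return ProbeValidationTable(df)

    def test_enough_unique_probes_retained(self, layout):
        probes = layout.chromosome_probes("chr1").head(6)
        cnvrs = merge_calls(
            [_call("A", "chr1", int(probes["start"].min()), int(probes["end"].max()))]
        )
        kept = validate_cnvrs(cnvrs, layout, self._validation(layout), min_probes=5)
        assert len(kept) == 1
        assert kept[0].n_probes >= 5

    def test_multimapping_probes_drop_cnvr(self, layout):
        probes = layout.chromosome_probes("chr1").head(6)
        cnvrs = merge_calls(
            [_call("A", "chr1", int(probes["start"].min()), int(probes["end"].max()))]
        )
        multi = set(probes["probe_id"].head(2))
        rejects: list = []
        kept = validate_cnvrs(
            cnvrs, layout, self._validation(layout, multi), min_probes=5, rejects=rejects
        )
        assert kept == []
        assert "fewer than 5" in rejects[0]["reason"]

    def test_gap_overlap_drops_cnvr(self, layout):
        probes = layout.chromosome_probes("chr1").head(8)
        start, end = int(probes["start"].min()), int(probes["end"].max())
        cnvrs = merge_calls([_call("A", "chr1", start, end)])
        rejects: list = []
        kept = validate_cnvrs(
            cnvrs, layout, gaps={"chr1": [(end - 10, end + 500)]}, rejects=rejects
        )
        assert kept == []
        assert rejects[0]["reason"] == "gap overlap"


class TestGenotype:
    def test_states_and_frequency(self, layout):
        calls = [_call("A", "chr1", 100, 3000), _call("B", "chr1", 200, 2500, "gain")]
        cnvrs = merge_calls(calls)
        panel = ["A", "B", "C", "D"]
        matrix = genotype(cnvrs, calls, panel)
        cid = cnvrs[0].id
        assert matrix.states.loc["A", cid] == "L"
        assert matrix.states.loc["B", cid] == "G"
        assert matrix.states.loc["C", cid] == "N"
        assert cnvrs[0].frequency == pytest.approx(0.5)
        assert cid in matrix.excluded_complex  # loss+gain region is complex

    def test_unique_cnvr_flagged(self, layout):
        calls = [_call("A", "chr1", 100, 3000)]
        cnvrs = merge_calls(calls)
        panel = [f"S{i}" for i in range(19)] + ["A"]
        matrix = genotype(cnvrs, calls, panel)
        assert unique_cnvrs(matrix) == [cnvrs[0].id]
        assert cnvrs[0].frequency == pytest.approx(0.05)

    def test_all_carrier_group_frequency(self):
        panel = [f"S{i}" for i in range(9)]
        calls = [_call(s, "chr1", 100, 3000) for s in panel]
        cnvrs = merge_calls(calls)
        matrix = genotype(cnvrs, calls, panel)
        assert cnvrs[0].frequency == pytest.approx(1.0)
        assert (matrix.states[cnvrs[0].id] == "L").all()

    def test_unknown_sample_errors(self):
        calls = [_call("GHOST", "chr1", 100, 3000)]
        cnvrs = merge_calls(calls)
        with pytest.raises(ValueError, match="GHOST"):
            genotype(cnvrs, calls, ["A", "B"])

    def test_complex_excluded_from_analysis_columns(self):
        calls = [
            _call("A", "chr1", 100, 3000, "loss"),
            _call("B", "chr1", 500, 2000, "gain"),
            _call("A", "chr2", 100, 3000, "loss"),
        ]
        cnvrs = merge_calls(calls)
        matrix = genotype(cnvrs, calls, ["A", "B"])
        both = [r.id for r in cnvrs if r.type == "both"]
        assert set(matrix.excluded_complex) == set(both)
        assert set(matrix.analysis_columns()) == {
            r.id for r in cnvrs if r.type != "both"
        }
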