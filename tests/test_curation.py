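"""Curation pipeline tests: labels, filters, replicates, gates, conservation."""

import numpy as np
import pandas as pd
import pytest

import mhcload as m
from mhcload.curation import CurationError


def _raw(rows):
    return pd.DataFrame(rows, columns=["epitope", "hla", "raw_label", "cofactor"]).fillna("")


def _row(epitope="SIINFEKL", hla="HLA-A*02:01", raw_label="Positive", cofactor=""):
    return {"epitope": epitope, "hla": hla, "raw_label": raw_label, "cofactor": cofactor}


class TestReadAssayTable:
    def test_toy_tsv_yields_one_record_per_row(self, tmp_path):
        path = tmp_path / "toy.tsv"
        path.write_text(
            "Description\tAllele Name\tQualitative Measure\n"
            "SIINFEKL\tHLA-A*02:01\tPositive\n"
            "KVAELVHFL\tHLA-A*02:01\tNegative\n"
            "FPSLREAAL\tHLA-B*07:02\tPositive-Low\n"
        )
        records, n_malformed = m.read_assay_table(path)
        assert len(records) == 3 and n_malformed == 0
        assert list(records.columns) == ["epitope", "hla", "raw_label", "cofactor"]

    def test_empty_peptide_cell_counted_as_malformed(self, tmp_path):
        path = tmp_path / "toy.csv"
        path.write_text("peptide,hla,label\nSIINFEKL,HLA-A*02,Positive\n,HLA-A*02,Negative\n")
        records, n_malformed = m.read_assay_table(path)
        assert len(records) == 1 and n_malformed == 1

    def test_strict_mode_rejects_malformed_rows(self, tmp_path):
        path = tmp_path / "toy.csv"
        path.write_text("peptide,hla,label\n,HLA-A*02,Negative\n")
        with pytest.raises(CurationError, match="malformed"):
            m.read_assay_table(path, strict=True)

    def test_missing_mandatory_column_lists_available(self, tmp_path):
        path = tmp_path / "toy.csv"
        path.write_text("peptide,outcome_misc\nSIINFEKL,Positive\n")
        with pytest.raises(CurationError, match="available columns"):
            m.read_assay_table(path)

    def test_read_is_deterministic(self, tmp_path):
        path = tmp_path / "toy.tsv"
        path.write_text(
            "Description\tAllele Name\tQualitative Measure\nSIINFEKL\tHLA-A*02\tPositive\n"
        )
        a, _ = m.read_assay_table(path)
        b, _ = m.read_assay_table(path)
        pd.testing.assert_frame_equal(a, b)


class TestHarmonizeLabels:
    @pytest.mark.parametrize(
        "raw, expect",
        [
            ("Positive", 1),
            ("Positive-Low", 1),
            ("Positive-High", 1),
            ("Positive-Intermediate", 1),
            ("Negative", 0),
        ],
    )
    def test_outcome_mapping(self, raw, expect):
        out, n = m.harmonize_labels(_raw([_row(raw_label=raw)]))
        assert n == 0 and out["label"].tolist() == [expect]

    def test_unmappable_outcomes_excluded_and_counted(self):
        out, n = m.harmonize_labels(
            _raw([_row(), _row(raw_label="Untested"), _row(raw_label="")])
        )
        assert len(out) == 1 and n == 2


class TestFilterRecords:
    def test_unresolved_hla_dropped(self):
        rec, _ = m.harmonize_labels(_raw([_row(hla="HLA class I"), _row()]))
        out, counts = m.filter_records(rec)
        assert counts["unresolved_hla"] == 1 and len(out) == 1

    def test_noncanonical_peptide_dropped(self):
        rec, _ = m.harmonize_labels(_raw([_row(epitope="ALXDKEF"), _row()]))
        out, counts = m.filter_records(rec)
        assert counts["noncanonical_peptide"] == 1 and len(out) == 1

    def test_cofactor_annotation_dropped(self):
        rec, _ = m.harmonize_labels(_raw([_row(cofactor="beta-2m"), _row()]))
        out, counts = m.filter_records(rec)
        assert counts["cofactor_present"] == 1 and len(out) == 1

    def test_allele_names_grouped_and_preserved(self):
        rec, _ = m.harmonize_labels(_raw([_row(hla="HLA-A*02:01:01")]))
        out, _ = m.filter_records(rec)
        assert out["hla"].tolist() == ["HLA-A*02"]
        assert out["hla_full"].tolist() == ["HLA-A*02:01:01"]


class TestNormalizeHla:
    @pytest.mark.parametrize(
        "raw, expect",
        [
            ("HLA-A*02:01", "HLA-A*02"),
            ("HLA-A*02", "HLA-A*02"),
            ("HLA-B*0702", "HLA-B*07"),
            ("hla-c*07:02", "HLA-C*07"),
            ("HLA class I", None),
            ("HLA-A", None),
            ("H-2-Kb", None),
        ],
    )
    def test_allele_group_normalization(self, raw, expect):
        assert m.normalize_hla(raw) == expect


class TestAggregateReplicates:
    def _prepped(self, labels, epitope="SIINFEKL"):
        rec, _ = m.harmonize_labels(
            _raw([_row(epitope=epitope, raw_label=lab) for lab in labels])
        )
        rec, _ = m.filter_records(rec)
        return rec

    def test_majority_vote_sets_label_and_re(self):
        out, counts = m.aggregate_replicates(self._prepped(["Positive", "Positive-Low", "Negative"]))
        assert len(out) == 1
        assert out.iloc[0]["label"] == 1 and out.iloc[0]["re"] == 3
        assert counts["merged_replicates"] == 2

    def test_singleton_untouched(self):
        out, _ = m.aggregate_replicates(self._prepped(["Negative"]))
        assert out.iloc[0]["re"] == 1 and out.iloc[0]["label"] == 0

    def test_exact_tie_dropped_and_counted(self):
        out, counts = m.aggregate_replicates(self._prepped(["Positive", "Negative"]))
        assert len(out) == 0 and counts["tied_replicates"] == 2

    def test_any_positive_policy_keeps_conflicts(self):
        out, _ = m.aggregate_replicates(
            self._prepped(["Positive", "Negative"]), conflict_policy="any_positive"
        )
        assert out.iloc[0]["label"] == 1 and out.iloc[0]["re"] == 2

    def test_drop_conflicts_policy_requires_unanimity(self):
        rec = pd.concat(
            [self._prepped(["Positive", "Negative", "Negative"], "SIINFEKL"),
             self._prepped(["Negative", "Negative"], "KVAELVHFL")]
        )
        out, counts = m.aggregate_replicates(rec, conflict_policy="drop_conflicts")
        assert out["epitope"].tolist() == ["KVAELVHFL"]
        assert counts["tied_replicates"] == 3


class TestQcCutoff:
    def test_t1_is_identity(self):
        df = pd.DataFrame({"epitope": list("ABCD"), "hla": "HLA-A*02", "label": 1, "re": [1, 2, 3, 5]})
        out, dropped = m.apply_qc_cutoff(df, 1)
        assert len(out) == 4 and dropped == 0

    def test_threshold_keeps_records_at_or_above_t(self):
        df = pd.DataFrame({"epitope": list("ABCD"), "hla": "HLA-A*02", "label": 1, "re": [1, 2, 3, 5]})
        out, dropped = m.apply_qc_cutoff(df, 3)
        assert out["re"].tolist() == [3, 5] and dropped == 2

    def test_output_size_nonincreasing_in_t(self):
        df = pd.DataFrame(
            {"epitope": [f"P{i}" for i in range(20)], "hla": "HLA-A*02", "label": 1,
             "re": (np.arange(20) % 5) + 1}
        )
        sizes = [len(m.apply_qc_cutoff(df, t)[0]) for t in range(1, 6)]
        assert sizes == sorted(sizes, reverse=True)

    def test_all_singletons_at_t5_warns_empty(self):
        df = pd.DataFrame({"epitope": list("ABCDE"), "hla": "HLA-A*02", "label": 1, "re": 1})
        with pytest.warns(UserWarning, match="removed every record"):
            out, _ = m.apply_qc_cutoff(df, 5)
        assert out.empty

    @pytest.mark.parametrize("t", [0, 6, -1])
    def test_out_of_range_cutoff_rejected(self, t):
        df = pd.DataFrame({"epitope": ["A"], "hla": ["HLA-A*02"], "label": [1], "re": [1]})
        with pytest.raises(CurationError):
            m.apply_qc_cutoff(df, t)


class TestMinClassCounts:
    def _hla_block(self, hla, n_pos, n_neg):
        eps = [f"{hla}-P{i}" for i in range(n_pos + n_neg)]
        return pd.DataFrame(
            {"epitope": eps, "hla": hla, "label": [1] * n_pos + [0] * n_neg, "re": 1}
        )

    def test_boundary_hla_with_exactly_100_each_retained(self):
        df = self._hla_block("HLA-A*02", 100, 100)
        out, dropped, retained = m.enforce_min_class_counts(df, 100)
        assert retained == ["HLA-A*02"] and dropped == 0

    def test_hla_below_threshold_fully_dropped(self):
        df = pd.concat(
            [self._hla_block("HLA-A*02", 99, 500), self._hla_block("HLA-B*07", 120, 130)]
        )
        out, dropped, retained = m.enforce_min_class_counts(df, 100)
        assert retained == ["HLA-B*07"]
        assert dropped == 599

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            out, dropped, retained = m.enforce_min_class_counts(
                pd.DataFrame(columns=["epitope", "hla", "label", "re"]), 100
            )
        assert out.empty and retained == []


class TestFullPipeline:
    def test_record_conservation_balances_exactly(self, small_table):
        table, _ = small_table
        records = table.rename(
            columns={"Description": "epitope", "Allele Name": "hla",
                     "Qualitative Measure": "raw_label", "Co-factor": "cofactor"}
        )
        ds = m.curate(records, min_per_class=50)
        prov = ds.provenance
        assert prov["n_input"] == prov["n_output"] + sum(prov["dropped"].values())
        assert prov["n_input"] == len(table)

    def test_curation_is_idempotent_and_order_invariant(self, small_table):
        table, _ = small_table
        records = table.rename(
            columns={"Description": "epitope", "Allele Name": "hla",
                     "Qualitative Measure": "raw_label", "Co-factor": "cofactor"}
        )
        ds1 = m.curate(records, min_per_class=50)
        shuffled = records.sample(frac=1.0, random_state=9).reset_index(drop=True)
        ds2 = m.curate(shuffled, min_per_class=50)
        key = ["epitope", "hla", "label", "re"]
        pd.testing.assert_frame_equal(
            ds1.records[key].sort_values(key).reset_index(drop=True),
            ds2.records[key].sort_values(key).reset_index(drop=True),
        )

    def test_every_retained_hla_passes_the_class_gate(self, small_dataset):
        counts = small_dataset.records.groupby("hla")["label"].agg(["sum", "size"])
        assert (counts["sum"] >= 50).all()
        assert ((counts["size"] - counts["sum"]) >= 50).all()

    def test_at_most_one_record_per_pair_and_canonical_epitopes(self, small_dataset):
        rec = small_dataset.records
        assert not rec.duplicated(subset=["epitope", "hla"]).any()
        from mhcload.features import is_canonical

        assert rec["epitope"].map(is_canonical).all()

    def test_dataset_round_trips_through_disk(self, tmp_path, small_dataset):
        path = tmp_path / "dataset.tsv"
        small_dataset.write(path)
        loaded = m.CuratedDataset.read(path)
        pd.testing.assert_frame_equal(loaded.records, small_dataset.records)
        assert loaded.provenance == small_dataset.provenance
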