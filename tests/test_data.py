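"""Cq parsing, replicate collapsing, subsetting and the RQ transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab import (
    collapse_replicates,
    default_study_config,
    read_cq_table,
    relative_quantities,
    simulate_experiment,
    subset,
    write_cq_table,
)
from refstab.errors import CqValueError, FormatError, InsufficientDataError

from conftest import build_dataset


def _write_files(tmp_path, cq_text, meta_text):
    cq = tmp_path / "cq.csv"
    meta = tmp_path / "meta.csv"
    cq.write_text(cq_text)
    meta.write_text(meta_text)
    return cq, meta


class TestParsing:
    def test_minimal_well_formed_file(self, tmp_path):
        cq, meta = _write_files(
            tmp_path,
            "sample,gene,replicate,cq\ns1,a,1,20.0\ns1,b,1,21.0\ns2,a,1,20.5\ns2,b,1,21.5\n",
            "sample,fate\ns1,vegetative\ns2,flowering\n",
        )
        ds = read_cq_table(cq, meta)
        assert len(ds.cq) == 4
        assert ds.genes == ["a", "b"] and ds.samples == ["s1", "s2"]
        assert ds.metadata.loc["s2", "fate"] == "flowering"

    def test_na_cq_names_the_well(self, tmp_path):
        cq, meta = _write_files(
            tmp_path,
            "sample,gene,replicate,cq\ns1,a,1,20.0\ns1,b,2,NA\n",
            "sample\ns1\n",
        )
        with pytest.raises(CqValueError, match="gene='b'"):
            read_cq_table(cq, meta)

    @pytest.mark.parametrize("bad", ["-3.0", "0"])
    def test_nonpositive_cq_rejected(self, tmp_path, bad):
        cq, meta = _write_files(
            tmp_path, f"sample,gene,replicate,cq\ns1,a,1,{bad}\n", "sample\ns1\n"
        )
        with pytest.raises(CqValueError):
            read_cq_table(cq, meta)

    def test_missing_column_is_format_error(self, tmp_path):
        cq, meta = _write_files(tmp_path, "sample,gene,cq\ns1,a,20\n", "sample\ns1\n")
        with pytest.raises(FormatError, match="replicate"):
            read_cq_table(cq, meta)

    def test_unknown_sample_rejected(self, tmp_path):
        cq, meta = _write_files(
            tmp_path, "sample,gene,replicate,cq\nsX,a,1,20\n", "sample\ns1\n"
        )
        with pytest.raises(FormatError, match="sX"):
            read_cq_table(cq, meta)

    def test_duplicate_well_rejected(self, tmp_path):
        cq, meta = _write_files(
            tmp_path,
            "sample,gene,replicate,cq\ns1,a,1,20\ns1,a,1,20.5\n",
            "sample\ns1\n",
        )
        with pytest.raises(FormatError, match="duplicate"):
            read_cq_table(cq, meta)

    def test_simulated_dataset_roundtrip(self, tmp_path):
        ds, _ = simulate_experiment(default_study_config("celmisia", seed=3))
        write_cq_table(ds, tmp_path / "cq.csv", tmp_path / "meta.csv")
        back = read_cq_table(tmp_path / "cq.csv", tmp_path / "meta.csv")
        merged = ds.cq.merge(back.cq, on=["sample", "gene", "replicate"])
        assert len(merged) == len(ds.cq)
        assert (merged["cq_x"] == merged["cq_y"]).all()  # exact, not approximate
        pd.testing.assert_frame_equal(ds.metadata, back.metadata)


class TestCollapse:
    def test_identical_replicates_not_flagged(self):
        ds = build_dataset({"a": [20.0]})
        extra = ds.cq.copy()
        ds.cq = pd.concat(
            [ds.cq, extra.assign(replicate=2), extra.assign(replicate=3)], ignore_index=True
        )
        out, qc = collapse_replicates(ds, sd_tol=0.5)
        assert out.cq["cq"].tolist() == [20.0]
        assert qc["sd"].tolist() == [0.0] and not qc["flagged"].any()

    def test_two_replicates_hand_values(self):
        rows = pd.DataFrame(
            [("s1", "a", 1, 20.0), ("s1", "a", 2, 21.0)],
            columns=["sample", "gene", "replicate", "cq"],
        )
        meta = pd.DataFrame(index=pd.Index(["s1"], name="sample"))
        ds = build_dataset({"a": [20.0]})
        ds.cq = rows
        ds.metadata = meta
        out, qc = collapse_replicates(ds, sd_tol=0.5)
        assert out.cq["cq"].iloc[0] == pytest.approx(20.5)
        assert qc["sd"].iloc[0] == pytest.approx(0.70710678, abs=1e-6)
        assert bool(qc["flagged"].iloc[0])

    def test_flag_rate_under_default_technical_noise(self):
        # sigma_tech = 0.15 on triplicates: replicate SD > 0.5 is a > 3.3 sigma
        # event, so well under 1% of wells should be flagged
        ds, _ = simulate_experiment(default_study_config("celmisia", seed=11))
        _, qc = collapse_replicates(ds, sd_tol=0.5)
        assert qc["flagged"].mean() < 0.01


class TestSubset:
    def test_factor_level_counts(self, celmisia):
        ds, _ = celmisia
        veg = subset(ds, "fate", "vegetative")
        assert len(veg.samples) == 24
        assert veg.genes == ds.genes

    def test_composition(self, celmisia):
        ds, _ = celmisia
        both = subset(subset(ds, "altitude", "1520"), "month", "January")
        meta = both.metadata
        assert (meta["altitude"] == "1520").all() and (meta["month"] == "January").all()
        assert len(both.samples) == 4  # 2 fates x 2 bio reps

    def test_partition_property(self, celmisia):
        ds, _ = celmisia
        union = set()
        for level in ds.metadata["month"].unique():
            union |= set(subset(ds, "month", level).samples)
        assert union == set(ds.samples)

    def test_unknown_factor_and_level(self, celmisia):
        ds, _ = celmisia
        with pytest.raises(KeyError):
            subset(ds, "nope", "x")
        with pytest.raises(KeyError):
            subset(ds, "fate", "nope")

    def test_single_sample_level_insufficient(self):
        ds = build_dataset(
            {"a": [20, 21, 22]},
            metadata={"s1": {"grp": "x"}, "s2": {"grp": "y"}, "s3": {"grp": "y"}},
        )
        with pytest.raises(InsufficientDataError):
            subset(ds, "grp", "x")


class TestRelativeQuantities:
    def test_powers_of_two(self):
        ds = build_dataset({"a": [20.0, 21.0, 22.0]})
        rq = relative_quantities(ds)
        assert rq.rq.loc["a"].tolist() == pytest.approx([1.0, 0.5, 0.25])

    def test_efficiency_corrected(self):
        ds = build_dataset({"a": [20.0, 21.0]}, efficiencies={"a": 2.073})
        rq = relative_quantities(ds, use_efficiency=True)
        assert rq.rq.loc["a"].tolist() == pytest.approx([1.0, 1 / 2.073])
        assert rq.rq.loc["a", "s2"] == pytest.approx(0.48239, abs=1e-5)

    def test_requires_collapsed(self):
        ds = build_dataset({"a": [20.0]})
        ds.cq = pd.concat([ds.cq, ds.cq.assign(replicate=2)], ignore_index=True)
        with pytest.raises(InsufficientDataError, match="collapse"):
            relative_quantities(ds)

    @given(
        cqs=st.lists(st.floats(10, 35), min_size=2, max_size=8),
        e=st.floats(1.5, 2.2),
        shift=st.floats(-3, 3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_range_and_shift_invariance(self, cqs, e, shift):
        """RQ lies in (0, 1] with max exactly 1, and is invariant to adding a
        constant to every Cq of the gene (the minimum shifts along)."""
        ds = build_dataset({"a": list(cqs)}, efficiencies={"a": e})
        rq = relative_quantities(ds, use_efficiency=True).rq.loc["a"]
        assert rq.max() == 1.0
        assert ((rq > 0) & (rq <= 1)).all()
        shifted = build_dataset({"a": [c + shift + 5 for c in cqs]}, efficiencies={"a": e})
        rq2 = relative_quantities(shifted, use_efficiency=True).rq.loc["a"]
        np.testing.assert_allclose(rq.to_numpy(), rq2.to_numpy(), rtol=1e-9)

    def test_missing_well_recorded(self):
        ds = build_dataset({"a": [20.0, 21.0], "b": [20.0, 21.0]})
        ds.cq = ds.cq[~((ds.cq["gene"] == "b") & (ds.cq["sample"] == "s2"))].reset_index(drop=True)
        rq = relative_quantities(ds)
        assert ("b", "s2") in rq.missing
        assert np.isnan(rq.rq.loc["b", "s2"])

    def test_transform_after_subset_differs_from_before(self, celmisia):
        # Cqmin is subset-relative: the pipeline transforms AFTER subsetting
        ds, _ = celmisia
        collapsed, _ = collapse_replicates(ds)
        veg = subset(collapsed, "fate", "vegetative")
        rq_after = relative_quantities(veg).rq
        rq_before = relative_quantities(collapsed).rq.loc[:, rq_after.columns]
        assert (rq_after.max(axis=1) == 1.0).all()
        assert not np.allclose(rq_after.to_numpy(), rq_before.to_numpy())
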