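"""Event handling, transforms, threshold derivation, gating, summaries."""

import numpy as np
import pandas as pd
import pytest

from ifncyto import cyto, synth
from ifncyto.cyto import (EventTable, GateDefinition, arcsinh_transform,
                          assign_populations, derive_marker_threshold,
                          downsample, leaf_labels, load_gates, read_events,
                          summarize, zero_threshold)
from ifncyto.errors import ConfigError, DataError, SchemaError, StateError


def make_table(values: dict, state="raw", roles=None, **meta):
    return EventTable("S1", "US", pd.DataFrame(values), dict(roles or {}),
                      state, dict(meta))


class TestReadEvents:
    def test_csv_shape(self, tmp_path):
        p = tmp_path / "ev.csv"
        rng = np.random.default_rng(0)
        pd.DataFrame(rng.uniform(0, 100, (100, 5)),
                     columns=list("ABCDE")).to_csv(p, index=False)
        t = read_events(p, sample_id="s", stimulation="IFNa")
        assert t.data.shape == (100, 5)
        assert t.transform_state == "raw"

    def test_marker_map_renames(self, tmp_path):
        p = tmp_path / "ev.csv"
        pd.DataFrame({"Nd148Di": [1.0], "Time": [0.0]}).to_csv(p, index=False)
        t = read_events(p, marker_map={"Nd148Di": "CD25", "Time": "Time"})
        assert "CD25" in t.data.columns

    def test_unmapped_channel_rejected(self, tmp_path):
        p = tmp_path / "ev.csv"
        pd.DataFrame({"X": [1.0], "Y": [2.0]}).to_csv(p, index=False)
        with pytest.raises(SchemaError, match="Y"):
            read_events(p, marker_map={"X": "CD3"})

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "ev.csv"
        pd.DataFrame({"A": []}).to_csv(p, index=False)
        with pytest.raises(DataError):
            read_events(p)


class TestArcsinh:
    def test_fixed_point_and_closed_form(self):
        t = arcsinh_transform(make_table({"CD3": [0.0, 5.0]}))
        assert t.data["CD3"].iloc[0] == 0.0
        assert t.data["CD3"].iloc[1] == pytest.approx(np.log(1 + np.sqrt(2)), abs=1e-12)

    def test_monotone(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0, 1000, 100))
        t = arcsinh_transform(make_table({"CD3": x}))
        assert (np.diff(t.data["CD3"]) > 0).all()

    def test_roundtrip_within_1e9(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 500, 200)
        t = arcsinh_transform(make_table({"CD3": x}))
        back = 5.0 * np.sinh(t.data["CD3"].to_numpy())
        assert np.abs(back - x).max() < 1e-9

    def test_double_transform_rejected(self):
        t = arcsinh_transform(make_table({"CD3": [1.0]}))
        with pytest.raises(StateError):
            arcsinh_transform(t)

    def test_technical_channels_untouched(self):
        t = arcsinh_transform(make_table({"CD3": [5.0], "Time": [5.0]}))
        assert t.data["Time"].iloc[0] == 5.0


class TestZeroThreshold:
    def test_strictly_less_rule(self):
        t = arcsinh_transform(make_table({"CD3": [0.0, 0.0, 2.0]}))
        t.data["CD3"] = [0.124, 0.125, 2.0]
        out = zero_threshold(t)
        assert list(out.data["CD3"]) == [0.0, 0.125, 2.0]

    def test_requires_arcsinh_state(self):
        with pytest.raises(StateError):
            zero_threshold(make_table({"CD3": [1.0]}))


class TestDownsample:
    def test_count_saturation_determinism(self):
        t = make_table({"CD3": np.arange(100.0)})
        assert downsample(t, 10, seed=1).n_cells == 10
        assert downsample(t, 200, seed=1).n_cells == 100
        a = downsample(t, 10, seed=4).data["CD3"].tolist()
        b = downsample(t, 10, seed=4).data["CD3"].tolist()
        assert a == b


class TestMarkerThreshold:
    def test_two_point_masses(self):
        v = np.array([0.1] * 50 + [3.0] * 50)
        cut, degen = derive_marker_threshold(v)
        assert not degen
        assert cut == pytest.approx(1.55, abs=1e-6)

    def test_single_gaussian_degenerate(self):
        rng = np.random.default_rng(5)
        cut, degen = derive_marker_threshold(rng.normal(1.0, 0.1, 500))
        assert degen

    def test_all_identical_degenerate(self):
        cut, degen = derive_marker_threshold(np.full(30, 2.0), fallback=0.5)
        assert degen and cut == 0.5

    def test_mixture_cut_stable(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            v = np.concatenate([rng.normal(0.3, 0.1, 5000),
                                rng.normal(3.0, 0.3, 5000)])
            cut, degen = derive_marker_threshold(v)
            assert not degen
            assert 1.0 < cut < 2.5

    def test_too_few_values_rejected(self):
        with pytest.raises(DataError):
            derive_marker_threshold(np.arange(10.0))


class TestGates:
    def test_constraint_conjunction(self):
        t = make_table({"CD25": [2.0, 2.0], "CD127": [0.2, 1.5]}, state="arcsinh")
        g = [GateDefinition("Treg", (("CD25", "+"), ("CD127", "-")))]
        mem = assign_populations(t, g, {"CD25": 1.0, "CD127": 1.0})
        assert mem["Treg"].tolist() == [True, False]

    def test_boundary_goes_negative(self):
        t = make_table({"CD25": [1.0]}, state="arcsinh")
        g = [GateDefinition("P", (("CD25", "+"),))]
        mem = assign_populations(t, g, {"CD25": 1.0})
        assert not mem["P"].iloc[0]  # tie on the cut is "-"

    def test_parent_chain(self):
        t = make_table({"CD3": [2.0, 2.0, 0.1], "CD4": [2.0, 0.1, 2.0]},
                       state="arcsinh")
        g = [GateDefinition("T", (("CD3", "+"),)),
             GateDefinition("CD4T", (("CD4", "+"),), parent="T")]
        mem = assign_populations(t, g, {"CD3": 1.0, "CD4": 1.0})
        assert mem["CD4T"].tolist() == [True, False, False]

    def test_missing_cut_rejected(self):
        t = make_table({"CD25": [1.0]}, state="arcsinh")
        with pytest.raises(ConfigError, match="CD25"):
            assign_populations(t, [GateDefinition("P", (("CD25", "+"),))], {})

    def test_cycle_rejected(self, tmp_path):
        p = tmp_path / "gates.yaml"
        p.write_text("A: {parent: B, markers: {CD3: '+'}}\n"
                     "B: {parent: A, markers: {CD4: '+'}}\n")
        with pytest.raises(ConfigError, match="cycle"):
            load_gates(p)

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "gates.yaml"
        p.write_text("Treg:\n  parent: CD4_T\n  markers: {CD25: '+', CD127: '-'}\n"
                     "CD4_T:\n  markers: {CD4: '+'}\n")
        gates = load_gates(p)
        byname = {g.name: g for g in gates}
        assert byname["Treg"].parent == "CD4_T"
        assert ("CD127", "-") in byname["Treg"].constraints


class TestSummarize:
    def _gated(self):
        rng = np.random.default_rng(8)
        t = make_table({"CD3": np.where(np.arange(100) < 70, 2.0, 0.1),
                        "pSTAT1": rng.uniform(0, 3, 100)},
                       state="arcsinh", roles={"CD3": "lineage", "pSTAT1": "functional"})
        g = [GateDefinition("T", (("CD3", "+"),))]
        mem = assign_populations(t, g, {"CD3": 1.0})
        return t, mem, g

    def test_abundance_fraction(self):
        t, mem, g = self._gated()
        s = summarize(t, mem, g)
        ab = s[(s["population"] == "T") & (s["stat"] == "abundance")]["value"].iloc[0]
        assert ab == pytest.approx(0.70)

    def test_median_marker_stat(self):
        t = make_table({"CD3": [2.0, 2.0, 2.0], "pSTAT1": [1.0, 2.0, 3.0]},
                       state="arcsinh", roles={"CD3": "lineage", "pSTAT1": "functional"})
        g = [GateDefinition("T", (("CD3", "+"),))]
        mem = assign_populations(t, g, {"CD3": 1.0})
        s = summarize(t, mem, g, min_cells=1)
        med = s[(s["marker"] == "pSTAT1")]["value"].iloc[0]
        assert med == 2.0

    def test_event_order_invariance(self):
        t, mem, g = self._gated()
        s1 = summarize(t, mem, g)
        perm = np.random.default_rng(9).permutation(t.n_cells)
        t2 = EventTable("S1", "US", t.data.iloc[perm].reset_index(drop=True),
                        dict(t.roles), "arcsinh", {})
        mem2 = assign_populations(t2, g, {"CD3": 1.0})
        s2 = summarize(t2, mem2, g)
        pd.testing.assert_frame_equal(
            s1[["population", "marker", "stat", "value", "n_cells"]],
            s2[["population", "marker", "stat", "value", "n_cells"]])

    def test_low_count_flagged(self):
        t, mem, g = self._gated()
        s = summarize(t, mem, g, min_cells=80)
        assert s[s["population"] == "T"]["low_count"].all()


def test_gating_recovers_generator_truth():
    """Well-separated synthetic mixture: per-cell label agreement >= 99%."""
    tables, truth = synth.generate_cytof_events(2, cells_per_sample=2000, seed=21)
    gates = synth.truth_gates()
    markers = sorted({m for g in gates for m, _ in g.constraints})
    agree = []
    for t in tables:
        t = zero_threshold(arcsinh_transform(t))
        cuts = {m: derive_marker_threshold(t.data[m].to_numpy())[0] for m in markers}
        labels = leaf_labels(assign_populations(t, gates, cuts), gates)
        agree.append((labels.values == truth.cell_labels[(t.sample_id, t.stimulation)]).mean())
    assert min(agree) >= 0.99
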