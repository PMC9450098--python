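"""Generator contracts: determinism, truth invariants, count model shape."""

import json

import numpy as np
import pytest

from peakconcord import (
    SimulationConfig,
    generate_dataset,
    jittered_summit_replicates,
    simulate_peak_counts,
    write_fixture_bundle,
)
from peakconcord import io as pio


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(frac_de_genes=1.5), dict(frac_concordant=-0.1),
         dict(accessibility_effect=0.5), dict(replicates_per_condition=0),
         dict(baseline_shift_nonconcordant=0.9), dict(nb_dispersion=-1)],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_dataset(SimulationConfig(n_genes=10, **kwargs))


class TestTruthInvariants:
    def test_zero_effect_zero_de_gives_empty_truth(self):
        cfg = SimulationConfig(seed=1, n_genes=50, frac_de_genes=0.0,
                               accessibility_effect=1.0)
        ds = generate_dataset(cfg)
        assert ds.truth.true_diff_peaks == {}
        assert ds.truth.true_de_genes == {}
        assert set(ds.truth.gene_class.values()) == {"null"}

    def test_every_concordant_de_gene_has_matching_direction_peak(self):
        cfg = SimulationConfig(seed=5, n_genes=500, frac_de_genes=0.2,
                               frac_concordant=1.0)
        ds = generate_dataset(cfg)
        assert len(ds.truth.true_de_genes) == 100
        for gid, (direction, _) in ds.truth.true_de_genes.items():
            assert ds.truth.gene_class[gid] == "concordant"
            dirs = {
                ds.truth.true_diff_peaks[p]
                for p in ds.gene_peaks[gid]
                if p in ds.truth.true_diff_peaks
            }
            assert dirs == {direction}

    def test_nonconcordant_genes_have_no_true_diff_peaks(self):
        cfg = SimulationConfig(seed=6, n_genes=400, frac_de_genes=0.25,
                               frac_concordant=0.4)
        ds = generate_dataset(cfg)
        for gid, klass in ds.truth.gene_class.items():
            if klass == "nonconcordant":
                assert not any(
                    p in ds.truth.true_diff_peaks for p in ds.gene_peaks[gid]
                )

    def test_peaks_map_back_to_their_gene_by_nearest_rule(self, small_dataset):
        from peakconcord import assign_peaks

        asg = assign_peaks(small_dataset.peaks, small_dataset.genes, "nearest")
        got = asg.gene_to_peaks()
        expected = {g: set(p) for g, p in small_dataset.gene_peaks.items() if p}
        assert {g: set(p) for g, p in got.items()} == expected


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        cfg = SimulationConfig(seed=9, n_genes=60)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        np.testing.assert_array_equal(a.atac.values, b.atac.values)
        np.testing.assert_array_equal(a.expression.values, b.expression.values)
        assert a.truth.true_diff_peaks == b.truth.true_diff_peaks

    def test_different_seed_differs(self):
        a = generate_dataset(SimulationConfig(seed=1, n_genes=60))
        b = generate_dataset(SimulationConfig(seed=2, n_genes=60))
        assert not np.array_equal(a.atac.values, b.atac.values)


class TestCountModel:
    def test_overdispersion_exceeds_poisson(self):
        ds = generate_dataset(SimulationConfig(seed=3, n_genes=200,
                                               frac_de_genes=0.0,
                                               nb_dispersion=0.1))
        cols = ds.atac.condition_columns("EtOH-1")
        sub = ds.atac.values[:, cols]
        ratio = (sub.var(axis=1, ddof=1) / sub.mean(axis=1)).mean()
        assert ratio > 2  # expected 1 + alpha*mu = 11

    def test_zero_dispersion_is_poisson_like(self):
        ds = generate_dataset(SimulationConfig(seed=3, n_genes=200,
                                               frac_de_genes=0.0,
                                               nb_dispersion=0.0))
        cols = ds.atac.condition_columns("EtOH-1")
        sub = ds.atac.values[:, cols]
        ratio = (sub.var(axis=1, ddof=1) / sub.mean(axis=1)).mean()
        assert ratio == pytest.approx(1.0, abs=0.15)

    def test_monotone_dose_response_for_up_peaks(self):
        ds = generate_dataset(SimulationConfig(seed=4, n_genes=300,
                                               frac_de_genes=0.3,
                                               frac_concordant=1.0))
        up = [p for p, d in ds.truth.true_diff_peaks.items() if d == "up"]
        rows = ds.atac.row_indexer(up)
        means = [ds.atac.values[rows][:, ds.atac.condition_columns(c)].mean()
                 for c in ["EtOH-1", "dose-1", "dose-2", "dose-3"]]
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_baseline_shift_on_nonconcordant_gene_peaks(self):
        ds = generate_dataset(SimulationConfig(
            seed=8, n_genes=400, frac_de_genes=0.3, frac_concordant=0.5,
            baseline_shift_nonconcordant=2.0))
        ctrl = ds.atac.values[:, ds.atac.condition_columns("EtOH-1")].mean(axis=1)
        by_peak = dict(zip(ds.atac.row_ids, ctrl))
        conc, nonc = [], []
        for gid, klass in ds.truth.gene_class.items():
            if klass == "concordant":
                conc += [by_peak[p] for p in ds.gene_peaks[gid]]
            elif klass == "nonconcordant":
                nonc += [by_peak[p] for p in ds.gene_peaks[gid]]
        assert np.median(nonc) / np.median(conc) == pytest.approx(2.0, rel=0.15)

    def test_depth_factors_scale_column_totals(self):
        n_samples = 18
        depth = np.linspace(0.5, 1.5, n_samples)
        ds = generate_dataset(SimulationConfig(seed=2, n_genes=200,
                                               frac_de_genes=0.0,
                                               depth_factors=depth))
        totals = ds.atac.values.sum(axis=0)
        ratio = totals / totals.mean()
        np.testing.assert_allclose(ratio, depth / depth.mean(), rtol=0.05)


class TestPeakLevelSimulator:
    def test_truth_size_and_layout(self):
        m, truth = simulate_peak_counts(500, 20, seed=0)
        assert m.shape == (500, 15)
        assert len(truth) == 20
        assert sum(s.role == "control" for s in m.samples) == 9

    def test_effect_applies_only_to_true_peaks_in_experiment(self):
        m, truth = simulate_peak_counts(2000, 100, effect=4.0, seed=1)
        rows = m.row_indexer(sorted(truth))
        exp_cols = [i for i, s in enumerate(m.samples) if s.role == "experimental"]
        ctl_cols = [i for i, s in enumerate(m.samples) if s.role == "control"]
        ratio = (m.values[rows][:, exp_cols].mean()
                 / m.values[rows][:, ctl_cols].mean())
        assert ratio == pytest.approx(4.0, rel=0.1)


class TestFixtureBundle:
    def test_bundle_round_trip_and_checksums(self, tmp_path):
        cfg = SimulationConfig(seed=12, n_genes=20)
        ds = generate_dataset(cfg)
        out = tmp_path / "bundle"
        manifest_path = write_fixture_bundle(ds, str(out))
        manifest = json.loads((out / "manifest.json").read_text())
        assert len(manifest["files"]) == 6
        atac = pio.parse_count_matrix(str(out / "atac_counts.tsv"),
                                      str(out / "samples.tsv"))
        np.testing.assert_array_equal(atac.values, ds.atac.values)
        genes = pio.parse_gene_table(str(out / "genes.tsv"))
        assert genes == ds.genes
        truth = json.loads((out / "truth.json").read_text())
        assert truth["true_diff_peaks"] == ds.truth.true_diff_peaks
        # identical seed -> identical checksums
        out2 = tmp_path / "bundle2"
        write_fixture_bundle(generate_dataset(cfg), str(out2))
        manifest2 = json.loads((out2 / "manifest.json").read_text())
        assert manifest["files"] == manifest2["files"]
        assert manifest_path.endswith("manifest.json")

    def test_refuses_nonempty_dir_without_force(self, tmp_path):
        ds = generate_dataset(SimulationConfig(seed=1, n_genes=5))
        out = tmp_path / "bundle"
        write_fixture_bundle(ds, str(out))
        with pytest.raises(FileExistsError):
            write_fixture_bundle(ds, str(out))
        write_fixture_bundle(ds, str(out), force=True)  # explicit overwrite ok


class TestSummitJitter:
    def test_jitter_bounds_and_dropout(self, small_dataset):
        peaks = small_dataset.peaks[:50]
        reps = jittered_summit_replicates(peaks, n_replicates=3, jitter=10,
                                          dropout=0.3, seed=1)
        assert len(reps) == 3
        assert any(len(r) < len(peaks) for r in reps)
        mids = sorted(p.midpoint for p in peaks)
        for rep in reps:
            for s in rep:
                assert s.width == 1
                assert min(abs(s.start - m) for m in mids) <= 10
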