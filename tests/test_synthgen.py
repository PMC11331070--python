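"""Synthetic-data generator: determinism, spatial law, survival law,
rescue semantics, Mendelian genotype oracle, round trips."""

import numpy as np
import pandas as pd
import pytest

from metahet import synthgen
from metahet.synthgen import GeneratorConfig, generate_patches, write_dataset, read_dataset


class TestConfig:
    def test_invalid_extent_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(extent_km=(0.0, 10.0))

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(founder_maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            GeneratorConfig(founder_maf_range=(0.2, 0.7))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="n_years"):
            GeneratorConfig(n_years=2)

    def test_dict_round_trip(self):
        cfg = GeneratorConfig(seed=7, n_patches=50)
        assert GeneratorConfig.from_dict(cfg.to_dict()) == cfg


class TestPatches:
    def test_coordinates_inside_extent(self):
        cfg = GeneratorConfig(n_patches=100, seed=1)
        p = generate_patches(cfg)
        assert len(p) == 100
        assert p["x_km"].between(0, cfg.extent_km[0]).all()
        assert p["y_km"].between(0, cfg.extent_km[1]).all()
        assert p["host_abundance"].isin([1, 2, 3]).all()
        assert (p["area"] > 0).all()

    def test_deterministic(self):
        cfg = GeneratorConfig(n_patches=100, seed=1)
        pd.testing.assert_frame_equal(generate_patches(cfg), generate_patches(cfg))

    def test_nearest_neighbour_distance_matches_poisson_expectation(self):
        """Uniform placement: mean NN distance ~ 0.5/sqrt(density)."""
        cfg = GeneratorConfig(n_patches=4000, extent_km=(50.0, 70.0), seed=2)
        p = generate_patches(cfg)
        xy = p[["x_km", "y_km"]].to_numpy()
        d = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        observed = d.min(axis=1).mean()
        expected = 0.5 / np.sqrt(4000 / (50 * 70))
        assert observed == pytest.approx(expected, rel=0.10)


class TestDynamics:
    def test_identical_seed_identical_outputs(self, small_config):
        a = synthgen.simulate(small_config)
        b = synthgen.simulate(small_config)
        pd.testing.assert_frame_equal(a.survey, b.survey)
        pd.testing.assert_frame_equal(a.nests, b.nests)
        np.testing.assert_array_equal(a.genotypes.calls, b.genotypes.calls)

    def test_different_seeds_differ(self, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        a, b = synthgen.simulate(small_config), synthgen.simulate(other)
        assert not np.array_equal(a.genotypes.calls, b.genotypes.calls)

    def test_spring_never_exceeds_fall(self, small_dataset):
        fall = small_dataset.survey[small_dataset.survey["season"] == "fall"]
        spring = small_dataset.survey[small_dataset.survey["season"] == "spring"]
        merged = fall.merge(spring, on=["patch_id", "year"], suffixes=("_f", "_s"))
        assert (merged["nest_count_s"] <= merged["nest_count_f"]).all()

    def test_nest_table_consistent_with_survey(self, small_dataset):
        counts = small_dataset.nests.groupby(["patch_id", "year"]).size()
        fall = small_dataset.survey[
            (small_dataset.survey["season"] == "fall")
            & (small_dataset.survey["nest_count"] > 0)
        ].set_index(["patch_id", "year"])["nest_count"]
        pd.testing.assert_series_equal(
            counts.sort_index(), fall.sort_index(), check_names=False,
            check_dtype=False,
        )

    def test_survival_decile_law(self, default_dataset):
        """Net of patch catastrophes, nest survival follows S0*exp(-B*F)."""
        cfg = default_dataset.config
        nests = default_dataset.nests[default_dataset.nests["patch_catastrophe"] == 0]
        dec = pd.qcut(nests["f_true"], 10, duplicates="drop")
        g = nests.groupby(dec, observed=True).agg(
            surv=("survived_overwinter", "mean"),
            f=("f_true", "mean"),
            n=("nest_id", "count"),
        )
        pred = cfg.s0 * np.exp(-cfg.b_true * g["f"])
        z = (g["surv"] - pred) / np.sqrt(pred * (1 - pred) / g["n"])
        assert (z.abs() < 3).all()

    def test_no_load_survival_at_baseline(self):
        ds = synthgen.simulate(GeneratorConfig(seed=3, b_true=0.0))
        nests = ds.nests[ds.nests["patch_catastrophe"] == 0]
        p = nests["survived_overwinter"].mean()
        se = np.sqrt(0.7 * 0.3 / len(nests))
        assert abs(p - ds.config.s0) < 2 * se + 0.01

    @staticmethod
    def extinction_counts(ds):
        fall = ds.survey[ds.survey["season"] == "fall"].pivot_table(
            index="patch_id", columns="year", values="nest_count"
        )
        spring = ds.survey[ds.survey["season"] == "spring"].pivot_table(
            index="patch_id", columns="year", values="nest_count"
        )
        ow = ann = 0
        mismatches = 0
        for t in fall.columns[:-1]:
            occ = fall[t] > 0
            ow_t = (spring[t] == 0) & occ
            ann_t = (fall[t + 1] == 0) & occ
            ow += ow_t.sum()
            ann += ann_t.sum()
            mismatches += (ow_t != ann_t).sum()
        return ow, ann, mismatches

    def test_rescue_off_extinctions_coincide_patchwise(self):
        ds = synthgen.simulate(GeneratorConfig(seed=5, rescue_scale=0.0))
        ow, ann, mism = self.extinction_counts(ds)
        assert mism == 0
        assert ow == ann

    def test_rescue_on_annual_below_overwinter(self):
        ds = synthgen.simulate(GeneratorConfig(seed=5, rescue_scale=1.0))
        ow, ann, _ = self.extinction_counts(ds)
        assert ann < ow


class TestGenotypes:
    def test_codes_and_shape(self, small_dataset):
        gt = small_dataset.genotypes
        assert gt.calls.shape[1] == small_dataset.config.n_loci
        assert set(np.unique(gt.calls)) <= {-1, 0, 1, 2}

    def test_three_larvae_per_nest(self, small_dataset):
        sizes = small_dataset.genotypes.meta.groupby("nest_id").size()
        assert (sizes == small_dataset.config.larvae_genotyped_per_nest).all()

    def test_merged_fraction_about_nominal(self, default_dataset):
        frac = (default_dataset.nests["n_families"] > 1).mean()
        nominal = default_dataset.config.merged_nest_fraction
        se = np.sqrt(nominal * (1 - nominal) / len(default_dataset.nests))
        assert abs(frac - nominal) < 4 * se

    def test_missingness_rate_about_nominal(self, default_dataset):
        gt = default_dataset.genotypes
        rate = (gt.calls == -1).mean()
        assert rate == pytest.approx(default_dataset.config.missing_call_rate, abs=0.005)

    def test_mendelian_offspring_heterozygosity(self):
        """At F=0 the offspring heterozygote fraction matches the Mendelian
        expectation averaged over the nine parental genotype pairs (oracle:
        exact enumeration under Hardy-Weinberg parents)."""
        p = 0.3
        # enumeration: parent genotype probs under HW
        gp = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p**2}
        het_exp = 0.0
        for g1, w1 in gp.items():
            for g2, w2 in gp.items():
                # offspring heterozygous iff alleles differ
                p1 = g1 / 2  # P(transmit alt) from parent 1
                p2 = g2 / 2
                het_exp += w1 * w2 * (p1 * (1 - p2) + (1 - p1) * p2)
        assert het_exp == pytest.approx(2 * p * (1 - p), abs=1e-12)

        # simulate many F=0 nests at fixed allele frequency via the
        # generator's genotype machinery
        cfg = GeneratorConfig(
            n_patches=10, n_years=3, n_loci=400, seed=13, b_true=0.0,
            merged_nest_fraction=0.0, missing_call_rate=0.0, f_noise_sd=0.0,
            founder_maf_range=(p, p), burn_in=0, pool_anchor=1.0,
        )
        ds = synthgen.simulate(cfg)
        # restrict to nests with F = 0 exactly (freshly colonized patches)
        zero = ds.nests.loc[ds.nests["f_true"] == 0.0, "nest_id"]
        gt = ds.genotypes
        mask = gt.meta["nest_id"].isin(set(zero)).to_numpy()
        calls = gt.calls[mask]
        if calls.size:
            ho = (calls == 1).mean()
            n = calls.size
            # patch frequencies drift away from p after founding, inflating
            # the variance; generous MC tolerance on the binomial SE
            assert abs(ho - het_exp) < 0.05


class TestIO:
    def test_write_read_round_trip(self, small_dataset, tmp_path):
        write_dataset(small_dataset, tmp_path)
        back = read_dataset(tmp_path)
        pd.testing.assert_frame_equal(
            back.survey, small_dataset.survey, check_dtype=False
        )
        pd.testing.assert_frame_equal(
            back.nests[["nest_id", "patch_id", "year", "n_families"]],
            small_dataset.nests[["nest_id", "patch_id", "year", "n_families"]],
            check_dtype=False,
        )
        np.testing.assert_array_equal(back.genotypes.calls, small_dataset.genotypes.calls)
        assert back.config == small_dataset.config

    def test_provenance_records_seed(self, small_dataset, tmp_path):
        import yaml

        write_dataset(small_dataset, tmp_path)
        prov = yaml.safe_load((tmp_path / "provenance.yaml").read_text())
        assert prov["seed"] == small_dataset.config.seed

    def test_two_seeds_different_genotype_files(self, small_config, tmp_path):
        import dataclasses

        a = synthgen.simulate(small_config)
        b = synthgen.simulate(dataclasses.replace(small_config, seed=99))
        write_dataset(a, tmp_path / "a")
        write_dataset(b, tmp_path / "b")
        assert (tmp_path / "a" / "genotypes.csv").read_text() != (
            tmp_path / "b" / "genotypes.csv"
        ).read_text()
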